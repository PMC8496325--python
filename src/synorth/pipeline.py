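"""End-to-end orchestration of the four pipeline stages.

``run_pipeline`` wires the stages together — parse inputs, build tandem
arrays and ploidy-filtered tethers, score and filter the collinear
blocks, trim/split them to the fixed point, assemble and decompose the
gene graph — and writes every report file under one output prefix.
``run_comparison`` compares two finished runs (typically the unsplit,
ploidy-aware run against an a-priori subgenome split) after species-label
normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from synorth.errors import DataError
from synorth.formats_io import (
    NameMap,
    read_collinearity,
    read_gene_positions,
    read_orthogroups,
    read_ploidy,
    read_tandem,
)
from synorth.network import (
    ComparisonReport,
    GroupSummary,
    OrthoGroup,
    build_graph,
    compare_group_sets,
    connected_components,
    normalize_groups,
    summarize_groups,
    write_groups,
)
from synorth.scoring import block_passes, score_block, write_block_stats
from synorth.tethers import (
    TetherIndex,
    build_tandem_arrays,
    build_tethers,
    write_tether_report,
)
from synorth.trimming import refine_blocks, write_trim_log, write_used_blocks

log = logging.getLogger("synorth")


@dataclass
class RunConfig:
    """Inputs and output prefix for one pipeline run."""

    positions: str | Path
    orthogroups: str | Path
    collinearity: str | Path
    tandem: str | Path
    out_prefix: str | Path
    translation: str | Path | None = None
    ploidy: str | Path | None = None

    def check_paths(self) -> None:
        for name in ("positions", "orthogroups", "collinearity", "tandem"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise DataError(f"{name} file not found: {path}")
        for name in ("translation", "ploidy"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise DataError(f"{name} file not found: {value}")


@dataclass
class PipelineResult:
    groups: list[OrthoGroup]
    summary: GroupSummary
    registry: object
    name_map: NameMap | None
    species: list[str]
    ploidy: dict[str, int]
    stage_counts: dict[str, int]
    paths: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run all four stages and write the report files.

    On any error, partially written outputs are removed before the
    exception propagates.
    """
    config.check_paths()
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _out(suffix: str) -> Path:
        path = Path(f"{prefix}{suffix}")
        written.append(path)
        return path

    try:
        name_map = NameMap.read(config.translation) if config.translation else None
        registry = read_gene_positions(config.positions, name_map)
        ploidy = read_ploidy(config.ploidy, registry.species)
        log.info("loaded %d genes across %d species", len(registry), len(registry.species))

        orthogroups = read_orthogroups(config.orthogroups, name_map)
        tandem = read_tandem(config.tandem, registry)
        arrays, array_of = build_tandem_arrays(tandem, registry)
        tethers = build_tethers(orthogroups, array_of, ploidy)
        index = TetherIndex(tethers)
        log.info(
            "stage 1: %d orthogroups -> %d tethers (%d tandem arrays of size >= 2)",
            len(orthogroups),
            len(tethers),
            sum(1 for a in arrays if len(a) > 1),
        )
        write_tether_report(orthogroups, tethers, array_of, _out(".tethers.tsv"))

        collinearity = read_collinearity(config.collinearity)
        scored = [score_block(b, index, registry) for b in collinearity.blocks]
        kept = [b for b in scored if block_passes(b)]
        log.info("stage 2: %d blocks scored, %d pass the filter", len(scored), len(kept))

        survivors, actions = refine_blocks(kept)
        log.info("stage 3: %d blocks survive trimming/splitting", len(survivors))
        # a parent that was split is reported through its surviving children
        write_block_stats(scored, {b.block_id.split(".")[0] for b in survivors}, _out(".block_stats.tsv"))
        write_trim_log(actions, _out(".trim_log.tsv"))
        write_used_blocks(survivors, _out(".used_blocks.txt"))

        graph = build_graph(survivors, arrays, registry)
        groups = connected_components(graph, registry)
        summary = summarize_groups(groups, array_of, ploidy, registry.species)
        log.info(
            "stage 4: %d edges -> %d orthogroups (%d singleton, %d tether, %d species-specific)",
            graph.number_of_edges(),
            summary.totals["total_groups"],
            summary.totals["singleton_groups"],
            summary.totals["tether_groups"],
            summary.totals["species_specific_groups"],
        )

        write_groups(groups, registry.species, _out(".orthogroups.tsv"))
        if name_map is not None:
            write_groups(
                groups,
                registry.species,
                _out(".orthogroups.named.tsv"),
                rename=name_map.to_original,
            )
        summary.per_group.to_csv(_out(".gene_counts.tsv"), sep="\t", index=False)
        summary.per_group_genesets.to_csv(_out(".geneset_counts.tsv"), sep="\t", index=False)
        with _out(".summary.tsv").open("w") as fh:
            for key, value in summary.totals.items():
                fh.write(f"{key}\t{value}\n")

        stage_counts = {
            "genes": len(registry),
            "orthogroups_in": len(orthogroups),
            "tethers": len(tethers),
            "blocks_in": len(scored),
            "blocks_passing": len(kept),
            "blocks_surviving": len(survivors),
            "edges": graph.number_of_edges(),
            **summary.totals,
        }
        return PipelineResult(
            groups=groups,
            summary=summary,
            registry=registry,
            name_map=name_map,
            species=registry.species,
            ploidy=ploidy,
            stage_counts=stage_counts,
            paths={p.name: p for p in written},
        )
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def run_comparison(
    result_a: PipelineResult,
    result_b: PipelineResult,
    species_map: Mapping[str, str],
    out_path: str | Path | None = None,
) -> ComparisonReport:
    """Compare two runs' orthogroups after species-label normalization.

    ``species_map`` must cover every species of both runs (identity
    entries for labels that do not change).  Genes are compared by their
    original annotation IDs, which are mode-independent.
    """
    for res in (result_a, result_b):
        missing = [sp for sp in res.species if sp not in species_map]
        if missing:
            raise DataError(f"species map does not cover: {', '.join(missing)}")

    def _rename(res: PipelineResult):
        if res.name_map is None:
            return lambda g: g
        return res.name_map.to_original

    def _universe(res: PipelineResult) -> set[str]:
        return {rec.original_name for rec in res.registry.records.values()}

    norm_a = normalize_groups(result_a.groups, species_map, _rename(result_a))
    norm_b = normalize_groups(result_b.groups, species_map, _rename(result_b))
    report = compare_group_sets(norm_a, norm_b, _universe(result_a), _universe(result_b))
    if out_path is not None:
        with Path(out_path).open("w") as fh:
            fh.write(f"groups_run1\t{report.n_groups_run1}\n")
            fh.write(f"groups_run2\t{report.n_groups_run2}\n")
            fh.write(f"identical_groups\t{report.n_identical}\n")
            fh.write(f"identical_fraction\t{report.identical_fraction:.4f}\n")
            fh.write(f"unique_to_run1\t{report.n_unique_run1}\n")
            fh.write(f"unique_to_run2\t{report.n_unique_run2}\n")
            fh.write(f"overlap_clusters\t{len(report.clusters)}\n")
            fh.write(f"conflicting_clusters\t{report.n_conflicting}\n")
            fh.write(f"complementary_clusters\t{report.n_complementary}\n")
            for c in report.clusters:
                fh.write(
                    f"cluster\t{c.kind}\trun1:{';'.join(c.groups_run1)}\t"
                    f"run2:{';'.join(c.groups_run2)}\n"
                )
    return report
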