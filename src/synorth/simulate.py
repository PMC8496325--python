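"""Synthetic multi-genome datasets with planted orthology ground truth.

The generator emulates the study design the pipeline targets: a
caterpillar tree of three diploid genomes (an outgroup plus the two
model progenitors) and one allotetraploid whose genome is the union of
two progenitor-derived subgenomes.  Each lineage evolves from a shared
ancestral gene order through gene loss, tandem duplication, segmental
inversion and translocation; the emitted files are exactly the dialects
the pipeline reads (GFF3 + protein FASTA, orthogroup table, MCScanX-style
collinearity and tandem files, ploidy table), and every emitted gene is
traceable to one ancestral gene in the truth table.

Collinearity blocks are emitted pre-chained — the generator writes what
a pairwise collinearity caller would output on these genomes (monotone
runs of shared-ancestor anchors, minimum five anchors per block, broken
at inversion and translocation boundaries) — since running such a caller
is out of scope.  The orthogroup table can be perturbed with the two
failure modes a similarity-based grouper exhibits: merging two groups or
dropping a gene.

The polyploid can be emitted *unsplit* (one species with relative ploidy
2) or *a-priori split* (each subgenome its own diploid species); lineage
evolution is keyed only by the seed and the lineage, so the two modes
describe the identical underlying genomes and differ only in species
labeling.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from synorth.errors import DataError
from synorth.formats_io import (
    CollinearityFile,
    NameMap,
    RawBlock,
    TandemFile,
    translate_gff,
    write_collinearity,
    write_tandem,
)
from synorth.network import OrthoGroup

LINEAGES = ("outg", "dipA", "dipD", "tetA", "tetD")
_CHROM_PREFIX = {"outg": "oc", "dipA": "ac", "dipD": "dc", "tetA": "tAc", "tetD": "tDc"}
_MIN_BLOCK_ANCHORS = 5
_AA = "ACDEFGHIKLMNPQRSTVWY"


class SimGene(NamedTuple):
    anc: int  # ancestral gene id
    copy: int  # 0 = primary copy, >0 = tandem duplicate
    name: str  # original (annotation) gene id


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a small but realistic four-taxon analysis: two
    chromosomes of 250 genes per diploid genome (the tetraploid carries
    both subgenomes, so twice that), no noise.  Rates are per gene per
    lineage; ``orthogroup_noise`` is the probability that a true group is
    corrupted in the emitted orthogroup table.
    """

    n_chromosomes: int = 2
    genes_per_chromosome: int = 250
    tandem_rate: float = 0.0
    loss_rate: float = 0.0
    n_inversions: int = 0
    n_translocations: int = 0
    orthogroup_noise: float = 0.0
    split_polyploid: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("tandem_rate", "loss_rate", "orthogroup_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise DataError("need at least one chromosome with one gene")
        if self.n_inversions < 0 or self.n_translocations < 0:
            raise DataError("event counts must be non-negative")
        segments = self.n_inversions + self.n_translocations
        if segments * 5 > self.n_chromosomes * self.genes_per_chromosome:
            raise DataError("more rearranged segments than the genome can hold")


@dataclass
class TruthTable:
    """Planted ground truth: orthogroups, tandem arrays, per-species copies."""

    groups: dict[int, dict[str, list[str]]]  # anc -> species label -> original names
    arrays: list[list[str]]  # original names, arrays of size >= 2 only
    species: list[str]

    def planted_groups(self, min_genes: int = 2) -> list[frozenset[str]]:
        """Planted groups (as original-name sets) with >= min_genes genes."""
        out = []
        for anc in sorted(self.groups):
            members = self.groups[anc]
            genes = [g for gl in members.values() for g in gl]
            if len(genes) >= min_genes:
                out.append(frozenset(genes))
        return out

    def survivor_count(self, species: str) -> int:
        return sum(len(m.get(species, [])) for m in self.groups.values())


@dataclass
class SimResult:
    config: SimConfig
    species: list[str]
    truth: TruthTable
    name_map: NameMap
    positions_path: Path
    name_map_path: Path
    orthogroups_path: Path
    collinearity_path: Path
    tandem_path: Path
    ploidy_path: Path
    gff_paths: dict[str, Path] = field(default_factory=dict)
    fasta_paths: dict[str, Path] = field(default_factory=dict)


def _evolve_lineage(config: SimConfig, lineage: str) -> list[list[SimGene]]:
    """One lineage's genome: per-chromosome ordered gene lists."""
    li = LINEAGES.index(lineage)
    rng = np.random.default_rng([config.seed % 2**31, li])
    n_chr, n_genes = config.n_chromosomes, config.genes_per_chromosome
    chroms: list[list[SimGene]] = []
    for c in range(n_chr):
        genes = []
        for i in range(n_genes):
            anc = c * n_genes + i
            if config.loss_rate > 0 and rng.random() < config.loss_rate:
                continue
            genes.append(SimGene(anc, 0, f"{lineage}G{anc:05d}"))
        chroms.append(genes)
    if config.tandem_rate > 0:
        for c in range(n_chr):
            out = []
            for g in chroms[c]:
                out.append(g)
                if rng.random() < config.tandem_rate:
                    out.append(SimGene(g.anc, 1, f"{g.name}d1"))
            chroms[c] = out
    for _ in range(config.n_inversions):
        c = int(rng.integers(n_chr))
        if len(chroms[c]) < 6:
            continue
        length = int(rng.integers(5, min(31, len(chroms[c]))))
        start = int(rng.integers(0, len(chroms[c]) - length + 1))
        chroms[c][start : start + length] = chroms[c][start : start + length][::-1]
    for _ in range(config.n_translocations):
        src = int(rng.integers(n_chr))
        if len(chroms[src]) < 6:
            continue
        length = int(rng.integers(5, min(31, len(chroms[src]))))
        start = int(rng.integers(0, len(chroms[src]) - length + 1))
        segment = chroms[src][start : start + length]
        del chroms[src][start : start + length]
        dst = int(rng.integers(n_chr))
        pos = int(rng.integers(0, len(chroms[dst]) + 1))
        chroms[dst][pos:pos] = segment
    return chroms


def _species_layout(split: bool) -> dict[str, list[str]]:
    """Species label -> constituent lineages, in emission order."""
    if split:
        return {
            "dipA": ["dipA"],
            "dipD": ["dipD"],
            "outg": ["outg"],
            "tetAD_At": ["tetA"],
            "tetAD_Dt": ["tetD"],
        }
    return {
        "dipA": ["dipA"],
        "dipD": ["dipD"],
        "outg": ["outg"],
        "tetAD": ["tetA", "tetD"],
    }


def _protein_seq(name: str, length: int = 60) -> str:
    digest = hashlib.md5(name.encode()).digest() * ((length // 16) + 1)
    return "M" + "".join(_AA[b % len(_AA)] for b in digest[: length - 1])


def _write_gff3(path: Path, rows: list[tuple[str, str, int, int]]) -> None:
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, gid, start, end in rows:
            fh.write(
                f"{chrom}\tsynorth_sim\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n"
            )


def _chained_blocks(
    order_x: dict[int, tuple[str, int, str]],
    order_y: dict[int, tuple[str, int, str]],
) -> list[tuple[str, str, str, list[tuple[str, str]]]]:
    """Monotone anchor runs between two genomes.

    ``order_*`` maps ancestral id -> (chrom, position, gene name) for
    primary copies.  Returns (chrom_x, chrom_y, orientation, [(name_x,
    name_y), ...]) runs with >= _MIN_BLOCK_ANCHORS anchors, broken where
    the partner's anchor rank is not contiguous (inversion/translocation
    boundaries).
    """
    common = sorted(set(order_x) & set(order_y))
    by_chrom: dict[tuple[str, str], list[int]] = {}
    for anc in common:
        key = (order_x[anc][0], order_y[anc][0])
        by_chrom.setdefault(key, []).append(anc)
    blocks = []
    for (cx, cy), ancs in sorted(by_chrom.items()):
        ancs_by_x = sorted(ancs, key=lambda a: order_x[a][1])
        rank_y = {
            a: r
            for r, a in enumerate(sorted(ancs, key=lambda a: order_y[a][1]))
        }
        run: list[int] = []
        direction = 0

        def _flush():
            if len(run) >= _MIN_BLOCK_ANCHORS:
                orient = "minus" if direction < 0 else "plus"
                blocks.append(
                    (
                        cx,
                        cy,
                        orient,
                        [(order_x[a][2], order_y[a][2]) for a in run],
                    )
                )

        for anc in ancs_by_x:
            if not run:
                run.append(anc)
                direction = 0
                continue
            step = rank_y[anc] - rank_y[run[-1]]
            if direction == 0 and step in (1, -1):
                direction = step
                run.append(anc)
            elif direction != 0 and step == direction:
                run.append(anc)
            else:
                _flush()
                run = [anc]
                direction = 0
        _flush()
    return blocks


def simulate(config: SimConfig, out_dir: str | Path) -> SimResult:
    """Generate one dataset under ``config`` and write all input files.

    Deterministic: the seed fully determines every emitted byte.  The
    same seed with ``split_polyploid`` toggled describes the identical
    genomes under the two species labelings.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    lineage_genomes = {lg: _evolve_lineage(config, lg) for lg in LINEAGES}
    layout = _species_layout(config.split_polyploid)
    species = list(layout)

    # --- annotation (GFF3 + FASTA) per species --------------------------
    ann_dir = out_dir / "annotation"
    ann_dir.mkdir(exist_ok=True)
    gff_paths: dict[str, Path] = {}
    fasta_paths: dict[str, Path] = {}
    for sp, lineages in layout.items():
        rows = []
        for lg in lineages:
            for c, genes in enumerate(lineage_genomes[lg]):
                chrom = f"{_CHROM_PREFIX[lg]}{c + 1}"
                for pos, g in enumerate(genes):
                    start = pos * 1000 + 1
                    rows.append((chrom, g.name, start, start + 899))
        gff = ann_dir / f"{sp}.gff3"
        _write_gff3(gff, rows)
        fasta = ann_dir / f"{sp}.fasta"
        with fasta.open("w") as fh:
            for _, gid, _, _ in rows:
                fh.write(f">{gid}\n{_protein_seq(gid)}\n")
        gff_paths[sp] = gff
        fasta_paths[sp] = fasta

    # --- canonical naming through the real translation path -------------
    trans_dir = out_dir / "translated"
    positions_path, _, name_map = translate_gff(
        [gff_paths[sp] for sp in species],
        [fasta_paths[sp] for sp in species],
        trans_dir,
        species_labels=species,
    )

    species_of_lineage = {
        lg: sp for sp, lgs in layout.items() for lg in lgs
    }

    # --- truth table -----------------------------------------------------
    groups: dict[int, dict[str, list[str]]] = {}
    arrays: list[list[str]] = []
    for lg in LINEAGES:
        sp = species_of_lineage[lg]
        for genes in lineage_genomes[lg]:
            prev: SimGene | None = None
            for g in genes:
                groups.setdefault(g.anc, {}).setdefault(sp, []).append(g.name)
                if prev is not None and g.anc == prev.anc and g.copy == prev.copy + 1:
                    if arrays and arrays[-1][-1] == prev.name:
                        arrays[-1].append(g.name)
                    else:
                        arrays.append([prev.name, g.name])
                prev = g
    for members in groups.values():
        for sp in members:
            members[sp].sort()
    truth = TruthTable(groups=groups, arrays=arrays, species=species)

    # --- tandem file ------------------------------------------------------
    tandem_pairs = [
        (name_map.to_canonical(a), name_map.to_canonical(b))
        for arr in arrays
        for a, b in zip(arr, arr[1:])
    ]
    tandem_path = out_dir / "genes.tandem"
    write_tandem(TandemFile(pairs=tandem_pairs), tandem_path)

    # --- collinearity file ------------------------------------------------
    raw_blocks: list[RawBlock] = []
    orders: dict[str, dict[int, tuple[str, int, str]]] = {}
    for lg in LINEAGES:
        order: dict[int, tuple[str, int, str]] = {}
        for c, genes in enumerate(lineage_genomes[lg]):
            chrom = f"{_CHROM_PREFIX[lg]}{c + 1}"
            for pos, g in enumerate(genes):
                if g.copy == 0:
                    order[g.anc] = (chrom, pos, g.name)
        orders[lg] = order
    block_no = 0
    for i, lx in enumerate(LINEAGES):
        for ly in LINEAGES[i + 1 :]:
            for cx, cy, orient, pairs in _chained_blocks(orders[lx], orders[ly]):
                raw_blocks.append(
                    RawBlock(
                        block_id=str(block_no),
                        chrom_a=cx,
                        chrom_b=cy,
                        orientation=orient,
                        species_a="",
                        species_b="",
                        pairs=[
                            (name_map.to_canonical(a), name_map.to_canonical(b), 1e-50)
                            for a, b in pairs
                        ],
                        score=float(len(pairs) * 50),
                    )
                )
                block_no += 1
    collinearity_path = out_dir / "genes.collinearity"
    write_collinearity(CollinearityFile(blocks=raw_blocks), collinearity_path)

    # --- orthogroup table (optionally perturbed) --------------------------
    rng = np.random.default_rng([config.seed % 2**31, 97])
    emitted: list[tuple[str, dict[str, list[str]]]] = []
    for anc in sorted(groups):
        members = {sp: list(groups[anc].get(sp, [])) for sp in species}
        if sum(len(v) for v in members.values()) < 2:
            continue  # singleton genes stay unassigned, as a similarity grouper would
        emitted.append((f"OG{anc:07d}", members))
    if config.orthogroup_noise > 0:
        perturbed: list[tuple[str, dict[str, list[str]]]] = []
        pending_merge: dict[str, list[str]] | None = None
        for og_id, members in emitted:
            if pending_merge is not None:
                for sp, genes in pending_merge.items():
                    members[sp] = sorted(members[sp] + genes)
                pending_merge = None
            if rng.random() < config.orthogroup_noise:
                if rng.random() < 0.5:
                    pending_merge = members
                    continue
                flat = sorted(g for gl in members.values() for g in gl)
                victim = flat[int(rng.integers(len(flat)))]
                members = {
                    sp: [g for g in gl if g != victim] for sp, gl in members.items()
                }
            perturbed.append((og_id, members))
        if pending_merge is not None:
            perturbed.append(("OGmerged", pending_merge))
        emitted = perturbed
    orthogroups_path = out_dir / "orthogroups.tsv"
    with orthogroups_path.open("w") as fh:
        fh.write("Orthogroup\t" + "\t".join(species) + "\n")
        for og_id, members in emitted:
            cells = [", ".join(members.get(sp, [])) for sp in species]
            fh.write(og_id + "\t" + "\t".join(cells) + "\n")

    # --- ploidy table ------------------------------------------------------
    ploidy_path = out_dir / "ploidy.tsv"
    with ploidy_path.open("w") as fh:
        for sp in species:
            mult = 2 if sp == "tetAD" else 1
            fh.write(f"{sp}\t{mult}\n")

    return SimResult(
        config=config,
        species=species,
        truth=truth,
        name_map=name_map,
        positions_path=positions_path,
        name_map_path=trans_dir / "name_map.tsv",
        orthogroups_path=orthogroups_path,
        collinearity_path=collinearity_path,
        tandem_path=tandem_path,
        ploidy_path=ploidy_path,
        gff_paths=gff_paths,
        fasta_paths=fasta_paths,
    )


@dataclass
class RecoveryMetrics:
    exact_recovery: float  # fraction of planted groups recovered exactly
    pair_precision: float  # co-membership pairs: recovered that are true
    pair_recall: float  # co-membership pairs: true that are recovered
    n_planted: int
    n_recovered: int


def evaluate_against_truth(
    groups: list[OrthoGroup], truth: TruthTable, name_map: NameMap
) -> RecoveryMetrics:
    """Score recovered orthogroups against the planted ground truth.

    Comparison happens in original-name space.  Exact recovery counts
    planted groups (with >= 2 surviving genes) whose full membership is
    recovered as one group; precision/recall are over unordered
    co-membership gene pairs.
    """
    planted = set(truth.planted_groups(min_genes=2))
    recovered = {
        frozenset(name_map.to_original(g) for g in grp.genes()) for grp in groups
    }

    def _pairs(sets):
        out = set()
        for s in sets:
            members = sorted(s)
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    out.add((a, b))
        return out

    true_pairs = _pairs(planted)
    rec_pairs = _pairs(recovered)
    tp = len(true_pairs & rec_pairs)
    precision = tp / len(rec_pairs) if rec_pairs else 1.0
    recall = tp / len(true_pairs) if true_pairs else 1.0
    exact = len(planted & recovered) / len(planted) if planted else 1.0
    return RecoveryMetrics(
        exact_recovery=exact,
        pair_precision=precision,
        pair_recall=recall,
        n_planted=len(planted),
        n_recovered=len(recovered),
    )
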