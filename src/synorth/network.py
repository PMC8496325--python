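"""Gene-graph assembly and decomposition into syntenic orthogroups.

Every gene of every genome is a vertex.  Edges come from two sources:
each gene pair of each surviving collinear block (regardless of its pair
score — the block as a whole earned trust), and chains along tandem
arrays, which are a special case of syntenic orthology.  Connected
components with at least two genes are the final orthogroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from synorth.errors import DataError
from synorth.formats_io import GeneRegistry, _canonical_sort_key
from synorth.scoring import ScoredBlock
from synorth.tethers import TandemArray


@dataclass
class OrthoGroup:
    """One connected component of the synteny graph (>= 2 genes)."""

    group_id: str
    genes_by_species: dict[str, list[str]]

    def genes(self) -> list[str]:
        return [g for genes in self.genes_by_species.values() for g in genes]

    def gene_count(self, species: str) -> int:
        return len(self.genes_by_species.get(species, []))

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.genes_by_species.values())


def build_graph(
    blocks: Iterable[ScoredBlock],
    arrays: Iterable[TandemArray],
    registry: GeneRegistry,
) -> nx.Graph:
    """Assemble the synteny graph.

    Tandem edges chain consecutive members of every array, including
    arrays none of whose members touch a block edge — a purely tandem
    array of two or more genes therefore forms its own (species-specific)
    orthogroup.  Self-loops are dropped and duplicate edges collapse.
    """
    graph = nx.Graph()
    graph.add_nodes_from(registry.records)
    for block in blocks:
        for pair in block.pairs:
            if pair.gene_a == pair.gene_b:
                continue
            for g in (pair.gene_a, pair.gene_b):
                if g not in registry:
                    raise DataError(
                        f"block {block.block_id} references unknown gene {g!r}"
                    )
            graph.add_edge(pair.gene_a, pair.gene_b)
    for arr in arrays:
        for ga, gb in zip(arr.members, arr.members[1:]):
            graph.add_edge(ga, gb)
    return graph


def connected_components(graph: nx.Graph, registry: GeneRegistry) -> list[OrthoGroup]:
    """Decompose the graph into orthogroups (components with >= 2 genes).

    Groups are numbered deterministically by their lexicographically
    smallest member (canonical-name ordering), so identical inputs give
    byte-identical outputs on any platform.
    """
    comps = [c for c in nx.connected_components(graph) if len(c) >= 2]
    comps.sort(key=lambda c: min(_canonical_sort_key(g) for g in c))
    groups: list[OrthoGroup] = []
    for i, comp in enumerate(comps):
        by_species: dict[str, list[str]] = {}
        for gene in sorted(comp, key=_canonical_sort_key):
            by_species.setdefault(registry.species_of(gene), []).append(gene)
        groups.append(OrthoGroup(group_id=f"SG{i:07d}", genes_by_species=by_species))
    return groups


@dataclass
class GroupSummary:
    per_group: pd.DataFrame  # gene counts, one row per group, one col per species
    per_group_genesets: pd.DataFrame
    totals: dict[str, int]


def summarize_groups(
    groups: Sequence[OrthoGroup],
    array_of: Mapping[str, TandemArray],
    ploidy: Mapping[str, int],
    species: Sequence[str],
) -> GroupSummary:
    """Per-group per-species gene and gene-set counts plus global tallies.

    * *singleton groups*: every species contributes exactly its ploidy in
      genes (one per diploid-equivalent species, ploidy-many for a
      polyploid).
    * *tether groups*: every species contributes at most ploidy-many gene
      sets (zero allowed) — at most singletons or tandem arrays.
    * *species-specific groups*: exactly one species represented.
    """
    gene_rows = []
    set_rows = []
    n_singleton = n_tether = n_specific = 0
    for grp in groups:
        gene_counts = {sp: grp.gene_count(sp) for sp in species}
        set_counts = {}
        for sp in species:
            genes = grp.genes_by_species.get(sp, [])
            set_counts[sp] = len({id(array_of[g]) for g in genes}) if genes else 0
        gene_rows.append({"group_id": grp.group_id, **gene_counts})
        set_rows.append({"group_id": grp.group_id, **set_counts})
        if all(gene_counts[sp] == ploidy.get(sp, 1) for sp in species):
            n_singleton += 1
        if all(set_counts[sp] <= ploidy.get(sp, 1) for sp in species):
            n_tether += 1
        if sum(1 for sp in species if gene_counts[sp] > 0) == 1:
            n_specific += 1
    per_group = pd.DataFrame(gene_rows, columns=["group_id", *species])
    per_sets = pd.DataFrame(set_rows, columns=["group_id", *species])
    totals = {
        "total_groups": len(groups),
        "singleton_groups": n_singleton,
        "tether_groups": n_tether,
        "species_specific_groups": n_specific,
        "genes_in_groups": int(sum(g.n_genes for g in groups)),
    }
    return GroupSummary(per_group=per_group, per_group_genesets=per_sets, totals=totals)


def write_groups(
    groups: Sequence[OrthoGroup],
    species: Sequence[str],
    path: str | Path,
    rename: Callable[[str], str] | None = None,
) -> None:
    """Write groups in the orthogroup-table dialect (one column per species)."""
    rename = rename or (lambda g: g)
    with Path(path).open("w") as fh:
        fh.write("Orthogroup\t" + "\t".join(species) + "\n")
        for grp in groups:
            cells = [
                ", ".join(rename(g) for g in grp.genes_by_species.get(sp, []))
                for sp in species
            ]
            fh.write(grp.group_id + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Two-run comparison (ploidy-aware vs a-priori subgenome split)
# ---------------------------------------------------------------------------


@dataclass
class OverlapCluster:
    groups_run1: list[str]
    groups_run2: list[str]
    kind: str  # "conflicting" | "complementary"


@dataclass
class ComparisonReport:
    n_groups_run1: int
    n_groups_run2: int
    n_identical: int
    n_unique_run1: int
    n_unique_run2: int
    clusters: list[OverlapCluster] = field(default_factory=list)

    @property
    def n_conflicting(self) -> int:
        return sum(1 for c in self.clusters if c.kind == "conflicting")

    @property
    def n_complementary(self) -> int:
        return sum(1 for c in self.clusters if c.kind == "complementary")

    @property
    def identical_fraction(self) -> float:
        denom = max(self.n_groups_run1, self.n_groups_run2)
        return self.n_identical / denom if denom else 1.0


NormalizedGroup = dict[str, frozenset[str]]  # species label -> gene names


def compare_group_sets(
    run1: Sequence[NormalizedGroup],
    run2: Sequence[NormalizedGroup],
    universe1: set[str] | None = None,
    universe2: set[str] | None = None,
) -> ComparisonReport:
    """Compare two orthogroup sets over the same gene universe.

    Inputs are label-normalized groups (split-subgenome species renamed
    to the unsplit label, genes mapped back to annotation IDs).  Groups
    with identical total gene membership are *identical*; groups sharing
    no gene with the other run are *unique*; the remaining groups form
    overlap clusters (connected components of the shared-gene relation),
    classified *conflicting* when for some species both runs include a
    nonempty but different gene set, else *complementary*.
    """
    if universe1 is not None and universe2 is not None and universe1 != universe2:
        raise DataError(
            f"gene universes differ: {len(universe1)} vs {len(universe2)} genes"
        )

    def _geneset(group: NormalizedGroup) -> frozenset[str]:
        out: set[str] = set()
        for genes in group.values():
            out |= genes
        return frozenset(out)

    sets1 = [_geneset(g) for g in run1]
    sets2 = [_geneset(g) for g in run2]
    lookup2 = {s: i for i, s in enumerate(sets2)}
    identical1: set[int] = set()
    identical2: set[int] = set()
    for i, s in enumerate(sets1):
        j = lookup2.get(s)
        if j is not None:
            identical1.add(i)
            identical2.add(j)

    gene_to_2: dict[str, list[int]] = {}
    for j, s in enumerate(sets2):
        if j in identical2:
            continue
        for g in s:
            gene_to_2.setdefault(g, []).append(j)

    overlap = nx.Graph()
    for i, s in enumerate(sets1):
        if i in identical1:
            continue
        overlap.add_node(("r1", i))
        for g in s:
            for j in gene_to_2.get(g, ()):
                overlap.add_edge(("r1", i), ("r2", j))
    for j in range(len(sets2)):
        if j not in identical2:
            overlap.add_node(("r2", j))

    n_unique_1 = n_unique_2 = 0
    clusters: list[OverlapCluster] = []
    for comp in nx.connected_components(overlap):
        g1 = sorted(i for run, i in comp if run == "r1")
        g2 = sorted(j for run, j in comp if run == "r2")
        if not g2:
            n_unique_1 += len(g1)
            continue
        if not g1:
            n_unique_2 += len(g2)
            continue
        by_sp1: dict[str, set[str]] = {}
        by_sp2: dict[str, set[str]] = {}
        for i in g1:
            for sp, genes in run1[i].items():
                by_sp1.setdefault(sp, set()).update(genes)
        for j in g2:
            for sp, genes in run2[j].items():
                by_sp2.setdefault(sp, set()).update(genes)
        kind = "complementary"
        for sp in set(by_sp1) | set(by_sp2):
            a, b = by_sp1.get(sp, set()), by_sp2.get(sp, set())
            if a and b and a != b:
                kind = "conflicting"
                break
        clusters.append(
            OverlapCluster(
                groups_run1=[str(i) for i in g1],
                groups_run2=[str(j) for j in g2],
                kind=kind,
            )
        )
    return ComparisonReport(
        n_groups_run1=len(run1),
        n_groups_run2=len(run2),
        n_identical=len(identical1),
        n_unique_run1=n_unique_1,
        n_unique_run2=n_unique_2,
        clusters=clusters,
    )


def normalize_groups(
    groups: Sequence[OrthoGroup],
    species_map: Mapping[str, str],
    rename: Callable[[str], str],
) -> list[NormalizedGroup]:
    """Map species labels through ``species_map`` and genes through ``rename``.

    Every species of every group must be covered by the map.
    """
    out: list[NormalizedGroup] = []
    for grp in groups:
        norm: dict[str, set[str]] = {}
        for sp, genes in grp.genes_by_species.items():
            if sp not in species_map:
                raise DataError(f"species map does not cover {sp!r}")
            norm.setdefault(species_map[sp], set()).update(rename(g) for g in genes)
        out.append({sp: frozenset(genes) for sp, genes in norm.items()})
    return out
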