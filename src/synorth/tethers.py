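"""Tandem-array collapsing and ploidy-filtered tether construction.

A *gene set* (tandem array) is a gene together with all of its
immediately neighboring tandem duplicates; arrays partition the genome
(every gene is in exactly one array, singletons included).  An
orthogroup becomes a *tether set* when, counting gene sets rather than
genes, at least two species stay within the copy number expected from
their relative ploidy; species exceeding their ploidy are excluded from
the tether but the tether survives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from synorth.errors import DataError
from synorth.formats_io import GeneRegistry, OrthogroupTable, TandemFile

log = logging.getLogger("synorth")


@dataclass
class TandemArray:
    """A maximal run of immediately neighboring tandem duplicates."""

    species_id: str
    chrom: str
    members: list[str]  # canonical names, chromosomal order

    @property
    def representative(self) -> str:
        return self.members[0]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class TetherSet:
    """A ploidy-filtered orthogroup used as an orthology anchor.

    ``genes_by_species`` holds only included species; species whose
    gene-set count exceeded their ploidy are listed in
    ``excluded_species`` with their genes kept for reporting only.
    """

    tether_id: str
    genes_by_species: dict[str, list[str]]
    geneset_counts: dict[str, int]
    excluded_species: dict[str, list[str]] = field(default_factory=dict)

    def genes(self) -> Iterable[str]:
        for genes in self.genes_by_species.values():
            yield from genes


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller name becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def build_tandem_arrays(
    tandem: TandemFile, registry: GeneRegistry
) -> tuple[list[TandemArray], dict[str, TandemArray]]:
    """Chain tandem pairs into maximal arrays partitioning every genome.

    Pairs are chained transitively ({g1,g2} and {g2,g3} give one array
    [g1,g2,g3]).  Every gene not touched by a tandem pair becomes its own
    singleton array.  A pair whose members are not adjacent in gene order
    is still merged, with a warning (the tandem caller is trusted).
    Returns the arrays and a gene -> array lookup.
    """
    uf = _UnionFind()
    for ga, gb in tandem.pairs:
        ra, rb = registry.record(ga), registry.record(gb)
        if ra.species_id != rb.species_id or ra.chrom != rb.chrom:
            raise DataError(f"tandem pair {ga},{gb} spans chromosomes")
        if abs(registry.ordinal(ga) - registry.ordinal(gb)) != 1:
            log.warning(
                "tandem pair %s,%s is not adjacent in gene order; merged anyway",
                ga,
                gb,
            )
        uf.union(ga, gb)

    clusters: dict[str, list[str]] = {}
    for ga, gb in tandem.pairs:
        for g in (ga, gb):
            root = uf.find(g)
            bucket = clusters.setdefault(root, [])
            if g not in bucket:
                bucket.append(g)

    arrays: list[TandemArray] = []
    array_of: dict[str, TandemArray] = {}
    clustered = {g for members in clusters.values() for g in members}
    for species, chrom in registry.chromosomes():
        order = registry.chromosome_order(species, chrom)
        done: set[str] = set()
        for gene in order:
            if gene in done:
                continue
            if gene in clustered:
                members = sorted(
                    clusters[uf.find(gene)], key=registry.ordinal
                )
                done.update(members)
            else:
                members = [gene]
                done.add(gene)
            arr = TandemArray(species_id=species, chrom=chrom, members=members)
            arrays.append(arr)
            for m in members:
                array_of[m] = arr
    return arrays, array_of


def build_tethers(
    orthogroups: OrthogroupTable,
    array_of: Mapping[str, TandemArray],
    ploidy: Mapping[str, int],
) -> list[TetherSet]:
    """Convert orthogroups into tether sets under the ploidy filter.

    Per orthogroup and species, the distinct tandem arrays intersected
    by the group's genes are counted.  A species whose count exceeds its
    relative ploidy is excluded (its genes dropped from the tether); the
    orthogroup yields a tether iff at least two species have a count in
    [1, ploidy].  Orthogroups partition their genes, so no gene can end
    up in two tethers.
    """
    tethers: list[TetherSet] = []
    for og_id, members in orthogroups.groups:
        included: dict[str, list[str]] = {}
        excluded: dict[str, list[str]] = {}
        counts: dict[str, int] = {}
        for species, genes in members.items():
            if not genes:
                continue
            arrays = set()
            for g in genes:
                if g not in array_of:
                    raise DataError(
                        f"orthogroup {og_id}: gene {g!r} has no position record"
                    )
                arrays.add(id(array_of[g]))
            counts[species] = len(arrays)
            if len(arrays) <= ploidy.get(species, 1):
                included[species] = list(genes)
            else:
                excluded[species] = list(genes)
        if len(included) >= 2:
            tethers.append(
                TetherSet(
                    tether_id=og_id,
                    genes_by_species=included,
                    geneset_counts={sp: counts[sp] for sp in included},
                    excluded_species=excluded,
                )
            )
    return tethers


class TetherIndex:
    """Gene -> tether lookup used by pair scoring.

    Only genes of *included* species are visible; ploidy-excluded genes
    and genes outside every tether resolve to ``None``.
    """

    def __init__(self, tethers: Iterable[TetherSet]):
        self._tether_of: dict[str, str] = {}
        self._members: dict[str, dict[str, set[str]]] = {}
        for tether in tethers:
            by_species: dict[str, set[str]] = {}
            for species, genes in tether.genes_by_species.items():
                by_species[species] = set(genes)
                for g in genes:
                    if g in self._tether_of:
                        raise DataError(
                            f"gene {g!r} belongs to tethers "
                            f"{self._tether_of[g]} and {tether.tether_id}"
                        )
                    self._tether_of[g] = tether.tether_id
            self._members[tether.tether_id] = by_species

    def tether_of(self, gene: str) -> str | None:
        return self._tether_of.get(gene)

    def has_other_member(
        self, tether_id: str, species: str, exclude: tuple[str, ...]
    ) -> bool:
        """Does the tether contain a gene of ``species`` outside ``exclude``?"""
        genes = self._members[tether_id].get(species, ())
        return any(g not in exclude for g in genes)

    def __len__(self) -> int:
        return len(self._members)


def write_tether_report(
    orthogroups: OrthogroupTable,
    tethers: Iterable[TetherSet],
    array_of: Mapping[str, TandemArray],
    path: str | Path,
) -> None:
    """One row per source orthogroup: per-species gene and gene-set counts
    plus the included/excluded flag of the resulting tether (if any)."""
    by_id = {t.tether_id: t for t in tethers}
    species = orthogroups.species
    with Path(path).open("w") as fh:
        header = ["orthogroup", "is_tether"]
        for sp in species:
            header += [f"{sp}_genes", f"{sp}_genesets", f"{sp}_status"]
        fh.write("\t".join(header) + "\n")
        for og_id, members in orthogroups.groups:
            tether = by_id.get(og_id)
            row = [og_id, "yes" if tether else "no"]
            for sp in species:
                genes = members.get(sp, [])
                n_sets = len({id(array_of[g]) for g in genes}) if genes else 0
                if tether is None:
                    status = "-"
                elif sp in tether.genes_by_species:
                    status = "included"
                elif sp in tether.excluded_species:
                    status = "excluded"
                else:
                    status = "absent"
                row += [str(len(genes)), str(n_sets), status]
            fh.write("\t".join(row) + "\n")
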