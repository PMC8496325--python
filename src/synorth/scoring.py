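"""Gene-pair scoring against tether sets and the block acceptance filter.

Every gene pair along a collinear block receives one of three scores:

* ``PASS``     — both genes sit in the same tether set.
* ``NOT_PASS`` — both genes are tethered but in different tether sets, or
  exactly one is tethered and its tether already contains a *different*
  gene of the partner's species (the pair contradicts the tether).
* ``NO_CALL``  — neither gene is tethered, or one is tethered but its
  tether carries no gene of the partner's species (no evidence either way).

The score is symmetric in pair orientation.  Intra-genome blocks (both
sides of the alignment from the same genome, as in a polyploid aligned
to itself) use the same decision tree with species A equal to species B.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from synorth.formats_io import GeneRegistry, RawBlock
from synorth.tethers import TetherIndex


class PairScore(Enum):
    PASS = "P"
    NOT_PASS = "N"
    NO_CALL = "C"

    def __repr__(self) -> str:  # compact in test output
        return self.name


@dataclass(frozen=True)
class ScoredPair:
    gene_a: str
    gene_b: str
    score: PairScore


@dataclass
class ScoredBlock:
    """A collinear block with one score per gene pair, order preserved."""

    block_id: str
    species_a: str
    species_b: str
    chrom_a: str
    chrom_b: str
    orientation: str
    pairs: list[ScoredPair]

    @property
    def scores(self) -> list[PairScore]:
        return [p.score for p in self.pairs]

    @property
    def n_pass(self) -> int:
        return sum(1 for p in self.pairs if p.score is PairScore.PASS)

    @property
    def n_notpass(self) -> int:
        return sum(1 for p in self.pairs if p.score is PairScore.NOT_PASS)

    @property
    def n_nocall(self) -> int:
        return sum(1 for p in self.pairs if p.score is PairScore.NO_CALL)

    @property
    def is_intra(self) -> bool:
        return self.species_a == self.species_b

    def __len__(self) -> int:
        return len(self.pairs)

    def replace_pairs(self, pairs: list[ScoredPair], block_id: str | None = None) -> "ScoredBlock":
        return ScoredBlock(
            block_id=self.block_id if block_id is None else block_id,
            species_a=self.species_a,
            species_b=self.species_b,
            chrom_a=self.chrom_a,
            chrom_b=self.chrom_b,
            orientation=self.orientation,
            pairs=pairs,
        )


def score_pair(
    gene_a: str,
    species_a: str,
    gene_b: str,
    species_b: str,
    tethers: TetherIndex,
) -> PairScore:
    """Score one gene pair against the tether sets.

    A gene degenerately paired with itself carries no orthology evidence
    and scores ``NO_CALL``.  In the one-sided case the tethered gene's own
    membership never counts against the pair: only a co-member of the
    partner's species *other than the two genes in question* forces
    ``NOT_PASS``.
    """
    if gene_a == gene_b:
        return PairScore.NO_CALL
    t_a = tethers.tether_of(gene_a)
    t_b = tethers.tether_of(gene_b)
    if t_a is not None and t_b is not None:
        return PairScore.PASS if t_a == t_b else PairScore.NOT_PASS
    if t_a is None and t_b is None:
        return PairScore.NO_CALL
    if t_a is not None:
        tether, partner_species = t_a, species_b
    else:
        tether, partner_species = t_b, species_a
    if tethers.has_other_member(tether, partner_species, (gene_a, gene_b)):
        return PairScore.NOT_PASS
    return PairScore.NO_CALL


def score_block(block: RawBlock, tethers: TetherIndex, registry: GeneRegistry) -> ScoredBlock:
    """Score every pair of a raw block, preserving pair order."""
    species_a = registry.species_of(block.pairs[0][0]) if block.pairs else block.species_a
    species_b = registry.species_of(block.pairs[0][1]) if block.pairs else block.species_b
    scored = [
        ScoredPair(ga, gb, score_pair(ga, species_a, gb, species_b, tethers))
        for ga, gb, _ in block.pairs
    ]
    return ScoredBlock(
        block_id=block.block_id,
        species_a=species_a,
        species_b=species_b,
        chrom_a=block.chrom_a,
        chrom_b=block.chrom_b,
        orientation=block.orientation,
        pairs=scored,
    )


def block_passes(block: ScoredBlock) -> bool:
    """Block acceptance filter.

    A block is kept iff it has at least two PASS pairs and its NOT_PASS
    count does not exceed its PASS count (a tie is kept; only a strict
    excess of NOT_PASS discards).  NO_CALL pairs are irrelevant.
    """
    n_pass = block.n_pass
    return n_pass >= 2 and block.n_notpass <= n_pass


def write_block_stats(
    blocks: Iterable[ScoredBlock], accepted_ids: set[str], path: str | Path
) -> None:
    """Per-block statistics: size, score tallies, acceptance flag."""
    with Path(path).open("w") as fh:
        fh.write(
            "block_id\tspecies_a\tspecies_b\tchrom_a\tchrom_b\tn_pairs\t"
            "n_pass\tn_notpass\tn_nocall\taccepted\n"
        )
        for b in blocks:
            fh.write(
                f"{b.block_id}\t{b.species_a}\t{b.species_b}\t{b.chrom_a}\t"
                f"{b.chrom_b}\t{len(b)}\t{b.n_pass}\t{b.n_notpass}\t{b.n_nocall}\t"
                f"{'yes' if b.block_id in accepted_ids else 'no'}\n"
            )
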