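from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from synorth.formats_io import GeneRecord, GeneRegistry
from synorth.scoring import PairScore, ScoredBlock, ScoredPair

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

SCORE = {"P": PairScore.PASS, "N": PairScore.NOT_PASS, "C": PairScore.NO_CALL}


def block_from_string(s: str, block_id: str = "b0") -> ScoredBlock:
    """ScoredBlock with the given score string; gene names are synthetic."""
    pairs = [
        ScoredPair(f"0_{i}", f"1_{i}", SCORE[c]) for i, c in enumerate(s)
    ]
    return ScoredBlock(
        block_id=block_id,
        species_a="spA",
        species_b="spB",
        chrom_a="cA",
        chrom_b="cB",
        orientation="plus",
        pairs=pairs,
    )


def scores_of(block: ScoredBlock) -> str:
    return "".join(p.score.value for p in block.pairs)


def make_registry(rows) -> GeneRegistry:
    """rows: (species, chrom, ordinal, canonical[, original])."""
    records = []
    for row in rows:
        sp, chrom, pos, canon = row[:4]
        orig = row[4] if len(row) > 4 else canon
        start = pos * 1000 + 1
        records.append(
            GeneRecord(
                species_id=sp,
                chrom=chrom,
                start=start,
                end=start + 899,
                original_name=orig,
                canonical_name=canon,
            )
        )
    return GeneRegistry(records)


@pytest.fixture
def two_species_registry() -> GeneRegistry:
    """Five genes per species on one chromosome each, canonical names."""
    rows = []
    for sp_idx, sp in enumerate(["spA", "spB"]):
        for i in range(5):
            rows.append((sp, f"{sp}_c1", i, f"{sp_idx}_{i}"))
    return make_registry(rows)
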