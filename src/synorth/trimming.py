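"""Recursive trimming and splitting of scored collinear blocks.

Four rules are applied until a fixed point is reached:

* **End rule** — from each end, if any NOT_PASS pair lies closer to the
  end than the first PASS pair, everything from the end through the last
  such NOT_PASS is removed.  An end that opens with PASS, or with only
  NO_CALL pairs before the first PASS, is left alone.
* **Window rule** — among the first six *scored* (PASS or NOT_PASS)
  pairs from an end, three or more NOT_PASS trigger removal of the
  endmost pair; removal repeats (re-applying the end rule each time and
  recomputing the window) until PASS strictly outnumbers NOT_PASS in the
  window or the block is exhausted.
* **Split rule** — an internal run of three or more NOT_PASS pairs with
  no intervening PASS (NO_CALL pairs do not break the run) splits the
  block in two; the run itself is dropped and both children re-enter the
  pipeline from the end rule.
* **Acceptance** — a block must keep at least two PASS pairs, at least
  as many PASS as NOT_PASS, and at least five gene pairs in total.

Every action is logged; NO_CALL pairs are only ever removed as part of a
removed range and never count toward any threshold.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from synorth.scoring import PairScore, ScoredBlock, block_passes

MIN_BLOCK_PAIRS = 5
WINDOW_SIZE = 6
WINDOW_NOTPASS_TRIGGER = 3
SPLIT_RUN_LENGTH = 3


@dataclass
class TrimAction:
    block_id: str
    action: str  # KEEP | TRIM_END | TRIM_WINDOW | SPLIT | DISCARD
    detail: str = ""
    children: tuple[str, ...] = ()


def _left_trim_count(scores: list[PairScore]) -> int:
    """Pairs to drop from the left under the end rule."""
    cut = 0
    for i, s in enumerate(scores):
        if s is PairScore.PASS:
            break
        if s is PairScore.NOT_PASS:
            cut = i + 1
    return cut


def trim_ends(block: ScoredBlock) -> ScoredBlock:
    """Apply the end rule to both ends independently (may return empty)."""
    scores = block.scores
    left = _left_trim_count(scores)
    right = _left_trim_count(scores[::-1])
    if left + right >= len(scores):
        return block.replace_pairs([])
    if left == 0 and right == 0:
        return block
    end = len(scores) - right
    return block.replace_pairs(block.pairs[left:end])


def _window_counts(scores: list[PairScore]) -> tuple[int, int]:
    """(n_pass, n_notpass) among the first six scored pairs from the left."""
    n_pass = n_notpass = 0
    seen = 0
    for s in scores:
        if s is PairScore.NO_CALL:
            continue
        if s is PairScore.PASS:
            n_pass += 1
        else:
            n_notpass += 1
        seen += 1
        if seen == WINDOW_SIZE:
            break
    return n_pass, n_notpass


def trim_window(block: ScoredBlock) -> ScoredBlock:
    """Apply the sliding-window rule to both ends until neither triggers.

    The end rule is re-applied after every single-pair removal, and the
    window recomputed, so removals can cascade.
    """
    changed = True
    while changed and block.pairs:
        changed = False
        for end in ("left", "right"):
            scores = block.scores if end == "left" else block.scores[::-1]
            n_pass, n_notpass = _window_counts(scores)
            if n_notpass < WINDOW_NOTPASS_TRIGGER:
                continue
            while block.pairs and not (n_pass > n_notpass):
                if end == "left":
                    block = block.replace_pairs(block.pairs[1:])
                else:
                    block = block.replace_pairs(block.pairs[:-1])
                block = trim_ends(block)
                changed = True
                scores = block.scores if end == "left" else block.scores[::-1]
                n_pass, n_notpass = _window_counts(scores)
    return block


def split_internal(block: ScoredBlock) -> list[ScoredBlock]:
    """Split at the leftmost internal NOT_PASS run of length >= 3.

    The run spans from its first to its last NOT_PASS; NO_CALL pairs
    inside that span are dropped with it.  Returns ``[block]`` when no
    qualifying run exists, otherwise the two children (either of which
    may be empty).
    """
    run_start = None
    run_len = 0
    last_np = None
    for i, s in enumerate(block.scores):
        if s is PairScore.NOT_PASS:
            if run_start is None:
                run_start = i
            run_len += 1
            last_np = i
            continue
        if s is PairScore.PASS:
            if run_len >= SPLIT_RUN_LENGTH:
                break
            run_start = None
            run_len = 0
            last_np = None
        # NO_CALL: run continues uninterrupted
    if run_len < SPLIT_RUN_LENGTH or run_start is None:
        return [block]
    left = block.replace_pairs(block.pairs[:run_start], block_id=f"{block.block_id}.0")
    right = block.replace_pairs(block.pairs[last_np + 1 :], block_id=f"{block.block_id}.1")
    return [left, right]


def refine_blocks(
    blocks: Iterable[ScoredBlock],
) -> tuple[list[ScoredBlock], list[TrimAction]]:
    """Drive every block to the fixed point of all four rules.

    Children produced by a split re-enter the pipeline from the end rule.
    Surviving blocks simultaneously satisfy every acceptance condition;
    the function is idempotent, never adds pairs, and terminates because
    every productive step removes at least one pair.
    """
    survivors: list[ScoredBlock] = []
    actions: list[TrimAction] = []
    queue = deque(blocks)
    while queue:
        block = queue.popleft()
        original_len = len(block)
        # end + window rules to their joint fixed point
        while True:
            before = len(block)
            trimmed = trim_ends(block)
            if len(trimmed) != len(block):
                actions.append(
                    TrimAction(
                        block.block_id,
                        "TRIM_END",
                        detail=f"removed {len(block) - len(trimmed)} end pair(s)",
                    )
                )
            block = trimmed
            windowed = trim_window(block)
            if len(windowed) != len(block):
                actions.append(
                    TrimAction(
                        block.block_id,
                        "TRIM_WINDOW",
                        detail=f"removed {len(block) - len(windowed)} pair(s)",
                    )
                )
            block = windowed
            if len(block) == before:
                break
        if not block.pairs:
            actions.append(TrimAction(block.block_id, "DISCARD", detail="emptied by trimming"))
            continue
        children = split_internal(block)
        if len(children) == 2:
            kept = tuple(c.block_id for c in children if c.pairs)
            actions.append(
                TrimAction(
                    block.block_id,
                    "SPLIT",
                    detail=f"internal NOT_PASS run removed "
                    f"({len(block) - sum(len(c) for c in children)} pair(s))",
                    children=kept,
                )
            )
            for child in children:
                if child.pairs:
                    queue.append(child)
            continue
        block = children[0]
        if not block_passes(block):
            actions.append(
                TrimAction(
                    block.block_id,
                    "DISCARD",
                    detail=f"pass filter (n_pass={block.n_pass}, n_notpass={block.n_notpass})",
                )
            )
            continue
        if len(block) < MIN_BLOCK_PAIRS:
            actions.append(
                TrimAction(block.block_id, "DISCARD", detail=f"fewer than {MIN_BLOCK_PAIRS} pairs")
            )
            continue
        detail = "" if len(block) == original_len else f"kept {len(block)}/{original_len} pairs"
        actions.append(TrimAction(block.block_id, "KEEP", detail=detail))
        survivors.append(block)
    return survivors, actions


def write_trim_log(actions: Iterable[TrimAction], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("block_id\taction\tdetail\tchildren\n")
        for a in actions:
            fh.write(f"{a.block_id}\t{a.action}\t{a.detail}\t{','.join(a.children)}\n")


def write_used_blocks(blocks: Iterable[ScoredBlock], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for b in blocks:
            fh.write(b.block_id + "\n")
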