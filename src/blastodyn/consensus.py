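"""Replicate-consensus calling: collapse per-colony calls to one per gene.

A gene is accepted as differentially expressed for a comparison only when at
least ``min_clues`` biological replicates (colonies) call it significant in
the *same* direction, and that direction strictly outnumbers the opposite
one.  The study design uses 5 colonies and a threshold of 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Sequence

from .pairwise_de import Direction, PairCall


@dataclass(frozen=True)
class ConsensusCall:
    gene_id: str
    comparison: tuple[str, str]
    status: Direction
    support_up: int
    support_down: int
    n_replicates: int
    min_clues: int

    def __post_init__(self) -> None:
        if self.support_up + self.support_down > self.n_replicates:
            raise ValueError("directional support exceeds replicate count")


def consensus_call(calls: Sequence[PairCall], min_clues: int = 3) -> ConsensusCall:
    """Collapse the per-colony calls for one gene and comparison."""
    if not calls:
        raise ValueError("empty call list")
    if min_clues < 1:
        raise ValueError("min_clues must be >= 1")
    gene_ids = {c.gene_id for c in calls}
    comparisons = {c.comparison for c in calls}
    if len(gene_ids) != 1 or len(comparisons) != 1:
        raise ValueError("calls must share one gene and one comparison")
    up = sum(1 for c in calls if c.direction == "up")
    down = sum(1 for c in calls if c.direction == "down")
    if up >= min_clues and up > down:
        status: Direction = "up"
    elif down >= min_clues and down > up:
        status = "down"
    else:
        status = "ns"
    return ConsensusCall(
        gene_id=calls[0].gene_id,
        comparison=calls[0].comparison,
        status=status,
        support_up=up,
        support_down=down,
        n_replicates=len(calls),
        min_clues=min_clues,
    )


def consensus_table(calls: Sequence[PairCall], min_clues: int = 3) -> list[ConsensusCall]:
    """One ConsensusCall per (gene, comparison), sorted by gene then comparison."""
    key = lambda c: (c.gene_id, c.comparison)
    grouped = groupby(sorted(calls, key=key), key=key)
    return [consensus_call(list(group), min_clues) for _, group in grouped]
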