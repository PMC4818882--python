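"""GO-category regulation dynamics across consecutive phase comparisons.

Differentially expressed genes are tallied per GO definition and comparison
into down/up counts (D, U).  For an ordered pair of comparisons taken in
their temporal succession, two normalized statistics quantify the change:

    GRV = [(D1 - D2) + (U2 - U1)] / [D1 + D2 + U1 + U2]   regulation shift
    GNV = [(D2 + U2) - (D1 + U1)] / [D1 + D2 + U1 + U2]   gene-number shift

Both lie in [-1, 1]; a category is flagged as high-change when |GRV| or
|GNV| exceeds a threshold tau (default 0.9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from .consensus import ConsensusCall

SelectionRule = Literal["or", "and"]


@dataclass(frozen=True)
class CategoryTally:
    """Down/up DE-gene counts for one GO term in one phase comparison."""

    go_code: str
    go_name: str
    go_domain: str
    comparison: tuple[str, str]
    d: int
    u: int


@dataclass(frozen=True)
class CategoryDynamics:
    """GRV/GNV of one GO term over an ordered pair of comparisons.

    ``grv``/``gnv`` are NaN (and ``selected`` False) when the term has no
    DE gene in either comparison, so degenerate categories stay auditable
    instead of being dropped.
    """

    go_code: str
    go_name: str
    go_domain: str
    pair: tuple[tuple[str, str], tuple[str, str]]
    d1: int
    u1: int
    d2: int
    u2: int
    grv: float
    gnv: float
    selected: bool

    @property
    def total(self) -> int:
        return self.d1 + self.u1 + self.d2 + self.u2


def grv(d1: int, u1: int, d2: int, u2: int) -> float:
    """Gene regulation variation; NaN when the category is empty."""
    _check_counts(d1, u1, d2, u2)
    total = d1 + d2 + u1 + u2
    if total == 0:
        return math.nan
    return ((d1 - d2) + (u2 - u1)) / total


def gnv(d1: int, u1: int, d2: int, u2: int) -> float:
    """Gene number variation; NaN when the category is empty."""
    _check_counts(d1, u1, d2, u2)
    total = d1 + d2 + u1 + u2
    if total == 0:
        return math.nan
    return ((d2 + u2) - (d1 + u1)) / total


def _check_counts(*counts: int) -> None:
    if any(c < 0 for c in counts):
        raise ValueError("D/U counts must be non-negative")


def tally_categories(
    consensus: Sequence[ConsensusCall], go_map: pd.DataFrame
) -> list[CategoryTally]:
    """Count down/up consensus calls per GO term and comparison.

    ``go_map`` needs columns gene_id, go_code, go_name, go_domain; a gene
    annotated to several terms contributes once to each.  Unannotated genes
    are ignored.  Every (term, comparison) pair is reported, including
    all-ns ones (D = U = 0).
    """
    if go_map is None or len(go_map) == 0:
        raise ValueError("empty annotation map")
    comparisons: list[tuple[str, str]] = []
    for call in consensus:
        if call.comparison not in comparisons:
            comparisons.append(call.comparison)
    status: dict[tuple[str, str], dict[str, str]] = {c: {} for c in comparisons}
    for call in consensus:
        status[call.comparison][call.gene_id] = call.status
    terms = (
        go_map[["go_code", "go_name", "go_domain"]]
        .drop_duplicates("go_code")
        .sort_values("go_code")
    )
    members = go_map.groupby("go_code")["gene_id"].apply(list)
    tallies: list[CategoryTally] = []
    for _, term in terms.iterrows():
        code = term["go_code"]
        for comparison in comparisons:
            st = status[comparison]
            genes = members[code]
            d = sum(1 for g in genes if st.get(g) == "down")
            u = sum(1 for g in genes if st.get(g) == "up")
            tallies.append(
                CategoryTally(
                    go_code=code,
                    go_name=term["go_name"],
                    go_domain=term["go_domain"],
                    comparison=comparison,
                    d=d,
                    u=u,
                )
            )
    return tallies


def category_dynamics(
    tallies: Sequence[CategoryTally],
    pairs: Sequence[tuple[tuple[str, str], tuple[str, str]]],
    tau: float = 0.9,
    rule: SelectionRule = "or",
) -> list[CategoryDynamics]:
    """GRV/GNV for every GO term over each ordered comparison pair.

    ``selected`` is |GRV| > tau OR |GNV| > tau by default ("and" requires
    both).  The result is sorted by total DE-gene count descending (the
    "most represented" ordering), ties by GO code.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    if rule not in ("or", "and"):
        raise ValueError(f"unknown selection rule: {rule!r}")
    present = {t.comparison for t in tallies}
    for first, second in pairs:
        if first not in present or second not in present:
            raise ValueError(f"comparison pair ({first}, {second}) not in tallies")
    by_key: dict[tuple[str, tuple[str, str]], CategoryTally] = {
        (t.go_code, t.comparison): t for t in tallies
    }
    codes: list[str] = []
    for t in tallies:
        if t.go_code not in codes:
            codes.append(t.go_code)
    out: list[CategoryDynamics] = []
    for code in codes:
        for first, second in pairs:
            t1 = by_key[(code, first)]
            t2 = by_key[(code, second)]
            g_r = grv(t1.d, t1.u, t2.d, t2.u)
            g_n = gnv(t1.d, t1.u, t2.d, t2.u)
            if math.isnan(g_r) or math.isnan(g_n):
                selected = False
            elif rule == "or":
                selected = abs(g_r) > tau or abs(g_n) > tau
            else:
                selected = abs(g_r) > tau and abs(g_n) > tau
            out.append(
                CategoryDynamics(
                    go_code=code,
                    go_name=t1.go_name,
                    go_domain=t1.go_domain,
                    pair=(first, second),
                    d1=t1.d,
                    u1=t1.u,
                    d2=t2.d,
                    u2=t2.u,
                    grv=g_r,
                    gnv=g_n,
                    selected=selected,
                )
            )
    out.sort(key=lambda d: (-d.total, d.go_code, d.pair))
    return out


def consecutive_pairs(
    comparisons: Sequence[tuple[str, str]]
) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Ordered pairs of consecutive comparisons in temporal succession."""
    return [
        (comparisons[i], comparisons[i + 1]) for i in range(len(comparisons) - 1)
    ]
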