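"""Per-gene differential expression between two blastogenetic phases.

The colony design gives natural replicate pairing: each colony was split
into subclones, one sampled per phase, so a phase comparison is a pair of
libraries from the same genotype.  With a single library per condition the
appropriate tests operate on the two (count, library total) pairs directly:
a two-sided Fisher exact test on the 2x2 table of gene vs rest-of-library
reads, and a likelihood-ratio (G) test of equal relative abundance under
Poisson sampling.  A gene is called differentially expressed in a colony
when the combined rule rejects at ``alpha`` (default: both tests reject).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy
from scipy.stats import chi2

logger = logging.getLogger("blastodyn.pairwise_de")

Direction = Literal["up", "down", "ns"]
CombinationMode = Literal["both", "either", "fisher_only", "lrt_only"]

#: relative tolerance for probability-mass ties in the two-sided Fisher test
FISHER_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class CountExperiment:
    """Gene x sample read counts with per-sample colony/phase metadata.

    ``counts`` is a genes x samples DataFrame of non-negative integers;
    ``samples`` has one row per column of ``counts`` with columns
    ``sample_id``, ``colony_id``, ``phase``.  Library totals are the column
    sums and stand in for sequencing depth.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise ValueError("sample sheet order must match count columns")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.samples.duplicated(["colony_id", "phase"]).any():
            raise ValueError("each colony may carry at most one sample per phase")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def library_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def phases(self) -> list[str]:
        seen: list[str] = []
        for p in self.samples["phase"]:
            if p not in seen:
                seen.append(p)
        return seen

    @property
    def colonies(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples["colony_id"]:
            if c not in seen:
                seen.append(c)
        return seen

    def sample_for(self, colony_id: str, phase: str) -> str | None:
        m = self.samples[
            (self.samples["colony_id"] == colony_id) & (self.samples["phase"] == phase)
        ]
        if m.empty:
            return None
        return str(m["sample_id"].iloc[0])


@dataclass(frozen=True)
class PairCall:
    """Outcome of the two tests for one gene in one colony's phase pair.

    ``direction`` is "up" when the normalized abundance c_A/n_A exceeds
    c_B/n_B *and* the combined rule rejects; "ns" otherwise.
    """

    gene_id: str
    colony_id: str
    comparison: tuple[str, str]
    c_a: int
    c_b: int
    n_a: int
    n_b: int
    p_fisher: float
    p_lrt: float
    g_stat: float
    direction: Direction


def _check_pair(c_a: int, n_a: int, c_b: int, n_b: int) -> None:
    if n_a <= 0 or n_b <= 0:
        raise ValueError("library totals must be positive")
    if c_a < 0 or c_b < 0 or c_a > n_a or c_b > n_b:
        raise ValueError("counts must satisfy 0 <= c <= n")


def _log_comb(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def fisher_exact_p(c_a: int, n_a: int, c_b: int, n_b: int) -> float:
    """Two-sided Fisher exact p for the table [[c_A, n_A-c_A], [c_B, n_B-c_B]].

    Probability-mass rule: sum of hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed the observed
    table's, with a 1e-7 relative tolerance absorbing floating-point ties.
    Evaluated in log space so million-read libraries are exact to float
    precision without big-integer arithmetic.
    """
    _check_pair(c_a, n_a, c_b, n_b)
    m = c_a + c_b
    if m == 0 or m == n_a + n_b:
        return 1.0
    lo = max(0, m - n_b)
    hi = min(m, n_a)
    k = np.arange(lo, hi + 1)
    logpmf = _log_comb(n_a, k) + _log_comb(n_b, m - k) - _log_comb(n_a + n_b, m)
    obs = logpmf[c_a - lo]
    p = float(np.exp(logpmf[logpmf <= obs + np.log1p(FISHER_TIE_RTOL)]).sum())
    return min(p, 1.0)


def lrt_p(c_a: int, n_a: int, c_b: int, n_b: int) -> tuple[float, float]:
    """Likelihood-ratio (G) test of equal relative abundance.

    Under Poisson sampling with pooled rate p_hat = (c_A+c_B)/(n_A+n_B) and
    expectations E_i = n_i * p_hat,

        G = 2 * [c_A ln(c_A/E_A) + c_B ln(c_B/E_B)]    (0 ln 0 := 0)

    and the p-value is the upper tail of chi-square with 1 df at G.
    Returns ``(g_stat, p)``; the empty table c_A = c_b = 0 gives (0, 1).
    """
    _check_pair(c_a, n_a, c_b, n_b)
    m = c_a + c_b
    if m == 0:
        return 0.0, 1.0
    p_hat = m / (n_a + n_b)
    e_a = n_a * p_hat
    e_b = n_b * p_hat
    g = 2.0 * (float(xlogy(c_a, c_a / e_a)) + float(xlogy(c_b, c_b / e_b)))
    g = max(g, 0.0)
    return g, float(chi2.sf(g, df=1))


def call_pair(
    c_a: int,
    n_a: int,
    c_b: int,
    n_b: int,
    alpha: float = 0.05,
    mode: CombinationMode = "both",
    *,
    gene_id: str = "",
    colony_id: str = "",
    comparison: tuple[str, str] = ("A", "B"),
) -> PairCall:
    """Run both tests on one count pair and call a direction at ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p_f = fisher_exact_p(c_a, n_a, c_b, n_b)
    g, p_l = lrt_p(c_a, n_a, c_b, n_b)
    significant = _combine(p_f, p_l, alpha, mode)
    rate_a = c_a / n_a
    rate_b = c_b / n_b
    if not significant or rate_a == rate_b:
        direction: Direction = "ns"
    elif rate_a > rate_b:
        direction = "up"
    else:
        direction = "down"
    return PairCall(
        gene_id=gene_id,
        colony_id=colony_id,
        comparison=comparison,
        c_a=int(c_a),
        c_b=int(c_b),
        n_a=int(n_a),
        n_b=int(n_b),
        p_fisher=p_f,
        p_lrt=p_l,
        g_stat=g,
        direction=direction,
    )


def _combine(p_f: float, p_l: float, alpha: float, mode: str) -> bool:
    if mode == "both":
        return p_f < alpha and p_l < alpha
    if mode == "either":
        return p_f < alpha or p_l < alpha
    if mode == "fisher_only":
        return p_f < alpha
    if mode == "lrt_only":
        return p_l < alpha
    raise ValueError(f"unknown combination mode: {mode!r}")


def _fisher_vec(ca: np.ndarray, na: int, cb: np.ndarray, nb: int) -> np.ndarray:
    out = np.empty(ca.shape[0])
    for i in range(ca.shape[0]):
        out[i] = fisher_exact_p(int(ca[i]), na, int(cb[i]), nb)
    return out


def _lrt_vec(ca: np.ndarray, na: int, cb: np.ndarray, nb: int):
    m = ca + cb
    p_hat = m / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 2.0 * (xlogy(ca, ca / (na * p_hat)) + xlogy(cb, cb / (nb * p_hat)))
    g = np.where(m == 0, 0.0, np.maximum(g, 0.0))
    return g, chi2.sf(g, df=1)


def test_comparison(
    experiment: CountExperiment,
    phase_a: str,
    phase_b: str,
    alpha: float = 0.05,
    mode: CombinationMode = "both",
) -> list[PairCall]:
    """Call every gene in every colony that carries both phases.

    Comparison (A, B) is oriented so "up" means higher relative abundance in
    phase A.  Colonies lacking either phase are skipped with a warning; an
    error is raised only when no colony carries both.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    _combine(1.0, 1.0, alpha, mode)  # validate mode eagerly
    comparison = (phase_a, phase_b)
    totals = experiment.library_totals
    calls: list[PairCall] = []
    genes = experiment.gene_ids
    any_colony = False
    for colony in experiment.colonies:
        s_a = experiment.sample_for(colony, phase_a)
        s_b = experiment.sample_for(colony, phase_b)
        if s_a is None or s_b is None:
            logger.warning(
                "colony %s lacks phase %s; skipped for comparison %s vs %s",
                colony,
                phase_a if s_a is None else phase_b,
                phase_a,
                phase_b,
            )
            continue
        any_colony = True
        ca = experiment.counts[s_a].to_numpy()
        cb = experiment.counts[s_b].to_numpy()
        na = int(totals[s_a])
        nb = int(totals[s_b])
        p_f = _fisher_vec(ca, na, cb, nb)
        g, p_l = _lrt_vec(ca.astype(float), na, cb.astype(float), nb)
        if mode == "both":
            sig = (p_f < alpha) & (p_l < alpha)
        elif mode == "either":
            sig = (p_f < alpha) | (p_l < alpha)
        elif mode == "fisher_only":
            sig = p_f < alpha
        else:
            sig = p_l < alpha
        rate_diff = ca / na - cb / nb
        for i, gene in enumerate(genes):
            if not sig[i] or rate_diff[i] == 0:
                direction: Direction = "ns"
            elif rate_diff[i] > 0:
                direction = "up"
            else:
                direction = "down"
            calls.append(
                PairCall(
                    gene_id=gene,
                    colony_id=colony,
                    comparison=comparison,
                    c_a=int(ca[i]),
                    c_b=int(cb[i]),
                    n_a=na,
                    n_b=nb,
                    p_fisher=float(p_f[i]),
                    p_lrt=float(p_l[i]),
                    g_stat=float(g[i]),
                    direction=direction,
                )
            )
    if not any_colony:
        raise ValueError(f"no colony carries both phases {phase_a!r} and {phase_b!r}")
    return calls
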