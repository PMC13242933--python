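"""Shared statistical primitives used across pipeline stages.

Small wrappers with the conventions fixed once: two-sided P values,
Benjamini-Hochberg step-up for multiplicity, Pearson chi-squared without
continuity correction (Fisher's exact as a small-count fallback), and the
2^-ddCt fold-change rule for qPCR.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "overlap_chi2",
    "ddct",
]

#: pooled-size threshold below which the rank-sum test enumerates exactly
EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group (or contingency) test."""

    statistic: float
    p_value: float
    n_a: int
    n_b: int
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise ValueError("adjusted P below raw P")


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum P by enumeration of all group assignments.

    Enumerates every way the pooled values could have been split into groups
    of the observed sizes and counts assignments whose rank-sum deviates from
    its mean at least as much as the observed one.  Ties are handled with
    midranks.  Feasible only for small pooled n; doubles as the oracle the
    asymptotic path is checked against.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return float(w_obs), count / total


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration when the pooled sample size is at most
    ``EXACT_RANKSUM_MAX_N``; otherwise the tie-corrected normal
    approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("wilcoxon_rank_sum requires non-empty groups")
    if a.size + b.size <= EXACT_RANKSUM_MAX_N:
        stat, p = _exact_ranksum_p(a, b)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
    return TestResult(statistic=stat, p_value=min(p, 1.0), n_a=a.size, n_b=b.size)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_chi2(set_a, set_b, universe, correction: str = "none") -> TestResult:
    """Association between two gene sets within a universe.

    Builds the 2x2 table (in/out of A) x (in/out of B) over the universe and
    applies the Pearson chi-squared test with 1 df.  ``correction`` may be
    ``"none"`` (default), ``"yates"``, or ``"fisher"`` (Fisher's exact,
    recommended when any expected count is below 5).
    """
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    if len(universe) < 4:
        raise ValueError("universe must contain at least 4 elements")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    n11 = len(set_a & set_b)
    n10 = len(set_a - set_b)
    n01 = len(set_b - set_a)
    n00 = len(universe) - n11 - n10 - n01
    table = np.array([[n11, n10], [n01, n00]])
    if correction == "fisher":
        stat, p = sps.fisher_exact(table)
        stat = float(stat)
    else:
        res = sps.chi2_contingency(table, correction=(correction == "yates"))
        stat, p = float(res.statistic), float(res.pvalue)
    return TestResult(statistic=stat, p_value=float(min(p, 1.0)), n_a=len(set_a), n_b=len(set_b))


def ddct(ct_target_treated: float, ct_ref_treated: float,
         ct_target_control: float, ct_ref_control: float) -> float:
    """Relative expression fold change by the 2^-ddCt rule.

    ddCt = (Ct_target - Ct_reference) in the treated sample minus the same
    difference in the control sample; one qPCR cycle is a factor of two.
    """
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    delta_delta = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-delta_delta))
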