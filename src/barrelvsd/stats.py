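"""Nonparametric group comparisons of per-animal summary metrics.

Two groups of animals are compared with the two-sided Wilcoxon rank-sum
(Mann-Whitney) test; observed synchrony is compared with its spatial-
shuffle null by the two-sided Wilcoxon signed-rank test on per-animal
pairs.  Exact p-values are used for small samples without ties (combined
n <= 20 for the rank-sum test, n <= 25 nonzero pairs for the signed-rank
test), the tie-corrected normal approximation otherwise; the choice is
recorded in the result.  Summaries are mean ± SEM (sample sd with n-1
denominator over sqrt(n)).  The test unit is the animal, never the trial.
No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .core import MissingDataError, ParameterError

__all__ = ["GroupComparison", "rank_sum_test", "signed_rank_test", "summarize"]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of one two-sample (or paired) comparison."""

    metric: str
    test: str                 # "rank-sum" or "signed-rank"
    method: str               # "exact" or "asymptotic"
    statistic: float
    p_value: float
    a_values: tuple[float, ...]
    b_values: tuple[float, ...]
    a_mean: float
    b_mean: float
    a_sem: Optional[float]
    b_sem: Optional[float]
    alpha: float = DEFAULT_ALPHA
    n_zero_pairs_dropped: int = 0

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def stars(self) -> str:
        if self.p_value < 1e-3:
            return "***"
        return "*" if self.significant else "n.s."


def summarize(values) -> tuple[float, Optional[float], int]:
    """(mean, SEM, n); SEM is None for a single value."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise MissingDataError("cannot summarize an empty sample")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else None
    return mean, sem, int(v.size)


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def rank_sum_test(
    a, b, metric: str = "", alpha: float = DEFAULT_ALPHA
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test between two groups of animals."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 animals")
    exact = (a.size + b.size) <= 20 and not _has_ties(np.concatenate([a, b]))
    method = "exact" if exact else "asymptotic"
    # no continuity correction in the normal approximation: exchangeable
    # samples then give z = 0 and p = 1 exactly, matching the exact test
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    a_mean, a_sem, _ = summarize(a)
    b_mean, b_sem, _ = summarize(b)
    return GroupComparison(
        metric=metric, test="rank-sum", method=method,
        statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
        a_values=tuple(a), b_values=tuple(b),
        a_mean=a_mean, b_mean=b_mean, a_sem=a_sem, b_sem=b_sem, alpha=alpha,
    )


def signed_rank_test(
    observed, null_reference, metric: str = "", alpha: float = DEFAULT_ALPHA
) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test on per-animal pairs
    (observed synchrony vs the mean of its shuffle null).

    Zero differences are dropped by the standard convention and their count
    reported; if every difference is zero the pairing is degenerate.
    """
    obs = np.asarray(observed, dtype=float)
    ref = np.asarray(null_reference, dtype=float)
    if obs.shape != ref.shape:
        raise ParameterError("observed and null reference must pair 1:1")
    if obs.size < 2:
        raise ParameterError("need at least 2 pairs")
    diffs = obs - ref
    n_zero = int(np.sum(diffs == 0))
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        raise ParameterError("all paired differences are zero (degenerate pairing)")
    if nonzero.size < 2:
        raise ParameterError("fewer than 2 nonzero differences")
    exact = nonzero.size <= 25 and not _has_ties(np.abs(nonzero))
    method = "exact" if exact else "approx"
    res = sps.wilcoxon(nonzero, alternative="two-sided", method=method)
    a_mean, a_sem, _ = summarize(obs)
    b_mean, b_sem, _ = summarize(ref)
    return GroupComparison(
        metric=metric, test="signed-rank",
        method="exact" if exact else "asymptotic",
        statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
        a_values=tuple(obs), b_values=tuple(ref),
        a_mean=a_mean, b_mean=b_mean, a_sem=a_sem, b_sem=b_sem, alpha=alpha,
        n_zero_pairs_dropped=n_zero,
    )
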