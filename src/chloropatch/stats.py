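"""Discrimination index and the variance-gated t-test policy.

Three small pieces of statistical machinery:

* the novel-object discrimination index
  DI = (N_N − N_F) / (N_N + N_F);
* a two-sided variance-ratio F test with the larger-variance-on-top
  convention (F ≥ 1, p = 2 × upper-tail probability, capped at 1), also
  usable in summary mode from a printed (F, df) pair;
* a conditional two-sample t test that applies Welch's correction
  exactly when the F test is significant at the configured α, and the
  pooled-variance t test otherwise.

Omnibus ANOVA and post-hoc families are deliberately not implemented
here; pipelines call standard routines for those.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as ss

__all__ = [
    "ExplorationCounts", "VarianceTestResult", "TTestResult",
    "discrimination_index", "variance_ratio_test", "welch_conditional_ttest",
]


@dataclass(frozen=True)
class ExplorationCounts:
    """Novel / familiar object exploration counts."""

    n_novel: int
    n_familiar: int

    def __post_init__(self) -> None:
        if self.n_novel < 0 or self.n_familiar < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class VarianceTestResult:
    f: float
    df_num: int
    df_den: int
    p_two_sided: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    welch_applied: bool


def discrimination_index(counts: ExplorationCounts | tuple[int, int]) -> float:
    """DI = (N_N − N_F)/(N_N + N_F) ∈ [−1, 1]; undefined at (0, 0)."""
    if not isinstance(counts, ExplorationCounts):
        counts = ExplorationCounts(*counts)
    total = counts.n_novel + counts.n_familiar
    if total == 0:
        raise ValueError("DI undefined: no explorations of either object")
    return (counts.n_novel - counts.n_familiar) / total


def variance_ratio_test(x=None, y=None, *, f: float | None = None,
                        df: tuple[int, int] | None = None,
                        one_sided: bool = False) -> VarianceTestResult:
    """F test for equality of variances.

    Raw-data mode: pass samples ``x`` and ``y``; the larger sample
    variance goes on top, so F ≥ 1 and swapping the samples changes
    nothing. Summary mode: pass a precomputed ``f`` with its
    ``df=(df_num, df_den)`` to check printed values without raw data.
    Two-sided by default (p = 2 × upper tail, capped at 1).
    """
    if f is not None:
        if df is None:
            raise ValueError("summary mode needs df=(df_num, df_den)")
        if f < 1:
            raise ValueError("summary mode expects the larger-variance-"
                             "on-top convention (F >= 1)")
        df_num, df_den = df
    else:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 2 or y.size < 2:
            raise ValueError("each sample needs n >= 2")
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        if vx == 0 or vy == 0:
            raise ValueError("zero variance: F test undefined")
        if vx >= vy:
            f, df_num, df_den = vx / vy, x.size - 1, y.size - 1
        else:
            f, df_num, df_den = vy / vx, y.size - 1, x.size - 1
    tail = float(ss.f.sf(f, df_num, df_den))
    p = tail if one_sided else min(2.0 * tail, 1.0)
    return VarianceTestResult(f=float(f), df_num=df_num, df_den=df_den,
                              p_two_sided=p)


def welch_conditional_ttest(x, y, alpha_variance: float = 0.05
                            ) -> TTestResult:
    """Two-sample t test, Welch-corrected iff the F test is significant.

    Runs :func:`variance_ratio_test` first; if its two-sided p falls
    below ``alpha_variance``, the unequal-variance (Welch–Satterthwaite)
    t test is used, otherwise the pooled-variance test. Always
    two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vtest = variance_ratio_test(x, y)
    welch = vtest.p_two_sided < alpha_variance
    res = ss.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df)
    return TTestResult(t=float(res.statistic), df=df,
                       p=float(res.pvalue), welch_applied=welch)
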