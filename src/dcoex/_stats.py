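"""Shared small-sample statistical machinery.

The pathology, differential-expression and protein-panel stages all use the
same Levene-gated two-sample t framework: homogeneity of variance is tested
with Levene's test (mean-centered by default); when it rejects at ``alpha``
the Welch (unequal-variance) t-test with Welch–Satterthwaite degrees of
freedom is used, otherwise the pooled-variance t-test.  Cohen's d is derived
from the t statistic through d = t * sqrt(1/n1 + 1/n2), which is the identity
the downstream effect sizes obey.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TTestResult",
    "levene_gated_ttest",
    "cohens_d_from_t",
    "bh_qvalues",
    "tukey_outlier_mask",
]


def cohens_d_from_t(t: float, n1: int, n2: int) -> float:
    """Cohen's d implied by a two-sample t statistic: d = t*sqrt(1/n1 + 1/n2)."""
    return float(t) * math.sqrt(1.0 / n1 + 1.0 / n2)


@dataclass
class TTestResult:
    t: float
    df: float
    p_one: float
    p_two: float
    levene_F: float
    levene_p: float
    variant: str  # "pooled" | "welch"
    d: float
    n1: int
    n2: int
    mean_diff: float
    flags: list[str] = field(default_factory=list)

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags


def levene_gated_ttest(
    control,
    case,
    *,
    alpha: float = 0.05,
    levene_center: str = "mean",
    direction: str = "case_greater",
) -> TTestResult:
    """Levene-gated independent two-sample t-test, case vs control.

    The sign of t follows mean(case) - mean(control).  ``p_one`` is the
    one-sided p in the stated direction (default: case > control); ``p_two``
    is two-sided.  Both are always reported.
    """
    control = np.asarray(control, dtype=float)
    case = np.asarray(case, dtype=float)
    control = control[~np.isnan(control)]
    case = case[~np.isnan(case)]
    n1, n2 = len(control), len(case)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 values per group, got n1={n1}, n2={n2}")

    flags: list[str] = []
    v1, v2 = control.var(ddof=1), case.var(ddof=1)
    mean_diff = float(case.mean() - control.mean())

    if v1 == 0.0 and v2 == 0.0:
        # no within-group spread at all: t undefined
        flags.append("degenerate")
        t = 0.0 if mean_diff == 0.0 else math.inf * math.copysign(1.0, mean_diff)
        p_two = float("nan") if mean_diff != 0.0 else 1.0
        if mean_diff == 0.0:
            t = 0.0
        return TTestResult(
            t=t, df=float(n1 + n2 - 2), p_one=float("nan") if mean_diff != 0 else 1.0,
            p_two=p_two, levene_F=0.0, levene_p=1.0, variant="pooled",
            d=0.0 if mean_diff == 0 else math.copysign(math.inf, mean_diff),
            n1=n1, n2=n2, mean_diff=mean_diff, flags=flags,
        )

    lev_F, lev_p = stats.levene(control, case, center=levene_center)
    welch = bool(lev_p < alpha)
    res = stats.ttest_ind(case, control, equal_var=not welch)
    t = float(res.statistic)
    p_two = float(res.pvalue)
    df = float(res.df)
    if direction == "case_greater":
        p_one = float(stats.ttest_ind(case, control, equal_var=not welch,
                                      alternative="greater").pvalue)
    elif direction == "control_greater":
        p_one = float(stats.ttest_ind(case, control, equal_var=not welch,
                                      alternative="less").pvalue)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return TTestResult(
        t=t, df=df, p_one=p_one, p_two=p_two,
        levene_F=float(lev_F), levene_p=float(lev_p),
        variant="welch" if welch else "pooled",
        d=cohens_d_from_t(t, n1, n2),
        n1=n1, n2=n2, mean_diff=mean_diff, flags=flags,
    )


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def tukey_outlier_mask(values, k: float = 1.5) -> np.ndarray:
    """Boolean mask of Tukey-fence outliers (True = outlier).

    Fences are [Q1 - k*IQR, Q3 + k*IQR].  NaNs are never flagged.  With
    fewer than 3 non-missing values no screening is applied (all False).
    """
    values = np.asarray(values, dtype=float)
    mask = np.zeros(values.shape, dtype=bool)
    obs = values[~np.isnan(values)]
    if obs.size < 3:
        return mask
    q1, q3 = np.percentile(obs, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    with np.errstate(invalid="ignore"):
        mask = (values < lo) | (values > hi)
    return mask & ~np.isnan(values)


def zscore_outlier_mask(values, z: float = 3.0) -> np.ndarray:
    """Alternative rule: |value - mean| > z * sd.  NaNs never flagged."""
    values = np.asarray(values, dtype=float)
    mask = np.zeros(values.shape, dtype=bool)
    obs = values[~np.isnan(values)]
    if obs.size < 3 or obs.std(ddof=1) == 0:
        return mask
    zz = np.abs(values - obs.mean()) / obs.std(ddof=1)
    with np.errstate(invalid="ignore"):
        mask = zz > z
    return mask & ~np.isnan(values)
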