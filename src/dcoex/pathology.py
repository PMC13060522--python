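"""Neuropathological group comparisons for tiny case-control cohorts.

Implements the semiquantitative tau/amyloid colocalization index, exact
(tie-aware) Mann–Whitney permutation tests with Hodges–Lehmann location
estimates, 2x2 contingency statistics with small-cell corrections, and
Levene-gated comparisons of continuous pathology burden.

Conventions
-----------
* The reported U is the smaller of U1 and U2 (min convention); tied pairs
  contribute 0.5 to U (midrank equivalent).
* One-sided tests are directed case > control; the two-sided companion is
  always reported.
* The Haldane–Anscombe +0.5 correction is applied to every cell of the odds
  ratio unconditionally (not only when a cell is zero), with a Woolf
  confidence interval on the corrected cells.  The risk ratio is the plain
  (uncorrected) estimate with a Katz log-scale interval.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._stats import TTestResult, cohens_d_from_t, levene_gated_ttest

__all__ = [
    "ContingencyTable2x2",
    "IndexResult",
    "ContingencyResult",
    "BurdenResult",
    "colocalization_index",
    "index_group_test",
    "mann_whitney_exact",
    "contingency_stats",
    "burden_compare",
    "rank_biserial",
]

#: exhaustive enumeration is used while C(n1+n2, n1) does not exceed this
ENUMERATION_CAP = 1_000_000


def colocalization_index(amyloid_pos: bool, tau_pos: bool) -> int:
    """Ordinal 0/1/2 pathology score: neither, exactly one, or both present."""
    return int(bool(amyloid_pos)) + int(bool(tau_pos))


def rank_biserial(U: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation from a (min-convention) U: 1 - 2U/(n1*n2)."""
    return 1.0 - 2.0 * U / (n1 * n2)


def _u_case(case: np.ndarray, control: np.ndarray) -> float:
    """Pair-count U for the case group with 0.5 credit per tied pair."""
    diff = case[:, None] - control[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


@dataclass
class IndexResult:
    U: float
    p_one: float
    p_two: float
    hl_estimate: float
    hl_ci: tuple[float, float]
    hl_confidence: float
    r_rank_biserial: float
    n1: int
    n2: int
    method: str  # "exact" | "montecarlo"
    mc_se: float | None = None
    flags: list[str] = field(default_factory=list)


def _exact_null_u_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of the (tie-free) Mann–Whitney U statistic.

    Classic recursion: counts[u] over u = 0..n1*n2, normalized to a pmf.
    Used for the Hodges–Lehmann confidence interval.
    """
    # f(m, n)[u]: number of arrangements of m X's among m+n values with U = u.
    # Recurrence: f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u)
    table: dict[tuple[int, int], np.ndarray] = {}

    def f(m: int, n: int) -> np.ndarray:
        if (m, n) in table:
            return table[(m, n)]
        if m == 0 or n == 0:
            arr = np.array([1.0])
        else:
            a = f(m - 1, n)
            b = f(m, n - 1)
            arr = np.zeros(m * n + 1)
            arr[n : n + len(a)] += a
            arr[: len(b)] += b
        table[(m, n)] = arr
        return arr

    pmf = f(n1, n2)
    return pmf / pmf.sum()


def hodges_lehmann(
    control, case, confidence: float = 0.95
) -> tuple[float, tuple[float, float], float]:
    """Hodges–Lehmann median difference (case - control) with exact CI.

    The interval takes the k+1-th and (n1*n2-k)-th ordered pairwise
    differences where k is the largest integer with P(U <= k) <= (1-conf)/2
    under the exact tie-free null U distribution; the achieved confidence
    level (often different from the request at small n) is returned.
    """
    control = np.asarray(control, dtype=float)
    case = np.asarray(case, dtype=float)
    diffs = np.sort((case[:, None] - control[None, :]).ravel())
    est = float(np.median(diffs))
    n1, n2 = len(control), len(case)
    pmf = _exact_null_u_pmf(n1, n2)
    cdf = np.cumsum(pmf)
    alpha = (1.0 - confidence) / 2.0
    ks = np.nonzero(cdf <= alpha)[0]
    if ks.size == 0:
        # even the most extreme U exceeds alpha/2: widest possible interval
        lo, hi = float(diffs[0]), float(diffs[-1])
        achieved = 1.0 - 2.0 * 0.0
        return est, (lo, hi), achieved
    k = int(ks[-1])
    achieved = 1.0 - 2.0 * float(cdf[k])
    lo = float(diffs[k]) if k < diffs.size else float(diffs[0])
    hi = float(diffs[diffs.size - 1 - k])
    return est, (lo, hi), achieved


def mann_whitney_exact(
    control,
    case,
    *,
    confidence: float = 0.95,
    enumeration_cap: int = ENUMERATION_CAP,
    n_mc: int = 100_000,
    rng: np.random.Generator | None = None,
) -> IndexResult:
    """Exact (tie-aware) Mann–Whitney U test by permutation enumeration.

    All C(n1+n2, n1) assignments of the pooled values into the two groups
    are enumerated (Monte-Carlo sampled beyond ``enumeration_cap``).  The
    one-sided p is the proportion of assignments whose case-vs-control pair
    count is at least the observed one (direction case > control); the
    two-sided p is the proportion with min(U1, U2) at most the observed
    minimum.
    """
    control = np.asarray(control, dtype=float)
    case = np.asarray(case, dtype=float)
    n1, n2 = len(control), len(case)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    flags: list[str] = []
    pooled = np.concatenate([control, case])
    if np.all(pooled == pooled[0]):
        flags.append("constant_data")

    u_case_obs = _u_case(case, control)
    u_min_obs = min(u_case_obs, n1 * n2 - u_case_obs)
    eps = 1e-9

    n_total = n1 + n2
    n_assign = math.comb(n_total, n2)
    if n_assign <= enumeration_cap:
        ge = 0
        le_min = 0
        for case_idx in itertools.combinations(range(n_total), n2):
            sel = np.zeros(n_total, dtype=bool)
            sel[list(case_idx)] = True
            u = _u_case(pooled[sel], pooled[~sel])
            if u >= u_case_obs - eps:
                ge += 1
            if min(u, n1 * n2 - u) <= u_min_obs + eps:
                le_min += 1
        p_one = ge / n_assign
        p_two = le_min / n_assign
        method, mc_se = "exact", None
    else:
        rng = rng or np.random.default_rng()
        ge = le_min = 0
        for _ in range(n_mc):
            perm = rng.permutation(pooled)
            u = _u_case(perm[:n2], perm[n2:])
            if u >= u_case_obs - eps:
                ge += 1
            if min(u, n1 * n2 - u) <= u_min_obs + eps:
                le_min += 1
        p_one = ge / n_mc
        p_two = le_min / n_mc
        method = "montecarlo"
        mc_se = math.sqrt(p_one * (1 - p_one) / n_mc)

    hl_est, hl_ci, hl_conf = hodges_lehmann(control, case, confidence)
    if flags and "constant_data" in flags:
        hl_ci = (hl_est, hl_est)
    return IndexResult(
        U=u_min_obs,
        p_one=p_one,
        p_two=p_two,
        hl_estimate=hl_est,
        hl_ci=hl_ci,
        hl_confidence=hl_conf,
        r_rank_biserial=rank_biserial(u_min_obs, n1, n2),
        n1=n1,
        n2=n2,
        method=method,
        mc_se=mc_se,
        flags=flags,
    )


# ordinal-index comparison is the same machinery under its domain name
def index_group_test(group_control, group_case, confidence: float = 0.95) -> IndexResult:
    """Exact Mann–Whitney comparison of ordinal pathology-index scores."""
    return mann_whitney_exact(group_control, group_case, confidence=confidence)


@dataclass
class ContingencyTable2x2:
    """Counts of dual pathology by group.

    a: cases dual-positive, b: cases not, c: controls dual-positive,
    d: controls not.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("each group (row) must contain at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class ContingencyResult:
    or_point: float
    or_ci: tuple[float, float]
    rr_point: float
    rr_ci: tuple[float, float]
    fisher_p_one: float
    fisher_p_two: float
    confidence: float
    flags: list[str] = field(default_factory=list)


def contingency_stats(
    table: ContingencyTable2x2, confidence: float = 0.95
) -> ContingencyResult:
    """OR (Haldane-corrected, Woolf CI), RR (Katz CI) and Fisher exact p.

    The +0.5 correction is applied to every cell of the OR unconditionally;
    the RR is the plain ratio of row risks with the standard Katz log-scale
    interval (undefined cells are flagged rather than corrected).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    flags: list[str] = []
    z = stats.norm.ppf(0.5 + confidence / 2.0)

    ah, bh, ch, dh = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (ah * dh) / (bh * ch)
    se_ln_or = math.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
    or_ci = (or_point * math.exp(-z * se_ln_or), or_point * math.exp(z * se_ln_or))

    risk1 = a / (a + b)
    risk2 = c / (c + d)
    if risk2 == 0:
        flags.append("rr_undefined")
        rr_point = math.inf
        rr_ci = (math.nan, math.nan)
    elif risk1 == 0:
        flags.append("rr_zero")
        rr_point = 0.0
        rr_ci = (math.nan, math.nan)
    else:
        rr_point = risk1 / risk2
        # Katz: SE(ln RR) = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))
        se_ln_rr = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        rr_ci = (rr_point * math.exp(-z * se_ln_rr), rr_point * math.exp(z * se_ln_rr))

    arr = table.as_array()
    _, fisher_p_two = stats.fisher_exact(arr, alternative="two-sided")
    _, fisher_p_one = stats.fisher_exact(arr, alternative="greater")
    return ContingencyResult(
        or_point=float(or_point),
        or_ci=(float(or_ci[0]), float(or_ci[1])),
        rr_point=float(rr_point),
        rr_ci=(float(rr_ci[0]), float(rr_ci[1])),
        fisher_p_one=float(fisher_p_one),
        fisher_p_two=float(fisher_p_two),
        confidence=confidence,
        flags=flags,
    )


@dataclass
class BurdenResult:
    t: float
    df: float
    p_one: float
    p_two: float
    levene_F: float
    levene_p: float
    variance_ratio_F: float
    variance_ratio_p: float
    variant: str
    d: float
    U_fallback: float
    p_fallback: float
    r_rank_biserial: float
    n1: int
    n2: int
    mean_control: float
    mean_case: float
    flags: list[str] = field(default_factory=list)


def burden_compare(control, case, tail: str = "one") -> BurdenResult:
    """Levene-gated t comparison of percent-positive burden, with companions.

    Always reports the variance-ratio F (larger/smaller variance, folded
    two-sided p) and the exact nonparametric Mann–Whitney companion with its
    rank-biserial effect size.  ``tail`` selects which p (one- or two-sided)
    a caller should treat as primary; both are present in the result.
    """
    control = np.asarray(control, dtype=float)
    case = np.asarray(case, dtype=float)
    tt: TTestResult = levene_gated_ttest(control, case)

    v1, v2 = control.var(ddof=1), case.var(ddof=1)
    if min(v1, v2) > 0:
        if v2 >= v1:
            F, dfn, dfd = v2 / v1, len(case) - 1, len(control) - 1
        else:
            F, dfn, dfd = v1 / v2, len(control) - 1, len(case) - 1
        vr_p = min(1.0, 2.0 * stats.f.sf(F, dfn, dfd))
    else:
        F, vr_p = math.inf if max(v1, v2) > 0 else math.nan, math.nan

    mw = mann_whitney_exact(control, case)
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    return BurdenResult(
        t=tt.t,
        df=tt.df,
        p_one=tt.p_one,
        p_two=tt.p_two,
        levene_F=tt.levene_F,
        levene_p=tt.levene_p,
        variance_ratio_F=float(F),
        variance_ratio_p=float(vr_p),
        variant=tt.variant,
        d=tt.d,
        U_fallback=mw.U,
        p_fallback=mw.p_one if tail == "one" else mw.p_two,
        r_rank_biserial=mw.r_rank_biserial,
        n1=tt.n1,
        n2=tt.n2,
        mean_control=float(np.nanmean(control)),
        mean_case=float(np.nanmean(case)),
        flags=list(tt.flags) + list(mw.flags),
    )
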