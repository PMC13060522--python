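"""PCA module scores, MANOVA and covariate-adjusted hierarchical regression.

Dimensionality reduction over the FDR-passing genes: group-mean imputation,
correlation-matrix PCA with regression-method component scores, scree-based
component retention, a two-group MANOVA on the retained scores, per-component
ANOVA effect sizes, and a two-model hierarchical regression adding a binary
covariate (e.g. head-injury history) on top of group.

Correlation-matrix PCA is used because genes sit on heterogeneous scales;
with more genes than cases the gene correlation matrix is rank-deficient,
so regression scores go through the Moore–Penrose pseudo-inverse (flagged).
Component signs are fixed so the gene with the largest |loading| loads
positively, making runs reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "PCAModel",
    "ManovaResult",
    "HierRegResult",
    "impute_group_mean",
    "fit_pca",
    "retain_components",
    "manova_two_group",
    "eta_squared_from_F",
    "hierarchical_regression",
]


def impute_group_mean(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Replace each missing entry with its gene's mean within the case's group.

    ``matrix`` is genes x cases; ``groups`` maps case_id -> group label.
    Every gene must have at least one observed value in each group.
    """
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        raise ValueError("every column must have a group label")
    out = matrix.copy().astype(float)
    for g in groups.unique():
        cols = groups.index[groups == g]
        block = out[cols]
        fully_missing = block.isna().all(axis=1)
        if fully_missing.any():
            bad = list(block.index[fully_missing])
            raise ValueError(f"genes fully missing in group {g!r}: {bad}")
        out[cols] = block.T.fillna(block.mean(axis=1)).T
    return out


@dataclass
class PCAModel:
    eigenvalues: np.ndarray          # descending, length = n_genes
    loadings: pd.DataFrame           # genes x components (all components)
    communalities: pd.Series         # per gene, over retained components
    var_explained: np.ndarray        # per component proportion
    scores: pd.DataFrame             # cases x retained components, unit variance
    n_retained: int
    flags: list[str] = field(default_factory=list)


def fit_pca(matrix: pd.DataFrame, n_retained: int | None = None,
            retention_rule: str = "scree-elbow") -> PCAModel:
    """Correlation-matrix PCA of a genes x cases expression matrix.

    Genes are standardized across cases (pooled mean/SD); the eigensystem of
    the gene correlation matrix gives loadings (eigenvectors scaled by
    sqrt(eigenvalue)); per-case regression scores are Z' R^+ L, standardized
    to unit variance.  ``n_retained`` overrides the retention rule.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix must have no missing values (impute first)")
    genes = matrix.index
    cases = matrix.columns
    X = matrix.to_numpy(dtype=float)  # genes x cases
    n_genes, n_cases = X.shape
    if n_genes < 2 or n_cases < 2:
        raise ValueError("need at least 2 genes and 2 cases")
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = list(genes[sd == 0])
        raise ValueError(f"constant genes cannot be standardized: {bad}")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]  # genes x cases
    R = np.corrcoef(X)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    flags: list[str] = []
    rank = int(np.sum(evals > 1e-10))
    if rank < n_genes:
        flags.append("rank_deficient")

    loadings = evecs * np.sqrt(evals)[None, :]
    # deterministic sign: gene with the largest |loading| loads positively
    for j in range(n_genes):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
            evecs[:, j] = -evecs[:, j]

    if n_retained is None:
        n_retained = retain_components(evals[evals > 1e-10], rule=retention_rule)
    n_retained = int(min(n_retained, rank))

    var_explained = evals / n_genes
    L = loadings[:, :n_retained]
    communalities = pd.Series((L**2).sum(axis=1), index=genes, name="communality")

    R_pinv = np.linalg.pinv(R, rcond=1e-10)
    raw_scores = Z.T @ R_pinv @ L  # cases x components
    ssd = raw_scores.std(axis=0, ddof=1)
    ssd[ssd == 0] = 1.0
    scores = (raw_scores - raw_scores.mean(axis=0)) / ssd

    return PCAModel(
        eigenvalues=evals,
        loadings=pd.DataFrame(loadings, index=genes,
                              columns=[f"PC{j+1}" for j in range(n_genes)]),
        communalities=communalities,
        var_explained=var_explained,
        scores=pd.DataFrame(scores, index=cases,
                            columns=[f"PC{j+1}" for j in range(n_retained)]),
        n_retained=n_retained,
        flags=flags,
    )


def retain_components(eigenvalues, rule: str = "scree-elbow", k: int = 2,
                      min_proportion: float = 0.05) -> int:
    """Number of components to keep from a descending eigenvalue sequence.

    scree-elbow: keep components up to and including the point maximizing
    the discrete second difference of the scree (the sharpest bend).
    fixed-k: always k.  min-proportion: components explaining at least the
    given proportion of total variance.
    """
    ev = np.asarray(list(eigenvalues), dtype=float)
    if ev.size == 0 or np.any(np.diff(ev) > 1e-12):
        raise ValueError("eigenvalues must be non-ascending and nonempty")
    if rule == "fixed-k":
        if k > ev.size:
            raise ValueError(f"requested k={k} but only {ev.size} eigenvalues")
        return int(k)
    if rule == "min-proportion":
        props = ev / ev.sum()
        return max(1, int((props >= min_proportion).sum()))
    if rule == "scree-elbow":
        if ev.size < 3 or np.allclose(ev, ev[0]):
            warnings.warn("degenerate scree; falling back to fixed-k", stacklevel=2)
            return int(min(k, ev.size))
        second = ev[:-2] - 2 * ev[1:-1] + ev[2:]
        # elbow at interior index argmax(second)+1 (0-based); keep through it
        return int(np.argmax(second)) + 2
    raise ValueError(f"unknown retention rule {rule!r}")


@dataclass
class ManovaResult:
    wilks_lambda: float
    F: float
    df: tuple[int, int]
    p: float


def manova_two_group(scores: pd.DataFrame, groups: pd.Series) -> ManovaResult:
    """Two-group MANOVA on case x component scores via Wilks' Λ.

    Λ = |W|/|T| (within vs total scatter); for two groups the exact F is
    ((1-Λ)/Λ) * (n-p-1)/p on (p, n-p-1) degrees of freedom, equivalent to
    Hotelling's T².
    """
    groups = groups.reindex(scores.index)
    if groups.isna().any():
        raise ValueError("every case needs a group label")
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    Y = scores.to_numpy(dtype=float)
    n, p = Y.shape
    if n <= p + 1:
        raise ValueError("total n must exceed number of components + 1")
    T = (Y - Y.mean(axis=0)).T @ (Y - Y.mean(axis=0))
    W = np.zeros((p, p))
    for g in levels:
        Yg = Y[(groups == g).to_numpy()]
        if len(Yg) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cases")
        W += (Yg - Yg.mean(axis=0)).T @ (Yg - Yg.mean(axis=0))
    detW, detT = np.linalg.det(W), np.linalg.det(T)
    if detW <= 0 or detT <= 0:
        raise ValueError("singular within- or total-scatter matrix")
    lam = detW / detT
    df1, df2 = p, n - p - 1
    F = (1 - lam) / lam * df2 / df1
    pval = float(stats.f.sf(F, df1, df2))
    return ManovaResult(wilks_lambda=float(lam), F=float(F), df=(df1, df2), p=pval)


def eta_squared_from_F(F: float, df1: int, df2: int) -> float:
    """Variance explained implied by an F statistic: η² = F·df1/(F·df1+df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("F must be >= 0 and dfs positive")
    return F * df1 / (F * df1 + df2)


@dataclass
class HierRegResult:
    r2_model1: float
    f_model1: float
    df_model1: tuple[int, int]
    p_model1: float
    beta_group_m1: float
    r2_model2: float
    beta_group_m2: float
    beta_cov_m2: float
    p_cov_m2: float
    delta_r2: float
    f_change: float
    df_change: tuple[int, int]
    p_change: float
    n: int
    flags: list[str] = field(default_factory=list)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


def hierarchical_regression(
    y,
    group,
    covariate=None,
    unknown_policy: str = "as_no",
) -> HierRegResult:
    """Two-model OLS on standardized variables: group, then group + covariate.

    ``group`` is binary (0/1 or two labels); ``covariate`` may contain
    "unknown"/None entries, handled per policy: "as_no" recodes them to the
    absent level (default), "listwise" drops those cases from both models.
    ΔR² is tested with F-change = ΔR² / ((1-R²₂)/(n-3)) on (1, n-3) df.
    """
    y = np.asarray(y, dtype=float)
    group = pd.Series(list(group))
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError("group must have exactly two levels")
    g = (group == levels[-1]).to_numpy(dtype=float)

    flags: list[str] = []
    if covariate is None:
        cov = None
    else:
        cov_raw = pd.Series(list(covariate)).astype(object)
        is_unknown = cov_raw.isin(["unknown", "Unknown", None, np.nan])
        if unknown_policy == "as_no":
            cov_raw[is_unknown] = "no"
            keep = np.ones(len(y), dtype=bool)
        elif unknown_policy == "listwise":
            keep = (~is_unknown).to_numpy()
            cov_raw = cov_raw[keep]
        else:
            raise ValueError(f"unknown policy {unknown_policy!r}")
        y = y[keep]
        g = g[keep]
        cov = cov_raw.isin(["yes", "Yes", 1, True, "1"]).to_numpy(dtype=float)

    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 cases")
    ys = _standardize(y)
    gs = _standardize(g)

    X1 = sm.add_constant(gs)
    m1 = sm.OLS(ys, X1).fit()
    r2_1 = float(m1.rsquared)
    f1 = float(m1.fvalue)
    p1 = float(m1.f_pvalue)
    beta_g1 = float(m1.params[1])

    if cov is None or np.all(cov == cov[0]):
        if cov is not None:
            flags.append("covariate_constant")
        return HierRegResult(
            r2_model1=r2_1, f_model1=f1, df_model1=(1, n - 2), p_model1=p1,
            beta_group_m1=beta_g1, r2_model2=r2_1, beta_group_m2=beta_g1,
            beta_cov_m2=math.nan, p_cov_m2=math.nan, delta_r2=0.0,
            f_change=math.nan, df_change=(1, n - 3), p_change=math.nan,
            n=n, flags=flags,
        )

    cs = _standardize(cov)
    if np.allclose(cs, gs) or np.allclose(cs, -gs):
        flags.append("covariate_collinear_with_group")
        return HierRegResult(
            r2_model1=r2_1, f_model1=f1, df_model1=(1, n - 2), p_model1=p1,
            beta_group_m1=beta_g1, r2_model2=r2_1, beta_group_m2=beta_g1,
            beta_cov_m2=math.nan, p_cov_m2=math.nan, delta_r2=0.0,
            f_change=math.nan, df_change=(1, n - 3), p_change=math.nan,
            n=n, flags=flags,
        )

    X2 = sm.add_constant(np.column_stack([gs, cs]))
    m2 = sm.OLS(ys, X2).fit()
    r2_2 = float(m2.rsquared)
    delta = r2_2 - r2_1
    df2 = n - 3
    if r2_2 >= 1.0 - 1e-12:
        flags.append("model2_saturated")
        f_change, p_change = math.inf, 0.0
    else:
        f_change = delta / ((1.0 - r2_2) / df2)
        p_change = float(stats.f.sf(f_change, 1, df2))
    return HierRegResult(
        r2_model1=r2_1, f_model1=f1, df_model1=(1, n - 2), p_model1=p1,
        beta_group_m1=beta_g1,
        r2_model2=r2_2,
        beta_group_m2=float(m2.params[1]),
        beta_cov_m2=float(m2.params[2]),
        p_cov_m2=float(m2.pvalues[2]),
        delta_r2=float(delta),
        f_change=float(f_change),
        df_change=(1, df2),
        p_change=p_change,
        n=n,
        flags=flags,
    )
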