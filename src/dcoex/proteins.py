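"""Grouped protein-panel testing, loading-control QC, and PMI quality control.

Protein targets are organized a priori into four biological categories
(pathology, gliosis, excitatory, inhibitory).  Each target gets the same
outlier-screened, Levene-gated t framework used for gene expression;
Benjamini–Hochberg correction is applied *within* each category, preserving
power inside mechanistically coherent domains.  Per-target loading-control
totals are compared between groups as a QC for differential loading, and
targets with significant group effects are re-examined with the two-model
hierarchical regression adding the binary covariate.

The postmortem-interval (PMI) QC correlates PMI against pathology burden,
the first principal component of the full gene matrix, and total protein
abundance, before any outlier removal.  Both product-moment (Pearson) and
rank (Spearman) coefficients are reported side by side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues, levene_gated_ttest, tukey_outlier_mask
from .modules import HierRegResult, fit_pca, hierarchical_regression, impute_group_mean
from .synthetic import Cohort

__all__ = ["PanelResult", "panel_tests", "pmi_qc"]

CATEGORIES = ("pathology", "gliosis", "excitatory", "inhibitory")


@dataclass
class PanelResult:
    table: pd.DataFrame                    # per-target statistics
    regressions: dict[str, HierRegResult]  # for targets significant at alpha
    excluded: dict[str, str]               # target -> reason
    alpha: float


def _validate_panel(table: pd.DataFrame) -> None:
    required = {"target", "category", "case_id", "normalized_abundance",
                "loading_control_total"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"protein table missing columns: {sorted(missing)}")
    dup = table.duplicated(subset=["target", "case_id"])
    if dup.any():
        raise ValueError("duplicate (target, case_id) rows in protein table")
    bad = set(table["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown protein categories: {sorted(bad)}")


def panel_tests(
    table: pd.DataFrame,
    groups: pd.Series,
    *,
    tail: str = "two",
    alpha: float = 0.05,
    outlier_screen: bool = True,
    covariate: pd.Series | None = None,
    control_label: str = "control",
    case_label: str = "case",
) -> PanelResult:
    """Category-wise protein testing with per-target loading-control QC.

    ``table`` is long-format as produced by the generator/ingestion;
    ``groups`` maps case_id -> group.  ``tail`` selects the p used for
    category-wise FDR ("one" = directed case > control, "two" = default,
    since panel targets move in both directions).
    """
    _validate_panel(table)
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    rows = []
    excluded: dict[str, str] = {}
    for target, sub in table.groupby("target", sort=True):
        sub = sub.set_index("case_id")
        grp = groups.reindex(sub.index)
        vals = sub["normalized_abundance"].to_numpy(dtype=float)
        ctrl = vals[(grp == control_label).to_numpy()]
        case = vals[(grp == case_label).to_numpy()]
        n_out = 0
        if outlier_screen:
            m1, m2 = tukey_outlier_mask(ctrl), tukey_outlier_mask(case)
            n_out = int(m1.sum() + m2.sum())
            ctrl, case = ctrl[~m1], case[~m2]
        ctrl = ctrl[~np.isnan(ctrl)]
        case = case[~np.isnan(case)]
        if len(ctrl) < 2 or len(case) < 2:
            excluded[target] = "fewer than 2 cases in a group after screening"
            continue
        tt = levene_gated_ttest(ctrl, case)
        lc = sub["loading_control_total"].to_numpy(dtype=float)
        lc_ctrl = lc[(grp == control_label).to_numpy()]
        lc_case = lc[(grp == case_label).to_numpy()]
        lc_tt = levene_gated_ttest(lc_ctrl, lc_case)
        rows.append(
            dict(
                target=target,
                category=sub["category"].iloc[0],
                t=tt.t, df=tt.df, p_one=tt.p_one, p_two=tt.p_two,
                levene_F=tt.levene_F, levene_p=tt.levene_p, variant=tt.variant,
                d=tt.d, n_control=tt.n1, n_case=tt.n2,
                n_outliers_removed=n_out,
                loading_t=lc_tt.t, loading_p=lc_tt.p_two,
            )
        )
    out = pd.DataFrame(rows).set_index("target")
    pcol = "p_one" if tail == "one" else "p_two"
    out["q"] = np.nan
    for cat, idx in out.groupby("category").groups.items():
        out.loc[idx, "q"] = bh_qvalues(out.loc[idx, pcol].to_numpy())

    regressions: dict[str, HierRegResult] = {}
    sig = out.index[out[pcol] < alpha]
    for target in sig:
        sub = table[table["target"] == target].set_index("case_id")
        grp = groups.reindex(sub.index)
        y = sub["normalized_abundance"].to_numpy(dtype=float)
        cov = covariate.reindex(sub.index) if covariate is not None else None
        try:
            regressions[target] = hierarchical_regression(
                y, grp, cov if cov is not None else None
            )
        except ValueError as exc:
            excluded[target] = f"regression failed: {exc}"
    return PanelResult(table=out, regressions=regressions, excluded=excluded,
                       alpha=alpha)


def _corr_pair(x, y) -> dict:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return dict(pearson_r=math.nan, pearson_p=math.nan,
                    spearman_rho=math.nan, spearman_p=math.nan, n=len(x),
                    flag="undefined")
    pr, pp = stats.pearsonr(x, y)
    sr, sp = stats.spearmanr(x, y)
    return dict(pearson_r=float(pr), pearson_p=float(pp),
                spearman_rho=float(sr), spearman_p=float(sp), n=len(x), flag="")


def pmi_qc(cohort: Cohort) -> pd.DataFrame:
    """PMI quality-control correlations, computed before any outlier removal.

    Rows: each pathology burden column, the first principal component of
    the full gene matrix (group-mean imputed), and per-case total protein
    abundance.  Columns: Pearson and Spearman coefficients with two-sided p.
    """
    meta = cohort.metadata
    pmi = meta["pmi"]
    if pmi.nunique() <= 1:
        raise ValueError("constant PMI: correlations undefined")
    rows = {}
    for col in ("burden_amygdala", "burden_with_ec"):
        if col in cohort.pathology.columns:
            burden = cohort.pathology[col].reindex(pmi.index)
            rows[f"pmi_vs_{col}"] = _corr_pair(pmi, burden)

    expr = cohort.expression
    usable = expr.dropna(how="all")
    # genes must be observed in each group to group-mean impute; drop the rest
    grp = cohort.groups()
    ok = pd.Series(True, index=usable.index)
    for g in grp.unique():
        cols = grp.index[grp == g]
        ok &= usable[cols].notna().any(axis=1)
    usable = usable[ok]
    usable = usable[usable.std(axis=1, ddof=1) > 0]
    if len(usable) >= 2:
        imputed = impute_group_mean(usable, grp)
        imputed = imputed[imputed.std(axis=1, ddof=1) > 0]
        pca = fit_pca(imputed, n_retained=1)
        pc1 = pca.scores["PC1"].reindex(pmi.index)
        rows["pmi_vs_expression_pc1"] = _corr_pair(pmi, pc1)

    totals = cohort.proteins.groupby("case_id")["normalized_abundance"].sum()
    rows["pmi_vs_total_protein"] = _corr_pair(pmi, totals.reindex(pmi.index))
    return pd.DataFrame(rows).T
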