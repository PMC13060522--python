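"""Per-gene directional differential expression with FDR thresholding.

The pipeline for each gene: within-group Tukey-fence outlier screening,
a Levene-gated (pooled vs Welch) t-test on log2 expression, fold change as
the ratio of group geometric means, Cohen's d via d = t*sqrt(1/n1+1/n2),
then Benjamini–Hochberg q-values across genes and a discovery curve to
guide the q threshold (default 0.2, with 0.05/0.1 reported alongside).

Tests run on the log2 scale because relative quantities are ratio-scale
data; fold changes are reported on the linear scale.  The one-tailed
default direction is case > control (the directed hypothesis that disease-
related genes are upregulated); two-tailed values are always carried.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import (
    bh_qvalues,
    levene_gated_ttest,
    tukey_outlier_mask,
    zscore_outlier_mask,
)

__all__ = [
    "GeneStat",
    "DiscoveryCurve",
    "screen_outliers",
    "gene_t_test",
    "bh_qvalues",
    "discovery_curve",
    "run_de",
]

DEFAULT_Q_THRESHOLDS = (0.05, 0.1, 0.2)


def screen_outliers(values, rule: str = "tukey", **kw) -> np.ndarray:
    """Boolean outlier mask for one group's values (True = flagged).

    rule="tukey": 1.5*IQR fences (default); rule="zscore": |z| > 3.
    Fewer than 3 non-missing values: nothing is screened.
    """
    if rule == "tukey":
        return tukey_outlier_mask(values, **kw)
    if rule == "zscore":
        return zscore_outlier_mask(values, **kw)
    raise ValueError(f"unknown outlier rule {rule!r}")


@dataclass
class GeneStat:
    gene_id: str
    fc: float
    log2fc: float
    t: float
    df: float
    p_one: float
    p_two: float
    levene_F: float
    levene_p: float
    variant: str
    d: float
    q: float | None
    n_used: tuple[int, int]
    flags: list[str] = field(default_factory=list)


def gene_t_test(
    control,
    case,
    tail: str = "one",
    scale: str = "log2",
    gene_id: str = "",
) -> GeneStat:
    """Levene-gated two-sample t-test for one gene.

    Values are linear relative quantities (strictly positive); the test is
    run on log2(values) unless ``scale='linear'``.  Fold change is the ratio
    of geometric means case/control regardless of the test scale.
    """
    control = np.asarray(control, dtype=float)
    case = np.asarray(case, dtype=float)
    control = control[~np.isnan(control)]
    case = case[~np.isnan(case)]
    if np.any(control <= 0) or np.any(case <= 0):
        raise ValueError("expression values must be strictly positive")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")

    log2fc = float(np.log2(case).mean() - np.log2(control).mean())
    fc = float(2.0**log2fc)
    if scale == "log2":
        x, y = np.log2(control), np.log2(case)
    elif scale == "linear":
        x, y = control, case
    else:
        raise ValueError(f"unknown scale {scale!r}")
    tt = levene_gated_ttest(x, y)
    flags = list(tt.flags)
    if np.sign(tt.t) != 0 and np.sign(log2fc) != np.sign(tt.t) and scale == "linear":
        # possible when arithmetic and geometric orderings disagree
        flags.append("fc_t_sign_mismatch")
    return GeneStat(
        gene_id=gene_id,
        fc=fc,
        log2fc=log2fc,
        t=tt.t,
        df=tt.df,
        p_one=tt.p_one,
        p_two=tt.p_two,
        levene_F=tt.levene_F,
        levene_p=tt.levene_p,
        variant=tt.variant,
        d=tt.d,
        q=None,
        n_used=(tt.n1, tt.n2),
        flags=flags,
    )


@dataclass
class DiscoveryCurve:
    q_grid: np.ndarray
    discoveries: np.ndarray
    inflection_q: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"q_threshold": self.q_grid, "discoveries": self.discoveries})


def discovery_curve(qvals, q_grid=None) -> DiscoveryCurve:
    """Discoveries (count of q <= threshold) along an ascending q grid.

    The inflection estimate is the grid point maximizing the discrete second
    difference of the count curve — a documented heuristic; the threshold
    choice remains the analyst's (default downstream: 0.2).
    """
    q = np.asarray(list(qvals), dtype=float)
    if q_grid is None:
        q_grid = np.round(np.arange(0.01, 0.51, 0.01), 10)
    grid = np.asarray(list(q_grid), dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0) or grid[0] <= 0 or grid[-1] >= 1:
        raise ValueError("q_grid must be strictly ascending within (0, 1)")
    disc = np.array([(q <= g).sum() for g in grid], dtype=int)
    inflection = None
    if grid.size >= 3:
        second = disc[:-2] - 2 * disc[1:-1] + disc[2:]
        if np.any(second != 0):
            inflection = float(grid[1 + int(np.argmax(second))])
    return DiscoveryCurve(q_grid=grid, discoveries=disc, inflection_q=inflection)


def run_de(
    expression: pd.DataFrame,
    groups: pd.Series,
    *,
    tail: str = "one",
    scale: str = "log2",
    outlier_rule: str | None = "tukey",
    control_label: str = "control",
    case_label: str = "case",
    q_thresholds=DEFAULT_Q_THRESHOLDS,
) -> pd.DataFrame:
    """Screen → test → fold change → BH for a genes x cases matrix.

    Parameters
    ----------
    expression : DataFrame indexed by gene_id with case-id columns (linear
        relative quantities, NaN = missing).
    groups : Series mapping case_id -> group label.

    Returns a table sorted by the tail-selected p with per-gene exclusions
    recorded in ``flags`` and an ``excluded`` boolean.  q-values are BH over
    the genes actually tested; ``sig_at_<thr>`` columns mark each reporting
    threshold.
    """
    groups = groups.reindex(expression.columns)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise ValueError(f"cases missing group labels: {missing}")
    ctrl_cols = groups.index[groups == control_label]
    case_cols = groups.index[groups == case_label]
    if len(ctrl_cols) == 0 or len(case_cols) == 0:
        raise ValueError("both group labels must be present among cases")

    rows = []
    for gene_id, row in expression.iterrows():
        ctrl = row[ctrl_cols].to_numpy(dtype=float)
        case = row[case_cols].to_numpy(dtype=float)
        flags = []
        n_out = 0
        if outlier_rule is not None:
            m1 = screen_outliers(ctrl, rule=outlier_rule)
            m2 = screen_outliers(case, rule=outlier_rule)
            n_out = int(m1.sum() + m2.sum())
            ctrl = ctrl.copy()
            case = case.copy()
            ctrl[m1] = np.nan
            case[m2] = np.nan
            if n_out:
                flags.append("outliers_removed")
        ctrl = ctrl[~np.isnan(ctrl)]
        case = case[~np.isnan(case)]
        if len(ctrl) < 2 or len(case) < 2:
            rows.append(
                dict(gene_id=gene_id, excluded=True,
                     reason="fewer than 2 values in a group after screening",
                     n_control=len(ctrl), n_case=len(case),
                     n_outliers_removed=n_out)
            )
            continue
        gs = gene_t_test(ctrl, case, tail=tail, scale=scale, gene_id=str(gene_id))
        rows.append(
            dict(
                gene_id=gene_id, excluded=False, reason="",
                fc=gs.fc, log2fc=gs.log2fc, t=gs.t, df=gs.df,
                p_one=gs.p_one, p_two=gs.p_two,
                levene_F=gs.levene_F, levene_p=gs.levene_p,
                variant=gs.variant, d=gs.d,
                n_control=gs.n_used[0], n_case=gs.n_used[1],
                n_outliers_removed=n_out,
                flags=";".join(flags + gs.flags),
            )
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    pcol = "p_one" if tail == "one" else "p_two"
    tested = table.index[~table["excluded"] & table[pcol].notna()]
    table["q"] = np.nan
    if len(tested):
        table.loc[tested, "q"] = bh_qvalues(table.loc[tested, pcol].to_numpy())
    for thr in q_thresholds:
        table[f"sig_at_{thr}"] = table["q"] <= thr
    return table.sort_values(pcol, na_position="last")
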