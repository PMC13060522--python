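"""End-to-end pipeline: ingest → PMI QC → pathology → DE → modules → network
→ proteins → report.

PMI quality control runs first, before any outlier removal, because it must
see the unscreened data.  Identical config and inputs produce byte-identical
outputs; all floating-point output is printed at 4 significant decimals.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import discovery_curve, run_de
from .io import ingest
from .modules import (
    eta_squared_from_F,
    fit_pca,
    hierarchical_regression,
    impute_group_mean,
    manova_two_group,
)
from .network import annotate_and_export, build_network, read_sif, topology
from .pathology import (
    ContingencyTable2x2,
    burden_compare,
    colocalization_index,
    contingency_stats,
    index_group_test,
)
from .proteins import panel_tests, pmi_qc
from .synthetic import Cohort

log = logging.getLogger("dcoex")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    expression_path: str | None = None
    metadata_path: str | None = None
    pathology_path: str | None = None
    proteins_path: str | None = None
    curated_sif_path: str | None = None
    out_dir: str = "dcoex_out"
    tail: str = "one"
    outlier_rule: str = "tukey"
    levene_alpha: float = 0.05
    fdr_thresholds: tuple = (0.05, 0.1, 0.2)
    de_q_threshold: float = 0.2
    novel_rho_min: float = 0.9
    novel_p_max: float = 0.05
    retention_rule: str = "scree-elbow"
    unknown_covariate_policy: str = "as_no"
    protein_tail: str = "two"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("expression_path", "metadata_path", "pathology_path",
                     "proteins_path", "curated_sif_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file: {p}")
        for thr in (*self.fdr_thresholds, self.de_q_threshold, self.novel_p_max):
            if not 0 < thr < 1:
                raise ValueError(f"thresholds must lie in (0, 1), got {thr}")


def _round(x, nd=4):
    if isinstance(x, float):
        if math.isnan(x):
            return None
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        return float(f"{x:.4g}")
    return x


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _round(float(obj))
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (pd.Series,)):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="index"))
    return obj


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Execute every stage in order and write all outputs under out_dir.

    A pre-built Cohort (e.g. from the generator) may be passed directly;
    otherwise the configured input files are ingested.  Returns the report
    dict (also written as report.json).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": _jsonable(dataclasses.asdict(config)),
                    "stages": {}}
    timings: dict[str, float] = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception:
                log.exception("stage %s failed", name)
                raise RuntimeError(f"pipeline stage {name!r} failed") from None
            timings[name] = round(time.perf_counter() - t0, 3)
            report["stages"][name] = _jsonable(result)
            return result
        return wrap

    if cohort is None:
        if config.expression_path is None or config.metadata_path is None:
            raise ValueError("either a cohort or expression+metadata paths are required")
        cohort = ingest(config.expression_path, config.metadata_path,
                        config.pathology_path, config.proteins_path)
    groups = cohort.groups()
    meta = cohort.metadata

    # -- QC first: must precede outlier removal ------------------------------
    def qc_stage():
        qc = pmi_qc(cohort)
        qc.to_csv(out / "pmi_qc.tsv", sep="\t", float_format="%.4g")
        return {"table": qc}
    stage("pmi_qc")(qc_stage)

    # -- pathology -----------------------------------------------------------
    def pathology_stage():
        path = cohort.pathology
        if path.empty:
            return {"skipped": "no pathology table"}
        idx = path.apply(
            lambda r: colocalization_index(r["amyloid_pos"], r["tau_pos"]), axis=1
        )
        g = groups.reindex(path.index)
        ctrl_idx = idx[g == "control"].tolist()
        case_idx = idx[g == "case"].tolist()
        res = {"index_control": ctrl_idx, "index_case": case_idx}
        res["index_test"] = index_group_test(ctrl_idx, case_idx)
        dual = (path["amyloid_pos"] & path["tau_pos"])
        a = int((dual & (g == "case")).sum())
        b = int((~dual & (g == "case")).sum())
        c = int((dual & (g == "control")).sum())
        d = int((~dual & (g == "control")).sum())
        res["dual_table"] = {"a": a, "b": b, "c": c, "d": d}
        try:
            res["contingency"] = contingency_stats(ContingencyTable2x2(a, b, c, d))
        except ValueError as exc:
            res["contingency"] = {"error": str(exc)}
        for col in ("burden_amygdala", "burden_with_ec"):
            if col in path.columns:
                res[f"burden_{col}"] = burden_compare(
                    path.loc[g == "control", col], path.loc[g == "case", col],
                    tail=config.tail,
                )
        return res
    stage("pathology")(pathology_stage)

    # -- differential expression --------------------------------------------
    def de_stage():
        table = run_de(cohort.expression, groups, tail=config.tail,
                       outlier_rule=config.outlier_rule,
                       q_thresholds=config.fdr_thresholds)
        table.to_csv(out / "gene_stats.tsv", sep="\t", float_format="%.4g")
        curve = discovery_curve(table["q"].dropna())
        curve.to_frame().to_csv(out / "discovery_curve.tsv", sep="\t", index=False)
        n_sig = int((table["q"] <= config.de_q_threshold).sum())
        return {
            "n_tested": int((~table["excluded"]).sum()),
            "n_excluded": int(table["excluded"].sum()),
            "n_significant": n_sig,
            "inflection_q": curve.inflection_q,
        }
    de_result = stage("diffexpr")(de_stage)
    de_table = pd.read_csv(out / "gene_stats.tsv", sep="\t", index_col=0)

    # -- module scoring ------------------------------------------------------
    def module_stage():
        passing = de_table.index[
            de_table["q"].notna() & (de_table["q"] <= config.de_q_threshold)
        ]
        if len(passing) < 3:
            return {"skipped": f"only {len(passing)} FDR-passing genes"}
        sub = cohort.expression.loc[passing]
        sub = np.log2(sub)
        imputed = impute_group_mean(sub, groups)
        imputed = imputed[imputed.std(axis=1, ddof=1) > 0]
        pca = fit_pca(imputed, retention_rule=config.retention_rule)
        pca.loadings.iloc[:, : pca.n_retained].to_csv(
            out / "pca_loadings.tsv", sep="\t", float_format="%.4g")
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.4g")
        res = {
            "n_genes": int(imputed.shape[0]),
            "n_retained": pca.n_retained,
            "var_explained": pca.var_explained[: pca.n_retained],
            "communalities_min": float(pca.communalities.min()),
        }
        scores = pca.scores
        if pca.n_retained >= 1 and scores.shape[0] > pca.n_retained + 1:
            if pca.n_retained >= 2:
                res["manova"] = manova_two_group(scores, groups)
            comps = {}
            for comp in scores.columns:
                hr = hierarchical_regression(
                    scores[comp].to_numpy(),
                    groups.reindex(scores.index),
                    meta["covariate"].reindex(scores.index),
                    unknown_policy=config.unknown_covariate_policy,
                )
                comps[comp] = {
                    "anova_F": hr.f_model1,
                    "anova_df": hr.df_model1,
                    "eta_squared": eta_squared_from_F(hr.f_model1, *hr.df_model1),
                    "regression": hr,
                }
            res["components"] = comps
        return res
    module_result = stage("module_scoring")(module_stage)

    # -- network -------------------------------------------------------------
    def network_stage():
        passing = de_table.index[
            de_table["q"].notna() & (de_table["q"] <= config.de_q_threshold)
        ]
        if len(passing) < 3:
            return {"skipped": f"only {len(passing)} FDR-passing genes"}
        curated = read_sif(config.curated_sif_path) if config.curated_sif_path else []
        G = build_network(
            cohort.expression.loc[passing], groups, curated,
            rho_min=config.novel_rho_min, p_max=config.novel_p_max,
        )
        loadings = None
        if (out / "pca_loadings.tsv").exists():
            loadings = pd.read_csv(out / "pca_loadings.tsv", sep="\t", index_col=0)
        annotate_and_export(G, de_table, loadings, out, prefix="network")
        rep, _nodes = topology(G)
        return {"topology": rep,
                "n_curated_dropped": G.graph.get("n_curated_dropped", 0)}
    stage("network")(network_stage)

    # -- proteins ------------------------------------------------------------
    def protein_stage():
        if cohort.proteins is None or cohort.proteins.empty:
            return {"skipped": "no protein table"}
        panel = panel_tests(
            cohort.proteins, groups, tail=config.protein_tail,
            covariate=meta["covariate"],
        )
        panel.table.to_csv(out / "protein_stats.tsv", sep="\t", float_format="%.4g")
        return {
            "n_targets": int(panel.table.shape[0]),
            "n_excluded": len(panel.excluded),
            "significant": {t: r for t, r in panel.regressions.items()},
            "excluded": panel.excluded,
        }
    stage("proteins")(protein_stage)

    report["timings_s"] = timings
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    log.info("pipeline complete: %s", out / "report.json")
    return report
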