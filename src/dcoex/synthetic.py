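"""Synthetic case-control cohorts with recorded ground truth.

The generator emulates the statistical structure of a small postmortem
case-control study: two groups of ~5 donors; ~84 genes whose log2 expression
follows a latent-factor model (two correlated modules) plus a planted
group fold change and log2-normal noise; injected missing values and
symmetric outliers; binary dual tau/amyloid pathology with per-group rates
and continuous percent-positive burden; a protein panel with per-target
categories and planted standardized effects; a binary covariate (e.g. head-
injury history) associated with group; and postmortem-interval values drawn
independently of all signal.

On the log2 scale a gene with loading lambda on latent factor F has value

    mu + 1{case} * log2(fc) + noise_sd * (lambda*F + sqrt(1-lambda^2)*eps)

so the implied within-module correlation between two genes with loadings
l1, l2 is l1*l2, the total log2 SD is noise_sd, and the planted Cohen's d
is log2(fc)/noise_sd.

One global seed drives independent per-modality substreams (expression,
proteins, pathology, covariates, missingness/outliers), so adding one
modality never perturbs another.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "CaseRecord",
    "PlantedTruth",
    "Cohort",
    "generate_cohort",
    "truth_report",
    "write_cohort",
    "read_cohort",
]

PROTEIN_CATEGORIES = ("pathology", "gliosis", "excitatory", "inhibitory")


@dataclass
class CohortConfig:
    """Study-condition parameters for one simulated cohort."""

    n_per_group: int = 5
    n_genes: int = 84
    #: list of (gene index set, latent-factor loading in [0, 1])
    module_spec: list = field(
        default_factory=lambda: [
            (tuple(range(0, 12)), 0.85),
            (tuple(range(12, 20)), 0.8),
        ]
    )
    #: gene index -> linear fold change (case/control); defaults emulate the
    #: observed 1.5-6.7x upregulation across ~20 genes
    planted_fc: dict = field(
        default_factory=lambda: {
            **{i: fc for i, fc in enumerate(
                [2.1, 2.2, 2.7, 1.7, 6.7, 4.3, 2.4, 1.5, 3.1, 2.3, 2.7, 6.5])},
            **{i: fc for i, fc in zip(range(12, 20),
                                      [2.5, 4.0, 1.9, 1.5, 1.6, 1.8, 2.0, 2.9])},
        }
    )
    noise_sd: float = 0.75
    missing_rate: float = 0.02
    outlier_rate: float = 0.02
    outlier_magnitude: float = 4.0
    #: per-group probability of dual tau/amyloid positivity
    dual_pathology_prob: dict = field(
        default_factory=lambda: {"control": 0.25, "case": 1.0}
    )
    #: P(covariate = yes | case); P(yes | control) is its complement
    covariate_group_assoc: float = 0.6
    covariate_unknown_rate: float = 0.2
    pmi_range: tuple = (5.0, 48.0)
    #: target -> (category, planted Cohen's d)
    protein_spec: dict = field(
        default_factory=lambda: {
            "ptau": ("pathology", 2.6), "abeta": ("pathology", 4.6),
            "total_tau": ("pathology", 0.0), "neuronal_marker": ("pathology", 0.0),
            "microglia_cd68": ("gliosis", 1.6), "astro_vim": ("gliosis", 1.4),
            "astro_gfap": ("gliosis", 0.0), "microglia_iba1": ("gliosis", 0.0),
            "ampar1": ("excitatory", 2.2), "mglur5": ("excitatory", 1.8),
            "nmdar1": ("excitatory", 0.0), "vglut1": ("excitatory", 0.0),
            "gababr1a": ("inhibitory", -5.0), "gad67": ("inhibitory", 0.0),
            "vgat": ("inhibitory", 0.0), "gababr2": ("inhibitory", 0.0),
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_per_group, (int, np.integer)) and self.n_per_group >= 2):
            raise ValueError("n_per_group must be an integer >= 2")
        if not (isinstance(self.n_genes, (int, np.integer)) and self.n_genes >= 1):
            raise ValueError("n_genes must be a positive integer")
        for prob_name in ("missing_rate", "outlier_rate", "covariate_group_assoc",
                          "covariate_unknown_rate"):
            v = getattr(self, prob_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{prob_name} must lie in [0, 1], got {v}")
        for g, p in self.dual_pathology_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"dual_pathology_prob[{g!r}] must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for idx, fc in self.planted_fc.items():
            if fc <= 0:
                raise ValueError(f"planted_fc[{idx}] must be strictly positive")
            if not 0 <= idx < self.n_genes:
                raise ValueError(f"planted_fc index {idx} outside [0, n_genes)")
        for genes, loading in self.module_spec:
            if not 0.0 <= loading <= 1.0:
                raise ValueError("module loadings must lie in [0, 1]")
            if any(not 0 <= g < self.n_genes for g in genes):
                raise ValueError("module gene indices must lie in [0, n_genes)")
        if not (len(self.pmi_range) == 2 and 0 <= self.pmi_range[0] < self.pmi_range[1]):
            raise ValueError("pmi_range must be (low, high) with 0 <= low < high")
        for target, (cat, _d) in self.protein_spec.items():
            if cat not in PROTEIN_CATEGORIES:
                raise ValueError(f"protein {target!r} has unknown category {cat!r}")


@dataclass
class CaseRecord:
    case_id: str
    group: str  # "control" | "case"
    age: float
    pmi: float
    covariate: str  # "yes" | "no" | "unknown"


@dataclass
class PlantedTruth:
    de_genes: dict  # gene_id -> {"fc": ..., "d": ...}
    module_membership: dict  # gene_id -> module index
    true_correlations: pd.DataFrame  # latent-implied gene correlation matrix
    protein_effects: dict  # target -> true d

    def to_jsonable(self) -> dict:
        return {
            "de_genes": self.de_genes,
            "module_membership": self.module_membership,
            "true_correlations": {
                "genes": list(self.true_correlations.index),
                "matrix": self.true_correlations.to_numpy().tolist(),
            },
            "protein_effects": self.protein_effects,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "PlantedTruth":
        corr = pd.DataFrame(
            np.asarray(d["true_correlations"]["matrix"], dtype=float),
            index=d["true_correlations"]["genes"],
            columns=d["true_correlations"]["genes"],
        )
        return cls(
            de_genes={k: dict(v) for k, v in d["de_genes"].items()},
            module_membership={k: int(v) for k, v in d["module_membership"].items()},
            true_correlations=corr,
            protein_effects={k: float(v) for k, v in d["protein_effects"].items()},
        )


@dataclass
class Cohort:
    cases: list  # of CaseRecord
    expression: pd.DataFrame  # genes x cases, linear scale, NaN = missing
    proteins: pd.DataFrame    # long: target, category, case_id, abundance, loading control
    pathology: pd.DataFrame   # per case: amyloid_pos, tau_pos, burdens
    truth: PlantedTruth | None = None

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            [asdict(c) for c in self.cases]
        ).set_index("case_id")

    def groups(self) -> pd.Series:
        return self.metadata["group"]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:03d}" for i in range(n)]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one cohort under the configured study conditions (deterministic
    under a fixed seed)."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("expression", "proteins", "pathology", "covariates", "corruption"),
            root.spawn(5),
        )
    }

    n = config.n_per_group
    n_cases = 2 * n
    case_ids = [f"C{i:02d}" for i in range(n)] + [f"P{i:02d}" for i in range(n)]
    group = ["control"] * n + ["case"] * n
    genes = _gene_ids(config.n_genes)

    # --- metadata -----------------------------------------------------------
    rng_cov = streams["covariates"]
    ages = rng_cov.uniform(70, 80, n_cases).round(1)
    pmis = rng_cov.uniform(*config.pmi_range, n_cases).round(2)
    covariate = []
    for g in group:
        p_yes = config.covariate_group_assoc if g == "case" else 1 - config.covariate_group_assoc
        val = "yes" if rng_cov.random() < p_yes else "no"
        if rng_cov.random() < config.covariate_unknown_rate:
            val = "unknown"
        covariate.append(val)
    cases = [
        CaseRecord(case_id=cid, group=g, age=float(a), pmi=float(p), covariate=c)
        for cid, g, a, p, c in zip(case_ids, group, ages, pmis, covariate)
    ]

    # --- expression ---------------------------------------------------------
    rng_expr = streams["expression"]
    loading = np.zeros(config.n_genes)
    module_of = {}
    for m, (idx_set, lam) in enumerate(config.module_spec, start=1):
        for gi in idx_set:
            loading[gi] = lam
            module_of[genes[gi]] = m
    factors = rng_expr.standard_normal((len(config.module_spec), n_cases))
    eps = rng_expr.standard_normal((config.n_genes, n_cases))
    latent = np.zeros((config.n_genes, n_cases))
    for m, (idx_set, lam) in enumerate(config.module_spec):
        for gi in idx_set:
            latent[gi] = lam * factors[m] + math.sqrt(1 - lam**2) * eps[gi]
    free = np.ones(config.n_genes, dtype=bool)
    for idx_set, _ in config.module_spec:
        free[list(idx_set)] = False
    latent[free] = eps[free]

    log2fc = np.zeros(config.n_genes)
    for gi, fc in config.planted_fc.items():
        log2fc[gi] = math.log2(fc)
    is_case = np.array([g == "case" for g in group], dtype=float)
    log2x = 3.0 + log2fc[:, None] * is_case[None, :] + config.noise_sd * latent

    # --- corruption: outliers then missingness -----------------------------
    rng_cor = streams["corruption"]
    if config.outlier_rate > 0 and config.noise_sd > 0:
        out_mask = rng_cor.random(log2x.shape) < config.outlier_rate
        signs = rng_cor.choice([-1.0, 1.0], size=log2x.shape)
        log2x = log2x + out_mask * signs * config.outlier_magnitude * config.noise_sd
    expr = np.power(2.0, log2x)
    if config.missing_rate > 0:
        miss = rng_cor.random(expr.shape) < config.missing_rate
        expr[miss] = np.nan
    expression = pd.DataFrame(expr, index=genes, columns=case_ids)

    # --- pathology ----------------------------------------------------------
    rng_path = streams["pathology"]
    amyloid_pos, tau_pos, burden_amy, burden_ec = [], [], [], []
    for g in group:
        p_dual = config.dual_pathology_prob.get(g, 0.0)
        dual = rng_path.random() < p_dual
        if dual:
            a_pos = t_pos = True
        else:
            a_pos = bool(rng_path.random() < 0.5)
            t_pos = bool(not a_pos and rng_path.random() < 0.5)
        amyloid_pos.append(a_pos)
        tau_pos.append(t_pos)
        # burden: log-normal percent-positive pixels, shifted upward in cases
        base = rng_path.lognormal(mean=-1.0 + (1.6 if g == "case" else 0.0), sigma=0.6)
        burden_amy.append(min(base, 100.0))
        burden_ec.append(min(base * rng_path.uniform(0.8, 1.6), 100.0))
    pathology = pd.DataFrame(
        {
            "amyloid_pos": amyloid_pos,
            "tau_pos": tau_pos,
            "burden_amygdala": burden_amy,
            "burden_with_ec": burden_ec,
        },
        index=pd.Index(case_ids, name="case_id"),
    )

    # --- proteins -----------------------------------------------------------
    rng_prot = streams["proteins"]
    prot_rows = []
    protein_effects = {}
    for target, (cat, d) in config.protein_spec.items():
        protein_effects[target] = float(d)
        sd = 0.3
        base = rng_prot.uniform(0.5, 2.0)
        for cid, g in zip(case_ids, group):
            shift = d * sd if g == "case" else 0.0
            abundance = base * 2.0 ** rng_prot.normal(shift, sd)
            loading_total = rng_prot.lognormal(mean=2.0, sigma=0.15)
            prot_rows.append(
                dict(target=target, category=cat, case_id=cid,
                     normalized_abundance=abundance,
                     loading_control_total=loading_total)
            )
    proteins = pd.DataFrame(prot_rows)

    # --- planted truth ------------------------------------------------------
    lam_vec = loading.copy()
    corr = np.outer(lam_vec, lam_vec)
    # cross-module latent factors are independent: zero out between-module cells
    module_idx = np.zeros(config.n_genes, dtype=int)
    for m, (idx_set, _) in enumerate(config.module_spec, start=1):
        module_idx[list(idx_set)] = m
    same_module = (module_idx[:, None] == module_idx[None, :]) & (module_idx[:, None] > 0)
    corr = np.where(same_module, corr, 0.0)
    np.fill_diagonal(corr, 1.0)
    truth = PlantedTruth(
        de_genes={
            genes[gi]: {"fc": float(fc), "d": float(math.log2(fc) / config.noise_sd)
                        if config.noise_sd > 0 else math.inf}
            for gi, fc in config.planted_fc.items() if fc != 1.0
        },
        module_membership=module_of,
        true_correlations=pd.DataFrame(corr, index=genes, columns=genes),
        protein_effects=protein_effects,
    )
    return Cohort(cases=cases, expression=expression, proteins=proteins,
                  pathology=pathology, truth=truth)


class NoTruthAvailable(Exception):
    """Raised when a cohort was built from user files and carries no truth."""


def truth_report(cohort: Cohort) -> PlantedTruth:
    """Return the recorded planted truth; real-data cohorts raise
    NoTruthAvailable."""
    if cohort.truth is None:
        raise NoTruthAvailable("no truth available: cohort not produced by the generator")
    return cohort.truth


# ---------------------------------------------------------------------------
# serialization: the same TSV layouts real-data ingestion consumes, plus a
# JSON truth side-car
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
        "pathology": out / "pathology.tsv",
        "proteins": out / "proteins.tsv",
        "truth": out / "truth.json",
    }
    cohort.expression.rename_axis("gene_id").to_csv(paths["expression"], sep="\t")
    cohort.metadata.to_csv(paths["metadata"], sep="\t")
    cohort.pathology.to_csv(paths["pathology"], sep="\t")
    cohort.proteins.to_csv(paths["proteins"], sep="\t", index=False)
    if cohort.truth is not None:
        paths["truth"].write_text(json.dumps(cohort.truth.to_jsonable(), indent=1,
                                             sort_keys=True))
    else:
        paths.pop("truth")
    return paths


def read_cohort(in_dir) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort` (or assembled
    by hand in the same layout; the truth side-car is optional)."""
    d = Path(in_dir)
    expression = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(d / "metadata.tsv", sep="\t", index_col=0, dtype={0: str})
    meta.index = meta.index.astype(str)
    pathology = pd.read_csv(d / "pathology.tsv", sep="\t", index_col=0)
    pathology.index = pathology.index.astype(str)
    proteins = pd.read_csv(d / "proteins.tsv", sep="\t", dtype={"case_id": str})
    cases = [
        CaseRecord(case_id=str(cid), group=row["group"], age=float(row["age"]),
                   pmi=float(row["pmi"]), covariate=str(row["covariate"]))
        for cid, row in meta.iterrows()
    ]
    truth = None
    truth_path = d / "truth.json"
    if truth_path.exists():
        truth = PlantedTruth.from_jsonable(json.loads(truth_path.read_text()))
    expression.columns = expression.columns.astype(str)
    return Cohort(cases=cases, expression=expression, proteins=proteins,
                  pathology=pathology, truth=truth)
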