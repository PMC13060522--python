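"""Tabular ingestion with validation for real-data cohorts.

All inputs are delimited text (TSV or CSV; the dialect is sniffed per file).
Tables join on ``case_id``; orphan records and out-of-range values are
rejected with the offending identifier named.  Cohorts built here carry no
planted truth.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CaseRecord, Cohort

__all__ = ["ingest", "read_table"]


def _sniff_sep(path: Path) -> str:
    sample = path.read_text()[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_table(path, index_col=None) -> pd.DataFrame:
    """Read a delimited table, auto-detecting tab/comma/semicolon."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    sep = _sniff_sep(path)
    return pd.read_csv(path, sep=sep, index_col=index_col)


def ingest(
    expression_path,
    metadata_path,
    pathology_path=None,
    proteins_path=None,
    *,
    group_labels: tuple[str, str] = ("control", "case"),
) -> Cohort:
    """Join the input tables on case_id into a Cohort (no truth attached).

    ``expression`` is genes x cases with a gene_id first column; metadata is
    keyed by case_id with columns group/age/pmi/covariate.  Pathology and
    protein tables are optional.
    """
    expression = read_table(expression_path, index_col=0)
    expression.columns = expression.columns.astype(str)
    meta = read_table(metadata_path, index_col=0)
    meta.index = meta.index.astype(str)

    required = {"group", "age", "pmi", "covariate"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")

    orphans = [c for c in expression.columns if c not in meta.index]
    if orphans:
        raise ValueError(f"cases present in expression but absent in metadata: {orphans}")

    labels = set(meta["group"])
    if labels != set(group_labels):
        raise ValueError(
            f"group column must contain exactly {sorted(group_labels)}, got {sorted(labels)}"
        )
    if (meta["age"] < 0).any() or (meta["pmi"] < 0).any():
        bad = list(meta.index[(meta["age"] < 0) | (meta["pmi"] < 0)])
        raise ValueError(f"negative age/PMI for cases: {bad}")

    vals = expression.to_numpy(dtype=float)
    if np.any(vals[~np.isnan(vals)] <= 0):
        raise ValueError("expression values must be strictly positive where present")

    pathology = None
    if pathology_path is not None:
        pathology = read_table(pathology_path, index_col=0)
        pathology.index = pathology.index.astype(str)
        orphans = [c for c in pathology.index if c not in meta.index]
        if orphans:
            raise ValueError(f"pathology rows without metadata: {orphans}")
        for col in ("burden_amygdala", "burden_with_ec"):
            if col in pathology.columns:
                burden = pathology[col].dropna()
                bad = burden[(burden < 0) | (burden > 100)]
                if len(bad):
                    raise ValueError(
                        f"burden percentages outside [0, 100] in {col}: {list(bad.index)}"
                    )

    proteins = None
    if proteins_path is not None:
        proteins = read_table(proteins_path)
        proteins["case_id"] = proteins["case_id"].astype(str)
        orphans = sorted(set(proteins["case_id"]) - set(meta.index))
        if orphans:
            raise ValueError(f"protein rows without metadata: {orphans}")

    cases = [
        CaseRecord(case_id=str(cid), group=str(r["group"]), age=float(r["age"]),
                   pmi=float(r["pmi"]), covariate=str(r["covariate"]))
        for cid, r in meta.iterrows()
    ]
    return Cohort(
        cases=cases,
        expression=expression,
        proteins=proteins if proteins is not None else pd.DataFrame(
            columns=["target", "category", "case_id", "normalized_abundance",
                     "loading_control_total"]),
        pathology=pathology if pathology is not None else pd.DataFrame(
            columns=["amyloid_pos", "tau_pos", "burden_amygdala", "burden_with_ec"]),
        truth=None,
    )
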