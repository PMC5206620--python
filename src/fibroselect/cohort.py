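"""Cohort tables: per-sample expression, clinical covariates and histology.

A cohort table holds one row per participant with relative expression for
every panel target gene, kidney-function covariates (serum creatinine in
umol/L, eGFR in mL/min/1.73 m2, 24-h urinary protein in g/d), demographics,
and histology scores (TIF percent/grade, GS score). Healthy participants
have no biopsy: their tif_pct and gs_score are missing by design and their
TIF grade is forced to 0 (no-TIF group).

The on-disk dialect is comma-separated UTF-8 with a header row; missing
values are empty fields. Numeric fields are written with ``repr`` so a
write/load round trip reproduces the table exactly.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import histology
from .panel import GenePanel

__all__ = ["CohortTable", "CohortError", "load_cohort", "write_cohort", "CLINICAL_COLUMNS"]


class CohortError(ValueError):
    """Raised when a cohort table violates its invariants."""


#: Non-gene columns, in canonical on-disk order.
CLINICAL_COLUMNS: tuple[str, ...] = (
    "sample_id", "cohort", "group", "scr", "egfr", "protein_24h",
    "age", "sex", "tif_pct", "tif_grade", "gs_score",
)

_COHORTS = {"test", "validation"}
_GROUPS = {"CKD", "healthy"}
_SEXES = {"M", "F"}


@dataclass
class CohortTable:
    """A validated samples x (expression + clinical + histology) table.

    ``data`` carries the columns of :data:`CLINICAL_COLUMNS`, a derived
    ``tif_label`` column, and one column per panel target gene. The binary
    TIF label is always recomputed from ``tif_grade`` and ``group``; it is
    1 iff the grade is 1-3 and the participant is not healthy.
    """

    data: pd.DataFrame
    panel: GenePanel

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise CohortError(f"missing clinical columns: {missing_cols}")
        absent = [g for g in self.panel.target_genes if g not in df.columns]
        if absent:
            raise CohortError(f"missing gene columns: {absent}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise CohortError(f"duplicate sample_id {dup!r}")

        bad_cohort = set(df["cohort"]) - _COHORTS
        if bad_cohort:
            raise CohortError(f"invalid cohort values: {sorted(bad_cohort)}")
        bad_group = set(df["group"]) - _GROUPS
        if bad_group:
            raise CohortError(f"invalid group values: {sorted(bad_group)}")
        bad_sex = set(df["sex"]) - _SEXES
        if bad_sex:
            raise CohortError(f"invalid sex values: {sorted(bad_sex)}")

        healthy = df["group"] == "healthy"
        df.loc[healthy, "tif_grade"] = 0
        if df["tif_grade"].isna().any():
            sid = df.loc[df["tif_grade"].isna(), "sample_id"].iloc[0]
            raise CohortError(f"sample {sid!r}: CKD sample without tif_grade")
        df["tif_grade"] = df["tif_grade"].astype(int)
        bad_grade = ~df["tif_grade"].isin([0, 1, 2, 3])
        if bad_grade.any():
            sid = df.loc[bad_grade, "sample_id"].iloc[0]
            raise CohortError(f"sample {sid!r}: tif_grade outside 0-3")

        df["tif_label"] = [
            histology.tif_label(g, grp)
            for g, grp in zip(df["tif_grade"], df["group"])
        ]

        expr = df[list(self.panel.target_genes)]
        if expr.isna().any().any():
            gene = expr.columns[expr.isna().any()][0]
            sid = df.loc[expr[gene].isna(), "sample_id"].iloc[0]
            raise CohortError(f"sample {sid!r}: missing expression for {gene}")
        nonpos = (expr <= 0).any(axis=1)
        if nonpos.any():
            sid = df.loc[nonpos, "sample_id"].iloc[0]
            raise CohortError(f"sample {sid!r}: non-positive expression value")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def labels(self) -> np.ndarray:
        """Binary TIF labels (1 = TIF), one per sample."""
        return self.data["tif_label"].to_numpy(dtype=int)

    def feature_matrix(self, features: Sequence[str]) -> np.ndarray:
        """Samples x features matrix over gene symbols and/or covariates.

        Gene expression enters on the log2 scale (the scale on which fold
        changes are additive); clinical covariates (scr, egfr, protein_24h,
        age) enter untransformed.
        """
        cols = []
        for name in features:
            if name not in self.data.columns:
                raise CohortError(f"feature {name!r} absent from cohort")
            col = self.data[name].to_numpy(dtype=float)
            if name in self.panel.target_genes:
                col = np.log2(col)
            if np.isnan(col).any():
                raise CohortError(f"feature {name!r} has missing values")
            cols.append(col)
        return np.column_stack(cols)

    def ckd_only(self) -> "CohortTable":
        """Subset to biopsy-proven CKD samples (drops healthy participants)."""
        sub = self.data[self.data["group"] == "CKD"].reset_index(drop=True).copy()
        return CohortTable(sub, self.panel)

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise CohortError(f"column {name!r} absent from cohort")
        return self.data[name].to_numpy(dtype=float)


def _parse_float(raw: str, *, what: str, sample: str) -> float:
    raw = raw.strip()
    if raw == "" or raw.upper() == "NA":
        return math.nan
    try:
        return float(raw)
    except ValueError as exc:
        raise CohortError(f"sample {sample!r}: bad numeric {what}={raw!r}") from exc


def load_cohort(path: str | Path, panel: GenePanel) -> CohortTable:
    """Read a cohort CSV and validate it against ``panel``.

    Raises :class:`CohortError` listing absent gene columns, and on
    non-positive expression or out-of-range histology values (naming the
    offending sample).
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortError(f"cohort file {path}: empty file")
        header = list(reader.fieldnames)
        missing = [c for c in CLINICAL_COLUMNS if c not in header]
        if missing:
            raise CohortError(f"cohort file {path}: missing columns {missing}")
        absent_genes = [g for g in panel.target_genes if g not in header]
        if absent_genes:
            raise CohortError(f"cohort file {path}: missing gene columns {absent_genes}")

        records: list[dict] = []
        for row in reader:
            sid = row["sample_id"]
            rec: dict = {
                "sample_id": sid,
                "cohort": row["cohort"].strip(),
                "group": row["group"].strip(),
                "sex": row["sex"].strip(),
            }
            for col in ("scr", "egfr", "protein_24h", "age", "tif_pct", "gs_score"):
                rec[col] = _parse_float(row[col], what=col, sample=sid)
            grade_raw = row["tif_grade"].strip()
            rec["tif_grade"] = math.nan if grade_raw == "" else int(float(grade_raw))
            for gene in panel.target_genes:
                rec[gene] = _parse_float(row[gene], what=gene, sample=sid)
            records.append(rec)

    columns = [*CLINICAL_COLUMNS, *panel.target_genes]
    df = pd.DataFrame.from_records(records, columns=columns) if records else \
        pd.DataFrame({c: pd.Series(dtype=object if c in ("sample_id", "cohort", "group", "sex") else float) for c in columns})
    return CohortTable(df, panel)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return "" if math.isnan(value) else repr(value)
    return str(value)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV such that ``load_cohort`` reproduces it exactly."""
    columns = [*CLINICAL_COLUMNS, *table.panel.target_genes]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for _, row in table.data.iterrows():
            writer.writerow([_fmt(row[c]) for c in columns])
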