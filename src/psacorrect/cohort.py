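"""Cohort table reading, validation, risk classification and eligibility filtering.

The screened-cohort analysis operates on men detected through PSA testing:
eligibility requires a PSA in the half-open window [3, 10) ng/mL, a clinical
stage short of locally advanced disease (T3-T4 excluded by default, because
such men are referred for biopsy regardless of any genetic correction of
PSA), and complete genotype dosages for the SNP panel in use.

Risk-of-progression classification, applied to biopsy-confirmed cancers:

* high risk:  Gleason score 7-10, or clinical stage T2c;
* low risk:   otherwise, when the Gleason score is 6 or less;
* men missing stage are classified on Gleason score alone.

The high-risk rule is evaluated first, so Gleason <= 6 with stage T2c is
high risk.  Men missing both Gleason and stage cannot be classified.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ClassificationError, SchemaError, ValidationError

__all__ = [
    "CohortTable",
    "classify_risk",
    "read_cohort",
    "write_cohort",
    "filter_eligible",
    "CANONICAL_ROLES",
]

CANONICAL_ROLES = ("subject_id", "psa", "age", "centre", "gleason", "stage")
_REQUIRED_ROLES = ("psa", "age", "centre", "gleason", "stage")

_STAGE_CANON = {
    "T1": "T1", "T2": "T2", "T2A": "T2a", "T2B": "T2b", "T2C": "T2c",
    "T3": "T3", "T4": "T4",
}
_EXCLUDED_STAGES = ("T3", "T4")
_MISSING_TOKENS = {"", ".", "na", "n/a", "nan", "none", "missing", "null"}


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip().lower() in _MISSING_TOKENS:
        return True
    return value is pd.NA


def parse_stage(value) -> str | None:
    """Normalise a stage label (case-insensitive, 'T2C'/'t2c' tolerated).

    Unknown labels are treated as missing, with a warning: the upstream
    clinical coding dialect is not standardised and silently inventing a
    stage would corrupt the risk classification.
    """
    if _is_missing(value):
        return None
    key = str(value).strip().upper().replace(" ", "")
    if key in _STAGE_CANON:
        return _STAGE_CANON[key]
    warnings.warn(f"unrecognised stage label {value!r} treated as missing", stacklevel=2)
    return None


def classify_risk(gleason, stage, include_t3t4: bool = False) -> str:
    """Classify a biopsy-confirmed cancer as 'low', 'high' or 'excluded'.

    Parameters
    ----------
    gleason
        Integer 2-10 or missing.
    stage
        Canonical stage label (see :func:`parse_stage`) or missing.
    include_t3t4
        When True, locally advanced stages T3-T4 are placed in the high-risk
        group (sensitivity-analysis configuration) instead of being excluded.

    Raises
    ------
    ClassificationError
        When both inputs are missing.
    """
    stage = parse_stage(stage)
    g = None if _is_missing(gleason) else int(gleason)
    if g is None and stage is None:
        raise ClassificationError("cannot classify risk: Gleason and stage both missing")
    if stage in _EXCLUDED_STAGES:
        return "high" if include_t3t4 else "excluded"
    if (g is not None and 7 <= g <= 10) or stage == "T2c":
        return "high"
    if g is not None and g <= 6:
        return "low"
    # Gleason missing with an uninformative stage (T1/T2/T2a/T2b): the
    # low-risk rule needs the grade, so the man cannot be classified.
    return "excluded"


@dataclass
class CohortTable:
    """Validated per-subject records plus provenance.

    ``data`` holds one row per subject with canonical columns
    (subject_id, psa, age, centre, gleason, stage, risk_group), one dosage
    column per rsID in ``panel_ids`` and any covariate columns (PC1...).
    """

    data: pd.DataFrame
    panel_ids: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def subjects(self) -> pd.Series:
        return self.data["subject_id"]

    def covariate_columns(self) -> list[str]:
        known = set(CANONICAL_ROLES) | {"risk_group"} | set(self.panel_ids)
        return [c for c in self.data.columns if c not in known]


def _sniff_sep(path: Path) -> str:
    sample = path.open("r", newline="").read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t"


def read_cohort(
    path,
    schema: dict | None = None,
    genotype_columns: Sequence[str] | None = None,
    include_t3t4: bool = False,
) -> CohortTable:
    """Read and validate a cohort table from delimited text or a spreadsheet.

    Parameters
    ----------
    path
        TSV/CSV (delimiter sniffed) or .xlsx/.xls file, one row per subject.
    schema
        Optional mapping from canonical role names (psa, age, centre,
        gleason, stage, subject_id) to the file's column names.  Roles whose
        canonical name already matches a column need not be listed.
    genotype_columns
        Dosage columns; defaults to every column whose name looks like an
        rsID (``rs`` followed by digits).
    include_t3t4
        Passed through to :func:`classify_risk` when deriving risk_group.

    Rows failing validation (non-numeric or non-positive PSA, dosage outside
    {0,1,2}, Gleason outside 2-10) are rejected with row-level diagnostics
    recorded in ``provenance['rejected_rows']``; nothing is silently coerced.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".xls", ".xlsx"}:
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path, sep=_sniff_sep(path), dtype=object)

    schema = dict(schema or {})
    colmap = {}
    for role in CANONICAL_ROLES:
        col = schema.get(role, role)
        if col in raw.columns:
            colmap[role] = col
    missing_roles = [r for r in _REQUIRED_ROLES if r not in colmap]
    if missing_roles:
        raise SchemaError(
            f"required column role(s) missing from {path.name}: {missing_roles}"
        )

    if genotype_columns is None:
        genotype_columns = [
            c for c in raw.columns
            if c.startswith("rs") and c[2:].isdigit()
        ]
    else:
        absent = [c for c in genotype_columns if c not in raw.columns]
        if absent:
            raise SchemaError(f"genotype column(s) missing: {absent}")
    genotype_columns = list(genotype_columns)

    # risk_group is derived, never read: drop any stored copy so it is
    # recomputed from gleason/stage and cannot masquerade as a covariate
    used = set(colmap.values()) | set(genotype_columns) | {"risk_group"}
    covariate_cols = [c for c in raw.columns if c not in used]

    rows = []
    rejected = []
    for idx, row in raw.iterrows():
        sid = row[colmap["subject_id"]] if "subject_id" in colmap else f"S{idx:05d}"
        issues = []
        rec = {"subject_id": str(sid)}

        psa = pd.to_numeric(pd.Series([row[colmap["psa"]]]), errors="coerce").iloc[0]
        if pd.isna(psa) or psa <= 0:
            issues.append(f"psa={row[colmap['psa']]!r} (must be a positive number)")
        rec["psa"] = float(psa) if pd.notna(psa) else np.nan

        age = pd.to_numeric(pd.Series([row[colmap["age"]]]), errors="coerce").iloc[0]
        if pd.isna(age) or not np.isfinite(age):
            issues.append(f"age={row[colmap['age']]!r} (must be finite)")
        rec["age"] = float(age) if pd.notna(age) else np.nan

        rec["centre"] = None if _is_missing(row[colmap["centre"]]) else str(row[colmap["centre"]])

        graw = row[colmap["gleason"]]
        if _is_missing(graw):
            rec["gleason"] = np.nan
        else:
            g = pd.to_numeric(pd.Series([graw]), errors="coerce").iloc[0]
            if pd.isna(g) or g != int(g) or not (2 <= g <= 10):
                issues.append(f"gleason={graw!r} (must be an integer 2-10 or missing)")
                rec["gleason"] = np.nan
            else:
                rec["gleason"] = int(g)

        rec["stage"] = parse_stage(row[colmap["stage"]])

        for snp in genotype_columns:
            v = row[snp]
            if _is_missing(v):
                rec[snp] = np.nan
                continue
            d = pd.to_numeric(pd.Series([v]), errors="coerce").iloc[0]
            if pd.isna(d) or d not in (0, 1, 2):
                issues.append(f"{snp}={v!r} (dosage must be 0, 1 or 2)")
                rec[snp] = np.nan
            else:
                rec[snp] = int(d)

        for cov in covariate_cols:
            v = row[cov]
            if _is_missing(v):
                rec[cov] = np.nan
                continue
            x = pd.to_numeric(pd.Series([v]), errors="coerce").iloc[0]
            if pd.isna(x) or not np.isfinite(x):
                issues.append(f"{cov}={v!r} (covariate must be finite)")
                rec[cov] = np.nan
            else:
                rec[cov] = float(x)

        if issues:
            rejected.append({"subject_id": str(sid), "row": int(idx), "issues": issues})
        else:
            rows.append(rec)

    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=list(CANONICAL_ROLES) + genotype_columns + covariate_cols)
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject_id values: {dupes[:5]}")

    df["risk_group"] = [
        _safe_classify(g, s, include_t3t4) for g, s in zip(df.get("gleason", []), df.get("stage", []))
    ] if len(df) else []

    provenance = {
        "source": str(path),
        "rows_read": int(len(raw)),
        "rows_valid": int(len(df)),
        "rejected_rows": rejected,
        "filters": [],
    }
    return CohortTable(df, panel_ids=genotype_columns, provenance=provenance)


def _safe_classify(gleason, stage, include_t3t4: bool) -> str | None:
    try:
        return classify_risk(gleason, stage, include_t3t4=include_t3t4)
    except ClassificationError:
        return None


def filter_eligible(
    table: CohortTable,
    psa_window: tuple[float, float] = (3.0, 10.0),
    require_panel: Iterable[str] = (),
    include_t3t4: bool = False,
) -> CohortTable:
    """Apply study eligibility: PSA in [low, high), stage not excluded,
    classifiable risk group, and non-missing dosage for every required rsID.

    The PSA window is half-open: 3.0 ng/mL is retained, 10.0 ng/mL removed.
    Removal counts per reason are appended to the provenance filter log.
    The operation is idempotent.
    """
    df = table.data.copy()
    lo, hi = psa_window
    removed: dict[str, int] = {}

    if include_t3t4:
        df = df.assign(risk_group=[
            _safe_classify(g, s, True) for g, s in zip(df["gleason"], df["stage"])
        ])

    keep = (df["psa"] >= lo) & (df["psa"] < hi)
    removed["psa_outside_window"] = int((~keep).sum())
    df = df[keep]

    unclass = df["risk_group"].isna()
    removed["unclassifiable"] = int(unclass.sum())
    df = df[~unclass]

    excl = df["risk_group"] == "excluded"
    removed["stage_excluded"] = int(excl.sum())
    df = df[~excl]

    require_panel = list(require_panel)
    if require_panel:
        absent = [s for s in require_panel if s not in df.columns]
        if absent:
            raise SchemaError(f"required genotype column(s) missing: {absent}")
        has_all = df[require_panel].notna().all(axis=1)
        removed["missing_genotype"] = int((~has_all).sum())
        df = df[has_all]

    if df.empty:
        warnings.warn("eligibility filtering removed every subject", stacklevel=2)

    provenance = dict(table.provenance)
    provenance = {**provenance, "filters": list(provenance.get("filters", [])) + [
        {
            "psa_window": [lo, hi],
            "require_panel": require_panel,
            "include_t3t4": include_t3t4,
            "removed": removed,
            "rows_out": int(len(df)),
        }
    ]}
    return CohortTable(df.reset_index(drop=True), panel_ids=list(table.panel_ids),
                       provenance=provenance)


def write_cohort(table: CohortTable, path) -> Path:
    """Write the canonical TSV plus a JSON provenance sidecar.

    Column order is canonical roles, risk_group, genotype columns, then
    covariates; this makes read -> write -> read round-trip bit-identically.
    """
    path = Path(path)
    cols = [c for c in CANONICAL_ROLES if c in table.data.columns]
    cols += ["risk_group"] if "risk_group" in table.data.columns else []
    cols += [c for c in table.panel_ids if c in table.data.columns]
    cols += table.covariate_columns()
    out = table.data[cols].copy()
    out.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps(table.provenance, indent=2, sort_keys=True) + "\n")
    return path
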