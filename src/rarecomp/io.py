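"""Readers and writers: cohort CSV, coded-visit CSV, code sets, JSON results.

Cohort CSV schema (header required): ``arm`` (rural/referral),
``comorbidity_level`` (integer 0-4), ``event`` (0/1), plus any covariate
columns.  Coded-visit CSV schema: ``patient_id``, ``date`` (ISO-8601),
``diagnosis_codes`` and ``intervention_codes`` as semicolon-separated code
strings.  Code sets are YAML or JSON mappings event-name -> list of code
prefixes (ICD-10-CA / CCI style).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .cohort import CodedVisit, _as_date

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_coded_visits_csv",
    "read_code_sets",
    "write_json",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("arm", "comorbidity_level", "event")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort table; logs row counts and per-column missingness."""
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cohort file {path} is missing required column {col!r}")
    bad_arm = sorted(set(df["arm"].unique()) - {"rural", "referral"})
    if bad_arm:
        raise ValueError(f"non-binary arm labels in {path}: {bad_arm}")
    bad_event = df.index[~df["event"].isin((0, 1))]
    if len(bad_event):
        raise ValueError(f"non-binary event values at rows {list(bad_event[:10])}")
    missing = df.isna().sum()
    report = {
        "rows": int(len(df)),
        "columns": list(df.columns),
        "missing_per_column": {c: int(m) for c, m in missing.items() if m},
    }
    df.attrs["validation"] = report
    logger.info("read cohort %s: %d rows, missingness %s",
                path, report["rows"], report["missing_per_column"] or "none")
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_coded_visits_csv(path) -> list:
    """Read coded hospital visits; code lists are semicolon-separated."""
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("patient_id", "date"):
        if col not in df.columns:
            raise ValueError(f"coded-visit file {path} is missing column {col!r}")

    def split(cell: str) -> tuple:
        return tuple(c.strip() for c in cell.split(";") if c.strip())

    visits = []
    for row in df.itertuples(index=False):
        visits.append(
            CodedVisit(
                patient_id=row.patient_id,
                date=_as_date(row.date),
                diagnosis_codes=split(getattr(row, "diagnosis_codes", "")),
                intervention_codes=split(getattr(row, "intervention_codes", "")),
            )
        )
    return visits


def read_code_sets(path) -> dict:
    """Load event-name -> code-prefix-list mapping from YAML or JSON."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict) or not data:
        raise ValueError(f"code-set file {path} must map event names to code lists")
    out = {}
    for name, codes in data.items():
        if not isinstance(codes, (list, tuple)) or not all(isinstance(c, str) for c in codes):
            raise ValueError(f"code set {name!r} must be a list of code strings")
        out[str(name)] = tuple(codes)
    return out


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
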