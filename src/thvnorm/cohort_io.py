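"""Cohort CSV reading/writing and generator-config files.

The cohort schema is a flat UTF-8 CSV with a mandatory header and columns

    id, sex, age, height_m, weight_kg, smoker, sah, hl, t2dm, cacs,
    thv_ml, lav_ml, rav_ml, biv_ml

where sex is F/M, booleans are serialized as 0/1, heights are meters only
(the column name says so to preclude the cm/m ambiguity the BSA formula
creates), and the last four columns may be empty.  Reading validates every
row; bad rows are reported as issues (row number, column, reason) and, in
strict mode, any issue raises.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import yaml
from pydantic import ValidationError

from .anthropometry import SubjectRecord
from .simulate import CohortConfig

__all__ = [
    "COHORT_COLUMNS",
    "ReadIssue",
    "CohortReadError",
    "read_cohort",
    "write_cohort",
    "load_config",
    "save_config",
]

COHORT_COLUMNS = [
    "id",
    "sex",
    "age",
    "height_m",
    "weight_kg",
    "smoker",
    "sah",
    "hl",
    "t2dm",
    "cacs",
    "thv_ml",
    "lav_ml",
    "rav_ml",
    "biv_ml",
]
_REQUIRED = COHORT_COLUMNS[:10]
_OPTIONAL = COHORT_COLUMNS[10:]

_BOOL_FIELDS = ("smoker", "sah", "hl", "t2dm")


class CohortReadError(ValueError):
    """Unrecoverable cohort-file problem (missing header/column, strict-mode issue)."""


@dataclass(frozen=True)
class ReadIssue:
    row: int  # 1-based data-row number (header excluded)
    column: str
    reason: str


def _parse_bool(raw: str) -> bool:
    if raw == "0":
        return False
    if raw == "1":
        return True
    raise ValueError("expected 0 or 1")


def _parse_row(row: dict) -> SubjectRecord:
    kwargs = {"id": row["id"], "sex": row["sex"]}
    for col, fieldname in (("age", "age"), ("height_m", "height"), ("weight_kg", "weight"), ("cacs", "cacs")):
        kwargs[fieldname] = float(row[col])
    for col in _BOOL_FIELDS:
        kwargs[col] = _parse_bool((row[col] or "").strip())
    for col, fieldname in (("thv_ml", "thv_measured"), ("lav_ml", "lav"), ("rav_ml", "rav"), ("biv_ml", "biv")):
        raw = (row.get(col) or "").strip()
        kwargs[fieldname] = float(raw) if raw else None
    return SubjectRecord(**kwargs)


def read_cohort(
    path, strict: bool = False
) -> Tuple[List[SubjectRecord], List[ReadIssue]]:
    """Read a cohort CSV; return (records, issues).

    Invalid rows are skipped and reported as issues; with ``strict=True``
    the first issue raises :class:`CohortReadError`.  A missing header or a
    missing required column is always a hard error.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortReadError(f"{path}: empty file, header row required")
        missing = [c for c in _REQUIRED if c not in reader.fieldnames]
        if missing:
            raise CohortReadError(f"{path}: missing required column(s): {missing}")
        records: List[SubjectRecord] = []
        issues: List[ReadIssue] = []
        for i, row in enumerate(reader, start=1):
            try:
                records.append(_parse_row(row))
            except ValidationError as exc:
                err = exc.errors()[0]
                col = str(err["loc"][0]) if err["loc"] else "?"
                issue = ReadIssue(row=i, column=col, reason=err["msg"])
                if strict:
                    raise CohortReadError(f"{path}: row {i}, column {col}: {err['msg']}")
                issues.append(issue)
            except (ValueError, KeyError) as exc:
                # locate the offending column by re-parsing field by field
                col = _find_bad_column(row)
                if strict:
                    raise CohortReadError(f"{path}: row {i}, column {col}: {exc}")
                issues.append(ReadIssue(row=i, column=col, reason=str(exc)))
    return records, issues


def _find_bad_column(row: dict) -> str:
    for col in ("age", "height_m", "weight_kg", "cacs", "thv_ml", "lav_ml", "rav_ml", "biv_ml"):
        raw = (row.get(col) or "").strip()
        if raw:
            try:
                float(raw)
            except ValueError:
                return col
    for col in _BOOL_FIELDS:
        try:
            _parse_bool((row.get(col) or "").strip())
        except ValueError:
            return col
    if row.get("sex") not in ("F", "M"):
        return "sex"
    return "?"


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(float(value))


def write_cohort(records: Sequence[SubjectRecord], path) -> None:
    """Write records in the cohort CSV schema (floats at full precision)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.sex.value,
                    _fmt(r.age),
                    _fmt(r.height),
                    _fmt(r.weight),
                    int(r.smoker),
                    int(r.sah),
                    int(r.hl),
                    int(r.t2dm),
                    _fmt(r.cacs),
                    _fmt(r.thv_measured),
                    _fmt(r.lav),
                    _fmt(r.rav),
                    _fmt(r.biv),
                ]
            )


def load_config(path) -> CohortConfig:
    """Load a generator config from YAML mirroring CohortConfig field names."""
    data = yaml.safe_load(Path(path).read_text())
    return CohortConfig(**data)


def save_config(config: CohortConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
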