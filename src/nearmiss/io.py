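"""CSV serialization of patient records.

One row per woman; nested marker groups flattened to dotted column names
(``cardiovascular.lactate``). Flags are written ``1``/``0`` and missing
values as the empty string, so ``read_patient_table(write_patient_table(x))``
reproduces the records exactly, including missingness. Files are UTF-8,
comma-separated, header mandatory; leading ``#`` lines carry provenance
(tool version, seed, configuration) and are ignored on read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import ValidationError

from .records import (
    Cardiovascular,
    Coagulation,
    Conditions,
    Extras,
    Hepatic,
    Interventions,
    Neurologic,
    PatientRecord,
    Renal,
    Respiratory,
    Uterine,
)

__all__ = [
    "SCHEMA_COLUMNS",
    "MANDATORY_COLUMNS",
    "PatientTableError",
    "RowIssue",
    "read_patient_table",
    "write_patient_table",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

_GROUP_MODELS = {
    "conditions": Conditions,
    "interventions": Interventions,
    "cardiovascular": Cardiovascular,
    "respiratory": Respiratory,
    "renal": Renal,
    "coagulation": Coagulation,
    "hepatic": Hepatic,
    "neurologic": Neurologic,
    "uterine": Uterine,
    "extras": Extras,
}

_TOP_COLUMNS = ("cohort_id", "setting", "age_years", "parity", "died", "units_blood")

#: Ordered schema: top-level fields, then dotted marker-group fields.
SCHEMA_COLUMNS: tuple[str, ...] = _TOP_COLUMNS + tuple(
    f"{group}.{field}"
    for group, model in _GROUP_MODELS.items()
    for field in model.model_fields
)

MANDATORY_COLUMNS: tuple[str, ...] = ("cohort_id", "setting", "died")

_FLAG_FIELDS = {
    col
    for col in SCHEMA_COLUMNS
    if "." in col
    and _GROUP_MODELS[col.split(".", 1)[0]].model_fields[col.split(".", 1)[1]].annotation
    == Optional[bool]
}
_INT_FIELDS = {"parity", "units_blood"}


class RowIssue(Exception):
    """A row that failed validation, with its 1-based data line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"row {line}: {message}")
        self.line = line
        self.message = message


class PatientTableError(Exception):
    """Raised when a patient table cannot be read (schema or row failures)."""

    def __init__(self, message: str, issues: Sequence[RowIssue] = ()):
        detail = message
        if issues:
            detail += "\n" + "\n".join(str(i) for i in issues)
        super().__init__(detail)
        self.issues = list(issues)


def _format_value(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def _record_to_row(record: PatientRecord) -> dict[str, str]:
    row = {
        "cohort_id": record.cohort_id,
        "setting": record.setting.value,
        "age_years": _format_value(record.age_years),
        "parity": _format_value(record.parity),
        "died": _format_value(record.died),
        "units_blood": _format_value(record.units_blood),
    }
    for group, model in _GROUP_MODELS.items():
        obj = getattr(record, group)
        for field in model.model_fields:
            row[f"{group}.{field}"] = _format_value(getattr(obj, field))
    return row


def _parse_cell(column: str, raw: str):
    raw = raw.strip()
    if raw == "":
        return None
    if column in _FLAG_FIELDS or column == "died":
        if raw in ("1", "true", "True"):
            return True
        if raw in ("0", "false", "False"):
            return False
        raise ValueError(f"flag column {column!r} must be 1/0/empty, got {raw!r}")
    if column in ("cohort_id", "setting"):
        return raw
    if column.split(".", 1)[-1] in _INT_FIELDS or column in _INT_FIELDS:
        return int(raw)
    return float(raw)


def _row_to_record(row: dict[str, str]) -> PatientRecord:
    top: dict = {}
    groups: dict[str, dict] = {g: {} for g in _GROUP_MODELS}
    for column in SCHEMA_COLUMNS:
        value = _parse_cell(column, row.get(column, ""))
        if "." in column:
            group, field = column.split(".", 1)
            if value is not None:
                groups[group][field] = value
        else:
            top[column] = value
    for name in MANDATORY_COLUMNS:
        if top.get(name) is None:
            raise ValueError(f"mandatory field {name!r} is empty")
    return PatientRecord(
        **top, **{g: model(**groups[g]) for g, model in _GROUP_MODELS.items()}
    )


def write_patient_table(
    records: Iterable[PatientRecord],
    path: str | Path,
    provenance: dict[str, object] | None = None,
) -> Path:
    """Write records as CSV, optionally preceded by ``#`` provenance lines."""
    path = Path(path)
    rows = [_record_to_row(r) for r in records]
    frame = pd.DataFrame(rows, columns=SCHEMA_COLUMNS)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False)
    logger.info("wrote %d records to %s", len(rows), path)
    return path


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Records as a flat string-valued DataFrame in schema order."""
    return pd.DataFrame([_record_to_row(r) for r in records], columns=SCHEMA_COLUMNS)


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read and validate a patient CSV.

    Extra columns are tolerated with a warning; missing mandatory columns
    (cohort_id, setting, died) raise immediately. Row-level failures are
    collected and raised together as :class:`PatientTableError`, each tagged
    with its data line number. An empty data section yields an empty cohort
    with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise PatientTableError(f"no such file: {path}")
    frame = pd.read_csv(
        path, dtype=str, keep_default_na=False, comment="#", skip_blank_lines=True
    )
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise PatientTableError(f"missing mandatory columns: {missing}")
    unknown = [c for c in frame.columns if c not in SCHEMA_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown columns: %s", unknown)
    if frame.empty:
        logger.warning("empty data section in %s", path)
        return []

    records: list[PatientRecord] = []
    issues: list[RowIssue] = []
    for i, row in enumerate(frame.to_dict(orient="records"), start=1):
        try:
            records.append(_row_to_record(row))
        except (ValueError, ValidationError) as exc:
            issues.append(RowIssue(i, str(exc)))
    if issues:
        raise PatientTableError(
            f"{len(issues)} invalid row(s) in {path}", issues
        )
    logger.info("read %d records from %s", len(records), path)
    return records
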