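"""Discharge-abstract data model and flat-file IO.

Discharge Abstract Database (DAD) extracts are institution-specific, so the
package defines its own documented dialect: a UTF-8 CSV with one row per
hospitalization and multi-valued code fields delimited by ``;`` inside a
cell.  A JSON-Lines dialect with the same field names (codes as JSON lists)
is accepted as an alternative.  Dates are ISO-8601 calendar dates — the DAD
records at day granularity.  All diagnosis and procedure codes are normalized
on ingest; ill-formed but non-empty codes are kept verbatim after
normalization (they simply never match any study code set), because real
administrative extracts contain codes outside the study's universe.

``abstracts`` files carry the columns::

    patient_id, visit_id, site_id, admission_date, discharge_date,
    surgery_date, age_years, sex, diagnosis_codes, procedure_codes,
    died_in_hospital, died_during_surgery

``reference_standard`` files (true POAF status from chart review) carry::

    patient_id, visit_id, true_poaf, excluded, exclusion_reason
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

from .codes import normalize_cci_code, normalize_icd_code

ABSTRACT_COLUMNS = [
    "patient_id",
    "visit_id",
    "site_id",
    "admission_date",
    "discharge_date",
    "surgery_date",
    "age_years",
    "sex",
    "diagnosis_codes",
    "procedure_codes",
    "died_in_hospital",
    "died_during_surgery",
]

REFERENCE_COLUMNS = ["patient_id", "visit_id", "true_poaf", "excluded", "exclusion_reason"]

EXCLUSION_REASONS = frozenset(
    {"chart_unavailable", "not_eligible_surgery", "died_during_surgery", "none"}
)

CODE_DELIM = ";"


class SchemaError(ValueError):
    """The file header does not match the documented schema."""


class RowError(ValueError):
    """A row could not be parsed; the message names the offending visit."""


class IntegrityError(ValueError):
    """Dataset-level invariant violated (e.g. duplicate visit_id)."""


@dataclass
class DischargeAbstract:
    """One hospitalization's coded administrative record (a DAD row).

    ``diagnosis_codes`` is ordered: position 0 is the principal diagnosis.
    ``surgery_date`` is absent for non-surgical stays.
    """

    patient_id: str
    visit_id: str
    site_id: str
    admission_date: date
    discharge_date: date
    surgery_date: date | None
    age_years: int
    sex: str  # "M", "F" or "U" (other/unknown)
    diagnosis_codes: list[str] = field(default_factory=list)
    procedure_codes: list[str] = field(default_factory=list)
    died_in_hospital: bool = False
    died_during_surgery: bool = False

    def validate(self) -> None:
        if self.admission_date > self.discharge_date:
            raise RowError(
                f"visit {self.visit_id}: admission_date after discharge_date"
            )
        if self.surgery_date is not None and not (
            self.admission_date <= self.surgery_date <= self.discharge_date
        ):
            raise RowError(
                f"visit {self.visit_id}: surgery_date outside the stay"
            )
        if self.age_years < 0:
            raise RowError(f"visit {self.visit_id}: negative age")
        if not self.diagnosis_codes:
            raise RowError(f"visit {self.visit_id}: no diagnosis codes")

    def normalized(self) -> "DischargeAbstract":
        return replace(
            self,
            sex=self.sex if self.sex in ("M", "F") else "U",
            diagnosis_codes=[normalize_icd_code(c) for c in self.diagnosis_codes],
            procedure_codes=[normalize_cci_code(c) for c in self.procedure_codes],
        )


@dataclass
class ReferenceStandardRecord:
    """True POAF status of one index hospitalization, per manual chart review."""

    patient_id: str
    visit_id: str
    true_poaf: bool
    excluded: bool = False
    exclusion_reason: str = "none"

    def validate(self) -> None:
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise RowError(
                f"visit {self.visit_id}: unknown exclusion_reason "
                f"{self.exclusion_reason!r}"
            )
        if self.excluded != (self.exclusion_reason != "none"):
            raise RowError(
                f"visit {self.visit_id}: excluded flag inconsistent with "
                f"exclusion_reason {self.exclusion_reason!r}"
            )


# --- parsing helpers -------------------------------------------------------

_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no", ""}


def _parse_bool(value: str, *, visit_id: str, column: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise RowError(f"visit {visit_id}: cannot parse boolean {column}={value!r}")


def _parse_date(value: str, *, visit_id: str, column: str) -> date:
    try:
        return date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise RowError(
            f"visit {visit_id}: unparseable {column} {value!r}"
        ) from exc


def _split_codes(cell: str) -> list[str]:
    if cell is None:
        return []
    return [c for c in (p.strip() for p in str(cell).split(CODE_DELIM)) if c]


def _infer_dialect(path: Path, schema_dialect: str | None) -> str:
    if schema_dialect is not None:
        if schema_dialect not in ("csv", "jsonl"):
            raise ValueError(f"unknown schema dialect {schema_dialect!r}")
        return schema_dialect
    return "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson") else "csv"


def _sort_abstracts(records: list[DischargeAbstract]) -> list[DischargeAbstract]:
    return sorted(records, key=lambda r: (r.patient_id, r.admission_date, r.visit_id))


# --- abstracts IO ----------------------------------------------------------

def _abstract_from_mapping(row: dict, diagnosis: list[str], procedures: list[str]) -> DischargeAbstract:
    visit_id = str(row["visit_id"]).strip()
    surgery_raw = row.get("surgery_date")
    surgery_raw = "" if surgery_raw is None else str(surgery_raw).strip()
    rec = DischargeAbstract(
        patient_id=str(row["patient_id"]).strip(),
        visit_id=visit_id,
        site_id=str(row["site_id"]).strip(),
        admission_date=_parse_date(row["admission_date"], visit_id=visit_id, column="admission_date"),
        discharge_date=_parse_date(row["discharge_date"], visit_id=visit_id, column="discharge_date"),
        surgery_date=(
            None if not surgery_raw else _parse_date(surgery_raw, visit_id=visit_id, column="surgery_date")
        ),
        age_years=int(str(row["age_years"]).strip()),
        sex=str(row["sex"]).strip().upper(),
        diagnosis_codes=diagnosis,
        procedure_codes=procedures,
        died_in_hospital=_parse_bool(row["died_in_hospital"], visit_id=visit_id, column="died_in_hospital"),
        died_during_surgery=_parse_bool(row["died_during_surgery"], visit_id=visit_id, column="died_during_surgery"),
    ).normalized()
    rec.validate()
    return rec


def read_abstracts(path: str | Path, schema_dialect: str | None = None) -> list[DischargeAbstract]:
    """Read discharge abstracts from a CSV or JSON-Lines file.

    Codes are normalized on ingest; rows are returned in deterministic order
    by ``(patient_id, admission_date, visit_id)``.  Raises
    :class:`SchemaError` on a missing column, :class:`RowError` on a bad row
    and :class:`IntegrityError` on duplicate visit ids.
    """
    path = Path(path)
    dialect = _infer_dialect(path, schema_dialect)
    records: list[DischargeAbstract] = []
    if dialect == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            for col in ABSTRACT_COLUMNS:
                if col not in header:
                    raise SchemaError(f"missing required column {col!r}")
            for row in reader:
                records.append(
                    _abstract_from_mapping(
                        row,
                        _split_codes(row["diagnosis_codes"]),
                        _split_codes(row["procedure_codes"]),
                    )
                )
    else:
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                row = json.loads(line)
                for col in ABSTRACT_COLUMNS:
                    if col not in row:
                        raise SchemaError(f"missing required field {col!r}")
                diag = row["diagnosis_codes"]
                proc = row["procedure_codes"]
                records.append(
                    _abstract_from_mapping(
                        row,
                        list(diag) if isinstance(diag, list) else _split_codes(diag),
                        list(proc) if isinstance(proc, list) else _split_codes(proc),
                    )
                )
    seen: set[str] = set()
    for rec in records:
        if rec.visit_id in seen:
            raise IntegrityError(f"duplicate visit_id {rec.visit_id!r}")
        seen.add(rec.visit_id)
    return _sort_abstracts(records)


def write_abstracts(records: Iterable[DischargeAbstract], path: str | Path,
                    schema_dialect: str | None = None) -> None:
    """Write abstracts so that :func:`read_abstracts` round-trips them exactly."""
    path = Path(path)
    dialect = _infer_dialect(path, schema_dialect)
    rows = list(records)
    if dialect == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(ABSTRACT_COLUMNS)
            for r in rows:
                writer.writerow(
                    [
                        r.patient_id,
                        r.visit_id,
                        r.site_id,
                        r.admission_date.isoformat(),
                        r.discharge_date.isoformat(),
                        "" if r.surgery_date is None else r.surgery_date.isoformat(),
                        r.age_years,
                        r.sex,
                        CODE_DELIM.join(r.diagnosis_codes),
                        CODE_DELIM.join(r.procedure_codes),
                        "true" if r.died_in_hospital else "false",
                        "true" if r.died_during_surgery else "false",
                    ]
                )
    else:
        with path.open("w", encoding="utf-8") as fh:
            for r in rows:
                fh.write(
                    json.dumps(
                        {
                            "patient_id": r.patient_id,
                            "visit_id": r.visit_id,
                            "site_id": r.site_id,
                            "admission_date": r.admission_date.isoformat(),
                            "discharge_date": r.discharge_date.isoformat(),
                            "surgery_date": (
                                None if r.surgery_date is None else r.surgery_date.isoformat()
                            ),
                            "age_years": r.age_years,
                            "sex": r.sex,
                            "diagnosis_codes": r.diagnosis_codes,
                            "procedure_codes": r.procedure_codes,
                            "died_in_hospital": r.died_in_hospital,
                            "died_during_surgery": r.died_during_surgery,
                        },
                        sort_keys=False,
                    )
                    + "\n"
                )


# --- reference standard IO -------------------------------------------------

def read_reference(path: str | Path) -> list[ReferenceStandardRecord]:
    """Read a reference-standard file (chart-review truth per index visit)."""
    path = Path(path)
    records: list[ReferenceStandardRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in REFERENCE_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing required column {col!r}")
        for row in reader:
            visit_id = str(row["visit_id"]).strip()
            rec = ReferenceStandardRecord(
                patient_id=str(row["patient_id"]).strip(),
                visit_id=visit_id,
                true_poaf=_parse_bool(row["true_poaf"], visit_id=visit_id, column="true_poaf"),
                excluded=_parse_bool(row["excluded"], visit_id=visit_id, column="excluded"),
                exclusion_reason=str(row["exclusion_reason"]).strip() or "none",
            )
            rec.validate()
            records.append(rec)
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.patient_id, rec.visit_id)
        if key in seen:
            raise IntegrityError(f"duplicate reference record for {key}")
        seen.add(key)
    return sorted(records, key=lambda r: (r.patient_id, r.visit_id))


def write_reference(records: Iterable[ReferenceStandardRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REFERENCE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.visit_id,
                    "true" if r.true_poaf else "false",
                    "true" if r.excluded else "false",
                    r.exclusion_reason,
                ]
            )


def reference_index(
    records: Sequence[ReferenceStandardRecord],
) -> dict[tuple[str, str], ReferenceStandardRecord]:
    """Index reference records by ``(patient_id, visit_id)``."""
    return {(r.patient_id, r.visit_id): r for r in records}
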