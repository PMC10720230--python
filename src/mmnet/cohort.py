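"""Reading, normalizing, and filtering inpatient hospitalization records.

The unit of analysis is the *baseline record*: each patient's earliest
admission, with its set of distinct 3-character ICD-10 category codes.
Filters keep middle-aged patients (ages 40-59 inclusive) and codes from
chapters 1-14; records left without any in-scope code are excluded.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

from . import icd10

__all__ = [
    "ColumnSchema",
    "Cohort",
    "InpatientRecord",
    "ParseReport",
    "apply_filters",
    "read_records",
    "read_cohort_csv",
    "select_baseline",
    "stratify_by_sex",
    "write_cohort_csv",
]

_SEX_ALIASES = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "2": "female",
}


class SchemaError(ValueError):
    """A required column is missing from the input table."""


@dataclass(frozen=True)
class ColumnSchema:
    """Column-name mapping for raw admission tables."""

    patient_id: str = "patient_id"
    admission_date: str = "admission_date"
    age: str = "age"
    sex: str = "sex"
    codes: str = "codes"

    def required(self) -> tuple[str, ...]:
        return (self.patient_id, self.admission_date, self.age, self.sex, self.codes)


@dataclass(frozen=True)
class InpatientRecord:
    """One admission: who, when, demographics, and the deduplicated code set."""

    patient_id: str
    admission_date: date
    age: int
    sex: str
    codes: frozenset[str]


@dataclass
class ParseReport:
    """Row-level accounting from :func:`read_records`."""

    n_rows: int = 0
    n_records: int = 0
    dropped_no_codes: int = 0
    dropped_bad_date: int = 0
    dropped_bad_row: int = 0
    invalid_codes_seen: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class Cohort:
    """One baseline record per patient, after filtering.

    ``exclusions`` counts records removed per filter rule so selection
    flowcharts can be reconstructed.
    """

    records: list[InpatientRecord]
    label: str = "cohort"
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def n_inpatients(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_date(text: str) -> date:
    text = text.strip()
    for fmt in ("%Y-%m-%d", "%Y/%m/%d", "%d/%m/%Y", "%Y%m%d"):
        try:
            return datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable date: {text!r}")


def _parse_codes(cell: str, sep: str, report: ParseReport) -> frozenset[str]:
    codes = set()
    for token in cell.split(sep):
        token = token.strip()
        if not token:
            continue
        try:
            codes.add(icd10.normalize_code(token))
        except icd10.InvalidCodeError:
            report.invalid_codes_seen += 1
    return frozenset(codes)


def read_records(
    path: str | Path,
    schema: ColumnSchema | None = None,
    delimiter: str = ",",
    code_sep: str = ";",
) -> tuple[list[InpatientRecord], ParseReport]:
    """Read one admission per row from a delimited text file.

    Raw codes are normalized to 3-character categories and deduplicated;
    rows with no parseable code, or an unparseable date or age, are dropped
    and counted in the returned :class:`ParseReport`.  A missing required
    column raises :class:`SchemaError`.
    """
    schema = schema or ColumnSchema()
    report = ParseReport()
    records: list[InpatientRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        missing = set(schema.required()) - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(f"missing required column(s): {sorted(missing)}")
        for row in reader:
            report.n_rows += 1
            codes = _parse_codes(row[schema.codes] or "", code_sep, report)
            if not codes:
                report.dropped_no_codes += 1
                continue
            try:
                when = _parse_date(row[schema.admission_date])
            except ValueError:
                report.dropped_bad_date += 1
                continue
            try:
                age = int(row[schema.age])
                if age < 0:
                    raise ValueError
            except (TypeError, ValueError):
                report.dropped_bad_row += 1
                continue
            sex = _SEX_ALIASES.get((row[schema.sex] or "").strip().lower(),
                                   (row[schema.sex] or "").strip().lower())
            records.append(InpatientRecord(
                patient_id=row[schema.patient_id].strip(),
                admission_date=when, age=age, sex=sex, codes=codes))
            report.n_records += 1
    return records, report


def select_baseline(records: list[InpatientRecord]) -> list[InpatientRecord]:
    """Keep each patient's earliest admission.

    Multiple admissions of one patient on the same earliest date are merged
    into a single baseline record whose code set is the union of the
    same-date code sets (the baseline is a snapshot of diagnoses, so no
    same-date row is privileged); age and sex are taken from the first row
    in a deterministic (age, sex) ordering.  The output is sorted by
    patient id and invariant under permutation of the input.
    """
    by_patient: dict[str, list[InpatientRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    out = []
    for pid in sorted(by_patient):
        recs = by_patient[pid]
        first_date = min(r.admission_date for r in recs)
        same_day = sorted((r for r in recs if r.admission_date == first_date),
                          key=lambda r: (r.age, r.sex))
        codes = frozenset().union(*(r.codes for r in same_day))
        head = same_day[0]
        out.append(InpatientRecord(pid, first_date, head.age, head.sex, codes))
    return out


def apply_filters(
    records: list[InpatientRecord],
    age_min: int = 40,
    age_max: int = 59,
    label: str = "cohort",
) -> Cohort:
    """Apply the inclusion/exclusion rules to baseline records.

    Codes from chapters 15-22 (and gap codes with no chapter) are removed
    from each record; records left with no code are excluded, as are
    records with age outside ``[age_min, age_max]`` (inclusive bounds).
    """
    kept: list[InpatientRecord] = []
    excl = {"age_out_of_range": 0, "no_in_scope_code": 0}
    for rec in records:
        if not (age_min <= rec.age <= age_max):
            excl["age_out_of_range"] += 1
            continue
        codes = frozenset(c for c in rec.codes if icd10.in_scope(c))
        if not codes:
            excl["no_in_scope_code"] += 1
            continue
        kept.append(InpatientRecord(rec.patient_id, rec.admission_date,
                                    rec.age, rec.sex, codes))
    return Cohort(records=kept, label=label, exclusions=excl)


def stratify_by_sex(cohort: Cohort) -> dict[str, Cohort]:
    """Partition a cohort into male and female strata.

    Records with an unrecognized sex value are excluded from both strata
    with a warning; their count is recorded in each stratum's exclusions.
    """
    male, female, unknown = [], [], 0
    for rec in cohort.records:
        if rec.sex == "male":
            male.append(rec)
        elif rec.sex == "female":
            female.append(rec)
        else:
            unknown += 1
    if unknown:
        warnings.warn(f"{unknown} record(s) with unrecognized sex excluded "
                      "from sex strata", stacklevel=2)
    return {
        "male": Cohort(male, label=f"{cohort.label}_male",
                       exclusions={"unknown_sex": unknown}),
        "female": Cohort(female, label=f"{cohort.label}_female",
                         exclusions={"unknown_sex": unknown}),
    }


def write_cohort_csv(cohort: Cohort, path: str | Path,
                     report_path: str | Path | None = None) -> None:
    """Write the canonical cohort CSV (codes pipe-joined, rows by patient id)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "admission_date", "age", "sex", "codes"])
        for rec in sorted(cohort.records, key=lambda r: r.patient_id):
            writer.writerow([rec.patient_id, rec.admission_date.isoformat(),
                             rec.age, rec.sex, "|".join(sorted(rec.codes))])
    if report_path is not None:
        payload = {"label": cohort.label, "n_inpatients": cohort.n_inpatients,
                   "exclusions": cohort.exclusions}
        Path(report_path).write_text(json.dumps(payload, indent=2))


def read_cohort_csv(path: str | Path, label: str = "cohort") -> Cohort:
    """Read a canonical cohort CSV back into a :class:`Cohort`."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(InpatientRecord(
                patient_id=row["patient_id"],
                admission_date=_parse_date(row["admission_date"]),
                age=int(row["age"]), sex=row["sex"],
                codes=frozenset(filter(None, row["codes"].split("|")))))
    return Cohort(records=records, label=label)
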