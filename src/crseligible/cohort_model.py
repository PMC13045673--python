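"""Patient-record schema, validation, and CSV I/O for CRSwNP cohorts.

One row per patient, one snapshot per row (index-date data only).  Every
field except ``patient_id`` may be missing; missing values are empty CSV
cells on write, and either empty cells or the literal string ``NA`` on read.

The column dictionary (names, types, legal ranges) is the module-level
``FIELDS`` mapping and is also shipped as ``data/column_dictionary.tsv``.
Counts of prior endoscopic sinus surgeries (``n_ess``) and systemic
corticosteroid courses (``n_scs_past_year``) banded as ">3" in source data
are stored as the integer 4: every rule threshold on these fields is <= 2,
so any value >= 4 behaves identically under every bundled rule set.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Union

import pandas as pd


class CohortError(Exception):
    """Base class for cohort I/O and validation errors."""


class CohortParseError(CohortError):
    """Malformed CSV (bad header, unreadable cell, unknown column)."""


class CohortValidationError(CohortError):
    """A present value violates its documented range or category set."""


class CohortIntegrityError(CohortError):
    """Cohort-level invariant broken (duplicate patient_id)."""


@dataclass(frozen=True)
class FieldSpec:
    """One entry of the column dictionary."""

    name: str
    kind: str  # 'str' | 'float' | 'int' | 'bool' | 'category'
    lo: Optional[float] = None
    hi: Optional[float] = None
    categories: Optional[tuple] = None
    description: str = ""


_F = FieldSpec

#: Column dictionary, in canonical CSV column order.
FIELDS: dict[str, FieldSpec] = {
    s.name: s
    for s in [
        _F("patient_id", "str", description="opaque unique identifier"),
        _F("age", "float", 0, 120, description="age in years"),
        _F("sex", "category", categories=("male", "female")),
        _F("bmi", "float", 5, 100, description="body mass index, kg/m^2"),
        _F("smoking", "category", categories=("current", "ex", "never")),
        _F("disease_duration", "float", 0, 120, description="CRS duration, years"),
        _F("n_ess", "int", 0, None, description="endoscopic sinus surgeries, ever"),
        _F("n_scs_past_year", "int", 0, None,
           description="systemic corticosteroid courses, past year"),
        _F("asthma", "bool", description="physician/self-reported asthma"),
        _F("allergy", "bool"),
        _F("nerd", "bool", description="NSAID-exacerbated respiratory disease"),
        _F("snot22", "int", 0, 110, description="SNOT-22 total score"),
        _F("lund_mackay", "int", 0, 24, description="Lund-Mackay CT score"),
        _F("vas_tss", "float", 0, 100, description="VAS total sinus symptoms, mm"),
        _F("vas_nb", "float", 0, 100, description="VAS nasal blockage, mm"),
        _F("vas_los", "float", 0, 100, description="VAS loss of smell, mm"),
        _F("nps", "int", 0, 8, description="nasal polyp score, 0-4 per side"),
        _F("bec", "float", 0, None, description="blood eosinophil count, cells/uL"),
        _F("ige", "float", 0, None, description="serum total IgE, IU/mL"),
        _F("biologic_initiated", "bool",
           description="biologic started at index date"),
        _F("incs", "bool", description="intranasal corticosteroid use"),
        _F("ics", "bool", description="inhaled corticosteroid use"),
    ]
}

COLUMNS: tuple = tuple(FIELDS)

#: Strings accepted as a missing cell on read (empty cell emitted on write).
MISSING_TOKENS = ("", "NA")

_BOOL_TRUE = {"true", "1", "yes", "y"}
_BOOL_FALSE = {"false", "0", "no", "n"}


@dataclass
class PatientRecord:
    """One patient's index-date snapshot; every field but the id is optional."""

    patient_id: str
    age: Optional[float] = None
    sex: Optional[str] = None
    bmi: Optional[float] = None
    smoking: Optional[str] = None
    disease_duration: Optional[float] = None
    n_ess: Optional[int] = None
    n_scs_past_year: Optional[int] = None
    asthma: Optional[bool] = None
    allergy: Optional[bool] = None
    nerd: Optional[bool] = None
    snot22: Optional[int] = None
    lund_mackay: Optional[int] = None
    vas_tss: Optional[float] = None
    vas_nb: Optional[float] = None
    vas_los: Optional[float] = None
    nps: Optional[int] = None
    bec: Optional[float] = None
    ige: Optional[float] = None
    biologic_initiated: Optional[bool] = None
    incs: Optional[bool] = None
    ics: Optional[bool] = None


@dataclass(frozen=True)
class Violation:
    """A single range/category violation found on a record (data, not an
    exception: validation reports all problems at once)."""

    patient_id: str
    field: str
    value: object
    bound: str

    def __str__(self) -> str:
        return (f"patient {self.patient_id!r}: field {self.field!r} = "
                f"{self.value!r} violates {self.bound}")


def validate_record(record: PatientRecord) -> List[Violation]:
    """Check all present fields against the column dictionary.

    Missing values are never violations.  Returns an empty list iff the
    record satisfies every documented range and category constraint.
    """
    out: List[Violation] = []
    pid = record.patient_id
    if not isinstance(pid, str) or pid == "":
        out.append(Violation(str(pid), "patient_id", pid, "non-empty string"))
    for spec in FIELDS.values():
        if spec.name == "patient_id":
            continue
        value = getattr(record, spec.name)
        if value is None:
            continue
        if spec.kind == "bool":
            if not isinstance(value, bool):
                out.append(Violation(pid, spec.name, value, "boolean"))
            continue
        if spec.kind == "category":
            if value not in spec.categories:
                out.append(Violation(
                    pid, spec.name, value, f"one of {spec.categories}"))
            continue
        # numeric kinds
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            out.append(Violation(pid, spec.name, value, spec.kind))
            continue
        if spec.kind == "int" and float(value) != int(value):
            out.append(Violation(pid, spec.name, value, "integer"))
            continue
        if isinstance(value, float) and not math.isfinite(value):
            out.append(Violation(pid, spec.name, value, "finite"))
            continue
        if spec.lo is not None and value < spec.lo:
            out.append(Violation(pid, spec.name, value, f">= {spec.lo:g}"))
        if spec.hi is not None and value > spec.hi:
            out.append(Violation(pid, spec.name, value, f"<= {spec.hi:g}"))
    return out


@dataclass
class CohortTable:
    """Ordered collection of validated patient records."""

    records: List[PatientRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def validate(self) -> None:
        """Raise on duplicate ids or any per-record violation."""
        seen = set()
        for rec in self.records:
            if rec.patient_id in seen:
                raise CohortIntegrityError(
                    f"duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)
            violations = validate_record(rec)
            if violations:
                raise CohortValidationError(
                    "; ".join(str(v) for v in violations))

    def to_dataframe(self) -> pd.DataFrame:
        """Cohort as a DataFrame with canonical columns; missing -> NaN/None."""
        return pd.DataFrame(
            [{c: getattr(r, c) for c in COLUMNS} for r in self.records],
            columns=list(COLUMNS),
        )


def _parse_cell(raw: str, spec: FieldSpec, pid: str, line: int):
    text = raw.strip()
    if text in MISSING_TOKENS:
        return None
    where = f"line {line}, patient {pid!r}, column {spec.name!r}"
    if spec.kind == "str":
        return text
    if spec.kind == "category":
        return text  # membership checked by validate_record
    if spec.kind == "bool":
        low = text.lower()
        if low in _BOOL_TRUE:
            return True
        if low in _BOOL_FALSE:
            return False
        raise CohortParseError(f"{where}: cannot parse boolean from {raw!r}")
    try:
        num = float(text)
    except ValueError as exc:
        raise CohortParseError(
            f"{where}: cannot parse number from {raw!r}") from exc
    if spec.kind == "int":
        if not num.is_integer():
            raise CohortParseError(
                f"{where}: expected integer, got {raw!r}")
        return int(num)
    return num


def read_cohort(
    path: Union[str, Path],
    *,
    unknown_columns: str = "error",
    exclude_prior_biologic: bool = False,
    provenance: Optional[str] = None,
) -> CohortTable:
    """Read a cohort CSV into a validated :class:`CohortTable`.

    Parameters
    ----------
    path
        UTF-8, comma-separated file with a mandatory header row.
    unknown_columns
        ``"error"`` (default) rejects columns outside the dictionary;
        ``"warn"`` drops them with a logged warning; ``"ignore"`` drops
        silently.  An optional ``prior_biologic`` boolean column is always
        tolerated (see below).
    exclude_prior_biologic
        If the file carries a ``prior_biologic`` column, drop rows where it
        is true.  Mirrors the registry analysis convention of excluding
        patients already on a biologic before the index date; the column is
        never stored on the record.

    Raises
    ------
    CohortParseError, CohortValidationError, CohortIntegrityError
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False,
                            na_values=[], encoding="utf-8")
    except pd.errors.ParserError as exc:
        raise CohortParseError(f"{path}: malformed CSV: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise CohortParseError(f"{path}: no header row") from exc

    extra = [c for c in frame.columns if c not in FIELDS and c != "prior_biologic"]
    if extra:
        if unknown_columns == "error":
            raise CohortParseError(f"{path}: unknown columns {extra}")
        if unknown_columns == "warn":
            import logging
            logging.getLogger(__name__).warning(
                "%s: ignoring unknown columns %s", path, extra)
    if "patient_id" not in frame.columns:
        raise CohortParseError(f"{path}: missing mandatory column 'patient_id'")

    records: List[PatientRecord] = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header is line 1
        pid = str(row["patient_id"]).strip()
        if exclude_prior_biologic and "prior_biologic" in frame.columns:
            flag = _parse_cell(row["prior_biologic"],
                               FieldSpec("prior_biologic", "bool"), pid, line)
            if flag is True:
                continue
        kwargs = {"patient_id": pid}
        for name, spec in FIELDS.items():
            if name == "patient_id" or name not in frame.columns:
                continue
            kwargs[name] = _parse_cell(row[name], spec, pid, line)
        records.append(PatientRecord(**kwargs))

    cohort = CohortTable(records=records,
                         provenance=provenance if provenance is not None else str(path))
    cohort.validate()
    return cohort


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # shortest exact round-trip
    return str(value)


def write_cohort(cohort: CohortTable, path: Union[str, Path]) -> None:
    """Write the cohort as UTF-8 CSV; missing values become empty cells.

    ``read_cohort(write_cohort(c))`` reproduces every field value and every
    missingness flag exactly (floats are written in shortest round-trip
    form).
    """
    frame = pd.DataFrame(
        [[_format_cell(getattr(r, c)) for c in COLUMNS] for r in cohort.records],
        columns=list(COLUMNS),
    )
    frame.to_csv(path, index=False, encoding="utf-8")


def column_dictionary() -> pd.DataFrame:
    """The machine-readable column dictionary as a DataFrame."""
    return pd.DataFrame(
        [
            {
                "column": s.name,
                "type": s.kind,
                "min": s.lo,
                "max": s.hi,
                "categories": "|".join(s.categories) if s.categories else "",
                "description": s.description,
            }
            for s in FIELDS.values()
        ]
    )
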