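"""Patient-level data model and tabular I/O.

A study record holds two readers' pH readings under each of two index
tests (the standard pH strip and the ester-impregnated "novel" strip)
together with the reference-standard tube location.  Gastric samples come
from patients receiving routine nasogastric feeding; lung samples come
from a separate surgical cohort and carry novel-strip readings only, so
the one-index-test exclusion rule applies to gastric records alone.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "TubeLocation",
    "ReferenceMethod",
    "PatientRecord",
    "PatientDataset",
    "ExclusionLog",
    "ParseError",
    "ValidationError",
    "CSV_COLUMNS",
    "read_patient_table",
    "write_patient_table",
    "write_results_table",
]

#: exact column order of the interchange CSV
CSV_COLUMNS = (
    "patient_id",
    "site_id",
    "true_location",
    "std_r1",
    "std_r2",
    "novel_r1",
    "novel_r2",
    "acid_suppression",
    "fasting",
    "reference_method",
)

PH_MIN, PH_MAX = 0.0, 14.0
_GRID_TOL = 1e-6


class ParseError(ValueError):
    """A CSV row could not be parsed; the message names the row."""


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


class TubeLocation(str, Enum):
    GASTRIC = "gastric"
    LUNG = "lung"


class ReferenceMethod(str, Enum):
    CXR = "cxr"
    CLINICAL_OBSERVATION = "clinical_observation"
    CAPNOGRAPHY = "capnography"


@dataclass(frozen=True)
class PatientRecord:
    """One patient's paired, two-reader pH readings plus ground truth.

    Missing readings are ``None``.  A record "has" an index test if at
    least one of its two readers produced a reading; single-reader
    records are accepted and the lone reading stands as its own average.
    """

    patient_id: str
    site_id: str
    true_location: TubeLocation
    std_r1: Optional[float] = None
    std_r2: Optional[float] = None
    novel_r1: Optional[float] = None
    novel_r2: Optional[float] = None
    acid_suppression: bool = False
    fasting: bool = False
    reference_method: ReferenceMethod = ReferenceMethod.CLINICAL_OBSERVATION

    @property
    def has_standard(self) -> bool:
        return self.std_r1 is not None or self.std_r2 is not None

    @property
    def has_novel(self) -> bool:
        return self.novel_r1 is not None or self.novel_r2 is not None

    @property
    def has_any_reading(self) -> bool:
        return self.has_standard or self.has_novel

    @property
    def single_reader(self) -> bool:
        """True if either present index test has only one reader's value."""
        std_partial = self.has_standard and (self.std_r1 is None or self.std_r2 is None)
        novel_partial = self.has_novel and (self.novel_r1 is None or self.novel_r2 is None)
        return std_partial or novel_partial

    def readings(self, strip: str) -> tuple[Optional[float], Optional[float]]:
        if strip == "standard":
            return self.std_r1, self.std_r2
        if strip == "novel":
            return self.novel_r1, self.novel_r2
        raise ValueError(f"unknown strip {strip!r}; expected 'standard' or 'novel'")

    def _present(self) -> Iterator[float]:
        for v in (self.std_r1, self.std_r2, self.novel_r1, self.novel_r2):
            if v is not None:
                yield v


def _on_grid(value: float, step: float) -> bool:
    return abs(value / step - round(value / step)) < _GRID_TOL


@dataclass(frozen=True)
class PatientDataset:
    """Ordered, validated collection of :class:`PatientRecord`.

    Invariants enforced at construction: unique patient ids, non-empty,
    all present pH readings in [0, 14] and on the strip granularity grid,
    lung records confirmed by capnography.
    """

    records: tuple[PatientRecord, ...]
    granularity: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValidationError("dataset is empty")
        if self.granularity <= 0:
            raise ValidationError("granularity must be positive")
        seen: set[str] = set()
        for rec in self.records:
            if rec.patient_id in seen:
                raise ValidationError(f"duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)
            for v in rec._present():
                if not (PH_MIN <= v <= PH_MAX):
                    raise ValidationError(
                        f"patient {rec.patient_id!r}: pH {v} outside [{PH_MIN}, {PH_MAX}]"
                    )
                if not _on_grid(v, self.granularity):
                    raise ValidationError(
                        f"patient {rec.patient_id!r}: pH {v} not on the "
                        f"{self.granularity} strip granularity grid"
                    )
            if rec.true_location is TubeLocation.LUNG and (
                rec.reference_method is not ReferenceMethod.CAPNOGRAPHY
            ):
                raise ValidationError(
                    f"patient {rec.patient_id!r}: lung records require capnography "
                    "as the reference method"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def subset(self, location: TubeLocation) -> tuple[PatientRecord, ...]:
        return tuple(r for r in self.records if r.true_location is location)

    @property
    def gastric(self) -> tuple[PatientRecord, ...]:
        return self.subset(TubeLocation.GASTRIC)

    @property
    def lung(self) -> tuple[PatientRecord, ...]:
        return self.subset(TubeLocation.LUNG)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "site_id": r.site_id,
                    "true_location": r.true_location.value,
                    "std_r1": r.std_r1,
                    "std_r2": r.std_r2,
                    "novel_r1": r.novel_r1,
                    "novel_r2": r.novel_r2,
                    "acid_suppression": r.acid_suppression,
                    "fasting": r.fasting,
                    "reference_method": r.reference_method.value,
                }
            )
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


@dataclass
class ExclusionLog:
    """Counts of records dropped while reading a patient table."""

    one_test_only: int = 0
    no_aspirate: int = 0
    flagged_single_reader: int = 0  # retained, but noted

    @property
    def total_excluded(self) -> int:
        return self.one_test_only + self.no_aspirate


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(text: str, row: int, col: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ParseError(f"row {row}: cannot parse boolean {col}={text!r}")


def _parse_ph(text: str, row: int, col: str) -> Optional[float]:
    t = text.strip()
    if t == "":
        return None
    try:
        v = float(t)
    except ValueError as exc:
        raise ParseError(f"row {row}: cannot parse {col}={text!r} as pH") from exc
    if math.isnan(v):
        return None
    if not (PH_MIN <= v <= PH_MAX):
        raise ValidationError(f"row {row}: {col}={v} outside pH range [0, 14]")
    return v


def read_patient_table(
    path: Union[str, Path], granularity: float = 0.5
) -> tuple[PatientDataset, ExclusionLog]:
    """Read the interchange CSV, applying the study exclusion rules.

    Gastric records with readings from only one index test are excluded
    (counted in ``one_test_only``); records with no readings at all are
    excluded as aspiration failures (``no_aspirate``).  Lung records need
    only novel-strip readings.  Returns the validated dataset together
    with the exclusion log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != CSV_COLUMNS:
            raise ParseError(
                f"header mismatch: expected {','.join(CSV_COLUMNS)}, "
                f"got {','.join(reader.fieldnames or [])}"
            )
        log = ExclusionLog()
        records: list[PatientRecord] = []
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            if any(row.get(c) is None for c in CSV_COLUMNS):
                raise ParseError(f"row {i}: wrong number of fields")
            try:
                location = TubeLocation(row["true_location"].strip().lower())
                method = ReferenceMethod(row["reference_method"].strip().lower())
            except ValueError as exc:
                raise ParseError(f"row {i}: {exc}") from exc
            rec = PatientRecord(
                patient_id=row["patient_id"].strip(),
                site_id=row["site_id"].strip(),
                true_location=location,
                std_r1=_parse_ph(row["std_r1"], i, "std_r1"),
                std_r2=_parse_ph(row["std_r2"], i, "std_r2"),
                novel_r1=_parse_ph(row["novel_r1"], i, "novel_r1"),
                novel_r2=_parse_ph(row["novel_r2"], i, "novel_r2"),
                acid_suppression=_parse_bool(row["acid_suppression"], i, "acid_suppression"),
                fasting=_parse_bool(row["fasting"], i, "fasting"),
                reference_method=method,
            )
            if not rec.has_any_reading:
                log.no_aspirate += 1
                continue
            if rec.true_location is TubeLocation.GASTRIC and not (
                rec.has_standard and rec.has_novel
            ):
                log.one_test_only += 1
                continue
            if rec.true_location is TubeLocation.LUNG and not rec.has_novel:
                log.one_test_only += 1
                continue
            if rec.single_reader:
                log.flagged_single_reader += 1
            records.append(rec)
    return PatientDataset(tuple(records), granularity=granularity), log


def _fmt_ph(v: Optional[float]) -> str:
    return "" if v is None else repr(v)


def write_patient_table(dataset: PatientDataset, path: Union[str, Path]) -> None:
    """Write a dataset to the interchange CSV (round-trips exactly)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in dataset:
            writer.writerow(
                [
                    r.patient_id,
                    r.site_id,
                    r.true_location.value,
                    _fmt_ph(r.std_r1),
                    _fmt_ph(r.std_r2),
                    _fmt_ph(r.novel_r1),
                    _fmt_ph(r.novel_r2),
                    "true" if r.acid_suppression else "false",
                    "true" if r.fasting else "false",
                    r.reference_method.value,
                ]
            )


def write_results_table(
    rows: Union[pd.DataFrame, Sequence[Mapping[str, object]]],
    path: Union[str, Path],
) -> None:
    """Write tabular results to CSV at full numeric precision."""
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        frame = pd.DataFrame(list(rows))
    if frame.empty:
        raise ValueError("refusing to write an empty results table")
    frame.to_csv(path, index=False)
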