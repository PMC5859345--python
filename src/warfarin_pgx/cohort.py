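"""Patient/visit domain types, CSV I/O and cohort-level descriptive summaries.

A cohort is stored as two human-auditable CSV files: one row per patient for
the static fields, and a long-format visits file keyed by patient id.  Visit
rows may carry a prothrombin time (seconds), an INR, or both; a visit with
neither is invalid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

SEXES = ("male", "female")
RACES = ("white", "asian", "black_or_african_american", "missing_or_mixed")
CYP2C9_DIPLOTYPES = ("*1/*1", "*1/*2", "*1/*3", "*2/*2", "*2/*3", "*3/*3", "unknown")
VKORC1_GENOTYPES = ("GG", "GA", "AA", "unknown")
BLEEDING_CLASSES = ("none", "minor", "major")
INDICATIONS = ("thromboembolic", "cardiovascular", "both")

PATIENT_COLUMNS = [
    "id", "sex", "age", "height_cm", "weight_kg", "race",
    "enzyme_inducer", "amiodarone", "cyp2c9", "vkorc1",
    "target_inr_low", "target_inr_high", "bleeding", "indication",
]
VISIT_COLUMNS = ["patient_id", "visit_index", "weekly_dose", "pt_seconds", "inr"]


class CohortSchemaError(ValueError):
    """A cohort CSV does not match the documented schema."""


class RecordError(ValueError):
    """A single patient row failed validation; carries the offending id."""

    def __init__(self, patient_id: str, message: str):
        self.patient_id = patient_id
        super().__init__(f"patient {patient_id!r}: {message}")


@dataclass(frozen=True)
class TargetRange:
    """Therapeutic INR window; 2.0-3.0 for most indications, 2.5-3.5 for mechanical valves."""

    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise ValueError(f"require 0 < low < high, got ({self.low}, {self.high})")

    def contains(self, inr: float) -> bool:
        # inclusive at both ends
        return self.low <= inr <= self.high


@dataclass(frozen=True)
class Visit:
    """One anticoagulation-clinic visit: prescribed weekly dose and coagulation status."""

    index: int
    weekly_dose: float
    pt_seconds: float | None = None
    inr: float | None = None

    def __post_init__(self):
        if self.weekly_dose < 0:
            raise ValueError(f"weekly_dose must be >= 0, got {self.weekly_dose}")
        if self.pt_seconds is None and self.inr is None:
            raise ValueError("a visit needs at least one of pt_seconds / inr")
        if self.pt_seconds is not None and self.pt_seconds <= 0:
            raise ValueError(f"pt_seconds must be > 0, got {self.pt_seconds}")


@dataclass(frozen=True)
class PatientRecord:
    """One subject: demographics, anthropometrics, genotypes, therapy flags, visit history."""

    id: str
    sex: str
    age: float
    height: float           # cm
    weight: float           # kg
    race: str
    enzyme_inducer: bool    # carbamazepine / phenytoin / rifampin
    amiodarone: bool
    cyp2c9: str
    vkorc1: str
    target_inr: TargetRange
    visits: tuple[Visit, ...] = ()
    bleeding: str = "none"  # worst-ever event class
    indication: str = "thromboembolic"

    def __post_init__(self):
        if self.sex not in SEXES:
            raise RecordError(self.id, f"sex must be one of {SEXES}, got {self.sex!r}")
        for name, value in (("age", self.age), ("height", self.height), ("weight", self.weight)):
            if not value > 0:
                raise RecordError(self.id, f"{name} must be > 0, got {value}")
        if self.race not in RACES:
            raise RecordError(self.id, f"race must be one of {RACES}, got {self.race!r}")
        if self.cyp2c9 not in CYP2C9_DIPLOTYPES:
            raise RecordError(self.id, f"unparseable CYP2C9 diplotype {self.cyp2c9!r}")
        if self.vkorc1 not in VKORC1_GENOTYPES:
            raise RecordError(self.id, f"unparseable VKORC1 genotype {self.vkorc1!r}")
        if self.bleeding not in BLEEDING_CLASSES:
            raise RecordError(self.id, f"bleeding must be one of {BLEEDING_CLASSES}")
        if self.indication not in INDICATIONS:
            raise RecordError(self.id, f"indication must be one of {INDICATIONS}")
        indices = [v.index for v in self.visits]
        if indices != sorted(indices):
            raise RecordError(self.id, "visits must be ordered by visit index")

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2


def bmi_class(bmi: float) -> str:
    """WHO adult BMI classes."""
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


@dataclass
class CohortSummary:
    """Descriptive cohort table: n, percentage breakdowns and mean +/- SD continuous traits."""

    n: int
    percent_sex: dict[str, float]
    percent_indication: dict[str, float]
    percent_bleeding: dict[str, float]
    percent_bmi_class: dict[str, float]
    mean_age: float
    sd_age: float
    mean_bmi: float
    sd_bmi: float
    mean_inr: float = float("nan")
    sd_inr: float = float("nan")
    extras: dict = field(default_factory=dict)


def summarize_cohort(cohort: list[PatientRecord]) -> CohortSummary:
    """Compute the descriptive characteristics table of a cohort.

    BMI is weight/(height/100)^2 classified on WHO cut-offs; the INR summary
    pools every visit INR observed across the cohort.  Raises on an empty
    cohort.
    """
    import numpy as np

    if not cohort:
        raise ValueError("cannot summarize an empty cohort")
    n = len(cohort)

    def pct(categories, getter):
        return {c: 100.0 * sum(getter(p) == c for p in cohort) / n for c in categories}

    ages = np.array([p.age for p in cohort], dtype=float)
    bmis = np.array([p.bmi for p in cohort], dtype=float)
    inrs = np.array([v.inr for p in cohort for v in p.visits if v.inr is not None], dtype=float)
    return CohortSummary(
        n=n,
        percent_sex=pct(SEXES, lambda p: p.sex),
        percent_indication=pct(INDICATIONS, lambda p: p.indication),
        percent_bleeding=pct(BLEEDING_CLASSES, lambda p: p.bleeding),
        percent_bmi_class=pct(("underweight", "normal", "overweight", "obese"),
                              lambda p: bmi_class(p.bmi)),
        mean_age=float(ages.mean()),
        sd_age=float(ages.std(ddof=1)) if n > 1 else 0.0,
        mean_bmi=float(bmis.mean()),
        sd_bmi=float(bmis.std(ddof=1)) if n > 1 else 0.0,
        mean_inr=float(inrs.mean()) if inrs.size else float("nan"),
        sd_inr=float(inrs.std(ddof=1)) if inrs.size > 1 else float("nan"),
    )


# ---------------------------------------------------------------------------
# CSV I/O

def _require_columns(header: list[str], required: list[str], path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise CohortSchemaError(f"{path}: missing mandatory column(s) {missing}")


def _parse_bool(s: str) -> bool:
    if s.lower() in ("true", "1", "yes"):
        return True
    if s.lower() in ("false", "0", "no"):
        return False
    raise ValueError(f"unparseable boolean {s!r}")


def read_cohort(patients_path, visits_path=None) -> list[PatientRecord]:
    """Read and validate a cohort from the patient CSV (and optional visits CSV).

    Every row becomes a validated :class:`PatientRecord`; the row count is
    preserved.  A malformed header raises :class:`CohortSchemaError` naming
    the column; a bad row raises :class:`RecordError` carrying the patient id.
    """
    patients_path = Path(patients_path)
    visits_by_patient: dict[str, list[Visit]] = {}
    if visits_path is not None:
        with open(visits_path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            _require_columns(reader.fieldnames or [], VISIT_COLUMNS, visits_path)
            for row in reader:
                pid = row["patient_id"]
                visits_by_patient.setdefault(pid, []).append(Visit(
                    index=int(row["visit_index"]),
                    weekly_dose=float(row["weekly_dose"]),
                    pt_seconds=float(row["pt_seconds"]) if row["pt_seconds"] != "" else None,
                    inr=float(row["inr"]) if row["inr"] != "" else None,
                ))

    cohort: list[PatientRecord] = []
    with open(patients_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames or [], PATIENT_COLUMNS, patients_path)
        for row in reader:
            pid = row["id"]
            try:
                visits = tuple(sorted(visits_by_patient.get(pid, []), key=lambda v: v.index))
                cohort.append(PatientRecord(
                    id=pid,
                    sex=row["sex"],
                    age=float(row["age"]),
                    height=float(row["height_cm"]),
                    weight=float(row["weight_kg"]),
                    race=row["race"],
                    enzyme_inducer=_parse_bool(row["enzyme_inducer"]),
                    amiodarone=_parse_bool(row["amiodarone"]),
                    cyp2c9=row["cyp2c9"],
                    vkorc1=row["vkorc1"],
                    target_inr=TargetRange(float(row["target_inr_low"]),
                                           float(row["target_inr_high"])),
                    bleeding=row["bleeding"],
                    indication=row["indication"],
                    visits=visits,
                ))
            except RecordError:
                raise
            except (ValueError, KeyError) as exc:
                raise RecordError(pid, str(exc)) from exc
    return cohort


def write_cohort(cohort: list[PatientRecord], patients_path, visits_path=None) -> None:
    """Write a cohort to the patient CSV (and the visits CSV if a path is given)."""
    with open(patients_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PATIENT_COLUMNS)
        for p in cohort:
            writer.writerow([
                p.id, p.sex, repr(p.age), repr(p.height), repr(p.weight), p.race,
                str(p.enzyme_inducer).lower(), str(p.amiodarone).lower(),
                p.cyp2c9, p.vkorc1, repr(p.target_inr.low), repr(p.target_inr.high),
                p.bleeding, p.indication,
            ])
    if visits_path is not None:
        with open(visits_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(VISIT_COLUMNS)
            for p in cohort:
                for v in p.visits:
                    writer.writerow([
                        p.id, v.index, repr(v.weekly_dose),
                        "" if v.pt_seconds is None else repr(v.pt_seconds),
                        "" if v.inr is None else repr(v.inr),
                    ])
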