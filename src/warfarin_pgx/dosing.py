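"""The three weekly-dose prediction models and the INR formula.

Both IWPC equations are linear on the square root of the weekly dose in
mg/week: the pharmacogenetic (PGx) model includes CYP2C9 diplotype and
VKORC1 -1639G>A genotype indicators on top of age, height, weight, race and
interacting-drug terms; the clinical model drops the genotype terms.  The
third comparator is a fixed 35 mg/week (the customary 5 mg/day start).

Coefficients ship as a versioned JSON configuration
(``data/iwpc_coefficients.json``) and can be overridden by a user file of
the same shape.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from importlib import resources

from warfarin_pgx.cohort import PatientRecord

_CYP2C9_KEYS = {
    "*1/*2": "cyp2c9_12", "*1/*3": "cyp2c9_13", "*2/*2": "cyp2c9_22",
    "*2/*3": "cyp2c9_23", "*3/*3": "cyp2c9_33", "unknown": "cyp2c9_unknown",
}
_VKORC1_KEYS = {"GA": "vkorc1_GA", "AA": "vkorc1_AA", "unknown": "vkorc1_unknown"}
_RACE_KEYS = {
    "asian": "race_asian",
    "black_or_african_american": "race_black_or_african_american",
    "missing_or_mixed": "race_missing_or_mixed",
}


@dataclass(frozen=True)
class ClinicalCoefficients:
    """Genotype-free IWPC equation terms (sqrt mg/week scale)."""

    intercept: float
    age_decades: float
    height_cm: float
    weight_kg: float
    race_asian: float
    race_black_or_african_american: float
    race_missing_or_mixed: float
    enzyme_inducer: float
    amiodarone: float


@dataclass(frozen=True)
class PgxCoefficients(ClinicalCoefficients):
    """Full pharmacogenetic IWPC equation terms (sqrt mg/week scale)."""

    vkorc1_GA: float = 0.0
    vkorc1_AA: float = 0.0
    vkorc1_unknown: float = 0.0
    cyp2c9_12: float = 0.0
    cyp2c9_13: float = 0.0
    cyp2c9_22: float = 0.0
    cyp2c9_23: float = 0.0
    cyp2c9_33: float = 0.0
    cyp2c9_unknown: float = 0.0


@dataclass(frozen=True)
class InrParams:
    """INR standardization parameters: normal-pool PT and reagent ISI."""

    pt_normal: float = 15.0
    isi: float = 1.03

    def __post_init__(self):
        if self.pt_normal <= 0 or self.isi <= 0:
            raise ValueError("pt_normal and isi must be > 0")


@dataclass(frozen=True)
class DosePrediction:
    patient_id: str
    model: str  # pgx / clinical / fixed
    weekly_dose: float

    def __post_init__(self):
        if self.weekly_dose < 0:
            raise ValueError("weekly_dose must be >= 0")


def load_coefficients(path=None) -> tuple[PgxCoefficients, ClinicalCoefficients]:
    """Load the (pgx, clinical) coefficient sets from JSON; default = shipped IWPC values."""
    if path is None:
        text = resources.files("warfarin_pgx.data").joinpath("iwpc_coefficients.json").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = json.loads(text)
    return PgxCoefficients(**raw["pgx"]), ClinicalCoefficients(**raw["clinical"])


def _shared_linear_terms(patient: PatientRecord, c: ClinicalCoefficients) -> float:
    for name, value in (("age", patient.age), ("height", patient.height),
                        ("weight", patient.weight)):
        if value is None or not value > 0:
            raise ValueError(f"patient {patient.id}: {name} missing or non-positive")
    lp = (c.intercept
          + c.age_decades * (patient.age / 10.0)   # continuous decades, not floored
          + c.height_cm * patient.height
          + c.weight_kg * patient.weight)
    race_key = _RACE_KEYS.get(patient.race)
    if race_key is not None:
        lp += getattr(c, race_key)
    if patient.enzyme_inducer:
        lp += c.enzyme_inducer
    if patient.amiodarone:
        lp += c.amiodarone
    return lp


def _square(lp: float, model: str) -> float:
    if lp < 0:
        warnings.warn(f"{model}: negative linear predictor {lp:.4f} clamped to dose 0",
                      stacklevel=3)
        return 0.0
    return lp * lp


def pgx_sqrt_dose(patient: PatientRecord, coeffs: PgxCoefficients) -> float:
    """PGx linear predictor on the sqrt(mg/week) scale (before squaring)."""
    lp = _shared_linear_terms(patient, coeffs)
    key = _VKORC1_KEYS.get(patient.vkorc1)
    if key is not None:
        lp += getattr(coeffs, key)
    key = _CYP2C9_KEYS.get(patient.cyp2c9)
    if key is not None:
        lp += getattr(coeffs, key)
    return lp


def iwpc_pgx_weekly_dose(patient: PatientRecord, coeffs: PgxCoefficients | None = None) -> float:
    """Predicted weekly warfarin dose (mg/week) from the IWPC pharmacogenetic equation."""
    if coeffs is None:
        coeffs = _default_pgx()
    return _square(pgx_sqrt_dose(patient, coeffs), "pgx")


def iwpc_clinical_weekly_dose(patient: PatientRecord,
                              coeffs: ClinicalCoefficients | None = None) -> float:
    """Predicted weekly warfarin dose (mg/week) from the genotype-free IWPC equation."""
    if coeffs is None:
        coeffs = _default_clinical()
    return _square(_shared_linear_terms(patient, coeffs), "clinical")


def fixed_weekly_dose() -> float:
    """The fixed-dose comparator: 35 mg/week (5 mg/day)."""
    return 35.0


def inr_from_pt(pt_patient: float, params: InrParams = InrParams()) -> float:
    """INR = (PT_patient / PT_normal)^ISI."""
    if pt_patient <= 0:
        raise ValueError(f"pt_patient must be > 0, got {pt_patient}")
    return (pt_patient / params.pt_normal) ** params.isi


def pt_from_inr(inr: float, params: InrParams = InrParams()) -> float:
    """Inverse of :func:`inr_from_pt`; used when synthesizing visit records."""
    if inr <= 0:
        raise ValueError(f"inr must be > 0, got {inr}")
    return params.pt_normal * inr ** (1.0 / params.isi)


def predict_all_models(patient: PatientRecord,
                       pgx: PgxCoefficients | None = None,
                       clinical: ClinicalCoefficients | None = None) -> dict[str, float]:
    """Weekly-dose predictions from all three models for one patient."""
    return {
        "pgx": iwpc_pgx_weekly_dose(patient, pgx),
        "clinical": iwpc_clinical_weekly_dose(patient, clinical),
        "fixed": fixed_weekly_dose(),
    }


_DEFAULTS: list = []


def _default_pgx() -> PgxCoefficients:
    if not _DEFAULTS:
        _DEFAULTS.extend(load_coefficients())
    return _DEFAULTS[0]


def _default_clinical() -> ClinicalCoefficients:
    if not _DEFAULTS:
        _DEFAULTS.extend(load_coefficients())
    return _DEFAULTS[1]


def coefficients_as_dict(c: ClinicalCoefficients) -> dict[str, float]:
    return asdict(c)
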