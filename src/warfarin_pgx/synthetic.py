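"""Seeded synthetic-cohort generator emulating the study population's structure.

The generator reproduces the statistical shape of the motivating cohort —
age 48.8 +/- 14.4 y truncated to [16, 76], BMI 27.8 +/- 5.2 kg/m^2, 42.4%
male, CYP2C9 *2 genotype probabilities (0.743, 0.248, 0.010) and VKORC1
-1639G>A probabilities (0.297, 0.485, 0.218) — and plants a recoverable
ground truth: each patient's true stable dose is the pharmacogenetic model's
prediction perturbed by Gaussian noise on the square-root-of-dose scale, the
terminal visits sit at that dose with in-range INR so the stable-dose
scanner recovers it exactly, and bleeding risk rises logistically with the
relative excess of the achieved dose over the model-calculated dose,
emulating the observed bleeding/dose-group association.

With the noise at zero the pharmacogenetic model is exactly correct by
construction; the clinical model still mispredicts genotype carriers, which
is what makes the genetic contribution identifiable in evaluation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit
from scipy.stats import truncnorm

from warfarin_pgx import genotyping
from warfarin_pgx.cohort import PatientRecord, TargetRange, Visit, write_cohort
from warfarin_pgx.dosing import (
    InrParams,
    PgxCoefficients,
    load_coefficients,
    pgx_sqrt_dose,
    pt_from_inr,
)

FRAGMENT_COLUMNS = ["patient_id", "assay", "fragments_bp"]

#: diplotype labels matching the per-locus genotype-class order
CYP2C9_CLASSES = ("*1/*1", "*1/*2", "*2/*2")
VKORC1_CLASSES = ("GG", "GA", "AA")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic cohort; defaults emulate the study conditions."""

    n: int = 101
    cyp2c9_probs: tuple[float, float, float] = (0.743, 0.248, 0.010)
    vkorc1_probs: tuple[float, float, float] = (0.297, 0.485, 0.218)
    age_mean: float = 48.8
    age_sd: float = 14.4
    age_range: tuple[float, float] = (16.0, 76.0)
    height_mean: float = 165.0
    height_sd: float = 9.0
    height_range: tuple[float, float] = (140.0, 195.0)
    bmi_mean: float = 27.8
    bmi_sd: float = 5.2
    bmi_range: tuple[float, float] = (16.0, 45.0)
    male_fraction: float = 0.424
    indication_probs: tuple[float, float, float] = (0.505, 0.414, 0.081)
    amiodarone_prob: float = 0.05
    enzyme_inducer_prob: float = 0.02
    valve_target_prob: float = 0.03       # patients needing the 2.5-3.5 INR window
    dose_noise_sd: float = 0.85           # sigma on the sqrt(mg/week) scale
    min_weekly_dose: float = 7.0          # 1 mg/day floor for the true stable dose
    stable_visits: int = 3
    max_titration_visits: int = 3
    inr_noise_sd: float = 0.25            # spread of in-range INR around the window centre
    bleeding_intercept: float = -0.35     # logit of bleeding risk at dose == calculated
    bleeding_slope: float = 1.5           # per unit relative dose excess
    major_fraction: float = 0.154         # major : any bleeding, as observed (7 : 45.5)
    seed: int = 0

    def __post_init__(self):
        for probs in (self.cyp2c9_probs, self.vkorc1_probs, self.indication_probs):
            if abs(sum(probs) - 1.0) > 0.01 or min(probs) < 0:
                raise ValueError(f"probabilities must be >= 0 and sum to ~1, got {probs}")
        if self.dose_noise_sd < 0 or self.inr_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _norm(probs):
    p = np.asarray(probs, dtype=float)
    return p / p.sum()


def simulate_cohort(params: SimulationParams = SimulationParams(),
                    coeffs: PgxCoefficients | None = None) -> list[PatientRecord]:
    """Draw a fully deterministic (seeded) synthetic cohort.

    Genotypes at the two loci are independent; the true weekly stable dose is
    ``(pgx linear predictor + Normal(0, dose_noise_sd))^2`` floored at
    ``min_weekly_dose``; the visit history ends with ``stable_visits`` visits
    at that dose with in-range INR, preceded by 0-``max_titration_visits``
    out-of-range titration visits; bleeding is Bernoulli with logit
    ``intercept + slope * (actual - calculated)/calculated``.
    """
    if coeffs is None:
        coeffs = load_coefficients()[0]
    rng = np.random.default_rng(params.seed)
    n = params.n

    ages = _trunc_normal(rng, params.age_mean, params.age_sd, *params.age_range, size=n)
    heights = _trunc_normal(rng, params.height_mean, params.height_sd,
                            *params.height_range, size=n)
    bmis = _trunc_normal(rng, params.bmi_mean, params.bmi_sd, *params.bmi_range, size=n)
    weights = bmis * (heights / 100.0) ** 2
    sexes = np.where(rng.random(n) < params.male_fraction, "male", "female")
    cyp = rng.choice(3, size=n, p=_norm(params.cyp2c9_probs))
    vko = rng.choice(3, size=n, p=_norm(params.vkorc1_probs))
    indications = rng.choice(("thromboembolic", "cardiovascular", "both"),
                             size=n, p=_norm(params.indication_probs))
    amiodarone = rng.random(n) < params.amiodarone_prob
    inducer = rng.random(n) < params.enzyme_inducer_prob
    valve = rng.random(n) < params.valve_target_prob
    inr_params = InrParams()

    cohort: list[PatientRecord] = []
    for i in range(n):
        target = TargetRange(2.5, 3.5) if valve[i] else TargetRange(2.0, 3.0)
        base = PatientRecord(
            id=f"P{i + 1:03d}",
            sex=str(sexes[i]),
            age=float(ages[i]),
            height=float(heights[i]),
            weight=float(weights[i]),
            race="white",  # study population maps to the reference category
            enzyme_inducer=bool(inducer[i]),
            amiodarone=bool(amiodarone[i]),
            cyp2c9=CYP2C9_CLASSES[cyp[i]],
            vkorc1=VKORC1_CLASSES[vko[i]],
            target_inr=target,
            indication=str(indications[i]),
        )
        lp = pgx_sqrt_dose(base, coeffs)
        noisy = lp + rng.normal(0.0, params.dose_noise_sd) if params.dose_noise_sd > 0 else lp
        wsd = max(noisy, 0.0) ** 2
        wsd = max(wsd, params.min_weekly_dose)
        calculated = max(lp, 0.0) ** 2

        visits = []
        idx = 0
        for _ in range(rng.integers(0, params.max_titration_visits + 1)):
            low_side = rng.random() < 0.5
            factor = rng.uniform(0.6, 0.85) if low_side else rng.uniform(1.15, 1.4)
            inr = (rng.uniform(max(0.8, target.low - 1.0), target.low - 0.05) if low_side
                   else rng.uniform(target.high + 0.05, target.high + 1.5))
            visits.append(Visit(idx, float(wsd * factor),
                                pt_seconds=pt_from_inr(inr, inr_params), inr=float(inr)))
            idx += 1
        mid = 0.5 * (target.low + target.high)
        half = 0.5 * (target.high - target.low)
        for _ in range(params.stable_visits):
            inr = mid + rng.normal(0.0, params.inr_noise_sd) if params.inr_noise_sd > 0 else mid
            inr = float(np.clip(inr, target.low + 0.02 * half, target.high - 0.02 * half))
            visits.append(Visit(idx, float(wsd),
                                pt_seconds=pt_from_inr(inr, inr_params), inr=inr))
            idx += 1

        excess = (wsd - calculated) / calculated
        p_bleed = float(expit(params.bleeding_intercept + params.bleeding_slope * excess))
        if rng.random() < p_bleed:
            bleeding = "major" if rng.random() < params.major_fraction else "minor"
        else:
            bleeding = "none"
        cohort.append(PatientRecord(
            **{**base.__dict__, "visits": tuple(visits), "bleeding": bleeding}))
    return cohort


def fragment_rows_for_patient(patient: PatientRecord) -> list[tuple[str, str, str]]:
    """RFLP fragment observations (full patterns) consistent with a patient's genotypes."""
    star2 = {"*1/*1": "hom_ref", "*1/*2": "het", "*2/*2": "hom_var",
             "*1/*3": "hom_ref", "*2/*3": "het", "*3/*3": "hom_ref"}[patient.cyp2c9]
    star3 = {"*1/*1": "hom_ref", "*1/*2": "hom_ref", "*2/*2": "hom_ref",
             "*1/*3": "het", "*2/*3": "het", "*3/*3": "hom_var"}[patient.cyp2c9]
    msp = {"GG": "hom_ref", "GA": "het", "AA": "hom_var"}[patient.vkorc1]
    rows = []
    for assay_name, cls in (("CYP2C9_star2_AvaII", star2),
                            ("CYP2C9_star3_KpnI", star3),
                            ("VKORC1_1639_MspI", msp)):
        assay = genotyping.ASSAYS[assay_name]
        frags = sorted(genotyping.fragments_for_genotype(assay, cls), reverse=True)
        rows.append((patient.id, assay_name, ",".join(str(f) for f in frags)))
    return rows


def generate_fixture_files(params: SimulationParams, directory) -> dict[str, Path]:
    """Write patients.csv, visits.csv and fragments.csv for a simulated cohort.

    The fragment patterns decode back to the generating genotypes, so the
    files round-trip through the whole pipeline; the same seed reproduces
    byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(params)
    paths = {
        "patients": directory / "patients.csv",
        "visits": directory / "visits.csv",
        "fragments": directory / "fragments.csv",
    }
    write_cohort(cohort, paths["patients"], paths["visits"])
    with open(paths["fragments"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(FRAGMENT_COLUMNS)
        for p in cohort:
            if p.cyp2c9 == "unknown" or p.vkorc1 == "unknown":
                continue
            writer.writerows(fragment_rows_for_patient(p))
    return paths
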