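"""Empirical warfarin stable dose (WSD) and dose-group/bleeding cross-tabulation.

A patient has reached a stable dose when some run of at least three
consecutive visits shares a single weekly dose and every INR in that run
lies inside the patient's therapeutic target range (bounds inclusive).  The
earliest qualifying window defines the WSD, mirroring a prospective reading
of the chart.
"""

from __future__ import annotations

from dataclasses import dataclass

from warfarin_pgx.cohort import PatientRecord, TargetRange, Visit

MIN_STABLE_RUN = 3


@dataclass(frozen=True)
class StableDoseResult:
    patient_id: str
    is_stable: bool
    wsd: float | None = None            # mg/week, present iff stable
    window: tuple[int, ...] = ()        # visit indices of the qualifying run

    def __post_init__(self):
        if self.is_stable:
            if self.wsd is None or len(self.window) < MIN_STABLE_RUN:
                raise ValueError("stable result requires a WSD and a >=3-visit window")


@dataclass(frozen=True)
class DoseGroupTable:
    """2x3 bleeding-by-dose-group counts; columns are dose vs model-calculated dose."""

    none: tuple[int, int, int]   # (higher, same, lower)
    bleed: tuple[int, int, int]

    def __post_init__(self):
        if min(self.none + self.bleed) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return sum(self.none) + sum(self.bleed)

    def as_matrix(self) -> list[list[int]]:
        return [list(self.none), list(self.bleed)]


def find_stable_dose(visits, target: TargetRange, patient_id: str = "") -> StableDoseResult:
    """Scan a visit history for the earliest >=3-visit constant-dose in-range run.

    A visit with a missing INR disqualifies any window containing it (the
    in-range condition cannot be verified) without disqualifying the patient:
    a later complete run may still qualify.
    """
    visits = list(visits)
    if not visits:
        raise ValueError("need at least one visit")

    def ok(v: Visit) -> bool:
        return v.inr is not None and target.contains(v.inr)

    for start in range(len(visits) - MIN_STABLE_RUN + 1):
        run = visits[start:start + MIN_STABLE_RUN]
        if len({v.weekly_dose for v in run}) == 1 and all(ok(v) for v in run):
            return StableDoseResult(patient_id, True, run[0].weekly_dose,
                                    tuple(v.index for v in run))
    return StableDoseResult(patient_id, False)


def dose_group_vs_predicted(actual: float, predicted: float, tolerance: float = 0.20) -> str:
    """Classify the given dose as higher / same / lower than the calculated dose.

    "Same" means a relative difference (against the predicted dose) below
    ``tolerance``; otherwise the sign of actual - predicted decides.
    """
    if actual <= 0 or predicted <= 0:
        raise ValueError("doses must be > 0")
    if abs(actual - predicted) / predicted < tolerance:
        return "same"
    return "higher" if actual > predicted else "lower"


def bleeding_contingency(cohort: list[PatientRecord], predictions: dict[str, float],
                         actual_doses: dict[str, float] | None = None,
                         tolerance: float = 0.20) -> DoseGroupTable:
    """Cross-tabulate worst-ever bleeding (none vs any) against dose group.

    ``predictions`` maps patient id to the model-calculated weekly dose.  The
    given therapeutic dose defaults to the patient's last recorded visit dose;
    pass ``actual_doses`` to override (e.g. with stable doses).  Bleeding
    "yes" means at least one minor or major event.
    """
    cols = ("higher", "same", "lower")
    counts = {"none": [0, 0, 0], "yes": [0, 0, 0]}
    for p in cohort:
        if p.id not in predictions:
            raise KeyError(f"no prediction for patient {p.id}")
        if actual_doses is not None:
            actual = actual_doses[p.id]
        else:
            if not p.visits:
                raise ValueError(f"patient {p.id} has no visits and no explicit actual dose")
            actual = p.visits[-1].weekly_dose
        group = dose_group_vs_predicted(actual, predictions[p.id], tolerance)
        row = "none" if p.bleeding == "none" else "yes"
        counts[row][cols.index(group)] += 1
    return DoseGroupTable(tuple(counts["none"]), tuple(counts["yes"]))
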