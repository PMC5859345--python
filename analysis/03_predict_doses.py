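"""Predict weekly warfarin doses for the simulated cohort with all three models.

Writes a long-format CSV (patient, model, predicted mg/week) and prints the
per-model mean predicted dose next to the mean empirically stable dose.
"""

import csv
import statistics
from pathlib import Path

from warfarin_pgx.cohort import read_cohort
from warfarin_pgx.dosing import predict_all_models
from warfarin_pgx.stability import find_stable_dose

RESULTS = Path(__file__).resolve().parent.parent / "results"
fixtures = RESULTS / "synthetic_cohort"

cohort = read_cohort(fixtures / "patients.csv", fixtures / "visits.csv")
out = RESULTS / "dose_predictions.csv"
by_model = {"pgx": [], "clinical": [], "fixed": []}
with open(out, "w", newline="") as fh:
    writer = csv.writer(fh)
    writer.writerow(["patient_id", "model", "weekly_dose"])
    for p in cohort:
        for model, dose in predict_all_models(p).items():
            by_model[model].append(dose)
            writer.writerow([p.id, model, f"{dose:.2f}"])

wsds = [find_stable_dose(p.visits, p.target_inr, p.id).wsd for p in cohort]
wsds = [w for w in wsds if w is not None]
print(f"empirical stable dose: mean {statistics.mean(wsds):.1f} mg/week (n={len(wsds)})")
for model, doses in by_model.items():
    print(f"{model:9s} mean predicted {statistics.mean(doses):.1f} mg/week")
print(f"predictions -> {out}")
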