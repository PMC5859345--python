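"""Full retrospective evaluation of the three dosing models on the simulated cohort.

Runs the end-to-end pipeline (stable-dose filter, MAE, regression, +/-20%
classification, event rates and NNG, bleeding contingency, genotype-group
comparisons) and writes the JSON report plus a compact model-comparison CSV.
"""

import csv
import json
from pathlib import Path

from warfarin_pgx.cohort import read_cohort
from warfarin_pgx.pipeline import MODELS, evaluate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
fixtures = RESULTS / "synthetic_cohort"

cohort = read_cohort(fixtures / "patients.csv", fixtures / "visits.csv")
report = evaluate_cohort(cohort)
(RESULTS / "evaluation_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

print(f"n={report['n']}  stable-dose patients: {report['stable']['n_stable']}")
rows = []
for model in MODELS:
    perf = report["performance"][model]
    cls = perf["classification"]
    reg = perf.get("regression", {})
    rows.append({
        "model": model,
        "mae": f"{perf['mae']:.1f}", "mae_se": f"{perf['mae_se']:.1f}",
        "r2": f"{reg['r_squared']:.3f}" if reg else "n/a",
        "ideal_pct": f"{100 * cls['ideal'] / cls['total']:.1f}",
        "event_rate": f"{perf['event_rate']:.3f}",
    })
    print(f"{model:9s} MAE {rows[-1]['mae']} +/- {rows[-1]['mae_se']}  "
          f"R2 {rows[-1]['r2']}  ideal {rows[-1]['ideal_pct']}%  "
          f"ER {rows[-1]['event_rate']}")
for pair, res in report["nng"].items():
    print(f"NNG {pair}: {res['nng']:.1f}  (ARR {res['arr']:.3f})")
if "chi_square" in report.get("bleeding", {}):
    b = report["bleeding"]
    print(f"bleeding vs dose group: chi2 {b['chi_square']:.3f}  p {b['p_value']:.3f}")

out = RESULTS / "model_comparison.csv"
with open(out, "w", newline="") as fh:
    writer = csv.DictWriter(fh, fieldnames=rows[0].keys())
    writer.writeheader()
    writer.writerows(rows)
print(f"report -> {RESULTS / 'evaluation_report.json'}; comparison table -> {out}")
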