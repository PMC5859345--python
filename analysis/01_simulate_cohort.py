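"""Generate the synthetic study cohort and its descriptive summary.

Writes the patients/visits/RFLP-fragment CSVs for a seeded 101-patient
cohort emulating the study population, plus a descriptive-characteristics
table (the Table-1 analogue) as JSON.
"""

import json
from dataclasses import asdict
from pathlib import Path

from warfarin_pgx.cohort import read_cohort, summarize_cohort
from warfarin_pgx.synthetic import SimulationParams, generate_fixture_files

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1

params = SimulationParams(n=101, seed=SEED)
paths = generate_fixture_files(params, RESULTS / "synthetic_cohort")
cohort = read_cohort(paths["patients"], paths["visits"])
summary = summarize_cohort(cohort)

out = RESULTS / "cohort_summary.json"
out.write_text(json.dumps(asdict(summary), indent=2))

print(f"wrote {', '.join(str(p) for p in paths.values())}")
print(f"n={summary.n}  age {summary.mean_age:.1f} +/- {summary.sd_age:.1f} y  "
      f"BMI {summary.mean_bmi:.1f} +/- {summary.sd_bmi:.1f} kg/m^2  "
      f"male {summary.percent_sex['male']:.1f}%")
print(f"descriptive summary -> {out}")
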