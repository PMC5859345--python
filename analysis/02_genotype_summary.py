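"""Call genotypes from the simulated RFLP fragment file and summarize them.

Decodes every patient's fragment patterns back to CYP2C9/VKORC1 genotypes,
checks them against the cohort file, and writes genotype/allele frequencies
with Hardy-Weinberg tests for both the synthetic cohort and the published
study counts.
"""

import csv
import json
from pathlib import Path

from warfarin_pgx import published
from warfarin_pgx.cohort import read_cohort
from warfarin_pgx.genotyping import (
    allele_frequencies,
    count_genotypes,
    genotype_frequencies,
    genotypes_from_fragments,
    hwe_chi_square,
    read_fragment_observations,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
fixtures = RESULTS / "synthetic_cohort"

cohort = read_cohort(fixtures / "patients.csv", fixtures / "visits.csv")
observations = read_fragment_observations(fixtures / "fragments.csv")
mismatches = 0
for p in cohort:
    called = genotypes_from_fragments(observations[p.id])
    mismatches += called != (p.cyp2c9, p.vkorc1)
print(f"RFLP decoding: {len(cohort)} patients, {mismatches} genotype mismatches")

rows = []
for label, cohort_counts, study_counts in (
        ("cyp2c9_star2", count_genotypes(cohort, "cyp2c9"), published.CYP2C9_COUNTS),
        ("vkorc1_1639", count_genotypes(cohort, "vkorc1"), published.VKORC1_COUNTS)):
    for source, counts in (("synthetic", cohort_counts), ("published", study_counts)):
        hwe = hwe_chi_square(counts)
        rows.append({
            "locus": label, "source": source,
            "counts": "/".join(map(str, counts.as_tuple())),
            "genotype_pct": "/".join(f"{100*f:.1f}" for f in genotype_frequencies(counts)),
            "variant_allele_pct": f"{100*allele_frequencies(counts)[1]:.1f}",
            "hwe_chi2": f"{hwe.chi_square:.3f}", "hwe_p": f"{hwe.p_value:.3f}",
        })
        print(f"{label:13s} {source:9s} counts={rows[-1]['counts']:10s} "
              f"variant allele {rows[-1]['variant_allele_pct']}%  HWE p={rows[-1]['hwe_p']}")

out = RESULTS / "genotype_summary.csv"
with open(out, "w", newline="") as fh:
    writer = csv.DictWriter(fh, fieldnames=rows[0].keys())
    writer.writeheader()
    writer.writerows(rows)
print(f"genotype summary -> {out}")
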