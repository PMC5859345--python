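"""Recompute the study's desk-scale statistics from its published summary tables.

Everything here needs only the printed counts and group summaries: the
bleeding-by-dose-group chi-square, the event-rate/ARR/NNG chain, the ideal
percentages, genotype and allele frequencies with Hardy-Weinberg tests, and
the genotype-group stable-dose comparisons.
"""

import json
from pathlib import Path

from warfarin_pgx import published
from warfarin_pgx.evaluation import (
    event_rate,
    group_dose_comparison,
    number_needed_to_genotype,
    pearson_chi_square,
)
from warfarin_pgx.genotyping import allele_frequencies, hwe_chi_square

RESULTS = Path(__file__).resolve().parent.parent / "results"

stat, df, p = pearson_chi_square(published.BLEEDING_TABLE.as_matrix())
print(f"bleeding vs dose group: chi2 {stat:.3f} (df {df}), p {p:.3f}")

er = {m: event_rate(t) for m, t in published.CLASSIFICATION.items()}
nng = {other: number_needed_to_genotype(er["pgx"], er[other])
       for other in ("clinical", "fixed")}
for model, rate in er.items():
    ideal = published.CLASSIFICATION[model]
    print(f"{model:9s} ideal {100 * ideal.ideal / ideal.total:.1f}%  ER {rate:.3f}")
for other, res in nng.items():
    print(f"NNG pgx vs {other}: {res.nng:.1f}  (ARR {res.arr:.3f})")

for label, counts in (("CYP2C9 *2", published.CYP2C9_COUNTS),
                      ("VKORC1 -1639A", published.VKORC1_COUNTS)):
    hwe = hwe_chi_square(counts)
    print(f"{label}: variant allele {100 * allele_frequencies(counts)[1]:.1f}% "
          f"(by direct count), HWE chi2 {hwe.chi_square:.3f}, p {hwe.p_value:.3f}")

f_stat, p_anova = group_dose_comparison(list(published.WSD_BY_VKORC1.values()),
                                        from_summaries=True)
t_stat, p_t = group_dose_comparison(list(published.WSD_BY_CYP2C9.values()),
                                    from_summaries=True)
print(f"WSD by VKORC1 (ANOVA): F {f_stat:.2f}, p {p_anova:.3f}")
print(f"WSD by CYP2C9 (pooled t): t {t_stat:.2f}, p {p_t:.3f}")

out = RESULTS / "published_reanalysis.json"
out.parent.mkdir(exist_ok=True)
out.write_text(json.dumps({
    "bleeding_chi_square": {"statistic": stat, "df": df, "p": p},
    "event_rates": er,
    "nng": {k: v.nng for k, v in nng.items()},
    "anova_vkorc1": {"F": f_stat, "p": p_anova},
    "ttest_cyp2c9": {"t": t_stat, "p": p_t},
}, indent=2))
print(f"-> {out}")
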