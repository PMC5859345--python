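"""Published summary tables of the motivating Gaza-strip warfarin cohort.

The retrospective study this package evaluates reported only summary
tables, not patient-level data.  The counts and group summaries below are
those printed tables, kept here as reference inputs: the desk-scale
statistics (genotype/allele frequencies, Hardy-Weinberg tests, the
bleeding-by-dose-group chi-square, classification percentages, event rates
and NNG, genotype-group dose comparisons) are all recomputable from them
with this package's evaluation functions.
"""

from warfarin_pgx.evaluation import ClassificationTable
from warfarin_pgx.genotyping import GenotypeCounts
from warfarin_pgx.stability import DoseGroupTable

N_GENOTYPED = 101   # patients genotyped
N_STABLE = 47       # patients who reached a stable dose

#: genotype counts among the 101 genotyped patients (no *3 allele observed)
CYP2C9_COUNTS = GenotypeCounts("CYP2C9_star2", hom_ref=75, het=25, hom_var=1)
VKORC1_COUNTS = GenotypeCounts("VKORC1_1639", hom_ref=30, het=49, hom_var=22)

#: bleeding (none / at least one event) by given-dose group (higher/same/lower
#: than the pharmacogenetic-model calculation); 99 patients with complete data
BLEEDING_TABLE = DoseGroupTable(none=(19, 25, 11), bleed=(23, 19, 2))

#: +/-20% classification of each model's predictions among the 47 stable-dose patients
CLASSIFICATION = {
    "pgx": ClassificationTable("pgx", ideal=32, underestimation=12, overestimation=3),
    "clinical": ClassificationTable("clinical", ideal=25, underestimation=12, overestimation=10),
    "fixed": ClassificationTable("fixed", ideal=21, underestimation=15, overestimation=11),
}

#: stable-dose (n, mean, sd) in mg/week by genotype group
WSD_BY_CYP2C9 = {"*1/*1": (34, 42.6, 13.8), "*1/*2": (13, 39.4, 17.5)}
WSD_BY_VKORC1 = {"GG": (15, 51.2, 15.9), "GA": (23, 39.1, 13.0), "AA": (9, 32.5, 8.8)}
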