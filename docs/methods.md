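# Methods

## Setting and models

The package evaluates three strategies for choosing a patient's weekly
warfarin dose against the dose the patient empirically stabilized on:

1. **Pharmacogenetic (PGx)** — the IWPC equation, linear on the square root
   of the weekly dose (mg/week): an intercept plus terms for age (in
   decades, entered continuously as age/10, not floored — the choice changes
   predictions by under 2%), height (cm), weight (kg), VKORC1 −1639G>A
   genotype (GA, AA, unknown), CYP2C9 diplotype (*1/*2 … *3/*3, unknown),
   race indicators, enzyme-inducer co-medication and amiodarone. The
   predicted dose is the square of the linear predictor; a negative linear
   predictor (possible only with pathological user-supplied coefficients) is
   clamped to dose 0 with a warning rather than squared into a spurious
   positive dose.
2. **Clinical** — the same equation with every genotype term removed.
3. **Fixed** — 35 mg/week, i.e. the customary 5 mg/day starting practice.

Coefficients live in a versioned JSON file
(`src/warfarin_pgx/data/iwpc_coefficients.json`) so a user can substitute a
different published set without touching code. The study population this
package emulates maps to the equations' reference race category, so all race
indicators default to 0.

INR is computed from prothrombin time as (PT_patient/PT_normal)^ISI with
defaults PT_normal = 15.0 s and ISI = 1.03 (the reagent used in the
motivating clinic).

## Genotyping

Genotypes come from restriction-digest fragment patterns:

| assay | amplicon | enzyme cuts | cut fragments |
|---|---|---|---|
| CYP2C9 *2 (AvaII) | 454 bp | wild-type *1 | 397 + 57 bp |
| CYP2C9 *3 (KpnI) | 105 bp | variant *3 | 85 + 20 bp |
| VKORC1 −1639 (MspI) | 290 bp | wild-type G | 167 + 123 bp |

Cut-only patterns call the homozygote of the cut allele, uncut-only the
other homozygote, both together the heterozygote. Fragments under 60 bp
(the 57 and 20 bp products) routinely run off 2.5–3.5% agarose gels, so an
observation missing only sub-60 bp fragments still calls when the remaining
pattern is unambiguous; anything else is a no-call with a diagnostic, never
a guess.

Hardy–Weinberg equilibrium is tested with a Pearson chi-square against
expected counts n·(p², 2pq, q²) from the observed allele frequencies, one
degree of freedom, no continuity correction. Allele frequencies are direct
allele counts over 2n; a monomorphic locus is returned flagged (statistic 0,
p 1) rather than raising.

## Stable dose and evaluation statistics

A patient's warfarin stable dose (WSD) is the dose of the earliest run of at
least three consecutive visits sharing one weekly dose with every INR in the
run inside the patient's target range (bounds inclusive; the stricter
all-visits reading of the in-range condition is used). A visit with a
missing INR disqualifies windows containing it, not the patient.

Model performance is computed on the stable-dose subset:

- **MAE ± SE** — mean |prediction − WSD|; the SE is the sample SD of the
  absolute errors over √n (the convention adopted here for "MAE ± SE").
- **Regression** — OLS of the WSD on the prediction (this direction matches
  how such studies plot stable against predicted dose); F is the slope test
  on (1, n−2) df, which for simple regression equals t². A constant
  predictor (the fixed-dose model) is flagged degenerate, not regressed.
- **±20% classification** — ideal if |prediction − WSD|/WSD < 0.20; a
  relative deviation of exactly 20% counts as over/underestimation ("at
  least 20%"), resolving the boundary the two verbal definitions share.
- **ER / ARR / NNG** — event rate (under + over)/total; ARR is the absolute
  difference of two models' event rates; NNG = 1/ARR, reported as infinite
  with an explicit flag when the rates tie.
- **Bleeding contingency** — patients cross-tabulated as bleeding
  (none vs ≥1 event) against given dose higher/same/lower than the
  PGx-calculated dose. The "same" band is a relative difference below 20%
  of the predicted dose — the same clinically-motivated threshold as the
  classification, reused because no separate definition exists. Note the
  documented asymmetry: grouping divides by the predicted dose,
  classification by the achieved dose.
- **Genotype-group comparisons** — pooled-variance two-sample t-test for two
  groups, one-way ANOVA for three or more. Both accept (n, mean, sd)
  summaries, since both statistics depend on the data only through those;
  this lets published group tables be re-tested without patient-level data.

p-values are never compared as strings anywhere; tests use numeric
tolerances.

## Synthetic cohort generator

The generator produces cohorts with the statistical shape of the motivating
study population and a planted, exactly recoverable ground truth:

- n = 101; age ~ Normal(48.8, 14.4) truncated to [16, 76]; 42.4% male;
  BMI ~ Normal(27.8, 5.2) truncated to [16, 45] with height ~ Normal(165, 9)
  cm truncated to [140, 195] and weight = BMI·(height/100)² — height and
  weight marginals were not reported, so they are chosen to reproduce the
  reported BMI distribution at plausible adult statures.
- Genotype class probabilities (0.743, 0.248, 0.010) for CYP2C9 *2 and
  (0.297, 0.485, 0.218) for VKORC1, drawn independently per locus (no
  linkage was reported; the observed joint distribution serves as a
  validation reference, not a constraint).
- True stable dose = (PGx linear predictor + Normal(0, σ))², floored at
  7 mg/week (1 mg/day). Noise on the √dose scale matches the model's own
  scale, which makes zero-noise recovery exact — a clean acceptance surface.
  The default σ = 0.85 reproduces the magnitude of prediction error the
  study reported (MAE near 9 mg/week at a mean dose around 40 mg/week).
- Visit history: 0–3 titration visits at ±15–40% of the stable dose with
  out-of-range INR, then 3 terminal visits at the stable dose with INR drawn
  Normal(range midpoint, 0.25) clipped just inside the range — so the
  stable-dose scanner recovers the planted dose for every patient.
- Bleeding ~ Bernoulli(expit(−0.35 + 1.5·x)) where x is the relative excess
  of the achieved over the calculated dose. The logistic form is a modelling
  choice (the motivating data assert only an association); the defaults give
  an overall bleeding rate near the observed 45% and a rising rate across
  the lower/same/higher dose groups. A bleed is major with probability
  0.154, matching the observed major:any ratio.
- Co-medication rates (amiodarone 5%, enzyme inducers 2%) and the 3%
  mechanical-valve fraction (target INR 2.5–3.5 instead of 2.0–3.0) are
  realistic clinic values; none was reported by the study.

All randomness flows from one integer seed through `numpy.random.default_rng`;
the same seed yields byte-identical fixture files.

**What passing tests on synthetic data do and do not show.** The generator's
dose process is the PGx model plus noise, so the PGx model is correct by
construction; evaluation on synthetic cohorts demonstrates that the pipeline
*measures* model quality correctly (zero-noise ⇒ MAE 0, R² 1; genotype
effects active ⇒ the clinical model's R² falls short), not that the IWPC
equation is correct for any real population. Real cohorts differ in ways the
generator does not emulate: dose-titration dynamics and INR feedback,
non-independence of loci, measurement rounding of prescribed doses,
informative missingness, and patients who never stabilize.

## Numerical conventions and degenerate inputs

- Chi-square contingency tests require every margin-derived expected count
  positive; violations raise rather than return NaN.
- The ±20% boundary is assigned away from "ideal"/"same" (strict inequality
  for the inner band) in both the classification and the dose grouping.
- Monomorphic loci, constant predictors, equal event rates and empty
  stable-dose subsets all return explicitly flagged results instead of
  raising mid-pipeline; the CLI exits nonzero when the evaluation section is
  empty.
- The published allele percentages for the motivating cohort (13.6%, 46.5%)
  differ slightly from the direct allele counts over 2·101 (13.4%, 46.0%);
  the package always reports count-derived frequencies.
- Analysis problem sizes: the cohort scripts use n = 101 (the study size);
  the Monte-Carlo comparison of R² uses 200 cohorts of n = 47, the study's
  stable-dose subset size, which is ample to separate the models (the PGx
  model's R² exceeds the clinical model's in ~99% of cohorts with a mean
  gain near 0.3).

## Known limitations

- The IWPC equations are transcribed for the shipped default; users dosing
  other populations should review the race terms and consider re-fitting.
- The stable-dose rule is the ≥3-consecutive-visits convention; it does not
  implement time-in-therapeutic-range or survival-style bleeding analyses.
- The bleeding model is deliberately minimal (single logistic slope on
  relative dose excess) and should not be used for risk prediction.
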