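"""Model-performance statistics for dose-prediction evaluation.

Covers the full comparison battery: mean absolute error with its standard
error, ordinary least-squares regression of the achieved stable dose on the
prediction, the +/-20% ideal/under/over classification, event rates with the
absolute risk reduction and number needed to genotype (NNG), Pearson
chi-square contingency tests, and genotype-group dose comparisons (pooled
t-test / one-way ANOVA) computable from raw values or published
(n, mean, sd) summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

IDEAL, UNDER, OVER = "ideal", "underestimation", "overestimation"


@dataclass(frozen=True)
class PerformanceSummary:
    model: str
    mae: float      # mg/week
    mae_se: float   # mg/week
    n: int


@dataclass(frozen=True)
class RegressionSummary:
    r: float
    r_squared: float
    f_statistic: float
    p_value: float
    slope: float
    intercept: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class ClassificationTable:
    model: str
    ideal: int
    underestimation: int
    overestimation: int

    @property
    def total(self) -> int:
        return self.ideal + self.underestimation + self.overestimation


@dataclass(frozen=True)
class NNGResult:
    er_a: float
    er_b: float
    arr: float
    nng: float          # math.inf when arr == 0
    undefined: bool     # True iff arr == 0


def classify_dose(predicted: float, actual_wsd: float, tolerance: float = 0.20) -> str:
    """Ideal / underestimation / overestimation of a prediction against the WSD.

    Relative deviation is measured against the actual stable dose; a
    deviation of exactly ``tolerance`` counts as over/under ("at least 20%"),
    strict inequality is required for ideal.
    """
    if actual_wsd <= 0:
        raise ValueError("actual_wsd must be > 0")
    rel = (predicted - actual_wsd) / actual_wsd
    if abs(rel) < tolerance:
        return IDEAL
    return OVER if rel > 0 else UNDER


def mean_absolute_error(predictions, actuals, model: str = "") -> PerformanceSummary:
    """MAE = mean |prediction - actual|; SE = sample SD of the absolute errors / sqrt(n)."""
    pred = np.asarray(predictions, dtype=float)
    act = np.asarray(actuals, dtype=float)
    if pred.shape != act.shape or pred.size == 0:
        raise ValueError("predictions and actuals must be equal-length and nonempty")
    abs_err = np.abs(pred - act)
    n = abs_err.size
    se = float(abs_err.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return PerformanceSummary(model, float(abs_err.mean()), se, n)


def regress_wsd_on_prediction(predictions, actuals) -> RegressionSummary:
    """OLS of the achieved stable dose on the predicted dose.

    The F statistic tests the slope against zero on (1, n-2) degrees of
    freedom; for simple regression this is t^2 and the p-values coincide.  A
    constant predictor has no defined slope and returns a degenerate-flagged
    result.
    """
    pred = np.asarray(predictions, dtype=float)
    act = np.asarray(actuals, dtype=float)
    if pred.size != act.size or pred.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(pred) == 0:
        return RegressionSummary(float("nan"), float("nan"), float("nan"), float("nan"),
                                 float("nan"), float("nan"), int(pred.size), degenerate=True)
    fit = stats.linregress(pred, act)
    n = int(pred.size)
    # for simple regression F(1, n-2) = t^2 of the slope
    t = fit.slope / fit.stderr if fit.stderr > 0 else float("inf")
    f_stat = float(t * t)
    p = float(stats.f.sf(f_stat, 1, n - 2))
    return RegressionSummary(float(fit.rvalue), float(fit.rvalue ** 2), f_stat, p,
                             float(fit.slope), float(fit.intercept), n)


def classification_table(predictions, actuals, tolerance: float = 0.20,
                         model: str = "") -> ClassificationTable:
    """Tally per-patient :func:`classify_dose` outcomes into the three classes."""
    pred = np.asarray(predictions, dtype=float)
    act = np.asarray(actuals, dtype=float)
    if pred.shape != act.shape:
        raise ValueError("predictions and actuals must be equal-length")
    tallies = {IDEAL: 0, UNDER: 0, OVER: 0}
    for p, a in zip(pred, act):
        tallies[classify_dose(p, a, tolerance)] += 1
    return ClassificationTable(model, tallies[IDEAL], tallies[UNDER], tallies[OVER])


def event_rate(table: ClassificationTable) -> float:
    """Probability of a bad event: (underestimation + overestimation) / total."""
    if table.total == 0:
        raise ValueError("empty classification table")
    return (table.underestimation + table.overestimation) / table.total


def number_needed_to_genotype(er_pgx: float, er_other: float) -> NNGResult:
    """ARR = |ER_pgx - ER_other|; NNG = 1/ARR (infinite, flagged, when ARR is 0)."""
    for er in (er_pgx, er_other):
        if not 0.0 <= er <= 1.0:
            raise ValueError(f"event rate {er} outside [0, 1]")
    arr = abs(er_pgx - er_other)
    if arr == 0.0:
        return NNGResult(er_pgx, er_other, 0.0, math.inf, undefined=True)
    return NNGResult(er_pgx, er_other, arr, 1.0 / arr, undefined=False)


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a counts matrix.

    Expected counts from row/column margins; df = (rows-1)(cols-1); no
    continuity correction.  Requires every expected count > 0.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c matrix with r, c >= 2")
    expected = stats.contingency.expected_freq(obs)
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be > 0")
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def group_dose_comparison(groups, from_summaries: bool = False) -> tuple[float, float]:
    """Compare group mean doses: pooled t-test (2 groups) or one-way ANOVA (>=3).

    With ``from_summaries=False`` each group is a sequence of raw dose
    values; with ``from_summaries=True`` each group is a ``(n, mean, sd)``
    triple, so published group summaries can be tested without patient-level
    data (both statistics depend on the data only through these).  Returns
    (statistic, p_value): the t statistic for two groups, F otherwise.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    summaries = []
    for g in groups:
        if from_summaries:
            n, mean, sd = g
            if int(n) != n or n < 2:
                raise ValueError("summary n must be an integer >= 2")
            summaries.append((int(n), float(mean), float(sd)))
        else:
            arr = np.asarray(g, dtype=float)
            if arr.size < 2:
                raise ValueError("each group needs n >= 2")
            summaries.append((int(arr.size), float(arr.mean()), float(arr.std(ddof=1))))

    ns = np.array([s[0] for s in summaries], dtype=float)
    means = np.array([s[1] for s in summaries], dtype=float)
    sds = np.array([s[2] for s in summaries], dtype=float)

    if len(summaries) == 2:
        (n1, m1, s1), (n2, m2, s2) = summaries
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
        t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2.0 * float(stats.t.sf(abs(t), df))
        return float(t), p

    n_total = ns.sum()
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds ** 2).sum())
    df_between = len(summaries) - 1
    df_within = int(n_total) - len(summaries)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p
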