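"""End-to-end retrospective evaluation: cohort in, report dict out.

Mirrors the study workflow: genotype summaries and Hardy-Weinberg tests,
per-patient predictions from the three models, empirical stable-dose
determination, model-performance statistics restricted to the stable-dose
subset, the number-needed-to-genotype chain, the bleeding-by-dose-group
contingency analysis, and genotype-group stable-dose comparisons.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Any

import numpy as np

from warfarin_pgx import evaluation, genotyping, stability
from warfarin_pgx.cohort import PatientRecord
from warfarin_pgx.dosing import ClinicalCoefficients, PgxCoefficients, predict_all_models

MODELS = ("pgx", "clinical", "fixed")


def evaluate_cohort(cohort: list[PatientRecord],
                    tolerance: float = 0.20,
                    pgx_coeffs: PgxCoefficients | None = None,
                    clinical_coeffs: ClinicalCoefficients | None = None) -> dict[str, Any]:
    """Run the full evaluation pipeline and return a JSON-serializable report."""
    if not cohort:
        raise ValueError("empty cohort")

    report: dict[str, Any] = {"n": len(cohort), "tolerance": tolerance}

    # genotype summaries + HWE
    geno: dict[str, Any] = {}
    for locus in ("cyp2c9", "vkorc1"):
        counts = genotyping.count_genotypes(cohort, locus)
        if counts.total == 0:
            geno[locus] = {"counts": counts.as_tuple(), "note": "no called genotypes"}
            continue
        hwe = genotyping.hwe_chi_square(counts)
        geno[locus] = {
            "counts": counts.as_tuple(),
            "genotype_frequencies": genotyping.genotype_frequencies(counts),
            "allele_frequencies": genotyping.allele_frequencies(counts),
            "hwe": {"chi_square": hwe.chi_square, "df": hwe.df, "p_value": hwe.p_value,
                    "monomorphic": hwe.monomorphic},
        }
    report["genotyping"] = geno

    # predictions
    predictions = {p.id: predict_all_models(p, pgx_coeffs, clinical_coeffs) for p in cohort}
    report["predictions"] = predictions

    # stable-dose determination
    stable = {p.id: stability.find_stable_dose(p.visits, p.target_inr, p.id)
              for p in cohort if p.visits}
    stable_ids = [pid for pid, s in stable.items() if s.is_stable]
    report["stable"] = {
        "n_assessed": len(stable),
        "n_stable": len(stable_ids),
        "wsd": {pid: stable[pid].wsd for pid in stable_ids},
    }

    # model performance on the stable-dose subset
    perf: dict[str, Any] = {}
    actuals = np.array([stable[pid].wsd for pid in stable_ids])
    for model in MODELS:
        preds = np.array([predictions[pid][model] for pid in stable_ids])
        if actuals.size == 0:
            perf[model] = {"empty": True}
            continue
        mae = evaluation.mean_absolute_error(preds, actuals, model)
        table = evaluation.classification_table(preds, actuals, tolerance, model)
        entry = {
            "mae": mae.mae, "mae_se": mae.mae_se, "n": mae.n,
            "classification": {"ideal": table.ideal,
                               "underestimation": table.underestimation,
                               "overestimation": table.overestimation,
                               "total": table.total},
            "event_rate": evaluation.event_rate(table),
        }
        if model != "fixed" and actuals.size >= 3 and np.ptp(preds) > 0:
            reg = evaluation.regress_wsd_on_prediction(preds, actuals)
            entry["regression"] = dataclasses.asdict(reg)
        perf[model] = entry
    report["performance"] = perf
    report["evaluation_empty"] = actuals.size == 0

    # number needed to genotype, PGx vs each comparator
    if actuals.size:
        nng = {}
        for other in ("clinical", "fixed"):
            res = evaluation.number_needed_to_genotype(perf["pgx"]["event_rate"],
                                                       perf[other]["event_rate"])
            nng[f"pgx_vs_{other}"] = {
                "er_pgx": res.er_a, "er_other": res.er_b, "arr": res.arr,
                "nng": res.nng if math.isfinite(res.nng) else None,
                "undefined": res.undefined,
            }
        report["nng"] = nng

    # bleeding vs dose group (given dose = last visit dose, vs PGx calculation)
    with_visits = [p for p in cohort if p.visits]
    if with_visits:
        table = stability.bleeding_contingency(
            with_visits, {p.id: predictions[p.id]["pgx"] for p in with_visits},
            tolerance=tolerance)
        entry: dict[str, Any] = {"table": table.as_matrix()}
        matrix = np.asarray(table.as_matrix())
        if (matrix.sum(axis=0) > 0).all() and (matrix.sum(axis=1) > 0).all():
            chi2, df, p = evaluation.pearson_chi_square(matrix)
            entry.update({"chi_square": chi2, "df": df, "p_value": p})
        report["bleeding"] = entry

    # genotype-group WSD comparisons on the stable subset
    comparisons: dict[str, Any] = {}
    wsd_by = {pid: stable[pid].wsd for pid in stable_ids}
    by_cyp = _group_values(cohort, wsd_by, "cyp2c9", ("*1/*1", "*1/*2"))
    if all(len(v) >= 2 for v in by_cyp):
        t, p = evaluation.group_dose_comparison(by_cyp)
        comparisons["cyp2c9_11_vs_12"] = {"statistic": t, "p_value": p}
    by_vko = _group_values(cohort, wsd_by, "vkorc1", ("GG", "GA", "AA"))
    if all(len(v) >= 2 for v in by_vko):
        f, p = evaluation.group_dose_comparison(by_vko)
        comparisons["vkorc1_anova"] = {"statistic": f, "p_value": p}
    report["group_comparisons"] = comparisons
    return report


def _group_values(cohort, wsd_by_id, locus, classes):
    groups = []
    for cls in classes:
        groups.append([wsd_by_id[p.id] for p in cohort
                       if p.id in wsd_by_id and getattr(p, locus) == cls])
    return groups
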