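"""End-to-end assembly: phenotype a cohort, derive per-patient metrics,
score, and run the cohort statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import AnalysisConfig, Cohort, Region
from .phenotype import PhenotypeRuleSet, assign_cohort
from .score import score_cohort
from .spatial import patient_nna, region_density, subset_fraction
from .stats import (cox_multivariate_backward, cox_univariate,
                    scenario_analysis, subgroup_forest, table_one)

__all__ = ["patient_table", "analyze_cohort", "FOREST_STRATIFIERS"]

#: Stratifier columns for the subgroup forest (densities, fractions, NNA).
FOREST_STRATIFIERS = [
    "density_cd4_ims", "density_cd20_ims",
    "treg_fraction", "th1_fraction", "tfh_fraction",
    "dist_cd20_to_treg", "dist_cd20_to_th1", "dist_cd20_to_tfh",
    "cd20_within_treg", "cd20_within_th1", "cd20_within_tfh",
]


def patient_table(cohort: Cohort, assign: bool = True) -> pd.DataFrame:
    """Per-patient metrics table: score components and labels, TLS count,
    IM-S densities, CD4-subset fractions, nearest-neighbor metrics, and the
    clinical columns. NaN marks metrics undefined for a patient."""
    config = cohort.config
    if assign:
        assign_cohort(cohort, PhenotypeRuleSet(
            ambiguity_policy=config.ambiguity_policy))
    scores, medians = score_cohort(cohort)
    rows = {}
    r = config.neighbor_radius
    for p in cohort:
        row: dict[str, object] = {
            "age": p.age, "sex": p.sex, "pT": p.pT, "pN": p.pN,
            "pStage": p.pStage, "grade": p.grade, "lvi": p.lvi,
            "os_months": p.os_months, "os_event": p.os_event,
            "density_cd4_ims": region_density(p, "CD4 T cell", Region.IM_S),
            "density_cd20_ims": region_density(p, "CD20 B cell", Region.IM_S),
            "density_cd21_ims": region_density(p, "fDC", Region.IM_S),
        }
        for subset in ("Treg", "Th1", "Tfh"):
            row[f"{subset.lower()}_fraction"] = subset_fraction(
                p, subset, Region.IM_S, mode=config.fraction_mode)
            row[f"dist_cd20_to_{subset.lower()}"] = patient_nna(
                p, "CD20 B cell", subset, "nearest_distance").value
            row[f"cd20_within_{subset.lower()}"] = patient_nna(
                p, "CD20 B cell", subset, "count_within_radius",
                radius=r).value
        rows[p.patient_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "patient_id"
    table = scores.join(table)
    table.attrs["score_medians"] = medians
    return table


def analyze_cohort(cohort: Cohort) -> dict:
    """The full statistics layer on a phenotyped, scored cohort.

    Returns the per-patient table, the clinicopathological summary, the
    univariate/multivariate Cox results for the score, the subgroup forest,
    and the three-scenario survival analysis.
    """
    config = cohort.config
    table = patient_table(cohort)
    surv_ok = table["os_months"].notna() & table["os_event"].notna()
    work = table[surv_ok].copy()
    work["os_months"] = work["os_months"].astype(float)
    work["os_event"] = work["os_event"].astype(bool)
    work["score_high"] = (work["cd20_cluster_score"] == "high").astype(float)

    out: dict = {"patient_table": table,
                 "score_medians": table.attrs["score_medians"]}
    clin_cols = ["age", "sex", "pT", "pN", "pStage", "grade", "lvi",
                 "os_months", "os_event"]
    t1, t1_p = table_one(work[clin_cols], work["cd20_cluster_score"], config)
    out["table_one"] = t1
    out["table_one_p"] = t1_p

    if work["os_event"].any() and work["score_high"].nunique() == 2:
        out["cox_score_univariate"] = cox_univariate(work, "score_high")
        candidates = ["score_high", "age"]
        out["cox_backward"] = cox_multivariate_backward(
            work, candidates, config)
        out["forest"] = subgroup_forest(
            work, "cd20_cluster_score",
            [c for c in FOREST_STRATIFIERS if work[c].notna().any()])
    if work["tfh_fraction"].notna().sum() >= 2:
        out["scenarios"] = scenario_analysis(work, config)
    return out
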