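"""The CD20 cluster score and tertiary lymphoid structure (TLS) counting.

The score summarises B-cell clustering in the stroma of the invasive margin
(IM-S). Its two components are within-radius neighbor counts with CD20 B
cells in the IM-S as the source:

* ``cd20_within_cd20`` — mean number of other CD20 B cells within 20 µm of
  each CD20 B cell;
* ``cd20_within_cd4`` — mean number of CD4 T-cell neighbors within 20 µm of
  each CD20 B cell.

Each component is dichotomized at its cohort median (strictly above the
median is "high"; a tie at the median is "low"), and the combined ordinal
score is high only when both components are high. Patients with no CD20 B
cells in the IM-S get components of 0 rather than missing: the absence of
B-cell clustering is informatively low, and this keeps the score defined
cohort-wide.

TLS detection is an automated surrogate for manual counting: lymphocytes
(CD4 T plus CD20 B cells) in each IM field are clustered by single linkage
at a 40 µm link distance, and a cluster qualifies as a TLS when it has at
least 50 members within a convex hull of at most 0.3 mm². The patient's
TLS count is the sum over IM fields; fields are disjoint samples and are
never merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .model import UM2_PER_MM2, AnalysisConfig, Cohort, Field, Patient, Region
from .phenotype import LYMPHOCYTE_LABELS
from .spatial import count_within_radius_field, field_points

__all__ = [
    "ScoreResult",
    "TLSRecord",
    "cluster_score_components",
    "median_dichotomize",
    "combine_components",
    "detect_tls",
    "patient_tls_count",
    "score_cohort",
]


@dataclass
class ScoreResult:
    """Per-patient cluster-score components, labels, and the combined score."""

    patient_id: str
    cd20_within_cd20: float
    cd20_within_cd4: float
    label_ww: str  # high/low for CD20-within-CD20
    label_wc4: str  # high/low for CD20-within-CD4
    combined: str  # high iff both components high
    median_ww: float
    median_wc4: float


@dataclass
class TLSRecord:
    """One qualifying lymphocyte aggregate in an IM field."""

    field_id: str
    n_cells: int
    centroid: tuple[float, float]
    hull_area_mm2: float


def cluster_score_components(patient: Patient,
                             config: AnalysisConfig) -> tuple[float, float]:
    """The two cluster-score components for one patient.

    Each IM field with at least one IM-S CD20 B cell contributes its
    per-cell mean; the patient value is the unweighted mean over those
    fields. A patient without any IM-S CD20 B cell gets (0, 0).

    With ``config.score_direction == "cd4-source"`` the second component is
    transposed: CD4 T cells in the IM-S are the source and their CD20
    neighbors are counted.
    """
    r = config.neighbor_radius
    ww_vals: list[float] = []
    wc4_vals: list[float] = []
    for fld in patient.fields_of("IM"):
        cd20_src = field_points(fld, "CD20 B cell", "stroma")
        cd20_all = field_points(fld, "CD20 B cell")
        cd4_all = field_points(fld, "CD4 T cell")
        ww = count_within_radius_field(cd20_src, cd20_all, r, same_label=True)
        if ww is not None:
            ww_vals.append(ww)
        if config.score_direction == "cd4-source":
            cd4_src = field_points(fld, "CD4 T cell", "stroma")
            wc4 = count_within_radius_field(cd4_src, cd20_all, r)
        else:
            wc4 = count_within_radius_field(cd20_src, cd4_all, r)
        if wc4 is not None:
            wc4_vals.append(wc4)
    ww_patient = float(np.mean(ww_vals)) if ww_vals else 0.0
    wc4_patient = float(np.mean(wc4_vals)) if wc4_vals else 0.0
    return ww_patient, wc4_patient


def median_dichotomize(values: pd.Series) -> tuple[pd.Series, float]:
    """High/low labels at the cohort median (strictly above = high).

    NaNs are excluded from the median and labelled NaN. Requires at least
    two defined values. When all defined values are identical every patient
    is labelled low and a warning is emitted.
    """
    values = pd.Series(values, dtype=float)
    defined = values.dropna()
    if len(defined) < 2:
        raise ValueError("median dichotomization needs >= 2 defined values")
    med = float(defined.median())
    if defined.nunique() == 1:
        warnings.warn("all values identical; every patient labelled 'low'",
                      stacklevel=2)
    labels = pd.Series(
        np.where(values > med, "high", "low"), index=values.index, dtype=object
    )
    labels[values.isna()] = np.nan
    return labels, med


def combine_components(label_ww: str, label_wc4: str) -> str:
    """Combined ordinal score: high only when both components are high."""
    for lab in (label_ww, label_wc4):
        if lab not in ("high", "low"):
            raise ValueError(f"component label must be 'high' or 'low', got {lab!r}")
    return "high" if (label_ww == "high" and label_wc4 == "high") else "low"


def _hull_area_mm2(points: np.ndarray) -> float:
    if len(points) < 3:
        return 0.0
    try:
        hull = ConvexHull(points)
    except QhullError:  # collinear cells
        return 0.0
    return float(hull.volume) / UM2_PER_MM2  # 2-D "volume" is the area in µm²


def detect_tls(field: Field, config: AnalysisConfig) -> list[TLSRecord]:
    """Qualifying lymphocyte clusters in one IM field.

    Single-linkage clusters at ``config.tls_link_distance`` (points whose
    pairwise-link graph is connected), filtered to clusters with at least
    ``config.tls_min_cells`` members and a convex hull of at most
    ``config.tls_area_mm2``. Output order follows cluster centroid x then y,
    so it is invariant to the ordering of cells in the field.
    """
    if field.field_class != "IM":
        raise ValueError("TLS detection runs on IM fields only")
    pts = field_points(field, "lymphocyte")
    n = len(pts)
    if n < config.tls_min_cells:
        return []
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=config.tls_link_distance, output_type="ndarray")
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, comp = connected_components(graph, directed=False)
    records = []
    for label in range(n_comp):
        members = pts[comp == label]
        if len(members) < config.tls_min_cells:
            continue
        area = _hull_area_mm2(members)
        if area > config.tls_area_mm2:
            continue
        cx, cy = members.mean(axis=0)
        records.append(TLSRecord(
            field_id=field.field_id, n_cells=int(len(members)),
            centroid=(float(cx), float(cy)), hull_area_mm2=area,
        ))
    records.sort(key=lambda r: r.centroid)
    return records


def patient_tls_count(patient: Patient, config: AnalysisConfig) -> int:
    """Total number of TLSs over the patient's IM fields (no cross-field merging)."""
    return sum(len(detect_tls(fld, config)) for fld in patient.fields_of("IM"))


def score_cohort(cohort: Cohort) -> tuple[pd.DataFrame, dict[str, float]]:
    """Score every patient of a cohort.

    Returns a per-patient table (components, high/low labels, combined
    score, TLS count) indexed by patient id, plus the two cohort medians
    used for dichotomization.
    """
    config = cohort.config
    comps = {
        p.patient_id: cluster_score_components(p, config) for p in cohort
    }
    ww = pd.Series({k: v[0] for k, v in comps.items()})
    wc4 = pd.Series({k: v[1] for k, v in comps.items()})
    labels_ww, med_ww = median_dichotomize(ww)
    labels_wc4, med_wc4 = median_dichotomize(wc4)
    combined = pd.Series(
        {pid: combine_components(labels_ww[pid], labels_wc4[pid]) for pid in ww.index},
        dtype=object,
    )
    tls = pd.Series({p.patient_id: patient_tls_count(p, config) for p in cohort})
    table = pd.DataFrame({
        "cd20_within_cd20": ww,
        "cd20_within_cd4": wc4,
        "label_ww": labels_ww,
        "label_wc4": labels_wc4,
        "cd20_cluster_score": combined,
        "tls_count": tls,
    })
    table.index.name = "patient_id"
    medians = {"cd20_within_cd20": med_ww, "cd20_within_cd4": med_wc4}
    return table, medians
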