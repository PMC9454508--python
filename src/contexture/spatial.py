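"""Region-stratified densities, subset fractions, and nearest-neighbor metrics.

Two nearest-neighbor (NNA) metrics are provided, both computed on cell
centers with Euclidean distance inside a single field and then averaged
cell -> field -> patient:

* ``nearest_distance`` — for each source cell, the distance (µm) to the
  nearest target cell;
* ``count_within_radius`` — for each source cell, the number of target cells
  at distance <= r (default r = 20 µm).

When source and target labels coincide a cell is never its own neighbor
(self-exclusion), so an isolated cell contributes a count of 0 and the
nearest-distance metric needs at least two cells. Field borders are not
edge-corrected: every field is an independent observation window and the
simulator applies the same windowing, so comparisons are like-for-like.

Patient-level values are unweighted means over the fields where the metric
is defined (a field with no source cells contributes nothing, rather than a
zero). Fast paths use a k-d tree (:class:`scipy.spatial.cKDTree`); the test
suite checks them against an all-pairs brute-force oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import Field, Patient, Region
from .phenotype import B_SUBSETS, CD4_SUBSETS, expand_label

__all__ = [
    "NNAResult",
    "field_points",
    "nn_distance_field",
    "count_within_radius_field",
    "region_density",
    "subset_fraction",
    "patient_nna",
]

#: Subset label -> parent lineage roll-up, for fraction denominators.
PARENT_LINEAGE: dict[str, str] = {
    **{s: "CD4 T cell" for s in CD4_SUBSETS},
    **{s: "CD20 B cell" for s in B_SUBSETS},
}


@dataclass
class NNAResult:
    """A patient-level nearest-neighbor metric with its per-field values."""

    source: str
    target: str
    metric: str  # "nearest_distance" | "count_within_radius"
    radius: float | None
    per_field: dict[str, float]
    value: float | None
    n_fields: int
    n_source_cells: int

    @property
    def defined(self) -> bool:
        return self.value is not None


def field_points(field: Field, label: str,
                 compartment: str | None = None) -> np.ndarray:
    """Coordinates (n, 2) of cells with ``label`` (roll-ups allowed).

    Ambiguous-lineage cells are excluded implicitly: they carry the label
    ``ambiguous`` which no roll-up contains.
    """
    cells = field.cells
    if not len(cells):
        return np.empty((0, 2))
    mask = cells["phenotype"].isin(expand_label(label)).to_numpy()
    if compartment is not None:
        mask &= (cells["compartment"] == compartment).to_numpy()
    return cells.loc[mask, ["x_um", "y_um"]].to_numpy(float)


def nn_distance_field(source_xy: np.ndarray, target_xy: np.ndarray,
                      same_label: bool = False) -> float | None:
    """Mean distance from each source cell to its nearest target cell.

    Under ``same_label`` the source points are assumed to be a subset of the
    target points (each appearing exactly once) and the nearest *other*
    target is taken. Returns None when undefined (no sources; no targets;
    same-label with fewer than two targets).
    """
    source_xy = np.asarray(source_xy, float).reshape(-1, 2)
    target_xy = np.asarray(target_xy, float).reshape(-1, 2)
    if len(source_xy) == 0 or len(target_xy) == 0:
        return None
    if same_label and len(target_xy) < 2:
        return None
    tree = cKDTree(target_xy)
    if same_label:
        d, _ = tree.query(source_xy, k=2)
        return float(np.mean(d[:, 1]))
    d, _ = tree.query(source_xy, k=1)
    return float(np.mean(d))


def count_within_radius_field(source_xy: np.ndarray, target_xy: np.ndarray,
                              radius: float, same_label: bool = False) -> float | None:
    """Mean number of target cells within ``radius`` µm of each source cell.

    Self-excluded under ``same_label`` (source assumed a subset of target).
    Returns None when there are no source cells.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    source_xy = np.asarray(source_xy, float).reshape(-1, 2)
    target_xy = np.asarray(target_xy, float).reshape(-1, 2)
    if len(source_xy) == 0:
        return None
    if len(target_xy) == 0:
        return 0.0
    tree = cKDTree(target_xy)
    counts = tree.query_ball_point(source_xy, r=radius, return_length=True)
    counts = np.asarray(counts, float)
    if same_label:
        counts -= 1.0
    return float(np.mean(counts))


def region_density(patient: Patient, label: str, region: Region) -> float | None:
    """Cells per mm² of ``label`` in a region, averaged over the patient's fields.

    Per-field density is count / compartment area; fields whose region area
    is zero are skipped. Returns None when every corresponding field has
    zero region area (density undefined).
    """
    densities = []
    for fld in patient.fields_of(region.field_class):
        area = fld.region_area(region.compartment)
        if area <= 0:
            continue
        pts = field_points(fld, label, region.compartment)
        densities.append(len(pts) / area)
    if not densities:
        return None
    return float(np.mean(densities))


def subset_fraction(patient: Patient, subset_label: str, region: Region,
                    mode: str = "pooled") -> float | None:
    """Fraction of a lineage's cells belonging to ``subset_label`` in a region.

    ``mode="pooled"`` divides the subset count pooled over the patient's
    corresponding fields by the pooled parent-lineage count (ratio of sums);
    ``mode="per-field"`` averages per-field ratios over fields with a
    nonzero parent count. Undefined (None) when the parent count is zero
    everywhere.
    """
    if subset_label not in PARENT_LINEAGE:
        raise ValueError(f"{subset_label!r} is not a CD4 or B-cell subset")
    if mode not in ("pooled", "per-field"):
        raise ValueError("mode must be 'pooled' or 'per-field'")
    parent = PARENT_LINEAGE[subset_label]
    sub_total = 0
    parent_total = 0
    ratios = []
    for fld in patient.fields_of(region.field_class):
        n_sub = len(field_points(fld, subset_label, region.compartment))
        n_parent = len(field_points(fld, parent, region.compartment))
        sub_total += n_sub
        parent_total += n_parent
        if n_parent > 0:
            ratios.append(n_sub / n_parent)
    if mode == "pooled":
        if parent_total == 0:
            return None
        return sub_total / parent_total
    if not ratios:
        return None
    return float(np.mean(ratios))


def patient_nna(patient: Patient, source: str, target: str, metric: str,
                radius: float | None = None,
                region: Region = Region.IM_S) -> NNAResult:
    """A nearest-neighbor metric averaged cell -> field -> patient.

    Source cells are restricted to the region's compartment within fields of
    the region's class; target cells are taken from the whole field (a
    neighbor may sit across the tumor-stroma boundary). The patient value is
    the unweighted mean of per-field values over fields where the metric is
    defined; ``value`` is None (patient flagged missing) when no field
    defines it.
    """
    if metric not in ("nearest_distance", "count_within_radius"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "count_within_radius" and (radius is None or radius <= 0):
        raise ValueError("count_within_radius requires a positive radius")
    same = set(expand_label(source)) == set(expand_label(target))
    per_field: dict[str, float] = {}
    n_source = 0
    for fld in patient.fields_of(region.field_class):
        src = field_points(fld, source, region.compartment)
        tgt = field_points(fld, target)
        n_source += len(src)
        if metric == "nearest_distance":
            val = nn_distance_field(src, tgt, same_label=same)
        else:
            val = count_within_radius_field(src, tgt, radius, same_label=same)
        if val is not None:
            per_field[fld.field_id] = val
    value = float(np.mean(list(per_field.values()))) if per_field else None
    return NNAResult(
        source=source, target=target, metric=metric, radius=radius,
        per_field=per_field, value=value, n_fields=len(per_field),
        n_source_cells=n_source,
    )
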