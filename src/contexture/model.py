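"""Core data model: cells, fields, patients, cohorts, regions, and analysis settings.

A *field* is one multispectral acquisition window (690 x 516 µm by default),
classified as lying on the invasive margin (``IM``) or in the tumor center
(``center``), and partitioned into ``tumor`` and ``stroma`` compartments.
Cells are points (cell centers, µm) carrying seven binary marker calls
(CD4, CD20, CD21, FOXP3, Tbet, BCL6, CK) and, once phenotyping has run, a
phenotype label. A patient holds 16 fields (8 IM + 8 center by convention),
clinical covariates and the overall-survival outcome.

Cells are stored per field as a pandas DataFrame (one row per cell) so the
downstream spatial operations can stay vectorized; the :class:`Cell`
dataclass is the single-cell view used at construction and in tests.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field as dc_field, fields as dc_fields
from typing import Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MARKERS",
    "UM2_PER_MM2",
    "FieldClass",
    "Compartment",
    "Region",
    "AnalysisConfig",
    "Cell",
    "Field",
    "Patient",
    "Cohort",
    "empty_cell_frame",
]

#: Marker panel, in canonical column order. All seven calls are binary.
MARKERS: tuple[str, ...] = ("CD4", "CD20", "CD21", "FOXP3", "TBET", "BCL6", "CK")

UM2_PER_MM2 = 1e6

FieldClass = Literal["IM", "center"]
Compartment = Literal["tumor", "stroma"]

#: Columns of a per-field cell table.
CELL_FRAME_COLUMNS: tuple[str, ...] = ("x_um", "y_um", "compartment", *MARKERS, "phenotype")


def empty_cell_frame() -> pd.DataFrame:
    """An empty cell table with the canonical columns and dtypes."""
    return pd.DataFrame(
        {
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "compartment": pd.Series(dtype=object),
            **{m: pd.Series(dtype=np.int8) for m in MARKERS},
            "phenotype": pd.Series(dtype=object),
        }
    )


class Region(enum.Enum):
    """The four analysis regions: (field class, compartment) pairs.

    ``IM_S``/``IM_T`` are the stromal/tumor-cell compartments of the invasive
    margin, ``C_S``/``C_T`` the same compartments in the tumor center.
    """

    IM_S = ("IM", "stroma")
    IM_T = ("IM", "tumor")
    C_S = ("center", "stroma")
    C_T = ("center", "tumor")

    @property
    def field_class(self) -> FieldClass:
        return self.value[0]

    @property
    def compartment(self) -> Compartment:
        return self.value[1]

    @classmethod
    def from_parts(cls, field_class: str, compartment: str) -> "Region":
        for region in cls:
            if region.value == (field_class, compartment):
                return region
        raise ValueError(f"no region for ({field_class!r}, {compartment!r})")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return {"IM_S": "IM-S", "IM_T": "IM-T", "C_S": "C-S", "C_T": "C-T"}[self.name]


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters.

    Parameters
    ----------
    neighbor_radius
        Radius (µm) for within-radius neighbor counts and the cluster-score
        components.
    tls_min_cells
        Minimum lymphocyte count for a cluster to qualify as a tertiary
        lymphoid structure (TLS).
    tls_area_mm2
        Maximum convex-hull area (mm²) of a qualifying TLS cluster.
    tls_link_distance
        Single-linkage linking distance (µm) used to form lymphocyte clusters.
    survival_horizon
        Horizon (months) for the survival-rate estimates (60 = five years).
    univariate_entry_p
        Univariate p-value threshold for entry into multivariate Cox modeling.
    backward_removal_p
        Likelihood-ratio p-value at or above which a covariate is removed
        during backward elimination.
    percent_rounding
        Rounding rule for reported percentages; only
        ``"half-away-from-zero"`` is implemented.
    ambiguity_policy
        How cells positive for two lineage markers are phenotyped:
        ``"exclude"`` labels them ambiguous, ``"priority"`` resolves them
        CD20 > CD4 > CD21.
    fraction_mode
        Subset fractions as ``"pooled"`` (ratio of pooled counts over fields)
        or ``"per-field"`` (mean of per-field ratios).
    score_direction
        ``"cd20-source"`` counts neighbors per CD20 B cell (default);
        ``"cd4-source"`` transposes the CD20-within-CD4 component so CD4 T
        cells are the source.
    """

    neighbor_radius: float = 20.0
    tls_min_cells: int = 50
    tls_area_mm2: float = 0.3
    tls_link_distance: float = 40.0
    survival_horizon: float = 60.0
    univariate_entry_p: float = 0.1
    backward_removal_p: float = 0.10
    percent_rounding: str = "half-away-from-zero"
    ambiguity_policy: str = "exclude"
    fraction_mode: str = "pooled"
    score_direction: str = "cd20-source"

    def __post_init__(self) -> None:
        for name in ("neighbor_radius", "tls_min_cells", "tls_area_mm2",
                     "tls_link_distance", "survival_horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("univariate_entry_p", "backward_removal_p"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.ambiguity_policy not in ("exclude", "priority"):
            raise ValueError("ambiguity_policy must be 'exclude' or 'priority'")
        if self.fraction_mode not in ("pooled", "per-field"):
            raise ValueError("fraction_mode must be 'pooled' or 'per-field'")
        if self.score_direction not in ("cd20-source", "cd4-source"):
            raise ValueError("score_direction must be 'cd20-source' or 'cd4-source'")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "AnalysisConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown analysis settings: {sorted(unknown)}")
        return cls(**dict(mapping))  # type: ignore[arg-type]

    def to_dict(self) -> dict[str, object]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class Cell:
    """A single phenotyped cell (point) inside a field."""

    x: float
    y: float
    compartment: Compartment
    markers: Mapping[str, bool]
    phenotype: str = "unassigned"

    def __post_init__(self) -> None:
        missing = [m for m in MARKERS if m not in self.markers]
        if missing:
            raise ValueError(f"missing marker calls: {missing}")
        if self.compartment not in ("tumor", "stroma"):
            raise ValueError(f"invalid compartment {self.compartment!r}")


@dataclass
class Field:
    """One multispectral image: a fixed window with cells and compartment areas."""

    field_id: str
    field_class: FieldClass
    cells: pd.DataFrame = dc_field(default_factory=empty_cell_frame)
    area_tumor_mm2: float = 0.0
    area_stroma_mm2: float = 0.0
    width: float = 690.0
    height: float = 516.0

    def __post_init__(self) -> None:
        if self.field_class not in ("IM", "center"):
            raise ValueError(f"invalid field class {self.field_class!r}")
        self.validate()

    def validate(self) -> None:
        if self.area_tumor_mm2 < 0 or self.area_stroma_mm2 < 0:
            raise ValueError(f"field {self.field_id}: negative compartment area")
        window_mm2 = self.width * self.height / UM2_PER_MM2
        if self.area_tumor_mm2 + self.area_stroma_mm2 > window_mm2 * (1 + 1e-9):
            raise ValueError(
                f"field {self.field_id}: compartment areas exceed the "
                f"{self.width:g} x {self.height:g} µm window ({window_mm2:.4f} mm²)"
            )
        if len(self.cells):
            x = self.cells["x_um"].to_numpy(float)
            y = self.cells["y_um"].to_numpy(float)
            bad = np.flatnonzero((x < 0) | (x >= self.width) | (y < 0) | (y >= self.height))
            if bad.size:
                i = int(bad[0])
                raise ValueError(
                    f"field {self.field_id}: cell at row {i} "
                    f"({x[i]:g}, {y[i]:g}) lies outside [0, {self.width:g}) x "
                    f"[0, {self.height:g})"
                )
            comp = self.cells["compartment"]
            if not comp.isin(("tumor", "stroma")).all():
                bad_val = comp[~comp.isin(("tumor", "stroma"))].iloc[0]
                raise ValueError(f"field {self.field_id}: invalid compartment {bad_val!r}")

    def region_area(self, compartment: Compartment) -> float:
        return self.area_stroma_mm2 if compartment == "stroma" else self.area_tumor_mm2

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def add_cells(self, cells: Sequence[Cell]) -> None:
        if not cells:
            return
        rows = pd.DataFrame(
            {
                "x_um": [c.x for c in cells],
                "y_um": [c.y for c in cells],
                "compartment": [c.compartment for c in cells],
                **{m: np.asarray([int(bool(c.markers[m])) for c in cells], np.int8)
                   for m in MARKERS},
                "phenotype": [c.phenotype for c in cells],
            }
        )
        if len(self.cells):
            self.cells = pd.concat([self.cells, rows], ignore_index=True)
        else:
            self.cells = rows
        self.validate()


@dataclass
class Patient:
    """All fields of one tumor plus clinical covariates and survival outcome."""

    patient_id: str
    fields: list[Field] = dc_field(default_factory=list)
    age: float | None = None
    sex: str | None = None
    pT: str | None = None
    pN: str | None = None
    pStage: str | None = None
    grade: str | None = None
    lvi: bool | None = None
    os_months: float | None = None
    os_event: bool | None = None

    def __post_init__(self) -> None:
        if self.os_months is not None and self.os_months < 0:
            raise ValueError(f"patient {self.patient_id}: negative os_months")

    def fields_of(self, field_class: FieldClass) -> list[Field]:
        return [f for f in self.fields if f.field_class == field_class]

    @property
    def n_cells(self) -> int:
        return sum(f.n_cells for f in self.fields)


@dataclass
class Cohort:
    """A set of patients analyzed under one configuration."""

    patients: list[Patient] = dc_field(default_factory=list)
    config: AnalysisConfig = dc_field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate patient ids: {sorted(dupes)}")

    def __iter__(self) -> Iterator[Patient]:
        return iter(self.patients)

    def __len__(self) -> int:
        return len(self.patients)

    def patient(self, patient_id: str) -> Patient:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]
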