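"""Readers, writers and validation for the cohort CSV schemas.

Three flat files describe a cohort:

* ``cells.csv`` — one row per segmented cell:
  patient_id, field_id, field_class, x_um, y_um, compartment,
  CD4, CD20, CD21, FOXP3, TBET, BCL6, CK (binary flags), and optionally a
  phenotype column written back after phenotyping;
* ``areas.csv`` — per-field tissue areas:
  patient_id, field_id, area_tumor_mm2, area_stroma_mm2;
* ``clinical.csv`` — one row per patient:
  patient_id, age, sex, pT, pN, pStage, grade, lvi, os_months, os_event.

Loading is order-independent: rows are sorted canonically, so a shuffled
file yields an identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import AnalysisConfig, Cohort, Field, MARKERS, Patient

__all__ = [
    "SchemaError",
    "LoadReport",
    "ValidationReport",
    "load_cell_table",
    "load_clinical_table",
    "load_cohort",
    "cohort_to_frames",
    "write_cohort",
    "validate_cohort",
]

CELL_COLUMNS = ["patient_id", "field_id", "field_class", "x_um", "y_um",
                "compartment", *MARKERS]
AREA_COLUMNS = ["patient_id", "field_id", "area_tumor_mm2", "area_stroma_mm2"]
CLINICAL_COLUMNS = ["patient_id", "age", "sex", "pT", "pN", "pStage",
                    "grade", "lvi", "os_months", "os_event"]


class SchemaError(ValueError):
    """A required column is missing or a value violates the schema."""


@dataclass
class LoadReport:
    unmatched_clinical: list[str] = dc_field(default_factory=list)
    unmatched_cells: list[str] = dc_field(default_factory=list)


@dataclass
class ValidationReport:
    """Report-only cohort checks; ``issues`` is empty for a well-formed cohort."""

    field_counts: dict[str, dict[str, int]] = dc_field(default_factory=dict)
    lineage_conflicts: int = 0
    zero_area_regions: list[tuple[str, str, str]] = dc_field(default_factory=list)
    issues: list[str] = dc_field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def load_cell_table(cell_csv_path, area_csv_path,
                    width: float = 690.0, height: float = 516.0,
                    ) -> dict[str, list[Field]]:
    """Load cells.csv + areas.csv into per-patient field lists.

    Every field referenced in cells.csv must have an area row; fields with
    areas but no cells become empty fields. Coordinates outside the
    ``[0, width) x [0, height)`` window raise, citing the offending
    cells.csv row.
    """
    cells = pd.read_csv(cell_csv_path, float_precision="round_trip")
    areas = pd.read_csv(area_csv_path, float_precision="round_trip")
    _require_columns(cells, CELL_COLUMNS, "cells.csv")
    _require_columns(areas, AREA_COLUMNS, "areas.csv")

    if len(cells):
        x = pd.to_numeric(cells["x_um"], errors="raise").to_numpy(float)
        y = pd.to_numeric(cells["y_um"], errors="raise").to_numpy(float)
        bad = np.flatnonzero((x < 0) | (x >= width) | (y < 0) | (y >= height))
        if bad.size:
            i = int(bad[0])
            raise SchemaError(
                f"cells.csv row {i}: cell at ({x[i]:g}, {y[i]:g}) lies outside "
                f"[0, {width:g}) x [0, {height:g})")
        bad_class = ~cells["field_class"].isin(("IM", "center"))
        if bad_class.any():
            i = int(np.flatnonzero(bad_class)[0])
            raise SchemaError(f"cells.csv row {i}: invalid field_class "
                              f"{cells['field_class'].iloc[i]!r}")
        for m in MARKERS:
            vals = pd.to_numeric(cells[m], errors="raise")
            if not vals.isin((0, 1)).all():
                raise SchemaError(f"cells.csv column {m} must be binary 0/1")
            cells[m] = vals.astype(np.int8)

    dup_areas = areas.duplicated(["patient_id", "field_id"])
    if dup_areas.any():
        key = areas.loc[dup_areas, ["patient_id", "field_id"]].iloc[0].tolist()
        raise SchemaError(f"areas.csv: duplicate field {key}")

    area_index = areas.set_index(["patient_id", "field_id"])
    cell_fields = (set(map(tuple, cells[["patient_id", "field_id"]]
                           .drop_duplicates().to_numpy()))
                   if len(cells) else set())
    missing_area = cell_fields - set(area_index.index)
    if missing_area:
        raise SchemaError(f"areas.csv has no row for field(s): "
                          f"{sorted(missing_area)[:5]}")

    has_pheno = "phenotype" in cells.columns
    fields_by_patient: dict[str, list[Field]] = {}
    grouped = {k: g for k, g in cells.groupby(["patient_id", "field_id"])} \
        if len(cells) else {}
    for (pid, fid), area_row in area_index.sort_index().iterrows():
        g = grouped.get((pid, fid))
        if g is not None:
            g = g.sort_values(["x_um", "y_um", *MARKERS], kind="mergesort")
            field_class = g["field_class"].iloc[0]
            if not (g["field_class"] == field_class).all():
                raise SchemaError(f"field {fid}: inconsistent field_class")
            frame = pd.DataFrame({
                "x_um": g["x_um"].to_numpy(float),
                "y_um": g["y_um"].to_numpy(float),
                "compartment": g["compartment"].to_numpy(object),
                **{m: g[m].to_numpy(np.int8) for m in MARKERS},
                "phenotype": (g["phenotype"].to_numpy(object) if has_pheno
                              else np.full(len(g), "unassigned", object)),
            }).reset_index(drop=True)
        else:
            field_class = "IM" if "IM" in str(fid) else "center"
            frame = None
        fld = Field(
            field_id=str(fid), field_class=str(field_class),
            area_tumor_mm2=float(area_row["area_tumor_mm2"]),
            area_stroma_mm2=float(area_row["area_stroma_mm2"]),
            width=width, height=height,
            **({"cells": frame} if frame is not None else {}),
        )
        fields_by_patient.setdefault(str(pid), []).append(fld)
    for flds in fields_by_patient.values():
        flds.sort(key=lambda f: f.field_id)
    return fields_by_patient


def load_clinical_table(path) -> pd.DataFrame:
    """Load clinical.csv keyed by patient_id; duplicates and negative
    follow-up times raise."""
    clinical = pd.read_csv(path, float_precision="round_trip")
    _require_columns(clinical, CLINICAL_COLUMNS, "clinical.csv")
    dupes = clinical["patient_id"][clinical["patient_id"].duplicated()]
    if len(dupes):
        raise SchemaError(f"clinical.csv: duplicate patient_id {dupes.iloc[0]!r}")
    clinical = clinical.set_index("patient_id").sort_index()
    os_months = pd.to_numeric(clinical["os_months"], errors="raise")
    if (os_months < 0).any():
        bad = os_months[os_months < 0].index[0]
        raise SchemaError(f"clinical.csv: negative os_months for patient {bad!r}")
    clinical["os_months"] = os_months
    clinical["os_event"] = clinical["os_event"].astype(int).astype(bool)
    clinical["lvi"] = clinical["lvi"].map(
        {True: True, False: False, 1: True, 0: False,
         "True": True, "False": False, "true": True, "false": False})
    return clinical


def load_cohort(cell_csv_path, area_csv_path, clinical_csv_path,
                config: AnalysisConfig | None = None,
                width: float = 690.0, height: float = 516.0,
                ) -> tuple[Cohort, LoadReport]:
    """Assemble a cohort from the three CSVs; ids present on only one side
    are reported, never dropped silently."""
    fields_by_patient = load_cell_table(cell_csv_path, area_csv_path,
                                        width=width, height=height)
    clinical = load_clinical_table(clinical_csv_path)
    report = LoadReport(
        unmatched_clinical=sorted(set(clinical.index) - set(fields_by_patient)),
        unmatched_cells=sorted(set(fields_by_patient) - set(clinical.index)),
    )
    patients = []
    for pid in sorted(fields_by_patient):
        kwargs = {}
        if pid in clinical.index:
            row = clinical.loc[pid]
            kwargs = dict(
                age=float(row["age"]), sex=str(row["sex"]), pT=str(row["pT"]),
                pN=str(row["pN"]), pStage=str(row["pStage"]),
                grade=str(row["grade"]), lvi=bool(row["lvi"]),
                os_months=float(row["os_months"]),
                os_event=bool(row["os_event"]),
            )
        patients.append(Patient(patient_id=pid,
                                fields=fields_by_patient[pid], **kwargs))
    return Cohort(patients=patients, config=config or AnalysisConfig()), report


def cohort_to_frames(cohort: Cohort,
                     include_phenotype: bool = False,
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """The cohort as (cells, areas, clinical) DataFrames in schema order."""
    cell_rows = []
    area_rows = []
    clin_rows = []
    for p in cohort:
        for f in p.fields:
            area_rows.append({"patient_id": p.patient_id, "field_id": f.field_id,
                              "area_tumor_mm2": f.area_tumor_mm2,
                              "area_stroma_mm2": f.area_stroma_mm2})
            if len(f.cells):
                block = f.cells.copy()
                block.insert(0, "patient_id", p.patient_id)
                block.insert(1, "field_id", f.field_id)
                block.insert(2, "field_class", f.field_class)
                cell_rows.append(block)
        clin_rows.append({
            "patient_id": p.patient_id, "age": p.age, "sex": p.sex,
            "pT": p.pT, "pN": p.pN, "pStage": p.pStage, "grade": p.grade,
            "lvi": p.lvi, "os_months": p.os_months,
            "os_event": int(p.os_event) if p.os_event is not None else None,
        })
    columns = CELL_COLUMNS + (["phenotype"] if include_phenotype else [])
    cells = (pd.concat(cell_rows, ignore_index=True)[columns]
             if cell_rows else pd.DataFrame(columns=columns))
    return cells, pd.DataFrame(area_rows), pd.DataFrame(clin_rows)


def write_cohort(cohort: Cohort, out_dir,
                 include_phenotype: bool = False) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells, areas, clinical = cohort_to_frames(cohort, include_phenotype)
    paths = {
        "cells": out_dir / "cells.csv",
        "areas": out_dir / "areas.csv",
        "clinical": out_dir / "clinical.csv",
    }
    cells.to_csv(paths["cells"], index=False)
    areas.to_csv(paths["areas"], index=False)
    clinical.to_csv(paths["clinical"], index=False)
    return paths


def validate_cohort(cohort: Cohort, expected_im: int = 8,
                    expected_center: int = 8) -> ValidationReport:
    """Report-only checks: field counts per patient, lineage-conflicting
    marker calls, and zero-area regions."""
    report = ValidationReport()
    for p in cohort:
        n_im = len(p.fields_of("IM"))
        n_center = len(p.fields_of("center"))
        report.field_counts[p.patient_id] = {"IM": n_im, "center": n_center}
        if n_im != expected_im:
            report.issues.append(
                f"patient {p.patient_id}: {n_im} IM fields, expected {expected_im}")
        if n_center != expected_center:
            report.issues.append(
                f"patient {p.patient_id}: {n_center} center fields, "
                f"expected {expected_center}")
        for f in p.fields:
            if len(f.cells):
                conflict = (f.cells["CD4"].astype(bool)
                            & (f.cells["CD20"].astype(bool)
                               | f.cells["CD21"].astype(bool)))
                k = int(conflict.sum())
                if k:
                    report.lineage_conflicts += k
                    report.issues.append(
                        f"patient {p.patient_id} field {f.field_id}: "
                        f"{k} lineage-ambiguous cell(s)")
            for compartment in ("tumor", "stroma"):
                if f.region_area(compartment) <= 0:
                    report.zero_area_regions.append(
                        (p.patient_id, f.field_id, compartment))
                    report.issues.append(
                        f"patient {p.patient_id} field {f.field_id}: "
                        f"zero {compartment} area")
    return report
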