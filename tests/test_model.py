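import numpy as np
import pandas as pd
import pytest

from contexture.io import (SchemaError, cohort_to_frames, load_cell_table,
                           load_clinical_table, load_cohort, validate_cohort,
                           write_cohort)
from contexture.model import AnalysisConfig, Cohort, Field, Patient, Region
from contexture.simulate import SimConfig, simulate_cohort

from conftest import cells_frame, make_field, make_patient


CELL_HEADER = ("patient_id,field_id,field_class,x_um,y_um,compartment,"
               "CD4,CD20,CD21,FOXP3,TBET,BCL6,CK\n")
AREA_HEADER = "patient_id,field_id,area_tumor_mm2,area_stroma_mm2\n"
CLIN_HEADER = "patient_id,age,sex,pT,pN,pStage,grade,lvi,os_months,os_event\n"


def write_inputs(tmp_path, cell_rows="", area_rows="", clin_rows=""):
    cells = tmp_path / "cells.csv"
    areas = tmp_path / "areas.csv"
    clin = tmp_path / "clinical.csv"
    cells.write_text(CELL_HEADER + cell_rows)
    areas.write_text(AREA_HEADER + area_rows)
    clin.write_text(CLIN_HEADER + clin_rows)
    return cells, areas, clin


class TestRegion:
    def test_four_regions_total_mapping(self):
        pairs = {(r.field_class, r.compartment) for r in Region}
        assert pairs == {("IM", "stroma"), ("IM", "tumor"),
                         ("center", "stroma"), ("center", "tumor")}
        assert Region.from_parts("IM", "stroma") is Region.IM_S

    def test_unknown_pair_rejected(self):
        with pytest.raises(ValueError):
            Region.from_parts("IM", "nucleus")


class TestFieldInvariants:
    def test_cell_outside_window_rejected(self):
        frame = cells_frame([(700.0, 10.0, "stroma", "B-other")])
        with pytest.raises(ValueError, match="outside"):
            Field(field_id="F1", field_class="IM", cells=frame,
                  area_stroma_mm2=0.1, area_tumor_mm2=0.1)

    def test_areas_cannot_exceed_window(self):
        with pytest.raises(ValueError, match="exceed"):
            Field(field_id="F1", field_class="IM",
                  area_stroma_mm2=0.3, area_tumor_mm2=0.2)  # window is 0.356 mm2

    def test_negative_os_months_rejected(self):
        with pytest.raises(ValueError):
            Patient(patient_id="P1", os_months=-1.0)

    def test_duplicate_patient_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Cohort(patients=[Patient("P1"), Patient("P1")])


class TestLoading:
    def test_empty_input_gives_empty_cohort(self, tmp_path):
        cells, areas, clin = write_inputs(tmp_path)
        cohort, report = load_cohort(cells, areas, clin)
        assert len(cohort) == 0
        assert report.unmatched_clinical == [] and report.unmatched_cells == []

    def test_single_row_identity(self, tmp_path):
        cells, areas, clin = write_inputs(
            tmp_path,
            cell_rows="P1,F1,IM,10,10,stroma,0,1,0,0,0,0,0\n",
            area_rows="P1,F1,0.1,0.1\n",
            clin_rows="P1,63,male,pT1,pN0,1,well,0,62,0\n",
        )
        cohort, report = load_cohort(cells, areas, clin)
        assert len(cohort) == 1
        patient = cohort.patient("P1")
        assert len(patient.fields) == 1
        fld = patient.fields[0]
        assert fld.n_cells == 1 and fld.field_class == "IM"
        assert fld.cells.loc[0, "CD20"] == 1
        assert patient.os_months == 62 and patient.os_event is False
        assert report.unmatched_clinical == []

    def test_cell_outside_window_cites_row(self, tmp_path):
        cells, areas, _ = write_inputs(
            tmp_path,
            cell_rows=("P1,F1,IM,10,10,stroma,0,1,0,0,0,0,0\n"
                       "P1,F1,IM,700,10,stroma,0,1,0,0,0,0,0\n"),
            area_rows="P1,F1,0.1,0.1\n",
        )
        with pytest.raises(SchemaError, match="row 1"):
            load_cell_table(cells, areas)

    def test_missing_column_named(self, tmp_path):
        cells = tmp_path / "cells.csv"
        cells.write_text(CELL_HEADER.replace(",CK", ""))
        areas = tmp_path / "areas.csv"
        areas.write_text(AREA_HEADER)
        with pytest.raises(SchemaError, match="CK"):
            load_cell_table(cells, areas)

    def test_duplicate_clinical_id_named(self, tmp_path):
        _, _, clin = write_inputs(
            tmp_path,
            clin_rows=("P1,63,male,pT1,pN0,1,well,0,62,0\n"
                       "P1,70,male,pT1,pN0,1,well,0,30,1\n"),
        )
        with pytest.raises(SchemaError, match="P1"):
            load_clinical_table(clin)

    def test_negative_os_months_named(self, tmp_path):
        _, _, clin = write_inputs(
            tmp_path, clin_rows="P1,63,male,pT1,pN0,1,well,0,-5,0\n")
        with pytest.raises(SchemaError, match="P1"):
            load_clinical_table(clin)

    def test_clinical_without_cells_reported_not_dropped(self, tmp_path):
        cells, areas, clin = write_inputs(
            tmp_path,
            cell_rows="P1,F1,IM,10,10,stroma,0,1,0,0,0,0,0\n",
            area_rows="P1,F1,0.1,0.1\n",
            clin_rows=("P1,63,male,pT1,pN0,1,well,0,62,0\n"
                       "P2,70,female,pT2,pN0,2,moderate,0,40,1\n"),
        )
        _, report = load_cohort(cells, areas, clin)
        assert report.unmatched_clinical == ["P2"]


class TestRoundTripAndOrder:
    def test_round_trip_reproduces_cohort_exactly(self, tmp_path):
        cohort, _ = simulate_cohort(SimConfig(n_patients=2, n_im_fields=2,
                                              n_center_fields=2, seed=5))
        paths = write_cohort(cohort, tmp_path / "out")
        reloaded, report = load_cohort(paths["cells"], paths["areas"],
                                       paths["clinical"])
        assert report.unmatched_cells == [] and report.unmatched_clinical == []
        orig_cells, orig_areas, orig_clin = cohort_to_frames(cohort)
        new_cells, new_areas, new_clin = cohort_to_frames(reloaded)
        key = ["patient_id", "field_id", "x_um", "y_um"]
        orig_sorted = orig_cells.sort_values(key).reset_index(drop=True)
        new_sorted = new_cells.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(orig_sorted, new_sorted)
        pd.testing.assert_frame_equal(
            orig_areas.sort_values(["patient_id", "field_id"]).reset_index(drop=True),
            new_areas.sort_values(["patient_id", "field_id"]).reset_index(drop=True))
        assert orig_clin["os_months"].tolist() == new_clin["os_months"].tolist()

    def test_loading_is_order_independent(self, tmp_path, rng):
        cohort, _ = simulate_cohort(SimConfig(n_patients=2, n_im_fields=2,
                                              n_center_fields=2, seed=6))
        paths = write_cohort(cohort, tmp_path / "a")
        cells = pd.read_csv(paths["cells"])
        shuffled = cells.sample(frac=1.0, random_state=99)
        shuffled.to_csv(tmp_path / "a" / "cells_shuffled.csv", index=False)
        a = load_cell_table(paths["cells"], paths["areas"])
        b = load_cell_table(tmp_path / "a" / "cells_shuffled.csv", paths["areas"])
        assert a.keys() == b.keys()
        for pid in a:
            for fa, fb in zip(a[pid], b[pid]):
                assert fa.field_id == fb.field_id
                pd.testing.assert_frame_equal(fa.cells, fb.cells)


class TestValidateCohort:
    def test_well_formed_synthetic_cohort_is_clean(self):
        cohort, _ = simulate_cohort(SimConfig(n_patients=2, seed=1))
        assert validate_cohort(cohort).ok

    def test_missing_field_warned(self):
        fields = [make_field([], field_id=f"IM{i}") for i in range(7)]
        fields += [make_field([], field_id=f"C{i}", field_class="center")
                   for i in range(8)]
        cohort = Cohort(patients=[make_patient(fields)])
        report = validate_cohort(cohort)
        assert any("7 IM fields, expected 8" in i for i in report.issues)

    def test_lineage_conflicts_counted_by_scan(self):
        frame = cells_frame([(10, 10, "stroma", "B-other"),
                             (20, 20, "stroma", "Treg"),
                             (30, 30, "stroma", "Tfh")])
        frame.loc[0, "CD4"] = 1  # CD4+CD20+ conflict
        frame.loc[2, "CD20"] = 1  # CD4+CD20+ conflict
        fld = Field(field_id="F1", field_class="IM", cells=frame,
                    area_stroma_mm2=0.1, area_tumor_mm2=0.1)
        cohort = Cohort(patients=[make_patient([fld])])
        report = validate_cohort(cohort, expected_im=1, expected_center=0)
        # oracle: direct scan of the marker table
        expected = int((frame["CD4"].astype(bool)
                        & (frame["CD20"].astype(bool)
                           | frame["CD21"].astype(bool))).sum())
        assert report.lineage_conflicts == expected == 2

    def test_zero_area_region_flagged(self):
        fld = make_field([], area_tumor=0.0)
        cohort = Cohort(patients=[make_patient([fld])])
        report = validate_cohort(cohort, expected_im=1, expected_center=0)
        assert ("P1", "F1", "tumor") in report.zero_area_regions


def test_analysis_config_rejects_bad_values():
    with pytest.raises(ValueError):
        AnalysisConfig(neighbor_radius=-1)
    with pytest.raises(ValueError):
        AnalysisConfig(univariate_entry_p=1.5)
    with pytest.raises(ValueError):
        AnalysisConfig.from_mapping({"no_such_setting": 1})
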