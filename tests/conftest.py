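import numpy as np
import pandas as pd
import pytest

from contexture.model import AnalysisConfig, Field, MARKERS, Patient
from contexture.simulate import PHENOTYPE_MARKERS

# extend the generator's phenotype->marker map with labels it never emits,
# so tests can plant them directly
TEST_MARKERS = {
    **PHENOTYPE_MARKERS,
    "CD4-multi": ("CD4", "TBET", "BCL6"),
    "ambiguous": ("CD4", "CD20"),
}


def cells_frame(points):
    """Build a cell table from (x, y, compartment, phenotype) tuples.

    Marker flags are set deterministically from the phenotype so that
    re-running phenotype assignment reproduces the same labels.
    """
    rows = {
        "x_um": [p[0] for p in points],
        "y_um": [p[1] for p in points],
        "compartment": [p[2] for p in points],
    }
    phenos = [p[3] for p in points]
    for m in MARKERS:
        rows[m] = np.array([m in TEST_MARKERS[ph] for ph in phenos], np.int8)
    rows["phenotype"] = phenos
    return pd.DataFrame(rows)


def make_field(points, field_id="F1", field_class="IM",
               area_stroma=0.178, area_tumor=0.178):
    return Field(field_id=field_id, field_class=field_class,
                 cells=cells_frame(points),
                 area_stroma_mm2=area_stroma, area_tumor_mm2=area_tumor)


def make_patient(fields, patient_id="P1", **clinical):
    return Patient(patient_id=patient_id, fields=fields, **clinical)


# ---------------------------------------------------------------------------
# brute-force O(n^2) oracles for the spatial metrics


def brute_nn_cross(src, tgt):
    src = np.asarray(src, float).reshape(-1, 2)
    tgt = np.asarray(tgt, float).reshape(-1, 2)
    if len(src) == 0 or len(tgt) == 0:
        return None
    d = np.sqrt(((src[:, None, :] - tgt[None, :, :]) ** 2).sum(-1))
    return float(d.min(axis=1).mean())


def brute_nn_same(pts):
    pts = np.asarray(pts, float).reshape(-1, 2)
    if len(pts) < 2:
        return None
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def brute_count_cross(src, tgt, r):
    src = np.asarray(src, float).reshape(-1, 2)
    tgt = np.asarray(tgt, float).reshape(-1, 2)
    if len(src) == 0:
        return None
    if len(tgt) == 0:
        return 0.0
    d = np.sqrt(((src[:, None, :] - tgt[None, :, :]) ** 2).sum(-1))
    return float((d <= r).sum(axis=1).mean())


def brute_count_same(pts, r):
    pts = np.asarray(pts, float).reshape(-1, 2)
    if len(pts) == 0:
        return None
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return float((d <= r).sum(axis=1).mean())


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
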