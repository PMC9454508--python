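"""Synthetic cohorts of phenotyped cell maps with survival outcomes.

The generator reproduces the statistical structure the analysis assumes so
every pipeline stage is testable without patient data:

* geometry — 16 fields per patient (8 invasive-margin, 8 center), each a
  690 x 516 µm window split into stroma and tumor compartments by a straight
  vertical boundary (compartment areas are therefore exact);
* background — homogeneous Poisson cells per phenotype per compartment,
  immune intensities reduced in center fields;
* niches — a Thomas cluster process in the IM stroma: Poisson parent
  centers, with CD20 B-cell and CD4 T-cell offspring displaced from the
  *same* parents by an isotropic Gaussian, implementing B/T co-clustering.
  "Niche-high" patients carry active aggregates; "niche-low" patients have
  background only;
* subset structure — CD4 offspring split into Treg/Th1/Tfh/Tfr/CD4-other by
  a mixture whose Tfh share is a per-patient enrichment parameter (higher in
  niche-high patients); B offspring split into GC-B/B-other;
* survival — exponential with hazard
  ``h0 * exp(beta_score * I[niche-high] + beta_tfh * tfh_share)`` and
  independent uniform censoring, so hazard-ratio recovery targets are
  analytic.

Marker flags are set deterministically from the generated phenotype; the
``phenotype`` column is left "unassigned" so the phenotyping module is
always exercised downstream. Everything is driven by one
:class:`numpy.random.Generator`, making runs fully reproducible per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, fields as dc_fields, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .model import AnalysisConfig, Cohort, Field, MARKERS, Patient, UM2_PER_MM2

__all__ = [
    "SimConfig",
    "PHENOTYPE_MARKERS",
    "simulate_field",
    "simulate_patient",
    "simulate_cohort",
    "simulate_survival",
]

#: Deterministic marker flags per generated phenotype.
PHENOTYPE_MARKERS: dict[str, tuple[str, ...]] = {
    "Treg": ("CD4", "FOXP3"),
    "Th1": ("CD4", "TBET"),
    "Tfh": ("CD4", "BCL6"),
    "Tfr": ("CD4", "FOXP3", "BCL6"),
    "CD4-other": ("CD4",),
    "GC-B": ("CD20", "BCL6"),
    "B-other": ("CD20",),
    "fDC": ("CD21",),
    "tumor": ("CK",),
    "other": (),
}

CD4_MIX_LABELS = ("Treg", "Th1", "Tfh", "Tfr", "CD4-other")
B_MIX_LABELS = ("GC-B", "B-other")


def _default_background_stroma() -> dict[str, float]:
    # cells/mm² in IM stroma; immune infiltrate concentrated here
    return {
        "Treg": 60.0, "Th1": 50.0, "Tfh": 30.0, "Tfr": 3.0, "CD4-other": 150.0,
        "GC-B": 10.0, "B-other": 80.0, "fDC": 5.0, "tumor": 50.0, "other": 200.0,
    }


def _default_background_tumor() -> dict[str, float]:
    # cells/mm² in the tumor-cell compartment; dominated by CK+ cells
    return {
        "Treg": 15.0, "Th1": 12.0, "Tfh": 6.0, "Tfr": 1.0, "CD4-other": 40.0,
        "GC-B": 2.0, "B-other": 15.0, "fDC": 1.0, "tumor": 2000.0, "other": 100.0,
    }


def _default_b_mixture() -> dict[str, float]:
    return {"GC-B": 0.15, "B-other": 0.85}


@dataclass
class SimConfig:
    """All point-process, mixture, clinical and survival parameters.

    Aggregate parameters follow the Thomas-process convention:
    ``parent_intensity`` parents per mm² of IM stroma, Poisson
    ``offspring_cd20`` / ``offspring_cd4`` offspring per parent, isotropic
    Gaussian displacement with standard deviation ``offspring_sigma`` µm.
    Setting ``parents_per_field`` places exactly that many well-separated
    parents per IM field (jittered grid) instead of Poisson placement.
    """

    n_patients: int = 40
    n_im_fields: int = 8
    n_center_fields: int = 8
    field_width: float = 690.0
    field_height: float = 516.0
    stroma_fraction_im: float = 0.5
    stroma_fraction_center: float = 0.4
    background_stroma: dict[str, float] = dc_field(default_factory=_default_background_stroma)
    background_tumor: dict[str, float] = dc_field(default_factory=_default_background_tumor)
    center_immune_factor: float = 0.5
    parent_intensity: float = 8.0
    parents_per_field: int | None = None
    offspring_cd20: float = 80.0
    offspring_cd4: float = 60.0
    offspring_sigma: float = 25.0
    b_mixture: dict[str, float] = dc_field(default_factory=_default_b_mixture)
    tfh_share_high: tuple[float, float] = (0.15, 0.45)
    tfh_share_low: tuple[float, float] = (0.03, 0.15)
    fraction_niche_high: float = 0.5
    baseline_hazard: float = 0.006  # events per month for the reference patient
    beta_score: float = math.log(0.3)  # protective niche effect on the log-hazard
    beta_tfh: float = -1.0  # per unit Tfh share
    censoring_months: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.background_stroma, self.background_tumor):
            if any(v < 0 for v in d.values()):
                raise ValueError("background intensities must be >= 0")
        if abs(sum(self.b_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("b_mixture probabilities must sum to 1")
        if self.offspring_sigma <= 0:
            raise ValueError("offspring_sigma must be positive")
        if not 0.0 <= self.fraction_niche_high <= 1.0:
            raise ValueError("fraction_niche_high must lie in [0, 1]")

    def to_dict(self) -> dict[str, object]:
        out = {}
        for f in dc_fields(self):
            v = getattr(self, f.name)
            out[f.name] = dict(v) if isinstance(v, dict) else (
                list(v) if isinstance(v, tuple) else v)
        return out

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "SimConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown simulator settings: {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("tfh_share_high", "tfh_share_low"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])  # type: ignore[arg-type]
        return cls(**kwargs)  # type: ignore[arg-type]


def _cd4_mixture(tfh_share: float) -> dict[str, float]:
    """CD4 subset mixture with the Tfh share pinned and the rest rescaled."""
    base = {"Treg": 0.22, "Th1": 0.18, "Tfr": 0.01, "CD4-other": 0.49}  # sums to 0.9
    rest = sum(base.values())
    return {"Tfh": tfh_share,
            **{k: v * (1 - tfh_share) / rest for k, v in base.items()}}


def _patient_background(cfg: SimConfig, tfh_share: float,
                        compartment: str) -> dict[str, float]:
    """Background intensities with the CD4 total preserved but Tfh share adjusted."""
    base = dict(cfg.background_stroma if compartment == "stroma"
                else cfg.background_tumor)
    cd4_total = sum(base[k] for k in CD4_MIX_LABELS)
    mix = _cd4_mixture(tfh_share)
    for k in CD4_MIX_LABELS:
        base[k] = cd4_total * mix[k]
    return base


def _grid_parents(k: int, x_lo: float, x_hi: float, height: float,
                  rng: np.random.Generator) -> np.ndarray:
    """k well-separated parent centers on a jittered grid inside a strip."""
    if k == 0:
        return np.empty((0, 2))
    margin = 80.0
    # grid aspect follows the strip so parent separation is maximized
    strip_w = max(x_hi - x_lo - 2 * margin, 1.0)
    strip_h = max(height - 2 * margin, 1.0)
    cols = max(1, round(math.sqrt(k * strip_w / strip_h)))
    rows = int(math.ceil(k / cols))
    xs = np.linspace(x_lo + margin, x_hi - margin, cols)
    ys = np.linspace(margin, height - margin, rows)
    centers = np.array([(x, y) for y in ys for x in xs])[:k]
    return centers + rng.uniform(-20.0, 20.0, size=centers.shape)


def simulate_field(cfg: SimConfig, field_class: str, rng: np.random.Generator,
                   field_id: str = "F", tfh_share: float = 0.10,
                   aggregates: bool = False) -> Field:
    """One synthetic field.

    The stroma occupies the vertical strip ``x < stroma_fraction * width``;
    background cells are homogeneous Poisson per phenotype per compartment.
    With ``aggregates=True`` (IM fields only) Thomas-process niches add
    co-localized CD20/CD4 offspring around shared parents in the stroma;
    offspring falling outside the window are clipped to its edge, and each
    cell's compartment follows the partition at its final position.
    """
    w, h = cfg.field_width, cfg.field_height
    s = cfg.stroma_fraction_im if field_class == "IM" else cfg.stroma_fraction_center
    x_split = s * w
    area_stroma = x_split * h / UM2_PER_MM2
    area_tumor = (w - x_split) * h / UM2_PER_MM2

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    phenos: list[np.ndarray] = []

    center_scale = cfg.center_immune_factor if field_class == "center" else 1.0
    for compartment, (x_lo, x_hi, area) in (
        ("stroma", (0.0, x_split, area_stroma)),
        ("tumor", (x_split, w, area_tumor)),
    ):
        if area <= 0:
            continue
        background = _patient_background(cfg, tfh_share, compartment)
        for pheno in sorted(background):
            lam = background[pheno]
            if pheno != "tumor":
                lam *= center_scale
            n = rng.poisson(lam * area)
            if n == 0:
                continue
            xs.append(rng.uniform(x_lo, x_hi, n))
            ys.append(rng.uniform(0.0, h, n))
            phenos.append(np.full(n, pheno, dtype=object))

    if aggregates and field_class == "IM":
        if cfg.parents_per_field is not None:
            parents = _grid_parents(cfg.parents_per_field, 0.0, x_split, h, rng)
        else:
            n_par = rng.poisson(cfg.parent_intensity * area_stroma)
            parents = np.column_stack([
                rng.uniform(0.0, x_split, n_par), rng.uniform(0.0, h, n_par),
            ]) if n_par else np.empty((0, 2))
        cd4_mix = _cd4_mixture(tfh_share)
        cd4_labels = np.array(list(cd4_mix), dtype=object)
        cd4_probs = np.array([cd4_mix[k] for k in cd4_labels], float)
        b_labels = np.array(list(cfg.b_mixture), dtype=object)
        b_probs = np.array([cfg.b_mixture[k] for k in b_labels], float)
        for px, py in parents:
            for mean_n, labels, probs in (
                (cfg.offspring_cd20, b_labels, b_probs),
                (cfg.offspring_cd4, cd4_labels, cd4_probs),
            ):
                n = rng.poisson(mean_n)
                if n == 0:
                    continue
                pos = rng.normal([px, py], cfg.offspring_sigma, size=(n, 2))
                xs.append(np.clip(pos[:, 0], 0.0, np.nextafter(w, 0.0)))
                ys.append(np.clip(pos[:, 1], 0.0, np.nextafter(h, 0.0)))
                phenos.append(labels[rng.choice(len(labels), n, p=probs)])

    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        pheno = np.concatenate(phenos)
    else:
        x = np.empty(0)
        y = np.empty(0)
        pheno = np.empty(0, dtype=object)
    compartment = np.where(x < x_split, "stroma", "tumor").astype(object)
    marker_cols = {
        m: np.array([m in PHENOTYPE_MARKERS[p] for p in pheno], np.int8)
        for m in MARKERS
    }
    cells = pd.DataFrame({
        "x_um": x, "y_um": y, "compartment": compartment, **marker_cols,
        "phenotype": np.full(len(x), "unassigned", dtype=object),
    })
    return Field(field_id=field_id, field_class=field_class, cells=cells,
                 area_tumor_mm2=area_tumor, area_stroma_mm2=area_stroma,
                 width=w, height=h)


_PT_LEVELS = (("pT1", 0.51), ("pT2", 0.40), ("pT3", 0.09))
_PN_LEVELS = (("pN0", 0.92), ("pN1", 0.08))
_STAGE_LEVELS = (("1", 0.48), ("2", 0.35), ("3", 0.17))
_GRADE_LEVELS = (("well", 0.21), ("moderate", 0.67), ("poor", 0.12))


def _draw_level(levels, rng: np.random.Generator) -> str:
    names = [n for n, _ in levels]
    probs = np.array([p for _, p in levels])
    return names[rng.choice(len(names), p=probs / probs.sum())]


def simulate_patient(cfg: SimConfig, niche_high: bool,
                     rng: np.random.Generator,
                     patient_id: str = "P1") -> tuple[Patient, dict]:
    """One patient: 16 fields, clinical covariates, and the programmed truth.

    Returns the patient (survival not yet set; :func:`simulate_cohort`
    attaches it) together with the programmed phenotype
    ``{"niche_high": bool, "tfh_share": float}``.
    """
    lo, hi = cfg.tfh_share_high if niche_high else cfg.tfh_share_low
    tfh_share = float(rng.uniform(lo, hi))
    fields = []
    for i in range(cfg.n_im_fields):
        fields.append(simulate_field(
            cfg, "IM", rng, field_id=f"{patient_id}-IM{i + 1}",
            tfh_share=tfh_share, aggregates=niche_high))
    for i in range(cfg.n_center_fields):
        fields.append(simulate_field(
            cfg, "center", rng, field_id=f"{patient_id}-C{i + 1}",
            tfh_share=tfh_share, aggregates=False))
    patient = Patient(
        patient_id=patient_id,
        fields=fields,
        age=float(np.clip(round(rng.normal(62, 13)), 30, 92)),
        sex="male" if rng.random() < 0.56 else "female",
        pT=_draw_level(_PT_LEVELS, rng),
        pN=_draw_level(_PN_LEVELS, rng),
        pStage=_draw_level(_STAGE_LEVELS, rng),
        grade=_draw_level(_GRADE_LEVELS, rng),
        lvi=bool(rng.random() < 0.09),
    )
    return patient, {"niche_high": niche_high, "tfh_share": tfh_share}


def simulate_survival(niche_high, tfh_share, cfg: SimConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Survival outcomes for programmed phenotypes.

    Event times are exponential with hazard
    ``h0 * exp(beta_score * niche + beta_tfh * tfh_share)``; censoring is
    independent uniform on (0, ``censoring_months``).
    """
    niche = np.asarray(niche_high, float)
    tfh = np.asarray(tfh_share, float)
    hazard = cfg.baseline_hazard * np.exp(cfg.beta_score * niche
                                          + cfg.beta_tfh * tfh)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, cfg.censoring_months, size=len(niche))
    return pd.DataFrame({
        "os_months": np.minimum(t_event, t_cens),
        "os_event": t_event <= t_cens,
    })


def simulate_cohort(cfg: SimConfig,
                    analysis_config: AnalysisConfig | None = None,
                    ) -> tuple[Cohort, pd.DataFrame]:
    """A full synthetic cohort plus the programmed ground truth.

    The first ``round(n * fraction_niche_high)`` patients are niche-high
    (patient order carries no other meaning). Returns the cohort and a
    truth table (patient_id, niche_high, tfh_share) indexed by patient id.
    """
    rng = np.random.default_rng(cfg.seed)
    n_high = int(round(cfg.n_patients * cfg.fraction_niche_high))
    patients = []
    truths = []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        patient, truth = simulate_patient(cfg, niche_high=i < n_high,
                                          rng=rng, patient_id=pid)
        patients.append(patient)
        truths.append({"patient_id": pid, **truth})
    truth_df = pd.DataFrame(truths).set_index("patient_id")
    surv = simulate_survival(truth_df["niche_high"], truth_df["tfh_share"],
                             cfg, rng)
    for patient, (_, row) in zip(patients, surv.iterrows()):
        patient.os_months = float(row["os_months"])
        patient.os_event = bool(row["os_event"])
    cohort = Cohort(patients=patients,
                    config=analysis_config or AnalysisConfig())
    return cohort, truth_df
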