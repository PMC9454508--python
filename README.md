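# contexture

Spatial immune-contexture analysis of multiplexed-immunofluorescence cell
maps from tumor sections, built around the prognostic **CD20 cluster
score** for early-stage oral squamous cell carcinoma (OSCC).

Multiplex in situ immunofluorescence yields, per tumor, a set of 690 × 516 µm
multispectral image fields — half on the invasive margin (IM), half in the
tumor center — in which every segmented cell carries seven binary marker
calls (CD4, CD20, CD21, FOXP3, Tbet, BCL6, CK), a position, and a
tumor/stroma compartment label. `contexture` takes these per-cell tables and
computes:

- **Phenotyping** — marker-combination rules assigning each cell to
  Treg (FOXP3⁺CD4⁺), Th1 (Tbet⁺CD4⁺), Tfh (BCL6⁺CD4⁺), Tfr
  (FOXP3⁺BCL6⁺CD4⁺), other CD4, GC B (BCL6⁺CD20⁺), other B, fDC (CD21⁺),
  tumor (CK⁺), or other; double-lineage cells are excluded as ambiguous by
  default.
- **Region-stratified densities and fractions** — cells/mm² and subset
  fractions in the four regions IM-S, IM-T, C-S, C-T (invasive
  margin/center × stroma/tumor).
- **Nearest-neighbor analysis (NNA)** — per-cell nearest-neighbor distances
  and within-20 µm neighbor counts between phenotypes, averaged
  cell → field → patient.
- **The CD20 cluster score** — two components, *CD20 within CD20* and
  *CD20 within CD4* (mean neighbors within 20 µm of each CD20 B cell in the
  IM stroma), each dichotomized at the cohort median; the combined score is
  *high* only when both components are high.
- **TLS counting** — tertiary lymphoid structures as single-linkage
  lymphocyte clusters (CD4 T + CD20 B, 40 µm link) with ≥ 50 cells within
  ≤ 0.3 mm².
- **Cohort statistics** — Mann–Whitney U / Wilcoxon / chi-square / Spearman
  tests, Kaplan–Meier survival, log-rank, univariate and
  backward-elimination Cox models (Efron ties), a subgroup forest of the
  score across density/fraction/NNA strata, a three-scenario classification
  (score low; score high with low Tfh fraction; score high with high Tfh
  fraction), and a clinicopathological summary table.
- **A synthetic-cohort simulator** — Thomas-process B/T-cell niches on
  Poisson background with programmed Tfh enrichment and survival whose
  hazard depends on the programmed spatial phenotype, so the whole pipeline
  is testable end-to-end without patient data.

## Worked example

Simulate a 40-patient cohort (half carrying planted B/T niches), score it,
and run the statistics — either from Python or the `contexture` CLI:

```bash
contexture report --seed 5 --out out/
# report written to out (score/truth agreement 100%)
```

```python
from contexture import SimConfig, simulate_cohort, patient_table

cohort, truth = simulate_cohort(SimConfig(n_patients=40, seed=5))
table = patient_table(cohort)           # phenotypes, scores, TLS counts...
print(table[["cd20_within_cd20", "cd20_within_cd4",
             "cd20_cluster_score", "tls_count"]].head(2))
```

```
            cd20_within_cd20  cd20_within_cd4 cd20_cluster_score  tls_count
patient_id
P001                8.415590         7.057284               high          9
P002                6.968213         4.830309               high          5
```

Patient P001 has on average 8.4 other CD20 B cells and 7.1 CD4 T cells
within 20 µm of each of its IM-stromal CD20 B cells — both above the cohort
medians (2.02 and 1.67 here), so the combined score is *high* — and 9
detected TLSs across its 8 IM fields. On this run all 20 niche-high
patients score high and all 20 background-only patients score low
(agreement 100%); niche-low patients have 0 TLSs. At n = 40 with 7 observed
deaths, the univariate Cox fit of survival on the score is, as expected at
this sample size, wide and uninformative (95% CI 0.35–7.2); the programmed
protective hazard ratio of 0.3 is recovered in the calibration runs at
n = 300 (see below).

As a worked arithmetic example on published group-level data, the
clinicopathological table of the 75-patient OSCC cohort (43 score-low,
32 score-high) is bundled:

```python
from contexture.datasets import recompute_percentages
t = recompute_percentages()   # 28/43 alive -> 65%, 28/32 alive -> 88%, ...
```

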