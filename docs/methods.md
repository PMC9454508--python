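# Methods

This note documents the models, conventions and numerical choices behind
`contexture`, in the spirit of the methods documentation of statsmodels or
msprime: what is computed, under which assumptions, and where the design
was genuinely open.

## Cell maps and regions

A field is a fixed 690 × 516 µm observation window (one 20× multispectral
acquisition, 0.5 µm pixels) classified as invasive margin (IM) or tumor
center, and partitioned into tumor and stroma compartments. Coordinates are
continuous µm with the origin at the field's top-left corner and a
half-open window [0, W) × [0, H), which maps cleanly onto pixel grids
without off-by-one ambiguity. Fields are analyzed independently — they are
disjoint samples of the section, never stitched. Compartment labels and
compartment areas (mm²) are *inputs*: tissue segmentation happens upstream,
and cells straddling the tumor–stroma boundary are taken as labelled.
Marker calls are binary inputs as well; intensity gating is out of scope.

The four analysis regions are (field class × compartment): IM-S, IM-T,
C-S, C-T.

## Phenotyping

Lineages: CD20 → B cell, CD4 → helper T cell, CD21 alone → follicular
dendritic cell (fDC). CD4 subsets by transcription factors: FOXP3 → Treg,
Tbet → Th1, BCL6 → Tfh, FOXP3+BCL6 → Tfr; none → CD4-other; any remaining
double/triple combination (all involve Tbet) → CD4-multi, kept inside the
CD4 roll-up but reported separately. B subsets: BCL6⁺ → GC B, else B-other.
CK⁺ lineage-negative cells are tumor cells; everything else is "other".

Two genuinely open points are handled as configurable policies:

- **Double lineage** (e.g. CD4⁺CD20⁺). Default `exclude`: the cell is
  labelled ambiguous and omitted from every lineage count — exclusion
  avoids double counting when nothing justifies a preference. The
  alternative `priority` policy resolves CD20 > CD4 > CD21. CD21 on a
  CD20⁺ cell is *not* a conflict under either policy: follicular B cells
  express CD21, so the B lineage wins.
- Under `exclude`, the exclusive labels partition every field, which gives
  the invariants the test suite checks (counts sum to totals, subset
  fractions sum to 1).

## Densities, fractions, nearest-neighbor metrics

Density of a phenotype in a region is count/area per field, averaged
(unweighted) over the patient's corresponding fields; fields whose region
area is zero are skipped, and a patient with no usable field is flagged
missing rather than zero. Subset fractions divide subset count by
parent-lineage count (CD4 subsets over all CD4 T cells, B subsets over all
CD20 B cells) in the same region. By default the counts are pooled over
fields before dividing (ratio of sums): per-field ratios with tiny
denominators are unstable, and pooling keeps the fraction well-defined
whenever the patient has any parent cell. The per-field-mean alternative is
available as `fraction_mode="per-field"`.

The two NNA metrics are computed on cell centers with Euclidean distance
inside a single field:

- nearest distance (µm) from each source cell to the closest target cell;
- number of target cells within radius r (default 20 µm) of each source
  cell.

Conventions:

- **Self-exclusion**: when source and target phenotypes coincide, a cell is
  not its own neighbor. An isolated cell therefore contributes a count of
  0, and the same-label nearest distance needs at least two cells.
- **No edge correction**: metrics are computed per window exactly as
  observed. The simulator applies the same windowing, so synthetic and
  analytic values are compared like-for-like.
- **Averaging**: per-cell values are averaged within a field, then field
  values are averaged (unweighted) per patient over the fields where the
  metric is defined. The default patient-level region is IM-S.
- **Targets cross compartments**: source cells are restricted to the
  region's compartment, but their neighbors are searched in the whole
  field — a B cell sitting near the boundary genuinely has neighbors on
  both sides.

The fast paths use `scipy.spatial.cKDTree`; the test suite proves them
equal to an O(n²) all-pairs brute force on hundreds of random fields, and
checks rigid-motion invariance and monotonicity in the radius.

## The CD20 cluster score

Components, per patient: *CD20 within CD20* and *CD20 within CD4* — the
mean number of CD20 B-cell and CD4 T-cell neighbors within 20 µm of each
CD20 B cell in the IM stroma, averaged cell → field → patient. The naming
reads "CD20 (neighbors counted) within (20 µm of) CD4"; since the phrase is
ambiguous about direction, the transposed variant (CD4 T cells as source)
is available via `score_direction="cd4-source"`, but the default keeps CD20
B cells as the source for both components so they share a denominator
population.

Each component is dichotomized at its cohort median: *high* means strictly
above the median, so ties at the median are *low* — the conservative
reading of "median as cut-off" that keeps the high group strictly above it.
The combined ordinal score is high only when both components are high.
Patients with no IM-S CD20 B cell get components of 0 rather than missing:
absence of B-cell clustering is informatively low, and the score stays
defined cohort-wide. Dichotomization is invariant under adding a constant
to all patients, and a degenerate all-equal cohort labels everyone low with
a warning.

## TLS detection

The package automates what is usually a manual count: a tertiary lymphoid
structure is operationalized as a single-linkage cluster of lymphocytes
(CD4 T plus CD20 B cells) in an IM field at a 40 µm linking distance, with
at least 50 members and a convex hull of at most 0.3 mm². The linking
distance is a design choice — the manual criterion (~>50 cells per
0.3 mm²) implies no linkage rule — and is configurable. Because 0.3 mm²
corresponds to a disc of radius ≈ 309 µm, nearly a whole field, the hull
bound rarely binds and the count threshold dominates. Clusters are computed
as connected components of the ≤ 40 µm pair graph (exactly single linkage
cut at 40 µm), so the result is invariant to cell ordering. The patient's
TLS count sums over IM fields; fields are non-adjacent samples and are
never merged.

## Cohort statistics

All tests are two-sided.

- **Mann–Whitney U**: exact enumeration of all rank splits when both groups
  have ≤ 8 observations (ties via midranks; two-sided p as the null
  probability of a U at least as far from its mean); otherwise the tie- and
  continuity-corrected normal approximation. The continuity correction
  keeps the two regimes within 0.02 of each other at the switchover.
- **Wilcoxon signed-rank**: zeros dropped; exact enumeration of the 2ⁿ sign
  patterns for ≤ 15 nonzero pairs, normal approximation beyond.
- **Chi-square**: Pearson without continuity correction by default (Yates
  available). On the bundled 5-year-survival 2 × 2 (28/15 vs 28/4) Pearson
  gives p ≈ 0.027 and Yates ≈ 0.053; the corresponding published p of
  0.034 sits between the two and its exact variant is not reconstructible,
  so both are reported and neither is forced to agree.
- **Survival**: Kaplan–Meier product limit for horizon estimates (60
  months = 5 years), plus the crude alive fraction among patients whose
  follow-up reached the horizon or who died first — the two coincide
  exactly when nobody is censored early, and both are reported because
  group summaries in the literature mix the two conventions. Log-rank
  across k groups. Cox proportional hazards via lifelines with Efron tie
  handling; degenerate fits (separation, no events) are flagged
  non-estimable, never raised.
- **Model building**: candidates enter multivariate Cox when their
  univariate p < 0.1; backward elimination then repeatedly removes the
  covariate with the largest likelihood-ratio removal p while that p ≥
  0.10. An empty final model is a reported outcome. Note a calibration
  consequence of this design: a pure-noise candidate survives screening
  with probability ≈ 0.1 and, once screened, is usually retained (its
  removal p mirrors the screening p), so with k noise candidates the final
  model is empty with probability ≈ 0.9ᵏ.
- **Subgroup forest**: each density/fraction/NNA stratifier is
  dichotomized at its cohort median (same convention as the score); within
  each stratum a univariate Cox of survival on the score is fitted, flagged
  non-estimable when a score level has no events.
- **Scenarios**: 1 = score low (regardless of Tfh); 2 = score high, Tfh
  fraction ≤ cohort median; 3 = score high, Tfh fraction above it. A
  high-score patient with an undefined Tfh fraction is unclassifiable.
- **Summary table**: percentages are rounded half away from zero
  (28/32 = 87.5 % → 88 %).

## The synthetic-cohort generator

The generator emulates the data structure the analysis assumes — it is the
package's study condition, not a fitting device.

- **Geometry**: 8 IM + 8 center fields of 690 × 516 µm; stroma as a
  vertical strip (fraction 0.5 in IM, 0.4 in center fields), making
  compartment areas exact and densities analytically checkable; curvature
  of the real boundary adds nothing testable.
- **Background**: homogeneous Poisson per phenotype per compartment.
  Defaults (cells/mm², IM stroma): Treg 60, Th1 50, Tfh 30, Tfr 3,
  other CD4 150, GC B 10, other B 80, fDC 5, CK⁺ 50, other 200; the tumor
  compartment is immune-poorer and dominated by CK⁺ cells (2000/mm²);
  center-field immune intensities are halved. These orders of magnitude
  mirror a moderately infiltrated carcinoma with stroma-concentrated
  lymphocytes; the background lymphocyte density (~380/mm² stromal) is
  deliberately subcritical for 40 µm-link percolation, so background alone
  does not form ≥ 50-cell clusters.
- **Niches**: a Thomas process in the IM stroma — Poisson parents
  (8/mm² of stroma) with Poisson(80) CD20 and Poisson(60) CD4 offspring
  displaced by an isotropic Gaussian (σ = 25 µm) around *shared* parents,
  implementing B/T co-clustering; offspring are clipped to the window and
  take the compartment of their final position. `parents_per_field` places
  a fixed number of well-separated parents (jittered grid, 80 µm margins)
  for planted-recovery experiments; with σ = 25 µm and a 40 µm link,
  "well separated" requires parent separations above ≈ 190 µm, which the
  345 × 516 µm stroma strip accommodates for up to two parents per field.
- **Subset structure**: CD4 offspring and background follow a mixture
  whose Tfh share is a per-patient enrichment parameter (drawn
  U(0.15, 0.45) for niche-high patients, U(0.03, 0.15) for niche-low,
  straddling the 0.10 baseline share), with the remaining mass rescaled
  over Treg/Th1/Tfr/CD4-other; B cells split 15 % GC B / 85 % B-other.
- **Survival**: exponential event times with hazard
  h₀·exp(β₁·I[niche-high] + β₂·TfhShare), h₀ = 0.006/month (≈ 70 % 5-year
  survival at baseline), β₁ = log 0.3, β₂ = −1, independent uniform
  censoring on (0, 120) months. The closed-form hazard makes Cox-recovery
  targets analytic.
- **Determinism**: a single `numpy.random.Generator` seeded from
  `SimConfig.seed` drives everything; identical seeds give byte-identical
  CSVs.

What the generator does *not* emulate: staining noise and segmentation
error (marker flags are exact by construction), irregular tissue
boundaries, spatial correlation between fields of one section, and
non-exponential hazards. Passing tests therefore demonstrate correctness of
the computational pipeline under its stated assumptions, not robustness of
the biology to measurement noise.

## Problem sizes in the shipped checks

The bundled verification runs use sizes chosen to make Monte-Carlo error
negligible relative to the tested effects while staying quick on one CPU:
200 random fields (≤ 500 cells) for oracle equivalence, a 40-patient
cohort for planted-niche discrimination, 24 planted aggregates for TLS
recovery, and 200 simulated cohorts of n = 300 for Cox calibration and
null log-rank uniformity.

## Known limitations

- The TLS surrogate is a clustering heuristic; it approximates, and was
  not validated against, expert manual counting on images.
- GC B cells are defined by BCL6⁺CD20⁺ alone — broader than the classical
  CD23/AID/Ki-67-based definition.
- The published summary table bundled for the worked example was
  hand-rounded at source (12.5 % appears as both 12 % and 13 % in
  different rows), so no deterministic rounding rule reproduces every
  printed cell; the half-away-from-zero rule reproduces 34 of 38.
- Backward elimination inherits the usual instabilities of stepwise
  selection; it is provided because it is the field's convention, not as a
  recommendation.
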