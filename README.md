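# spatialtme

Spatial tumour-microenvironment analysis for multiplex immunofluorescence
(mIF) imaging: from stained tissue fields (or typed cell-coordinate
tables) to Delaunay cell-graph spatial features, nucleus-segmentation
quality metrics, and an immune-related risk score (IRRS) for
disease-free survival.

The package is aimed at computational pathology and tumour-immunology
groups who profile immune infiltrates with two five-marker mIF panels on
serial sections (panel 1: CD38, CD20, CD4, FOXP3, CD66b; panel 2: PD-L1,
CD163, CD8, CD68, CD133 over a DAPI counterstain) and want to quantify
not only *how many* cells of each phenotype a tumour contains, but *how
they are arranged* — and whether that arrangement predicts recurrence.
Everything is exercised end-to-end on synthetic scenes and cohorts with
known ground truth, so the full pipeline is testable without any imaging
data.

## What it computes

**Cell detection and typing.** RGB fields are split into channels; each
marker's stained area is thresholded at its positivity level X with
small-object denoising; nuclei are detected on the nuclear channel by a
classical smoothing / thresholding / distance-transform-watershed
detector (the detector is a pluggable interface — a learned star-convex
model can be dropped in); a cell is positive for a marker iff its nucleus
centroid falls inside the marker's mask. Staining strength is binned at
X / 2X / 3X into `+`, `++`, `+++` and summarised by the H-score

    H = %(+) × 1 + %(++) × 2 + %(+++) × 3   ∈ [0, 300],

together with densities (cells/mm²) and percentages per tissue
compartment (tumour nest TN vs. tumour stroma TS).

**Spatial features.** Cells of one panel on one image are connected by
the Delaunay triangulation. Each edge, with its Euclidean length, is
tallied into the unordered marker-pair category of its endpoints — 15
categories per 5-marker panel (C(5,2) + 5), 30 in total — giving per
image a connection count n_c and mean connection length L̄_c per
category: 60 features, plus their within-image relative forms

    pct_len(A,B) = L̄(A,B) / (Σᵢ nᵢ·L̄ᵢ / Σᵢ nᵢ),   pct_num(A,B) = n(A,B) / Σᵢ nᵢ.

Multi-positive cells (e.g. CD8+CD133+) enter as single nodes carrying
their full marker set. Slide-level features are averaged per patient.

**Segmentation evaluation.** Predicted nucleus masks are matched to
ground truth one-to-one by descending IoU with matches kept iff
IoU > 0.6; detection coverage, precision, recall, F1 = 2PR/(P+R) and
binary pixel accuracy are reported.

**Association statistics.** Pairwise-complete Spearman correlations
between quantitative and spatial variables; rank-sum / Kruskal–Wallis
group comparisons; chi-square (Fisher fallback) for categorical
contrasts.

**IRRS survival model.** With an event-stratified 70/30 split, candidate
features pass a univariate Cox screen (p < 0.05), then a LASSO-penalized
Cox model tuned by 10-fold cross-validation at minimal partial-likelihood
deviance selects the robust prognosticators. Each patient's score is

    IRRS = Σ_z ln(HR_z) · proportion_z,

with HR_z the univariate training-cohort hazard ratio of variable z. The
score is dichotomised at the training-cohort cutpoint maximising the
log-rank statistic over score quantiles, and that identical cutoff is
applied to the test and entire cohorts. Validation reports Kaplan–Meier
curves with the log-rank test, covariate-adjusted hazard ratios, and
IPCW time-dependent AUC at 1/3/5 years.

## Worked example

`examples/` contains one short script per capability. The end-to-end
survival example:

```sh
python examples/05_irrs_cohort.py
```

prints (numbers from the run above):

```
cohort: 553 patients, 239 events (43.2%)
stratified split: 387 train / 166 test

selected 10 of 35 candidates (9/10 truly prognostic); cutoff 1.143

test cohort: log-rank p = 4.94e-26
adjusted HR high vs. low IRRS = 11.02 (95% CI 6.16-19.73)
time-dependent AUC: 1y 0.923, 3y 0.920, 5y 0.910
```

The simulated cohort has 10 truly prognostic descriptors hidden among 35
candidates; the pipeline recovers 9 of them on the training cohort alone,
and the resulting score separates held-out patients into risk groups
whose adjusted hazard ratio is far above 1 — the parameter-recovery
behaviour the synthetic generator is designed to make checkable. The
other examples walk through scene simulation and cell typing (`01`),
the 120-column spatial feature vector (`02`), IoU-matched segmentation
scoring (`03`) and the association statistics (`04`).

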