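# Methods

This note records the models, defaults and design choices behind each
stage of the pipeline, and what the synthetic-data tests do and do not
demonstrate about real mIF data.

## Coordinate and unit conventions

Positions are 0-based real-valued pixel coordinates, origin top-left,
`x` = column, `y` = row, pixel centre at the integer coordinate. All
spatial features (connection lengths) are reported in pixels; only cell
densities are converted to mm² via `microns_per_pixel` (default 0.5,
a typical 20× whole-slide scan resolution). Default synthetic scene size
is 1024 × 1024 px in the generator API (tests use smaller fields); scene
size is a parameter throughout.

## Synthetic scenes

The generator emulates the structure the analysis assumes, not the
physics of staining.

* **Cell placement** is a spatial point process inside an arbitrary
  binary region mask: homogeneous Poisson (count ~ Poisson(intensity ×
  foreground area), positions uniform over foreground pixels), a
  Thomas-style cluster process (Poisson parents, Gaussian offspring with
  `cluster_sigma`, offspring falling outside the mask discarded — the
  realised intensity is therefore slightly below nominal near mask
  edges), or simple sequential inhibition with a hard-core radius.
  Clustered placement produces the "closer and more connected" regime,
  inhibition the "farther and less connected" regime.
* **Phenotypes** are drawn from a mixture over single-marker identities
  (probabilities summing to ≤ 1; the remainder is marker-negative), then
  co-expression rules add secondary markers with stated probabilities,
  producing multi-positive cells such as CD8+CD133+. Intensity levels
  `+`/`++`/`+++` are drawn independently per positive marker
  (default 0.3/0.4/0.3).
* **Rendering** draws nuclei as discs (default radius 6 px, amplitude 200)
  in the blue channel and each positive marker as a disc in that marker's
  component map at 1.4X / 2.5X / 3.5X of its positivity threshold
  (default X = 60 on the 0–255 scale) — amplitudes chosen mid-band so the
  centroid read-out stays in the intended bin after the Gaussian PSF
  (default σ = 1 px). `noise_level` adds small bright speckles (1–2 px
  radius) per marker map for denoising tests. Because several markers of
  a panel share a composite colour channel, the renderer also returns
  per-marker component maps — the analogue of spectrally unmixed
  single-antigen images — and marker detection runs on those; the
  composite RGB is for visualisation and channel-splitting contracts.
  The two panels are rendered as separate serial-section scenes sharing
  region masks, so cross-panel spatial features cannot exist, consistent
  with the 30-category schema.
* **Not modelled:** spectral unmixing, autofluorescence, tyramide
  chemistry, nucleus shape variation, staining gradients, tissue folds.
  Passing round-trip tests therefore demonstrates the pipeline's
  correctness on idealised input, not detector robustness on real slides.

## Synthetic cohorts

Survival times are exponential with individual hazard
`exp(x·β) / baseline_hazard_scale` (default scale 1800 days, giving a
study-like event horizon); censoring is independent exponential with its
rate solved numerically so the expected censored fraction equals
`censoring_rate`. The study-scale cohort used for recovery checks has
553 (or 550) patients, 35 standardized candidate descriptors of which 10
carry true |ln HR| drawn from [0.4, 1.0] with alternating sign, and
censoring_rate 0.566 targeting a ~43% event fraction. These are the
fixed study conditions of the recovery tests, not tuning knobs. Effects
of this size on unit-variance features are strong; the reported AUCs
(~0.9) and hazard ratios (~10) on synthetic data are accordingly higher
than anything expected from real cohorts.

## Detection pipeline

* **Denoising** of marker masks removes connected components smaller
  than `min_object_px` (default 10 px); thresholding is `value ≥ X`.
* **Nucleus detection** (classical default): Gaussian smoothing
  (σ = 2 px), absolute or Otsu threshold, small-object removal,
  Euclidean distance transform, peak seeds with `min_distance` (default
  5 px, of the order of the nucleus radius), and watershed on the negated
  distance. Deterministic on fixed input. Any callable with the same
  signature can replace it; the pipeline's contribution is everything
  around the detector.
* **Typing rule:** a cell is positive for a marker iff its centroid
  pixel lies in the marker's mask — the minimal testable reading of
  intersecting cell coordinates with stained regions. The intensity
  read-out for binning is the component-map value at the centroid pixel
  (a mean-over-nucleus variant would be a straightforward extension; the
  centroid read-out is the default because it needs no segmentation of
  the marker signal). Blur can pull a mask-positive centroid's value
  marginally below X; such cells clamp to the low bin rather than
  losing positivity.
* **H-score** percentages are taken over *all* cells of the compartment
  (negatives contribute to the denominator only), so the score spans the
  full 0–300 range.
* The quantitative summary emits every computable phenotype × region ×
  {count, density, percentage, H-score} combination rather than a fixed
  66-variable list, because no canonical enumeration of the latter
  exists.

## Spatial graph

* Exactly co-located points are collapsed into one node carrying the
  union of marker sets before triangulation; each edge then increments
  every unordered marker pair formed from its endpoints' label sets.
  This preserves the contribution of multi-positive cells without the
  zero-length duplicate-point artefacts that concatenating per-marker
  coordinate lists would create. It is an interpretation: the
  alternative (duplicated nodes) degenerates the triangulation.
* Degeneracies: n ≤ 1 → no edges; n = 2 → the single segment; fully
  collinear inputs → the chain of consecutive segments along the
  principal axis; other Qhull failures retry once with a deterministic
  ±10⁻⁶ px jitter from a fixed seed.
* Normalization denominators (total edge count, edge-weighted overall
  mean length) are computed per image over all 30 categories of both
  panels' graphs; patient aggregation averages the already-normalized
  values, missing-aware (a category absent on one slide is ignored in
  that feature's mean; absent on all slides stays missing). Zero-fill
  averaging is the documented alternative; missing-aware was chosen so
  sparse slides do not drag patient means toward zero.

## Segmentation evaluation

Matching is greedy in descending IoU (ties: smaller GT label, then
smaller predicted label), one-to-one, keeping pairs with IoU strictly
greater than 0.6. Above threshold 0.5 an instance can overlap at most
one partner that much, so the greedy matching equals the optimal
assignment; tests verify this against a Hungarian oracle. Pixel accuracy
is binary foreground/background (not per-instance), which on
background-dominated fields yields values near 1 by construction.

## Statistics

Spearman correlations use average ranks for ties and pairwise-complete
observations; constant variables and pairs with fewer than 3 complete
observations are flagged missing rather than reported. Group comparisons
default to rank-based tests (Mann–Whitney U for two groups,
Kruskal–Wallis H beyond), with Welch's t-test as an explicit option.
Chi-square is Pearson without continuity correction; 2×2 tables with any
expected count below 5 switch to Fisher's exact test. No
multiple-testing correction is applied to the correlation matrix.
Reported correlations are signed Spearman rho throughout.

## IRRS survival model

* **Split:** largest-remainder stratified allocation guarantees the
  training cohort is exactly round(0.7 n) overall with each stratum
  within one patient of its share (553 → 387/166).
* **Screening** is unadjusted univariate Cox (Efron ties) at two-sided
  p < 0.05; candidates that fail to converge or are constant are
  excluded. A covariate-adjusted screen is a one-line switch via
  `multivariate_cox`.
* **LASSO-Cox:** penalty path log-spaced four decades down from full
  shrinkage (up to 100 values, as realised by the coordinate-descent
  path); 10-fold CV stratified by event status; fold deviance is the
  verification form −2·(ll(all at β₋ₖ) − ll(without fold k at β₋ₖ))
  with Breslow partial likelihood. The default selection rule is the
  deviance minimum. Note that the minimum-deviance rule over-selects by
  design — on the standard recovery scenario it retains all 10 true
  variables plus ~10–15 noise variables, matching R glmnet's
  `lambda.min` on identical data — so a `rule="1se"` option (strongest
  penalty within one SE of the minimum; selects ~10 variables with ≤ 2
  false on the same scenario) is provided for sparser models. In the
  full pipeline the univariate screen shrinks the candidate pool first,
  which in practice brings the min-rule selection close to the true
  support.
* **Weights** are the univariate training-cohort ln(HR) of each selected
  variable — deliberately *not* the penalized coefficients, matching the
  score's definition. `proportion_z` is the patient's value of variable
  z on its proportion scale (percentages/100; normalized spatial
  features as computed); for the synthetic standardized descriptors it
  is the feature value itself.
* **Cutpoint:** scan of score quantiles between the 10th and 90th
  percentile (81 candidates), maximising the log-rank χ², both groups
  ≥ 10% of the cohort; ties resolve to the lowest cutoff. The scan
  involves no multiple-testing correction, so the training-cohort χ² at
  the chosen cutoff is optimistically biased — which is why validation
  is reported on the held-out cohort with the cutoff transferred
  verbatim.
* **Validation:** multivariable Cox adjusting for sex, age, T stage,
  N stage, vascular embolus and dissected-lymph-node count; a
  monotone-likelihood failure (possible when a very strong score
  perfectly orders a small cohort's events) retries with a light ridge
  penalty (0.1) and warns. Time-dependent AUC is
  cumulative-case/dynamic-control with IPCW; horizons at 365/1095/1825
  days; horizons beyond follow-up, or without prior events, are missing.
  DeLong's comparison of two correlated AUCs is exposed as a thin
  utility.

## Problem sizes in the test suite

Tests run scenes of 200–512 px with ~30–180 cells, cohorts of 100–5000
patients, 100-seed Monte-Carlo checks for point-process moments and Cox
coverage, and 1000-simulation null calibrations for the rank and
log-rank tests — sizes chosen so the whole suite completes in about a
minute on one CPU while keeping Monte-Carlo standard errors well inside
the asserted tolerances.

## Known limitations

* The classical nucleus detector under-segments touching nuclei at high
  packing densities; round-trip guarantees hold only for well-separated
  nuclei (hard-core placement).
* Scene realism is deliberately minimal (see above); threshold X is a
  configuration input, not estimated from images.
* The exponential survival model has constant baseline hazard; the
  pipeline itself is distribution-agnostic, but recovery tolerances were
  set under this model.
* Censoring in the generator is independent exponential; informative
  censoring is not modelled.
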