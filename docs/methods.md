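# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `eccpipe`.

## Presence-background niche model

The per-ecomorph model is a Gibbs distribution over landscape cells,
`q_λ(x) = exp(λ·f(x))/Z`, whose feature expectations are pulled toward the
presence sample by maximizing the L1-penalized presence log-likelihood.

* **Features.** Linear and quadratic terms of each climate layer,
  standardized with background-sample mean and standard deviation.  This is
  a deliberate simplification relative to full Maxent feature machinery
  (hinge/product/threshold features are not implemented): linear+quadratic
  keeps the problem convex and is sufficient to express the unimodal
  responses the generator produces.  Layers that are constant over the
  background are dropped with a warning.
* **Elevation is not a model feature by default.**  Ensembles fit on the
  climate layers only, so the downstream ECC–elevation statistics relate
  community completeness to a variable the niche models never saw directly;
  elevation acts only through the climate it shapes.  `fit_ensemble` takes
  `feature_layers` to override this.
* **Penalty.** `β_j = β₀ · s_j/√m` with `s_j` the presence-sample standard
  deviation of feature j and m the presence count; `β₀ = 1` by default
  (`RunConfig.regularization`).  This mirrors the usual scaling principle
  (penalties shrink as presence information grows) without copying any
  tuned table.  A fit may legitimately return λ = 0 when the niche signal
  is weaker than the penalty — the suitability map is then uniform, which
  downstream code treats as "no detectable constraint".
* **Optimization.** λ is split as u − v with u, v ≥ 0, making the L1 term
  linear and the problem smooth with box constraints; L-BFGS-B runs to
  tight tolerances and a damped-Newton polishing pass on the active
  coordinates pushes the subgradient residual below 1e-5.  Every fit is
  verified against the stationarity conditions (|grad_j + sign(λ_j)β_j|
  small for active weights, |grad_j| ≤ β_j for inactive ones) and raises
  `ConvergenceError` with diagnostics otherwise.
* **Logistic output.** With H the entropy of q over the background, the
  map reports `expit(H + log q(x))`, which scores exactly 0.5 at a
  "typical" site (q = e^(−H)).  The choice calibrates the probability of
  presence at typical conditions to τ = 0.5.
* **Ensembles.** Each replicate re-draws a 75/25 train/test split and a
  fresh background sample from its own seeded stream (the protocol being
  re-implemented does not state whether background was fixed across
  replicates; re-drawing was chosen because it propagates background
  sampling variance into the ensemble).  Replicate logistic maps are
  combined cellwise by the arithmetic mean (median available via
  `combine="median"`); how the original 100 replicate models were combined
  is unstated, and rank-based downstream statistics are insensitive to
  this choice.  Held-out AUC is the rank (Mann–Whitney) statistic of test
  presences against the replicate's background sample, ties counted 0.5.

## ECC and overlap

Suitability maps are min-max rescaled over the island's own valid cells
("equal scaling between ecomorphs") and summed with configurable
non-negative weights (default 1, giving the documented [0, 6] range for
six ecomorphs; the stated range implies unit weights, so they are the
default rather than a free parameter).  A constant map cannot be min-max
scaled and is an explicit error.

Schoener's D normalizes both surfaces to sum to 1 over the **intersection**
of their valid cells (whether the original analysis used union or
intersection is unstated; intersection avoids imputing values where a
surface is undefined, and the excluded-cell count is logged).  For
cross-island comparisons each source island's model is projected onto every
island, the concatenated archipelago-wide vector is min-max scaled over
that common extent, and D is computed between these cross-fitted surfaces.
One deviation from the original protocol: models are fitted with their own
island's background rather than an archipelago-wide background (the
fit operates on a single environmental stack); the cross-island projection
step is unchanged, and the qualitative overlap contrasts survive this
choice.

## Correlations on decorrelated subsamples

Neighbouring raster cells are strongly redundant, so p-values computed on
all ~3 000 cells per island would be meaninglessly small.  Following the
cluster-subsampling idea: a correlation-matrix PCA reduces the climate
layers to BioPCs (Kaiser criterion, eigenvalue > 1; the PCA is computed on
the pooled all-island point table so BioPC axes are comparable across
islands — a per-island PCA would rotate differently on every island);
k-means (k = 100 by default, seeded, scikit-learn) clusters the BioPC
scores, and 1 or 10 points per cluster are drawn uniformly without
replacement.  Clusters smaller than the quota contribute all their points
with a warning.  The reduced set gets a Spearman correlation with a
two-sided permutation p-value, `p = (1 + #{|r_perm| ≥ |r_obs|})/(1 + B)`,
with B ≥ 1000 (default 100 000 at the function level; the pipeline uses
`RunConfig.n_permutations`, default 9 999).  A permutation test was chosen
because the original "manually calculated" p-values are not otherwise
specified; it is distribution-free and reproducible under a seed.

BioPCs are classified as elevation-dependent when |Pearson r| against
elevation reaches a threshold (default 0.5, configurable): the original
criterion for "elevation-correlated" is unstated, so the magnitude
threshold is explicit configuration rather than hidden behaviour.

## Model competition

Candidates per island: global (elevation + all BioPCs), elevation-only,
all-BioPCs, elevation-dependent BioPCs, elevation-independent BioPCs; when
every BioPC is elevation-dependent the partition models collapse and are
replaced by one single-BioPC model per component.  Fits are Gaussian OLS
(statsmodels) — the model family for ECC is never named in the source
protocol, and OLS with ML variance is the minimal reading for a bounded
continuous sum.  AICc uses the exact finite-sample formula with
k = predictors + intercept + variance; an exact fit is handled by flooring
the ML variance at 1e-12.  Averaging is full-set shrinkage averaging
(absent coefficients enter as 0) over the entire candidate set once the
top-two ΔAICc < 3, with unconditional standard errors combining
within-model variance and between-model spread, z-based 95% CIs, and
relative importance = summed weights of models containing the variable.
Conditional (Δ-cutoff) averaging was considered and not made the default
because reported importances cover every variable.

## Traits

The elevational constraint of an (ecomorph, island) pair is the Spearman
correlation between its ensemble-mean suitability and elevation over all
valid cells; because the statistic is rank-based it is identical for raw
logistic output and min-max-scaled maps (asserted by a test).  Constraints
are correlated against the fixed ordinal mass ranking (twig = 1 …
crown-giant = 6) with a seeded permutation p-value; actual mass values are
not needed.  Outlier handling is assistive only: a Theil–Sen line of
constraint on rank is fitted and rows whose residual departs from the
median by more than 1.5 IQR are *flagged*; exclusion is always an explicit
user action recorded in the output.

## The synthetic-landscape generator

The generator stands in for the real occurrence/climate data and defines
the study conditions for every recovery test.

* **Topography.** Elliptical island mask; elevation is a sum of 1–3
  Gaussian peaks with heights 300–520 m.  Heights were chosen once so that
  total relief stays below the lightest ecomorph's optimum: community
  completeness then rises monotonically with elevation, the montane
  pattern the analysis targets.  Gaussian bumps rather than fractal
  terrain: simpler, and sufficient to create an elevational gradient.
* **Climate.** Two correlated layer pairs.  The temperature pair
  (`temp_mean`, `temp_range`) follows linear lapse rates off elevation
  plus white noise on mountain islands; the wet pair (`precip`,
  `moisture`) consists of smoothed Gaussian random fields sharing 80% of
  their smooth component, independent of elevation.  Every random field
  carries a 30% white-noise "nugget" (cell-level microclimate), which is
  both realistic and statistically important: without it, any smooth
  residual in a regression can be proxied by the (equally smooth) terrain.
* **Suitability.** Gaussian response `exp(−(d−μ)²/2σ²)` along a driver.
  On mountain islands the driver is elevation, with optima strictly
  decreasing in mass rank (1050 m for twig down to 0 m for crown-giant)
  and breadths strictly increasing (180 m up to 650 m): light ecomorphs
  are narrow high-elevation specialists, heavy ones near-unconstrained
  generalists.  On flat-climate islands the driver is the standardized
  precip+moisture sum (the "wet axis") with an analogously graded design,
  and the temperature pair decouples from elevation — emulating a
  low-relief island whose climate, and therefore whose community
  completeness, is elevation-independent.  The flat island hosts four
  ecomorphs (grass-bush and trunk absent).
* **Occurrences.** Cells are drawn without replacement with probability
  proportional to true suitability, so presences are unique cells by
  construction, mirroring the deduplication applied to real locality
  records.  Default 150–200 occurrences per ecomorph per island (roughly
  30 unique localities for each of ~5–7 pooled species).

What the generator does *not* emulate: real Antillean geography, real
WorldClim values or their 19-layer covariance structure, sampling bias
along roads and coasts, georeferencing error, or species-level structure
within ecomorphs.  Passing recovery tests therefore demonstrate that the
pipeline's statistics recover known generating structure under realistic
noise — not that the original empirical values are reproduced.

## Problem sizes and determinism

Tests and the acceptance script run the pipeline at reduced scale chosen
to keep the whole suite fast while leaving the statistics well-powered:
islands of 48×60 to 64×80 cells (~2 000–3 300 valid cells), 120–150
occurrences per ecomorph, 2–8 replicate models with 800–1 500 background
points, k-means with 40–100 clusters, 1 000–20 000 permutations.
`RunConfig` defaults stay at the full protocol (100 replicates, 5 000
background points, k = 100).  Monte-Carlo recovery checks use 20
independent seeds.  All randomness flows from explicit integer seeds
through `numpy.random.SeedSequence` spawning, so every stage — including
k-means initialization and permutation tests — is bit-for-bit reproducible.

## Known limitations

* No hinge/threshold/product features, clamping, or MESS-style
  extrapolation flags; projections onto environments outside the training
  range extrapolate the quadratic features quietly.
* Rasters must be co-registered; there is no projection/reprojection
  support, and only the ESRI ASCII grid format is read and written.
* The flat-climate model competition is genuinely marginal when run
  through the full fitted-ENM chain: fitted ECC carries smooth nonlinear
  structure that a smooth terrain surface can partially proxy, so the
  global model sometimes edges out the no-elevation model on a flat
  island — the same near-tie the original Jamaica analysis shows
  (weights 0.33 vs 0.67).  The model-selection recovery tests therefore
  simulate ECC directly from the known drivers.
* Gaussian OLS for ECC ignores that ECC is bounded; with strongly skewed
  ECC distributions a GLM would be preferable (out of scope).
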