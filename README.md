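# eccpipe

Presence-background niche models, **ecomorph community completeness (ECC)**
surfaces, niche overlap, and trait-filtering statistics on island
landscapes — with a first-class synthetic-landscape generator so the whole
analysis is testable end to end with known ground truth.

## The scientific problem

Insular adaptive radiations (the canonical case being Greater Antillean
*Anolis* lizards) repeatedly evolve the same set of **ecomorphs** —
ecology/morphology/behaviour specialists such as *twig*, *grass-bush*,
*trunk*, *trunk-crown*, *trunk-ground* and *crown-giant* anoles.  Although
every structural microhabitat exists nearly everywhere, the full ecomorph
community is *not* present everywhere.  This package implements a pipeline
that asks whether broad-scale **environmental filtering** explains where
communities are complete, and whether the filter acts on **body mass** as a
functional trait:

1. Fit a presence-background (maximum-entropy) niche model per ecomorph per
   island, as a replicate ensemble with held-out AUC.
2. Rescale each suitability map to [0, 1] and sum them into an ECC surface
   (range [0, 6] with six ecomorphs and unit weights).
3. Quantify niche overlap of cross-fitted suitability/ECC surfaces between
   islands with Schoener's D.
4. Correlate ECC with elevation — at raster level (Pearson R, OLS slope and
   intercept) and on a decorrelated reduced point set (k-means-stratified
   subsample of the climate-PCA scores, Spearman r with a permutation
   p-value).
5. Compete linear ECC–environment models (elevation, bioclimatic principal
   components, and their elevation-dependent/independent partitions) by
   AICc, with Akaike weights and full-set model averaging.
6. Compute each ecomorph's **elevational constraint** — the Spearman
   correlation between its suitability surface and elevation — and test its
   relationship with the ordinal body-mass ranking
   twig < grass-bush < trunk < trunk-crown < trunk-ground < crown-giant.

## The core models

**Niche model.** Over landscape cells x with features f(x) (linear and
quadratic terms of each climate layer, standardized on the background
sample), the model is the Gibbs distribution

    q_λ(x) = exp(λ·f(x)) / Z,   Z = Σ_background exp(λ·f(x)),

fit by maximizing the L1-penalized presence log-likelihood
`(1/m) Σ_presence λ·f(x) − log Z(λ) − Σ_j β_j |λ_j|` with
`β_j = β₀ s_j / √m`.  The problem is convex and solved exactly via a
split-variable L-BFGS-B with Newton polishing; each fit is verified against
subgradient stationarity conditions.  Logistic output calibrates "typical"
sites to 0.5: with H the entropy of q over the background,
`p(x) = 1 / (1 + exp(−(H + log q(x))))`, so p = 0.5 exactly where
q = e^(−H).

**Overlap.** Schoener's `D(p_a, p_b) = 1 − ½ Σ_x |p_a(x) − p_b(x)|` after
normalizing both surfaces to sum to 1 over the shared valid cells.

**Model competition.** `AICc = −2 logLik + 2k + 2k(k+1)/(n−k−1)`,
Akaike weights `w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2)`; a top weight ≥ 0.9
marks a single most parsimonious model, Δ < 3 between the two best models
triggers full-set (shrinkage) model averaging with unconditional standard
errors.

## Worked example

```python
from eccpipe import make_archipelago, fit_ensemble, ecc, RunConfig
from eccpipe.envstats import correlation_pipeline
from eccpipe.traits import constraint_table, trait_correlation

stacks, occs, truth = make_archipelago(seed=11, n_islands=2,
                                       scenario="mountain",
                                       shape=(48, 60), n_occurrences=120)
cfg = RunConfig(seed=11, n_replicates=5, n_background=1000,
                kmeans_k=50, points_per_cluster=2, n_permutations=5000)

suitability = {isl: {} for isl in stacks}
for occ in occs:
    ens = fit_ensemble(occ, stacks[occ.island_id], cfg)
    suitability[occ.island_id][occ.ecomorph] = ens.mean_map

surface = ecc(suitability["island-1"])
corr = correlation_pipeline(surface, stacks["island-1"], cfg, seed=11)
table = constraint_table(suitability, {i: stacks[i].elevation for i in stacks})
r, p, _ = trait_correlation(table, n_permutations=5000, seed=11)
```

Output (island-1):

```
twig         mean held-out AUC = 0.954
grass-bush   mean held-out AUC = 0.851
trunk        mean held-out AUC = 0.608
trunk-crown  mean held-out AUC = 0.502
trunk-ground mean held-out AUC = 0.535
crown-giant  mean held-out AUC = 0.538
ECC range on island-1: [1.71, 3.88] of max 6
ECC~elevation: Pearson R = 0.884, Spearman r = 0.891 (p = 0.0002, n = 100)
trait correlation (constraint vs body-mass rank): r = -0.848, p = 0.0016
```

Reading it: the elevation-restricted specialists (twig, grass-bush) are
easy to discriminate from background (AUC 0.85–0.95) while the broad
generalists sit near 0.5, community completeness climbs strongly with
elevation (R ≈ 0.88, significant on the decorrelated 100-point subsample),
and across ecomorph × island pairs the elevational constraint *decreases*
with body mass (r ≈ −0.85): lighter ecomorphs are the ones restricted to
high elevations — the environmental-filtering signature the pipeline is
built to detect.

## Command line

All stages share one workspace directory:

```sh
eccpipe simulate --seed 1 --out ws --islands 4 --scenario mixed
eccpipe fit-enm  --out ws --seed 1 --project-to all
eccpipe ecc      --out ws
eccpipe overlap  --out ws
eccpipe correlate --out ws --seed 1
eccpipe select-models --out ws
eccpipe traits   --out ws --seed 1
# or everything at once, writing summary.json:
eccpipe pipeline --out ws --seed 1
```

Rasters are ESRI ASCII grids, tables are CSV, summaries are JSON; a YAML
config (`--config`) sets replicate counts, background size, k-means and
permutation parameters.

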