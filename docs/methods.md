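# Methods

This document records the model implemented by `hsmtransfer`, the parameter
values with units, the scope of the synthetic-data generator, and known
limitations. The library modules referenced are under `src/hsmtransfer/`.

## 1. Synthetic landscape and virtual species (`synthio`)

The study system is two rectangular regions on a shared metric grid
(default cell size 1,000 m) separated by a no-data gap, standing in for two
disjunct population clusters, A (large) and B (small).

**Environmental layers.** All continuous fields are Gaussian random fields
produced by FFT-free Gaussian smoothing of white noise with kernel scale
`spatial_corr_range` (m, default 10,000). To reproduce the strong
collinearity of real bioclim pools, the 19 bioclim-like layers are a latent
mixture: 5 shared latent fields; layer *k* loads ±0.96 on latent *k* mod 5
and √(1 − 0.96²) on its own idiosyncratic field, then is scaled to a random
mean ∈ [−2, 2] and SD ∈ [0.5, 2]. Monthly solar-radiation and wind-speed
stacks (12 layers each) get a sinusoidal seasonal cycle plus spatial noise.
Land cover is a categorical field at a finer resolution (`fine_factor`,
default 5 sub-cells per cell side) from which fractional cover is aggregated.
Region B can be made environmentally distinct via `b_env_shift` (in anomaly
SD units) and `heterogeneity` (per-region anomaly scaling); `mirror_regions`
makes B an exact environmental copy of A for identity tests.

**Virtual species.** True suitability is a product of Gaussian response
curves over `niche_vars` (default three layers), with region-B optima
optionally displaced (`b_niche_shift`, in layer SD units) and tolerances
narrowed (`b_niche_narrowing`) to create genuine niche differences between
clusters. Presences are drawn by weighted sampling of cells with probability
∝ suitability^`presence_concentration`, with optional distance-decaying
observation bias around seeded hubs. `truth_overlap` reports the true
Schoener's D between the regional suitability-weighted environmental
densities.

**Reproducibility.** Every stochastic component derives its generator from a
`numpy.random.SeedSequence` spawn of a single integer seed; derived integer
seeds are reduced mod 2³¹. Identical configs give bitwise-identical outputs.

## 2. Candidate predictors and collinearity filtering (`predictors`)

The candidate pool has exactly 31 layers:

- 19 bioclim-like layers `bio01` … `bio19`;
- 10 derived summaries of the monthly radiation/wind stacks:
  `Srad_Ann_Mean`, `Srad_Ann_Sd`, `Srad_MayOct_Mean`, `Srad_MayOct_Sd`,
  `Srad_LSM`, `Srad_MSM` (least/most sunny month), and the analogous
  `Wspeed_Ann_Mean/Sd`, `Wspeed_MayOct_Mean/Sd`. "MayOct" is months 5–10,
  the activity season;
- 2 habitat layers, `Grasslands` and `Rocks_SparseVeg`, as exact fractional
  cover (%) counted over the fine-resolution land-cover sub-cells.

Two predictor sets are built from a random sample of study-area cells
(default 10,000):

- **Ecol**: pairwise Pearson filter at |r| ≥ 0.7; within each conflicting
  pair the variable ranked higher in an ecology-first preference ordering is
  kept (activity-season and habitat variables ahead of annual summaries ahead
  of raw bioclim).
- **VIF**: two-stage variance-inflation filter at VIF = 10 — stage 1 on the
  study-area sample removes the worst variable iteratively; stage 2 confirms
  on per-dataset tables (occurrences + sample) and removes anything that
  re-inflates.

With the latent-mixture generator the filters retain roughly 13 (Ecol) and
18 (VIF) of 31 — the filtering stage does real work.

## 3. Datasets, thinning, pseudoabsences (`sampling`)

Six presence datasets: clusters A, B, and Joint, each Full and Thin. Thinning
enforces a 1,500 m minimum inter-point distance and keeps the best (largest)
of several random removal orders. Pseudoabsences are drawn without
replacement from cells in a buffer annulus 1,500–120,000 m around the
presences, avoiding presence cells, in 10 replicate sets of 1,000 (desk-scale
runs shrink both). Each presence dataset × pseudoabsence replicate is one
model-fitting dataset: 6 × 10 = 60.

## 4. Models (`models`)

- **GAM**: binomial GLM (statsmodels, logit link) over a hand-built natural
  cubic-spline basis (truncated-power form, boundary-linear). Stepwise AIC
  search moves one variable one level at a time through the scope
  {out, linear, 2-df smooth, 3-df smooth}, starting all-smooth with an
  all-linear fallback; AIC values are memoized per scope vector.
- **GBM**: `sklearn.GradientBoostingClassifier`, `max_depth=3`; the number of
  trees is chosen by cross-validated Bernoulli deviance over a tree grid.
  Reference settings are learning rate 0.001 with up to 10,000 trees;
  desk-scale runs keep the learning-rate × trees product with fewer trees.

## 5. Spatial blocking and validation (`blocking`, `evaluation`)

Residual spatial autocorrelation of a fitted model is profiled with a
distance-binned Moran's I correlogram; the block size is the smallest
distance at which the correlogram stabilizes near zero (first zero crossing
with a stable suffix). Folds are checkerboard assignments of square blocks,
in two phases (the checkerboard and its one-block-shifted complement).

The factorial is 6 datasets × 10 pseudoabsence replicates × 2 predictor sets
× 2 algorithms × 2 fold assignments = 480 models. Each model is evaluated:

- **internally** (mode `SpBlockCV`): refit on training folds, scored on
  held-out blocks; AUC and continuous Boyce index pooled over folds;
- **externally** (mode `External`): the full model scored on the disjunct
  cluster's presences against that region's background.

**Continuous Boyce index.** 101 moving windows of width = suitability
range/10; F-ratio per window = (presence share)/(background share); B is the
Spearman correlation of F with window centers. Note the windows overlap
~90%, so F values are strongly autocorrelated (see Limitations).

**Environmental novelty.** Each evaluation cell is *strict novel* if any
predictor leaves its calibration range, else *multivariate novel* if its
joint 5-bin-per-variable combination was unseen in calibration, else
*analog*. `%nonanalog` = strict + multivariate.

## 6. Ensembles (`ensemble`)

Members with internal Boyce B ≥ 0.7 enter a Boyce-weighted ensemble. The
weighted mean map uses weights B_i; the ensemble SD is

  SD = sqrt( Σ B_i (HS_i − HS_WA)² / ( ((N−1)/N) Σ B_i ) ),

which reduces exactly to the ddof-1 sample SD at equal weights. Variable
importance is 1 − Pearson(pred, pred with the variable shuffled), averaged
over shuffles, normalized to 100% and aggregated over members by weight.
Response curves are "inflated": each variable is profiled over its range at
many random complements of the other variables; for an additive GAM the
profiles are exact vertical translations on the link scale.

## 7. Niche overlap (`nicheoverlap`)

Environments are projected onto the first two axes of a PCA of the study-area
sample (PCA-env). Occupancy grids on an R × R lattice (default 100) are
occurrence kernel densities divided by background densities, normalized.
Schoener's D = 1 − ½ Σ|z₁ − z₂|. The equivalency test permutes pooled
occurrences (default 1,000 reps); the similarity test redraws virtual
occurrences from the other cluster's background. P-values use the +1
correction; both divergence and conservatism tails are reported.

## 8. Statistical comparisons (`comparisons`)

A Shapiro-Wilk gate on (optionally group-wise) residuals selects parametric
vs nonparametric branches; the synthetic metrics are non-normal, so in
practice: Mann-Whitney U with Hodges-Lehmann shift estimates for two-level
factors; Kruskal-Wallis with Benjamini-Hochberg-adjusted pairwise follow-ups
for three-level factors. The novelty–performance association is Pearson on
rank-based inverse-normal-transformed (Blom) variables, with the t-statistic
t = r √(df/(1 − r²)); it is invariant to monotone transforms of either input.

## 9. Problem sizes and runtimes (1 CPU)

| Configuration | Grid | Models | Time |
|---|---|---|---|
| acceptance-test factorial | 2 × 40×40 km, 1 km cells | 480 | ~8 min |
| `analysis/03_run_experiment.py` | 2 × 60×60 km, 1 km cells | 96 | ~11 min |
| `scripts/acceptance.py` | 2 × 60×60 km, 1 km cells | 96 | ~11 min |

GAM stepwise fitting dominates (seconds per model at 13–18 candidate
variables; memoized AIC keeps the search tractable).

## 10. Limitations

- **Novelty saturation at high dimensionality.** With 13–18 predictors the
  multivariate novelty component tests membership in up to 5¹⁸ joint bins, so
  ~90%+ of *both* evaluation regions are flagged nonanalog and `%nonanalog`
  loses contrast; the pooled novelty–performance correlation can then be
  uninformative or even sign-flipped. The mask is informative at low
  dimensionality (≤ ~5 variables); interpret full-factorial novelty values
  with that in mind.
- **Boyce window autocorrelation.** With 101 windows of width range/10,
  adjacent windows share ~90% of their data. Single-replicate B of a
  non-selective sample therefore scatters widely around zero (|B| up to
  ~0.7 observed) even though its expectation is 0; B is trustworthy in the
  mean over replicates or for genuinely selective species. Relatedly, a
  species confined to one suitability decile leaves most windows tied at
  F = 0, bounding B near 0.56 regardless of how selective it is — B near 1
  requires monotone preference across the gradient, not mere concentration.
- **Generator scope.** The landscape is stationary apart from the explicit
  regional shift/heterogeneity knobs; there are no gradients, no
  topography-linked covariance, and land cover is independent of climate.
  Niche truth is a product of independent Gaussian responses — no
  interactions. Conclusions about *mechanisms* of transfer failure should not
  be read beyond these ingredients.
- **Desk-scale GBM.** Reduced tree counts at raised learning rates preserve
  the product but not the exact regularization path of the reference
  configuration.
- **Statistical caveats.** The 480 factorial records share datasets and
  landscapes, so records are not independent; the group comparisons are
  descriptive, not confirmatory.
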