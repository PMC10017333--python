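# Methods

This note documents the models, the synthetic data generator, the
numerical choices and the known limitations of `pine-phenomics`.

## The phenotyping workflow

The package mirrors a UAV multispectral campaign over an open-pollinated
conifer progeny trial. Monthly flights yield a digital surface model
(DSM), a digital terrain model (DTM) and five reflectance bands (blue
450, green 560, red 650, red-edge 730, NIR 840 nm). The analysis chain
is: canopy height model → individual-tree detection → crown delineation
→ per-crown band means → 21 spectral predictors → trait prediction (N
and NSC, % dry mass) → per-month REML genetic evaluation → bivariate
family selection. Trait predictors are trained on a pooled set of
ground-sampled trees (needle chemistry from a few dozen trees per
month), then applied to every detected tree in every month; the genetic
evaluation runs on the predicted traits, as a breeding program using
imagery in place of exhaustive wet chemistry would.

## Synthetic orchard generator

The generator encodes the statistical structure the analysis assumes,
so recovery of its parameters is a meaningful correctness check.

**Layout.** Two sites, 20 incomplete blocks per site, 20 open-pollinated
families, one tree per family per block at 2 × 3 m spacing — 800 trees.
Family-to-position assignment within each block is a seeded random
permutation (a randomization proxy for the alpha-lattice design; the
generator does not construct resolvable lattices, which the per-month
model does not exploit anyway). Tree heights are drawn around 7 ± 1 m
(a plausible range for a pine trial roughly a decade after planting;
all above the 2.6 m detection floor) and crown radii uniformly from
0.7–1.2 m, inside the 1.25 m half of the maximum crown diameter.

**Traits.** For each trait and month, tree values are

    y = μ_month + site + block + family + residual

with `block ~ N(0, σ²_b)`, `family ~ N(0, σ²_f)`, `residual ~ N(0,
σ²_e)`. Family effects are drawn once and held constant across months
(one genetic value per family); a flagged redraw mode exists for
experiments with month-varying heritability. Block effects and
residuals are independent across months. Default variance components
put the true narrow-sense heritability `2.5 σ²_f / (σ²_f + σ²_b +
σ²_e)` at 0.25 for both traits — the middle of the 0–0.49 range the
method is intended to resolve. Default monthly means follow conifer
phenology: N rises with the spring flush (~1.45–2.0 %), NSC drains
through the growing season and refills in winter (~7.3–10.5 %). Values
are softly clipped to N ∈ [0.5, 4] %, NSC ∈ [5, 15] % with the clip
count recorded. Sample sizes for ground truth default to 35 trees per
month, giving a 385-sample campaign over the 11 flight months (February
has no flight).

**Optics.** Reflectance is a linear forward model per band: `band =
baseline + c_N·N + c_NSC·NSC + noise`, clipped to [0, 1], noise SD 0.01.
This is an artifact convention that gives the learning stage an
identifiable signal — not a radiative-transfer claim. Nitrogen
(chlorophyll) mainly depresses the visible bands and raises red-edge
and NIR; NSC mainly moves the NIR plateau. The 5 × 2 coefficient matrix
must have rank 2 so both traits are recoverable from band means.
Baselines and coefficients are chosen so all bands stay inside [0, 1]
across the trait ranges (no silent clipping of the signal). Soil
background reflectance is darker in NIR than canopy, so NDVI separates
crowns from ground.

**Rasters.** The DTM is a smooth sinusoidal swell (default 3 m total
relief, bounded at 10 m). Each tree is a right circular cone added to
the terrain (apex = true height, base radius = crown radius),
composited by maximum height; band rasters paint each crown's disc with
that tree's reflectance, overlaps resolved by nearest apex. The raster
grid is aligned so planting positions coincide with pixel centres:
every rendered apex is then an exact sample of the true height, and
`compute_chm` restores it exactly. Rasters are single-band float32
GeoTIFFs (ModelPixelScale/ModelTiepoint/GDAL_NODATA tags) with a JSON
sidecar; the world frame is a local metric system with a top-left
origin, row-major 0-based pixels and half-open pixel windows.

What the generator does **not** emulate: photogrammetric reconstruction
noise, shadows and illumination geometry, crown asymmetry and mutual
shading, spatial autocorrelation of the environment beyond block
effects, and genotype-by-environment interaction. Passing tests
therefore demonstrate correctness of the algorithms under the model's
own assumptions, not field performance.

## Image analysis choices

- CHM is exact cellwise subtraction; nodata propagates; negative cells
  (surface/terrain noise in real data) are clamped to zero with a
  logged count.
- Detection: a cell is an apex iff CHM ≥ 2.6 m and it is the *strict*
  maximum within a circular window of radius `clamp(a + b·h, r_min,
  1.25 m)` (defaults a = 0, b = 0.3, r_min = 0.5 m — the cap binds for
  all realistic heights at this planting density). Ties break to the
  row-major first cell; candidate apexes closer than r_min are merged
  keeping the taller. The linear clamped radius rule and its
  parameters are exposed in the call signature.
- Crowns: region growing from each apex (tallest first, 4-connected),
  admitting neighbours above both 0.45 × apex height and 0.55 × the
  running crown mean, never beyond 1.25 m from the apex, never into
  another crown (first claim wins). On a cone the 0.45 floor truncates
  growth at ~55 % of the base radius, so delineated crowns are
  intentionally smaller than the rendered discs; per-crown means are
  unaffected because rendered reflectance is constant within a crown.
- Spectra: mean reflectance over pixels whose centres fall inside the
  crown polygon, nodata excluded, pixel counts recorded; zero-pixel
  crowns are flagged and dropped downstream. Mean (not median) is used;
  shaded-pixel handling is out of scope because the renderer casts no
  shadows.
- Matching to field records: greedy nearest-neighbour, closest pairs
  first, 1 m tolerance, each field record used at most once; unmatched
  field records are reported, unmatched detections retained unlabeled.

## Spectral indices

The 16 index formulas are implemented exactly as published for this
feature set, including two nonstandard forms: EVI without the
conventional 2.5 gain, and MNLI with the green band where common forms
use red. NRI and GRVI are published with identical equations; both
columns are kept and ranked separately. Scalar and vectorized paths
share the same formula callables, so they agree bit for bit. A
vanishing denominator yields NaN plus an explicit flag
(`vi_undefined`); flagged rows are excluded from modeling rather than
imputed.

## Trait models

All four methods run inside a `StandardScaler → estimator` pipeline
whose statistics come from calibration rows only. The split is a seeded
uniform partition: `floor(0.8 n)` calibration rows, remainder
validation (383 → 306/77). Hyperparameters: PLSR selects 1–10
components by leave-one-out CV; SVM (RBF) searches C ∈ {0.25, 0.5, 1,
2, 4} × γ ∈ {0.01, 0.1, 1} and GBM searches learning rate ∈ {0.01,
0.05, 0.1} × trees ∈ {100, 300, 500, 1000}, both by 5-fold CV RMSE
within calibration; RF uses 300 trees untuned. R² is defined as
1 − SS_res/SS_tot about the evaluated set's own mean (not squared
correlation). Variable importance is permutation-based for every
method (mean RMSE increase over 10 seeded permutations, rescaled to
max = 100) so rankings are comparable across methods. PLSR's held-out
metrics are reported from the same 20 % validation set as the other
methods; its leave-one-out CV is used only for component selection.

## REML estimation

The restricted likelihood of the three-component model is maximized on
the log scale of the variance ratios (block/residual, family/residual)
with the residual variance concentrated out in closed form. One
evaluation costs O(q³) in the number of random-effect levels (q = 60 at
trial scale) via the Woodbury and determinant-lemma identities on
precomputed cross-products, so a full fit takes ~0.1 s at n = 800.
Optimization is Nelder-Mead from three starts, followed by explicit
boundary refits with the block and/or family term dropped; the best
criterion value wins, so zero variance components are estimated exactly
(and reported as boundary estimates) rather than floored. A single
block level is tolerated: its variance is confounded with the intercept
under REML and the term is dropped. The implementation agrees with
R/lme4 to six decimals on interior solutions (including the criterion
value) and with classical ANOVA moment estimators on balanced one-way
designs; a dense-matrix restricted likelihood and a lattice + refine
search serve as independent oracles in the tests.

The heritability numerator 2.5 (rather than the half-sib 4) reflects
the usual assumption of a mix of half- and full-sibs among
open-pollinated progeny; it is taken as given and overridable. h²
values above 1, which the coefficient permits, are reported with a
warning rather than truncated. μ̂ in the breeding-value formula is the
grand mean of the trait across all trees of the month. Selection uses
the bivariate quadrant rule: a family is selected when its breeding
value strictly exceeds the across-family mean for both traits in every
selected month, ranked by summed standardized breeding values. The
generator's `plant_superior_families` helper shifts chosen families by
a multiple of the phenotypic SD, defaulting to 1.5 — large enough that
"superior" families sit clearly in the first quadrant of the
breeding-value plane (a +1 σ_f shift, by contrast, is comparable to the
sampling noise of a 40-tree family mean and is not recoverable reliably
by any rule).

The mixed model is univariate per trait-month; a bivariate fit with a
genetic covariance between N and NSC is out of scope, and selection
operates on the per-trait breeding values directly.

## Pipeline and reproducibility

Every stage seed derives deterministically from one master seed
(`blake2s(master:stage) mod 2³¹`). The analysis half consumes only
files written by the generation half (CSV/GeoTIFF), so it is
re-runnable from any checkpoint and the raster entry point
(`run_from_rasters`) reproduces `run_pipeline`'s outputs byte for byte
on the same artifacts. Artifacts are flat CSV/JSON per month plus a
manifest echoing the config, stage seeds and versions; no figures are
rendered (tabular outputs are diffable in tests). A stage failure
aborts with the stage name, persisting partial artifacts and the
manifest.

Problem sizes used by the test suite and acceptance script: the
full-scale scenes use the complete 800-tree trial at 0.05 m/px;
recovery simulations use 50 replicates at that scale; the end-to-end
determinism runs use a reduced trial (2 sites × 4 blocks × 10 families,
3 months, 0.10 m/px) with trimmed tuning grids, since determinism is
scale-independent.

## Known limitations

- The linear trait→reflectance model makes the prediction task easier
  than real canopy optics; validation R² on synthetic campaigns
  (~0.65–0.8) should not be read as a field forecast.
- Cone crowns render no within-crown texture, so crown-statistic
  choices (mean vs median) cannot be discriminated here.
- Detection assumes discrete crowns at planting density; heavily
  interlocking canopies would need watershed or learned segmentation,
  which are out of scope.
- The genetic model ignores spatial autocorrelation beyond blocks and
  any pedigree structure deeper than the open-pollinated family.
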