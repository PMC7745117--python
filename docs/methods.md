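# Methods

This note documents the models behind `uavpheno`, the choices made where the
design was genuinely open, and what the synthetic benchmark does and does not
establish about real aerial imagery.

## Camera footprint geometry

`compute_footprint` models a nadir frame camera at height *h*: cross-track
ground width = 2·h·tan(hfov/2), GSD = width / horizontal pixel count, and the
along-track extent = GSD × vertical pixel count. The along-track side is
deliberately derived from the square-pixel GSD rather than from the vertical
view angle: consumer-camera spec sheets often quote view angles that are not
mutually consistent with the sensor aspect ratio, while the square-pixel
assumption keeps GSD, pixel dimensions and ground extent self-consistent. For
the reference survey configuration (80 m height, 46.8° HFOV, 4592 × 3448 px)
this yields 1.51 cm/px over a 69.2 m × 52 m footprint.

## Display enhancement

`enhance` applies, per band, a min–max linear stretch followed by gamma
correction and an optional sharpening filter:
v′ = 255·clip((v−min)/(max−min), 0, 1)^(1/γ). The gamma exponent follows the
display-gamma convention (γ = 0.9 brightens mid-tones slightly), matching how
GIS "gamma stretch" sliders behave; the opposite convention (exponent γ) exists
in other software, so the direction is stated here explicitly. The sharpen
kernel is the fixed 4-neighbour unsharp kernel (centre 5, edges −1). The chain
is monotone per band before sharpening and never alters grid or georeferencing.
Enhancement is **off** by default for classification input: it is a
visualization aid, and keeping the classifier on raw digital numbers makes the
pipeline deterministic with respect to display settings.

## Maximum-likelihood classification

Four classes — soil, green canopy, yellow canopy, dry canopy — are modelled as
multivariate Gaussians over raw 8-bit RGB. Signatures (mean, sample covariance,
pixel count) are estimated from labelled training polygons, with pixels
selected by the centre-in-polygon rule. Numerical choices:

* **Ridge.** `ridge · I` (default 1 DN²) is added to every class covariance so
  constant-color training patches (zero sample covariance) remain usable and
  all covariances are positive definite.
* **Priors** are equal by default and configurable; the discriminant is
  invariant to rescaling all priors, and `SignatureSet` normalises them.
* **Ties** in the discriminant go to the lowest class index (soil < green <
  yellow < dry) — an arbitrary but fixed rule that makes the map reproducible.
* **No reject class.** Every pixel is labelled; quality control is done by
  `evaluate_classification` against reference labels rather than by
  thresholding posteriors.

The implementation evaluates the discriminant with Cholesky factors in chunks;
tests pin it to an independent full-precision Gaussian log-density oracle.

## Plot extraction and zonal tabulation

Plot boundaries may arrive as digitized polylines; `polylines_to_polygons`
snaps endpoints within `snap_tol` (default 1 cm, below half a pixel), nodes
the arrangement, and closes every bounded face into a polygon with an
auto-incremented id in row-major centroid order. Dangling lines simply produce
no face (logged, not fatal).

Rasterization uses the centre-point rule on a north-up metre grid (row-major
from the NW corner, cells addressed by centre): a cell belongs to the polygon
containing its centre; a centre exactly on a shared edge goes to the lower id.
The same rule selects training pixels and renders synthetic plots, so pixel
sets agree exactly across stages. Centre-point rasterization of a 4 m × 1.5 m
plot at 1.5 cm GSD carries an unavoidable quantization error of up to roughly
one pixel row plus one column of the perimeter (≈ 0.03 m² here); class
*fractions* are unaffected because numerator and denominator use the same
pixel set. `tabulate_area` is exact integer pixel counting (verified against
exhaustive enumeration) times the pixel area; per zone, class areas sum to the
zone area exactly. Alleys between plots fall outside every polygon and are
excluded from all plot statistics.

## Canopy traits

From per-plot class areas: total cover = (G+Y+D)/area, RGC = G/area, and the
senescence index SI = (Y+D)/(Y+D+G). SI is undefined on plots with no canopy
pixels; such plots are flagged and excluded pairwise from SI correlations and
fits (the least-assumption treatment). SI is scale-invariant in the areas, so
it can be computed from areas or fractions interchangeably. Note that the SI
of mean class areas differs from the mean of per-plot SIs; the pipeline
reports per-plot SI and aggregates explicitly.

## REML variance components, H², ρg

The trial model is y = μ + rep + block(rep) + genotype + ε with rep fixed and
block-within-rep and genotype random — the convention of standard
multi-environment breeding-trial software. The REML criterion is profiled over
fixed effects and the residual variance, leaving variance *ratios*
γ_k = σ²_k/σ²_e ≥ 0:

−2ℓ_R(γ) = ln|H| + ln|XᵀH⁻¹X| + (n−p)·ln(yᵀPy),  H = I + Σ_k γ_k Z_k Z_kᵀ.

Ratios are maximized by bound-constrained L-BFGS-B followed by a
coordinate-wise golden-section polish (xatol 10⁻¹²), which keeps the optimum
deterministic and reproduces the closed-form ANOVA components on balanced data
to better than 10⁻⁶ relative. Components are bounded at zero by the
parametrization. Genotype BLUPs come from the random-genotype fit
(û = γ Zᵀ H⁻¹(y−Xβ̂)); BLUEs from a genotype-fixed GLS refit with block kept
random. A zero-variance response short-circuits to an all-zero degenerate fit,
flagged.

Heritability uses the genotype-mean definition H² = σ²_g/(σ²_g + σ²_e/n_reps).
Block variance is estimated but not part of the denominator — this matches the
printed definition used by breeders even when an incomplete-block model is
fitted; whether to include it is a known ambiguity, and the package follows
the formula as stated.

The genotypic covariance between traits uses the variance-of-sums identity on
univariate fits rather than a bivariate REML fit: σ_g(j,j′) =
[σ²_g(j+j′) − σ²_g(j) − σ²_g(j′)]/2. Inside `genetic_correlation` the traits
are first standardized to unit phenotypic variance (ρ_g is scale-invariant and
the sum trait stays well conditioned); the reported covariance is mapped back
to the raw scale. The ratio estimator can overshoot |1| under sampling noise
and is clamped with a warning; if either genotypic variance collapses to zero
the correlation is reported as NaN and flagged.

**Estimator precision.** The identity estimator's standard error is roughly
(1−ρ²)/(h²√G) for G genotypes with genotype-mean reliability h², plus the
sampling spread of the realized effect correlation itself (≈ (1−ρ²)/√(G−1)).
At 50 genotypes and H² = 0.6 a single-trial estimate has sd ≈ 0.25; recovery
statements in the tests therefore average over ≥ 20 independent trials, and
null-recovery checks use designs sized so the interval actually has the stated
coverage (150 genotypes for the correlation null, 6 replicates for the
variance null).

## Synthetic trial generator

The generator defines the benchmark conditions; it is the package's ground
truth, not a calibration target.

* **Layout.** Serpentine alpha-lattice-style layout: each replicate splits
  into incomplete blocks of 10 varieties, one block per field range; 2-row
  plots, 4 m long, 0.75 m row spacing (1.5 m plot width, 6 m² footprint),
  1 m alleys between ranges, varieties randomized within replicate. The
  default trial is 50 varieties × 3 replicates = 150 plots.
* **Genetic model.** Every trait follows y = μ + g_variety + r_rep + ε_plot on
  a latent scale, with genotype effect vectors drawn multivariate-normal so a
  target genotypic correlation matrix is realized; replicate and residual
  effects are independent across traits. Fraction traits use a logit latent
  scale squashed through the logistic, keeping the additive-normal assumptions
  of the mixed model on the latent scale while producing valid fractions; the
  squashing is gentle at the default variances (attenuation of genetic
  correlations < 2%).
* **Canonical traits.** total_cover (mean 0.66), si (mean 0.45), dry_share
  (mean 0.19) on the logit scale and grain yield (5.5 ± Mg/ha, identity).
  Latent variances give design H² ≈ 0.6 at three replicates for every trait —
  the moderately-high-heritability regime typical of canopy traits in
  low-nitrogen maize trials. Default genotypic correlations: cover–yield
  +0.6, SI–yield −0.4, cover–SI −0.3 (senescent, sparse canopies yield less).
  Class fractions derive as green = cover·(1−si), yellow = cover·si·(1−dry
  share), dry = cover·si·dry share, so Eq.-consistency SI(fractions) = si is
  exact and fractions sum to cover ≤ 1 (the remainder is soil). The
  distribution of fractions across plots is not pinned by any published data;
  these defaults were chosen once as field-plausible values.
* **Rendering.** The field is rasterized at the survey GSD (default 1.5 cm).
  Within each plot, latent classes are assigned by three hierarchical binary
  splits — canopy/soil, green/senesced, yellow/dry — each thresholding its own
  Gaussian-smoothed noise field (smoothing sigma = `within_plot_texture`,
  default 4 px). Thresholding at ranks makes per-plot class counts match the
  ground-truth fractions to the nearest pixel, while the smoothed fields make
  every class spatially clumped, so single-class training polygons exist (a
  single ordered-band threshold would make the middle classes thin shells).
  Pixel colors are drawn from per-class Gaussian RGB models; the defaults are
  separated by ≥ 8 pooled SDs, the "easy" regime in which MLC should be nearly
  perfect. Soil outside plots uses the same soil model as inside.
* **Visual scores.** score = clip(100·SI + bias + N(0, sd), 0, 100), a trained
  technician scoring percent dead leaf area; observer_sd (default 5) controls
  how faithfully scores track the image trait.
* **Seeds.** Each stage (layout, genetics, render, observer) has its own seed,
  recorded in the run config; identical seeds give bit-identical artifacts.

**What the benchmark shows — and does not.** Passing the end-to-end recovery
tests shows the pipeline's bookkeeping is correct: classification, zonal
counting, trait arithmetic and the genetics estimators recover the truth that
generated the images. It does not show that real mosaics classify this well:
the renderer has no illumination gradients, shadows, mixed pixels at canopy
edges, georeferencing error, or between-plot color drift, and its class
palette is deliberately well separated. Accuracy on real imagery is governed
by training-sample quality and spectral overlap (especially yellow vs dry),
which this benchmark does not probe.

## Problem sizes

Default test and acceptance runs use one 150-plot trial at 1.5 cm GSD
(≈ 6.6 M pixels), 20 independent trials for every recovery mean, and
2000×3000 rasters for the zonal-counting oracle — sizes chosen so the full
suite completes in a couple of minutes while keeping every estimate's sampling
error well inside the asserted tolerances.

## Known limitations

* Photogrammetric mosaicking, GCP georeferencing and radiometric correction
  are out of scope; inputs are assumed already georeferenced in projected
  metres (no lon/lat support).
* The REML engine targets the trial model (a few hundred observations, one or
  two variance components); it is not a general sparse mixed-model solver.
* Genotypic covariance comes from univariate fits via the sums identity; a
  bivariate REML fit would be more efficient but is not required for ρ_g.
* Single site-season analysis: no genotype-by-environment decomposition; with
  one trial the pairwise-mean form of ρ_g reduces to a single term.
* No p-values beyond the Pearson test and no multiple-testing correction.
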