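# Methods

`moltpath` implements the comparative toolchain for a specific evolutionary
question: does a second annual molt (the prealternate molt, which produces
the breeding plumage) evolve for feather renewal — driven by migration
distance and solar exposure — and only later get co-opted for seasonal
dichromatism, or does it evolve directly for color change?  The package is a
general phylogenetic-comparative library, but every design choice below is
anchored in that analysis.

## Data model

Species are scored per feather region on a three-level scale for two
channels: molt (1 = region completely replaced, 0.5 = partial replacement or
intraspecific variation, 0 = not replaced) and dichromatism (same scale for
color difference between basic and alternate plumage).  Two derived
variables drive the analyses:

- **extent** — the row sum of region scores (half scores count 0.5), range
  0 to the number of regions (11 by default);
- **presence** — 1 if any region scores above zero.

The default region list (head, breast, belly, back, tertials, median
coverts, greater coverts, rump, tail, remiges, alula) is ordered along the
stereotyped succession in which regions join the molt as it becomes more
extensive; the list is data, not code, and any ordered list can be supplied.
Definitive (adult-cycle) molts are assumed throughout.  Extent sums half
scores as halves by default; an integer-rounding convention
(`extent(..., round_halves=True)`) is available because either reading of
"number of regions involved" is defensible.

Dichromatism within a region logically requires that region to be molted.
The synthetic generator enforces this nestedness; observed data may violate
it, so on real input it is only reported as a consistency diagnostic
(`trait_scoring.consistency_diagnostic`), never enforced.

## Phylogenetic machinery

All model-based analyses flow through the Brownian-motion (BM)
variance-covariance matrix `C`, with `C[i, j]` the shared root-to-MRCA
branch length of tips i and j.  Deformations of `C` express the alternative
models:

- **Pagel's lambda** multiplies off-diagonals by `lambda`; the admissible
  upper bound is the largest `lambda` keeping the matrix positive
  semidefinite (found by a closed-form bound plus bisection), which exceeds
  1 slightly on most ultrametric trees.
- **Ornstein-Uhlenbeck (OU)** uses the fixed-root covariance
  `V_ij = exp(-alpha d_ij) (1 - exp(-2 alpha T_ij)) / (2 alpha)` with
  `T_ij` the shared time and `d_ij` the patristic distance.  On ultrametric
  trees this reduces to the familiar stationary form; on non-ultrametric
  trees it remains well defined and a warning is logged.
- **Early burst (EB)** rescales each branch spanning ages `t1 -> t2` to
  `(exp(r t2) - exp(r t1)) / r` with decay `r <= 0`, written via `expm1` to
  survive `r -> 0`.

Polytomies are retained as-is (all likelihoods used here are defined on
multifurcations) and zero-length branches are legal.  Ultrametricity is
reported, not enforced.  PSD checks use an eigenvalue tolerance of
`1e-8 x trace`.

## Gaussian model fitting

For any fixed structural parameter (OU `alpha`, EB `r`, `lambda`), the root
state and rate have closed-form GLS/ML solutions, so each fit is a bounded
one-dimensional search.  The search runs a deterministic grid of starting
points (8 for OU, 6 otherwise) refined by Brent's method on the bracketing
subinterval; parameter values where the covariance degenerates score
`-inf`.  The ML variance denominator `n` (not REML) is used so AICc
comparisons are consistent across models:
`AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1)` with `k = 2` (BM) or 3 (OU, EB,
lambda).  Default structural bounds are `alpha in [0, 50/depth]` and
`r in [-10/depth, 0]`; both are arguments.

Binary presence characters may be passed to these Gaussian fits — the
OU-vs-BM weight comparison for molt presence is part of the target analysis
— and the resulting fit is flagged `binary_trait` in its metadata so output
tables disclose the approximation.

Across-region rate summaries weight each region's per-model rate
(`sigma^2`) by the region's AICc weights and sum over regions.  Continuous
ancestral states are the BM conditional means given the tips (the root
estimate coincides with the GLS root state); variances come from the
standard Gaussian conditional formula.

## Discrete (Mk) machinery

Binary presence characters use continuous-time Markov chains with equal
(ER) or asymmetric (ARD) rates, compared by likelihood-ratio test
(chi-square, df = extra rates).  Likelihoods use Felsenstein pruning with
per-node rescaling; the root is integrated against a flat prior by default
(a stationary-distribution prior is available).  Branch transition matrices
use the closed form for two-state chains; larger chains use an
eigendecomposition when the eigenbasis is well conditioned (condition
number < 1e8) and fall back to scipy's scaling-and-squaring `expm`
otherwise, so defective ARD matrices remain exact.  Marginal ancestral
states come from combining rootward partial likelihoods with an "outside"
message per node (algebraically the re-rooting method); MAP ties are broken
toward absence — the conservative direction for counting gains — and
flagged.  Transition counts compare parent and child MAP states along every
branch.

The correlated-evolution (dependence) test couples two binary traits into a
four-state chain: the independent model has 4 free rates (each trait's gain
and loss, unaffected by the other trait), the dependent model 8 (each
single-trait rate may depend on the other trait's state); dual transitions
are forbidden in both.  Rates are optimized on the log scale by L-BFGS-B
from three deterministic starts (the dependent fit additionally starts from
the independent solution).  AIC (`-2 lnL + 2k`) is the reported comparison
statistic for this test, with AICc also emitted, and the LRT uses 4 degrees
of freedom.

## PGLS and model ranking

PGLS fits `y = X b + e` with residual covariance `sigma^2 V`, computed in
the whitened space `L^{-1}(.)` for `V = L L'`, so `lambda = 0` reproduces
OLS bit-for-bit and a star tree equals OLS.  `V` is pure BM by default —
matching the most common default of the GLS ecosystem this analysis sits in
— with fixed-lambda and ML-lambda modes available; the mode is recorded in
every output row.  R-squared is measured against the GLS intercept-only
model under the same `V`; `F = [(RSS0 - RSS)/p] / [RSS/(n-p-1)]`; with 48
species and one predictor the F degrees of freedom are (1, 46).  AICc
counts `k = p + 2` (coefficients, intercept, residual variance) plus one
when lambda is estimated, so BM and ML-lambda models compete fairly.  Model
sets are ranked ascending by AICc with Akaike weights
`w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)`; ties preserve input order.

## Phylogenetic ANOVA

The observed statistic is the ordinary one-way F of a continuous variable
(migration distance) across groups defined by molt presence in a region.
The null distribution comes from `n_sim` BM simulations on the tree (rate
and root fitted to the observed variable), recomputing F against the fixed
labels; `p = (1 + #{F_sim >= F_obs}) / (1 + n_sim)` (the add-one estimator,
so p is never 0; default `n_sim = 1000`).  Zero within-group variance is
flagged degenerate (infinite F).  Per-region p-values are corrected by
Holm's sequential Bonferroni in a separate pass.

## d-sep path analysis

A candidate causal hypothesis is a DAG over migration distance, day length,
foraging stratum, molt extent and dichromatism extent.  Its basis set has
one conditional-independence claim per non-adjacent vertex pair: the
topologically later vertex is regressed (PGLS) on the earlier plus the
union of both vertices' parents, and the claim's p-value is the two-sided p
of the earlier vertex's coefficient.  Claims combine into Fisher's
`C = -2 sum ln p` (chi-square, `2k` df); models with `C`-statistic p below
`alpha = 0.05` are rejected, and survivors are ranked by
`CICc = C + 2qn/(n-1-q)` with `q` = directed edges + one variance per
vertex (the common convention; configurable).

The bundled 12-model candidate set is a **reconstruction**: the source
analysis describes only three of its twelve models.  The stated constraints
are encoded exactly — every model has migration -> day length; the two
favored models differ only in whether migration or day length parents molt,
both with molt and stratum parenting dichromatism; the best
molt-independent model replaces the molt -> dichromatism edge with a direct
migration effect.  Following that description the set is built as separate
either/or hypotheses (one molt parent crossed with one
dichromatism-driver hypothesis) rather than nested one-extra-edge variants:
a model that merely adds one edge to another trades a chi-square(2) claim
against a ~2.25-point CICc penalty and therefore ties it almost exactly,
which is inconsistent with the described clear separation between the
favored pair and the rest.  The set lives in a plain-text edge-list file
and is fully replaceable by the user.

## Range-derived predictors

Six migration-distance measures are computed from breeding/nonbreeding
polygons: midlatitude difference (the representative measure), maximum- and
minimum-latitude differences, the two crossed extreme-latitude differences,
and the great-circle centroid distance (haversine, 6371 km radius).
Latitude-difference measures are in degrees (111.32 km/deg for reporting);
strict nonmigrants — complete breeding/nonbreeding overlap — are zeroed on
all six, while partial migrants use the same formulas.  The representative
measure is chosen by mean R-squared against the other measures.  Range
latitudes are means over uniform in-polygon points (rejection sampling,
reproducible by seed).

Day length uses a closed-form solar-declination model (the CBM model:
`theta = 0.2163108 + 2 atan(0.9671396 tan(0.00860 (J - 186)))`,
declination `phi = asin(0.39795 cos theta)`), clamped to [0, 24] for polar
day and night, so the pipeline needs no gridded download.  The model's
orbital-anomaly term makes northern summers slightly longer; annual means
are 12 h within 0.06 h at mid-latitudes and drift to ~12.25 h at 80 deg,
which is physical, not error.  Gridded products (radiation, climate) are
consumed as in-memory lon/lat grids (`GridRaster`) sampled at uniform
in-polygon points (default 10,000), skipping no-data cells; extraction
windows are May-July (breeding) and November-February (nonbreeding) for
every species regardless of migrant class.  Solar exposure is the product
radiation x day length.

## The synthetic generator

`synthetic_data.generate_warbler_like_dataset` emulates a ~48-species
warbler clade on a unit-depth Yule tree:

- **migration distance** — zero-inflated (35% residents) with lognormal
  nonzero values (log-mean 2.8, log-sd 0.7, capped at 60 degrees) whose
  ranking follows a BM latent, so migratory behavior is phylogenetically
  clustered;
- **day length** — `12 + 0.0283 x migration + BM(sd 0.7)` hours/day; the
  slope spans ~1.7 h across the migration range, the span quoted between
  the extreme species of the real dataset;
- **molt extent** — latent `0.04 x migration + 1.2 x (daylength - 12) +
  BM(sd 3.0)`, discretized to half-step region scores by thresholds spaced
  uniformly over the latent range and filled head-first along the
  succession order (the half score at the moving front);
- **dichromatism** — latent `0.3 x molt extent + 1.5 x stratum +
  BM(sd 2.0)`, discretized the same way, then capped cell-wise by the molt
  matrix so dichromatism is nested within molt;
- **stratum and habitat** — BM latents cut at population quantiles into
  their ordinal ranges (phylogenetically autocorrelated ordinal codes);
  nest type iid (5/15/80% cavity/dome/cup); mass lognormal around 9.5 g.

Noise scales and coefficients were fixed by matching the order of magnitude
of the published pairwise PGLS effect sizes (day length ~ migration
adjusted R-squared ~0.5, molt ~ migration ~0.2, dichromatism ~ molt ~0.3,
a detectable stratum effect) and are part of the package's study
conditions, not tuning knobs.  Everything derives from one integer seed;
two runs with the same configuration are byte-identical.

What the generator does **not** emulate: measurement error in museum
scoring, real geography (ranges are synthetic rectangles when the range
module is exercised), non-BM residual structure, and the discreteness of
real migration classes.  Passing tests therefore demonstrate correctness
of the machinery and recoverability of the assumed causal structure — not
that the real data satisfy those assumptions.

## Numerical choices and degenerate inputs

- Cholesky factorization everywhere; singular covariances raise with a
  repair hint rather than being silently regularized (the generator adds
  1e-12 jitter only when *simulating*).
- Mk rates bounded in [1e-9, 1e4]; optimizer slack of 1e-6 lnL units is
  tolerated before a nesting violation is treated as an optimizer failure.
- Invariant characters are rejected with explicit errors in every fitting
  routine; groups with fewer than two members are rejected in the ANOVA.
- Fisher's C clamps p = 0 to 1e-300 and flags the clamp.
- MAP ties in ancestral states break toward absence and are flagged.
- Species present in only the tree or only the tables are pruned to the
  intersection, with both sides reported in the pipeline manifest.

## Problem sizes used by the test suite and acceptance script

Calibration and recovery experiments run at the sizes the analyses are
designed around: 48-species trees for the ANOVA and pipeline checks,
100-200 tips for parameter recovery and test calibration (100 replicates),
500 tips for discrete-rate recovery, and 60-100 replicates of the
100-species synthetic dataset for the path-analysis and model-ranking
recovery rates.

## Known limitations

- The OU fit estimates no separate optimum parameter (root state and
  optimum coincide), the standard two-parameter reduction on ultrametric
  trees; multi-optimum OU is out of scope.
- PGLS assumes homoskedastic BM-type residuals; ordinal predictors
  (stratum, habitat) enter as numeric scores.
- The d-sep p-values inherit whatever misspecification the PGLS models
  carry (discretized responses, capped nestedness); the claim-calibration
  test quantifies this under the generator's conditions.
- Gaussian fits to 0/1 presence data are a deliberate reproduction of
  common practice and are flagged, not endorsed.
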