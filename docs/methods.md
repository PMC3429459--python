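# Methods

## Scope and model

The package computes, for a study region partitioned into block groups
with a point supply layer of service facilities, nine measures of
spatial accessibility; constructs a composite socioeconomic deprivation
index; quantifies the measures' pairwise and spatial concordance; and
tests their predictive validity against an individual-level binary
outcome (late- vs early-stage diagnosis) with multilevel logistic
models. A seeded synthetic-geography generator supplies every input, so
all stages run and are tested without external data.

## Travel times

Block-group centroids and facilities snap to the nearest road node by
Euclidean distance; access time to the node itself counts as zero. The
origin–destination matrix holds Dijkstra shortest-path times in minutes
(one pass per facility node); an unreachable pair is infinite and is
excluded from all catchments and from the "five nearest" average. DST
is the row minimum; DST5 averages the `min(5, available)` smallest
finite times — with fewer than five reachable facilities the mean runs
over what exists, a degenerate case that arises only in toy inputs.

## Accessibility scores

Service density: `D_k = scale × Σ_{j : t_kj ≤ T₀} S_j / P_k`.

Two-step floating catchment area: `R_j = S_j / Σ_{k : t_kj ≤ T₀}
W(t_kj) P_k`, then `A_k = scale × Σ_{j : t_kj ≤ T₀} W(t_kj) R_j`. A
facility whose catchment holds no centroid has an undefined ratio; it
contributes nothing (logged), rather than erroring, mirroring the
study-boundary edge case of real regions. With `W ≡ 1` and `scale = 1`
the scores obey the conservation identity `Σ_k P_k A_k = Σ_j S_j` over
facilities with non-empty catchments, which the tests assert to 1e-9.

Weighting schemes (`DecaySpec`):

- `none` — indicator of `t ≤ T₀`.
- `zonal` — stepwise weights per travel-time band. Bands are half-open
  on the left, `((i−1)w, iw]`, with `t = 0` in band 1; the catchment
  boundary is inclusive (`t ≤ T₀`). Neither boundary rule is forced by
  the construction itself; they are fixed here so results are
  bit-stable. The four stock vectors are quick/slow 3-zone (10-min
  bands) and quick/slow 6-zone (5-min bands) profiles; quick ≤ slow
  beyond the first band, so quick decay shifts access toward near
  block groups.
- `continuous` — truncated normalized Gaussian
  `W(t) = (e^{−t²/2β²} − e^{−T₀²/2β²}) / (1 − e^{−T₀²/2β²})`, the form
  standard in Gaussian-2SFCA work, with `W(0) = 1`, `W(T₀) = 0`.

Key parameters: `T₀ = 30` minutes (catchment limit; conventional for
drive-time access studies), `β = 15` minutes (continuous bandwidth; a
free parameter — the zonal vectors are taken as given constants rather
than derived from a β, since no closed form reproduces them), `scale =
10⁴` (scores per 10,000 eligible women; cosmetic and configurable).
Multi-year supply is handled by scoring each facility-year and
averaging the DES/SA columns element-wise; travel-time columns ride on
the year-invariant network.

## Deprivation index

The 21 covariates are standardized; common factors are extracted by
iterated principal-axis factoring (initial communalities = squared
multiple correlations; reduced correlation matrix eigendecomposed;
communalities re-estimated to convergence, tolerance 1e-6, up to 2000
iterations — weak-factor data converge geometrically but slowly). The
number of factors defaults to reduced-matrix eigenvalues > 1, at least
one. Retained factors are varimax-rotated (Kaiser normalization); the
factor loading most heavily on the poverty variable is the deprivation
factor, sign-oriented so poverty loads positively.

Selection keeps variables with |loading| ≥ 0.60 — the threshold that
cleanly splits the reference loading profile (minimum selected 0.620,
maximum excluded 0.585). The composite index is the mean of selected
variables' z-scores, signed by loading, which is transparent, monotone
in each item, and affine-invariant; Thurstone regression factor scores
are available behind `use_factor_scores=True` since either construction
is defensible and the two correlate above 0.95 on single-factor data.
Internal consistency is Cronbach's α on standardized items.

## Agreement battery

Spearman correlations use average ranks for ties; constant columns
yield flagged NaNs. Quartile categories cut at linear-interpolation
percentiles, intervals closed on the right (a value at a cut takes the
lower category). Weighted kappa is `1 − Σw O / Σw E` with linear
disagreement weights `|i−j|` by default (the common epidemiology
choice; quadratic available), expectation from marginal products, and
a seeded nonparametric percentile bootstrap (default 1000 resamples)
for the 95% CI — chosen over asymptotic variance formulas because it
is assumption-light and exactly reproducible. Verbal labels follow the
Landis–Koch scale with κ ≤ 0 as "no agreement" and κ > 0.80 as
"perfect agreement".

## Spatial autocorrelation

Inverse-distance weights `w_ij = 1/d_ij^p` with default power 1, no
distance cutoff (every pair interacts), row-standardized — the
configuration matching the "all features influence one another,
declining with distance" convention while keeping I in its familiar
range. Global Moran's I uses the randomization-assumption moments
(`E[I] = −1/(n−1)`, the standard kurtosis-corrected variance) and a
symmetric normal-approximation CI. Local statistics are `I_i = z_i
(Σ_j w_ij z_j) / (Σz²/n)`, so `Σ_i I_i = S₀ × I` exactly — asserted in
the tests. Significance comes from conditional permutations (default
999): unit *i*'s value is held fixed, the rest permuted, one-tailed
pseudo-p in the direction of the observed statistic; significant units
are classed HH/LL/HL/LH by the quadrant of `(z_i, lag_i)`, with no
multiple-testing correction (the common LISA practice; an FDR variant
would be a thin wrapper).

## Predictive-validity models

Exposures dichotomize at the median: "low accessibility" is below the
median for score-type measures and above it for travel times;
"more deprived" is above the deprivation median. Ties go to the
reference (higher-accessibility / less-deprived) side — arbitrary but
fixed. The stratified form reuses the overall (not within-stratum)
median.

The model is logistic with a block-group Gaussian random intercept.
The marginal likelihood integrates the intercept by Gauss–Hermite
quadrature (15 nodes), maximized by L-BFGS-B over `(β, σ)` with the
analytic gradient computed from posterior node weights and σ bounded
at zero. Fixing `σ² = 0` makes the objective exactly the ordinary
logistic likelihood; tests require agreement with an independent
plain-logistic fit to 1e-6. Wald CIs come from the observed
information (numerical Hessian); when σ sits on the zero boundary the
Hessian is taken over β alone at the fixed σ. Scaled deviance is
−2 log-likelihood (Bernoulli saturated log-likelihood is zero).
Apparent divergence (|β| > 30) or a failed line search raises a
ConvergenceError naming the likely separation problem. Forms: I
(exposure + age), II (+ race), III (+ deprivation), joint (4-level
accessibility × deprivation factor, reference = more accessible & less
deprived), stratified (form II within deprivation strata).

## Synthetic generator

What it emulates: uniform distinct block-group centroids over a square
extent with integer lognormal populations (log-mean 5.7, log-sd 0.5 ≈
median 300 women 40+ — plausible block-group scale with a heavy right
tail); facilities clustered round 3 attraction centers with Gaussian
scatter (σ = extent/10), mimicking urban service concentration;
machine counts Poisson (mean 2, floored at 1) with ±1 per-year jitter
at 5% probability, emulating slight year-to-year supply change; a
connected road network (Delaunay triangulation of random points, or a
lattice), edge minutes = length / speed with default 0.8 km/min ≈ 48
km/h, giving 0–40-minute travel times at the default 40 km extent; 21
covariates from one latent standard-normal factor with the reference
loading profile and unit total variance; cases multinomial in
population with late-stage outcomes from the logistic model above.
Age marginals (0.25, 0.35, 0.40) and race marginals (0.60, 0.35, 0.05)
are fixed, overridable placeholders — no registry joint distribution
exists to estimate them from.

What it does not emulate: real street topology or congestion,
geocoding error, spatially correlated deprivation (the latent factor
is spatially white, so deprivation–accessibility confounding is absent
unless induced through the outcome model), facility quality
differences, or in-/out-of-region boundary flows. Passing tests
therefore demonstrate the correctness and calibration of the
*methods*, not substantive conclusions about any real region.

A disconnected network draw is regenerated up to 5 times before
failing (Delaunay networks are connected in practice; the retry guards
degenerate draws). Every generator is a pure function of its spec,
including the seed.

## Pipeline

`run_all` derives each stage's seed as SHA-256(master seed, stage
name) mod 2³¹, so stages are reproducible independently of execution
order; outputs are CSV/JSON/GeoJSON with sorted keys and no
timestamps, making reruns byte-identical (asserted in tests). A stage
failure aborts the run, records the stage name in the manifest, and
leaves earlier outputs in place.

## Problem sizes used in tests

Oracle comparisons run on ≤ 20 × 5 instances where a literal
triple-loop transcription is exact and fast; calibration experiments
use 200 block groups with 4000-case replicates (multilevel-model
recovery: mean log-OR over replicates within ±0.05 of log 1.2; null
CI coverage ≥ 90%); factor-recovery tests use 500 block groups, and
the loading-order test 4000, the size at which the 0.035 gap between
the 9th and 10th reference loadings exceeds sampling error.
End-to-end determinism is checked on a 200-block-group region. These
sizes were chosen so each property is statistically decidable while
the whole suite stays quick.

## Known limitations

- Dense spatial-weight matrices are O(n²) memory; fine for thousands
  of block groups, unsuitable for hundreds of thousands.
- The local-Moran permutation loop is vectorized per unit but still
  O(n × n_perm) per measure.
- Quadrature with a single random-intercept level only; no crossed or
  nested random effects, no spatial (CAR/BYM) effects.
- The continuous-decay β and the zonal vectors are taken as inputs;
  the package does not estimate decay parameters from data.
- Variable catchment sizes and three-step aggregation variants of the
  floating-catchment family are out of scope.
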