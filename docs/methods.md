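# Methods

This note records the models, conventions and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would need to know.

## Composite index (entropy weighting)

Indicators carry a direction flag: benefit indicators enter as
`(x − min)/(max − min)`, cost indicators as `(max − x)/(max − min)`.
The normalization scope is **pooled** by default — one min/max per indicator
across all unit-years — so scores are comparable across years, which the
year-over-year comparisons (Markov transitions, Gini series, density drift)
require. A per-year scope is available but changes the weights and breaks
cross-year comparability; it is offered for sensitivity analysis only.

Weights use Shannon entropy over the m = units × years observation rows with
the limit convention `0·ln 0 = 0`. An `epsilon_shift` option adds a small
offset before forming shares instead, for users who prefer the
perturbation convention; the default is the limit convention because it
keeps exact zeros exact. A constant indicator has maximal entropy and zero
redundancy: it receives weight 0 with a warning rather than aborting —
an indicator that does not vary carries no ranking information. If *every*
indicator is constant the weights are undefined and the call errors.

Scores are the weighted sum of standardized values, clipped to [0, 1]
against floating-point spill. Level bands ("quintiles") use either explicit
cut points (right-closed intervals, so a score at a cut belongs to the band
below) or equal-width bands over the observed range.

## Standard deviation ellipse

Coordinates are treated as planar; geographic lon/lat input is projected by
an equirectangular projection about the mean latitude (adequate at
provincial extent; not for continental data). Deviations are taken about
the weighted mean center; the azimuth solves the usual quadratic form

    tan θ = [ (Σw x̃² − Σw ỹ²) + √((Σw x̃² − Σw ỹ²)² + 4(Σw x̃ ỹ)²) ] / (2 Σw x̃ ỹ)

and σ_x, σ_y are the weighted standard deviations along the rotated axes
with the **Σw normalizer** (each deviation weighted once). A variant that
weights deviations twice and normalizes by Σw² — a form that appears in
some applied papers — is available as `normalization="printed"`; it is not
the default because it makes the axis lengths scale with the weights'
magnitude, which breaks the invariance under uniform weight rescaling that
a summary of *where mass sits* should have. The reported azimuth is that of
the major axis, clockwise from north, in [0°, 180°). Collinear inputs yield
a degenerate ellipse (minor σ = 0) flagged, not an error.

## Kernel density dynamics

Standard KDE, `F(x) = (1/nh) Σ K((X_i − x)/h)`, evaluated on a 512-point
grid spanning the sample range ± 4h. Kernel: Gaussian by default
(Epanechnikov available); bandwidth: Silverman's rule
`0.9·min(sd, IQR/1.34)·n^(−1/5)` when "auto". A zero-variance sample has no
defensible automatic bandwidth and errors with advice to pass `h`.

Shape descriptors drive the narrative summaries: peaks are local maxima
with prominence ≥ 5% of the main-peak height (the threshold that makes
"weak bimodal" vs "unimodal" judgments reproducible at all — without a
prominence floor every ripple is a peak). The polarization label uses the
side-peak/main-peak height ratio: ≥ 0.5 → bimodal, ≥ 0.25 → main+side-peak,
below → weak-bimodal, no side peak → unimodal. FWHM is measured by walking
the grid from the main peak to the half-height crossings; tail masses are
the density mass beyond ± one FWHM of the peak.

## Markov chains

Classes come from pooled quantile cuts over the full window (default K = 4)
— pooled, not per-year, because single cut values quoted for a whole
observation window only make sense pooled. Intervals are half-open
`(lo, hi]` with the lowest closed, so a score exactly at a cut belongs to
the lower class. Ties that collapse quantile cuts raise with advice to pass
explicit cuts.

The spatial variant conditions each transition on the unit's **lag class**
at the origin year: the class of its neighbor-weighted average score,
discretized with the *same* cuts as the scores (this is what makes
"adjacent to class K" well defined). Spatial weights default to
row-standardized first-order contiguity; any nonnegative zero-diagonal
matrix is accepted and row-standardized, and an isolated unit is an error
naming the unit. Conditional counts sum over lag classes to the
unconditional counts exactly (integer identity, tested).

Empty rows (a class never occupied at an origin year) are reported as NaN
probabilities, not zeros — an unvisited state has no estimated distribution.

## Dagum Gini decomposition

For one cross-section split into groups j with sizes n_j and means ȳ_j
(grand mean ȳ, n units total):

    G     = Σ_i Σ_r |x_i − x_r| / (2 n² ȳ)
    G_jj  = Σ|x_ji − x_jr| / (2 n_j² ȳ_j)            p_j = n_j/n
    G_jh  = Σ|x_ji − x_hr| / (n_j n_h (ȳ_j + ȳ_h))   s_j = n_j ȳ_j/(n ȳ)
    G_w   = Σ_j G_jj p_j s_j
    G_nb  = Σ_{j>h} G_jh (p_j s_h + p_h s_j) D_jh
    G_t   = Σ_{j>h} G_jh (p_j s_h + p_h s_j)(1 − D_jh)

with the relative affluence `D_jh = (d_jh − p_jh)/(d_jh + p_jh)`, where
d_jh is the mean positive excess of the richer group over the poorer and
p_jh the mean positive excess the other way, the richer-on-average group
taken as j (region order breaks exact mean ties) so D ∈ [0, 1]. The
additive identity G = G_w + G_nb + G_t then holds to machine precision and
is asserted at 1e-10 over 1000 random group splits in the tests; the
brute-force oracle enumerates pairs directly so the closed forms are
independently checked. γ in the overall formula is the grand mean — for the
cross-section Gini no other reading makes the statistic scale-free.

The Gini is undefined for nonpositive means (scores are positive by
construction, so this only bites on degenerate input) and exactly zero for
a perfectly equal cross-section, in which case contribution rates are
reported as 0 rather than 0/0.

## Panel regression

FE is OLS on unit-demeaned data; RE is feasible GLS with Swamy–Arora
components (σ²_ε from the within residuals, σ²_u from the between
regression, quasi-demeaning parameter θ = 1 − √(σ²_ε/(Tσ²_u + σ²_ε))).
"Robust" means cluster-robust by unit with the usual G/(G−1)·(N−1)/(N−k)
correction; HC1 is available. Reported t-values are coef / robust SE.

Specification battery: F for joint unit-effect nullity (pooled vs within
SSRs), Breusch–Pagan LM on pooled residuals (balanced-panel form), and
Hausman on the common slopes. The Hausman statistic uses **classical**
covariances computed with a *common* σ² taken from the efficient model's
residuals: with a common σ² the within moment matrix is dominated by the
quasi-demeaned one, so V_FE − V_RE is positive semidefinite by
construction. (With two separate variance estimates the difference is
frequently indefinite in finite samples — in simulation roughly a third of
null replicates — which silently corrupts the statistic; the common-σ²
form restores exact nominal size in our null simulations.) A robust
Hausman is not well defined and is not offered.

FE R² is computed on the within-transformed model (share of within
variance explained), a definition that is stable across unit relabelings.

## Threshold regression

Hansen-style concentrated least squares on the within-transformed panel.
The candidate grid is the set of unique observed threshold-variable values
after 1% two-sided trimming, subsampled to at most 100 quantile points
(`max_grid`) — estimation error below one grid step is meaningless, and the
subsample keeps the bootstrap affordable. A candidate is excluded when any
regime would hold fewer observations than the regression has columns.
Multiple thresholds are found sequentially with one back-refinement of the
first threshold after the second is located.

The threshold variable itself stays in the model as a control: only the
regime variable's slope switches at γ. Omitting the threshold variable's
level effect provably biases γ̂ (verified on noiseless generator data:
recovery is within one grid step with the control present and off by
several steps without it).

Bootstrap F tests: for the k-th threshold, F_k = (SSR_{k−1} − SSR_k)/σ̂²
with σ̂² from the larger model; the null distribution regenerates data from
the (k−1)-threshold fit plus i.i.d. resampled within-residuals, re-searching
all thresholds on each replicate. Confidence sets invert
LR(γ) = (SSR(γ) − SSR(γ̂))/σ̂² at Hansen's critical value
−2·ln(1 − √level). The interval always contains γ̂ and collapses to the
grid cell under vanishing noise.

## Synthetic generator

The generator emulates the study conditions: 21 units in four regions
(9/4/3/5), 17 years, 20 directional indicators. One latent quality process
drives all indicators: region baseline + spatially autocorrelated unit
effect (SAR, `u = (I − ρW̃)⁻¹η` on the row-standardized Delaunay contiguity
of the region-clustered centroids, ρ = 0.4 by default) + linear regional
trend + noise; benefit indicators load positively on the latent, cost
indicators negatively. Spatial dependence is injected on the *unit
effects*, not the noise, so spillover signals (Moran correlation, spatial
Markov conditioning) are stable across years.

Covariates are calibrated to the published summary moments of the real
N = 357 panel (means/sds, truncated at their printed bounds). The pooled
variance of each covariate is split between between-unit, common-trend and
idiosyncratic components as 0.35/0.55/0.10: trend-dominant, because log
per-capita output in these prefectures grew by roughly 1.5–2 log points
over the window, so most pooled variance is common growth while
cross-sectional gaps persist. This matters for the threshold stage — units
must *cross* the thresholds within the window for γ to be identified — and
is exactly the feature of the real growth episode that makes Hansen
estimation feasible there. The published maximum for the urbanization rate
(3.5942, identical to the fiscal ratio's maximum and impossible for a
population share) is treated as ratio-like: the generator matches the
printed mean/sd and truncates at zero only.

The composite score is generated from the panel regression with unit fixed
effects, slopes at the published fixed-effects estimates (lnPGDP 0.0483,
FSS 0.0300, lnDEN 0.0147, UR 0.0117, ISU 0.0003), and — by default —
piecewise regime slopes for UR (0.0359/0.0523/0.0687 switching at lnPGDP
9.7638 and 11.5076) and FSS (0.0484/0.0658/0.0831 at 9.8257 and 11.4208);
the middle regime coefficients are midpoints, since only the outer two are
published for the double-threshold fits. The linear predictor is
intercept-shifted to the published score mean, a constant absorbed by the
fixed effects that keeps the score on its observed scale. `threshold_vars`
selects which slopes are piecewise — single-variable plants are what the
threshold-recovery tests use, since planting both confounds either fit's
regime split with the other's unmodelled one.

All draws come from `numpy.random.default_rng([seed, stream])` with a fixed
stream id per output, so regeneration is bit-identical and adding an output
never perturbs earlier draws.

**What passing tests do and do not show.** The generator produces linear
trends, Gaussian noise, exact moment calibration, and a score that obeys
the regression equation by construction. Real yearbook panels have
measurement revisions, serially correlated shocks, interpolated census
quantities and regime effects that are at best approximately piecewise —
so recovery results here certify the *machinery* (estimators find what was
planted, identities hold, tests are correctly sized), not that the
published point estimates would be reproduced from the real data, which
are not distributed with the paper.

## Problem sizes used in checks

Recovery and calibration checks run at the study's own cross-section size
(N = 357): 60 replicates for the regression recovery, 6 for the
double-threshold recovery (small score noise, σ = 0.005, so location error
is grid-limited rather than noise-limited), 50 replicates × B = 100 for the
bootstrap size check, and 10 × n = 1000 for the KDE calibration. These
sizes put Monte-Carlo error comfortably below the effects being checked
while keeping the default suite fast.

## Missing data

Interior gaps in a unit-indicator series are filled by linear interpolation
in the year; leading/trailing gaps take the nearest observed value (a pure
line is undefined there, and carrying the nearest value is the conservative
choice that never extrapolates a trend). A series with fewer than two
observations cannot anchor a line and errors, naming the unit and
indicator. Interpolation never alters observed cells.

## Known limitations

* The SDE stage summarizes second moments only; it does not draw geodesic
  ellipses and its equirectangular projection degrades beyond provincial
  scale.
* The spatial Markov tensor conditions on the origin-year lag class only
  (first-order conditioning), as is standard.
* RE relies on balanced panels; unbalanced input is rejected at the data
  model rather than handled.
* The bootstrap is i.i.d. residual resampling within the fixed-effects
  transform; it does not preserve serial dependence (a wild/block variant
  would, and the hook exists, but it is not implemented).
* Threshold location error under the generator's default score noise
  (σ = 0.02) is several grid steps for the small published regime jumps
  (~0.016); this is a property of small effects, not of the search, which
  is exact (global SSR minimizer, verified against exhaustive joint search).
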