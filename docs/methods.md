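# Methods

## The estimation problem

River-dolphin abundance surveys in large dammed rivers mix two protocols.
Cross-channel **line transects** traverse open water (river channel,
reservoir); detectability declines with perpendicular distance from the
trackline and is modelled explicitly. Shore-parallel **strip transects**
census a fixed 200 m band along margin habitats from a trackline 100 m
offshore; here no distance function is refitted per survey — each sighting
is instead weighted by a fixed detection probability for its
distance-from-shore band, imported from a large multi-survey *Inia* fit.
Both protocols share a double-platform design: bow and stern teams on a
double-decker boat search with "one-way" independence (the stern is blind to
bow detections), which yields the trackline detection probability g(0).

Density is estimated per habitat × geographic-stratum cell and scaled by
the cell area to abundance; the strata (downstream of the dam, two reservoir
sections, upstream) absorb the strong longitudinal density gradient the dam
imposes.

## Estimators

**Line transects.** For a cell with n detected groups, mean observed group
size E(s), pooled-fit detection density f(0) = 1/ESW and effort L:

    D = n · E(s) · f(0) / (2 · L · g(0))        [individuals / km²]

The detection function is fitted once on the pooled line data (the cells
individually have too few sightings) and only the encounter rate and group
size are stratified.

**Detection function.** Perpendicular distances within the truncation
distance w (default 300 m) follow a half-normal `exp(−x²/2σ²)` or
hazard-rate `1 − exp(−(x/σ)^−b)` key. Covariates (log group size, a stern
indicator) enter the scale log-linearly, the multiple-covariate
distance-sampling convention. The conditional likelihood
Π g(xᵢ|zᵢ)/∫₀ʷ g(u|zᵢ)du is maximized by multi-start L-BFGS-B (initial
σ₀ = sd of the distances, b₀ = 2; five jittered restarts; 1e-12 relative
tolerance on the objective). The half-normal integral uses the erf closed
form; the hazard-rate integral uses 96-point Gauss–Legendre quadrature.
Candidates are ranked by AICc with n = the number of fitted sightings.
No cosine/polynomial adjustment terms are offered: the candidate space is
key × covariates. The covariate-averaged ESW is the mean of per-observation
ESWs (the Horvitz–Thompson-consistent choice), and its CV comes from the
delta method through the inverse observed information (finite-difference
Hessian, relative step 1e-4 — accurate to ~1e-7 against the closed-form
half-normal information).

**g(0).** With n₁ stern sightings within 50 m of the trackline and n₀₁ of
them missed by the bow, q = n₀₁/n₁ estimates the single-platform miss
probability and g(0) = 1 − q². Only stern sightings inform q (one-way
independence); bow-conditional recaptures are not used. The default CV
treats q as binomial and propagates with |dg0/dq| = 2q; a seeded
nonparametric bootstrap is the alternative and the automatic fallback when
q ∈ {0, 1}. The estimator assumes the two platforms share the same
trackline miss probability; when they differ (as the simulator can
generate), 1 − q̂² targets 1 − (1 − p_bow)² rather than the true combined
probability — a documented limitation of the closed-form rule.

**Strip transects.** Bands 50–100 m and 100–150 m from shore lie within
50 m of the trackline and get probability P1 = 0.960; the outer bands
(0–50, 150–200 m) get P2 = 0.630. Density is

    D = E(s) · [n₁/P2 + n₂/P1 + n₃/P1 + n₄/P2] / (W · L · g(0))

with W = 0.2 km — a per-group Horvitz–Thompson correction (each group
weighted by the reciprocal of its band probability; the equivalence is
enforced by test). P1/P2 are treated as known constants; the external fit
they come from is not reproduced here. Sightings lacking a shore band but
carrying a perpendicular distance have the band derived (inshore side when
ambiguous — both candidates share a probability when the trackline runs
mid-strip); records with neither are dropped with a warning. The band map
is defined for the 4 × 50 m geometry only; other widths are rejected.

**Variances.** Encounter-rate variance is the classical length-weighted
between-transect estimator, var(n/L) = k/(L²(k−1)) Σ lᵢ²(nᵢ/lᵢ − n/L)².
The encounter rate itself is the pooled ratio n/L by default; a
mean-of-per-transect-ratios alternative sits behind
`AnalysisConfig.encounter_rate` because the two readings of "mean number of
groups per km" differ on unequal transect lengths. Cell CVs combine
independent components in quadrature: CV²(D) = CV²(n/L) + CV²(ESW) +
CV²(E(s)) + CV²(g0) for lines, with the ESW term replaced by nothing for
strips (P1/P2 known). Group size uses the plain observed mean — no
size-bias regression, appropriate for groups of 1–2 animals.

**Aggregation.** N = D·A per cell with SE(N) = SE(D)·A (areas known).
The total CV is deliberately the ratio of *summed SEs* to summed
abundances, ΣSE/ΣN — conservative relative to the root-sum-of-squares (it
equals it only when one cell dominates) but the convention this analysis
follows. Confidence intervals are the conventional distance-sampling
log-normal form N·exp(±z√ln(1+CV²)); the "most conservative" headline
abundance is the lower bound of the post-stratified total. Report rounding
(N to integers, D and CV to 2 decimals) applies only to display; full
precision is kept internally.

## The synthetic survey generator

Each habitat × stratum cell is an abstract rectangle of the stated area —
the estimators consume only distances, bands and areas, so no explicit
river geometry is modelled. Groups arrive as a homogeneous Poisson process
at the cell's group density (individual density / mean group size); group
size is 1 + Poisson(mean − 1), a zero-truncated surrogate for the 1–2
animal groups of river dolphins. Line-transect groups get a uniform
perpendicular offset within the simulated swath (default 300 m); strip
groups a uniform offshore position in [0, 200] m with the trackline fixed
100 m offshore. Each platform detects independently (conditional on
distance) with probability p_platform · g(x), where g is a half-normal or
hazard-rate key and a log-scale platform effect can shrink or stretch the
stern's range; groups seen by both platforms emit a duplicate-linked pair
of records. For calibration runs the strip protocol can instead detect with
the exact band probabilities P1/P2, making the strip estimator unbiased by
construction.

Not emulated: animal movement (attraction/avoidance of the vessel),
availability bias from diving, observer fatigue, measurement error in
angles and distances, and violations of the 100 m shore offset. Passing
tests therefore demonstrate internal consistency of the estimators under
their own assumptions, not robustness to these field realities.

## Validation design and problem sizes

Closed-form oracles anchor the numerics: the untruncated half-normal MLE
σ̂² = Σx²/n (and its delta-method CV(ESW) = 1/√(2n)), hand-evaluated
density formulas, the two-transect encounter-rate variance, and the
per-group Horvitz–Thompson sum. Stochastic properties use seeded
replication at sizes chosen to keep the default suite fast while leaving
Monte-Carlo error well below the effect being tested: hazard-rate parameter
recovery over 100 replicates of 500 distances (σ within 20%, b within 30%,
≥90% success); line- and strip-density recovery over 200 replicates
(mean ratio within 3 MC standard errors of 1); platform-covariate model
selection over 100 replicates (the +platform model out-ranks the null in
≥80%); and the stratification contrast over 100 replicates of a two-stratum
survey with a 16-fold density difference, where geographic stratification
lowers the summed-SE total CV in the clear majority of runs. That last
scenario uses long (5 km) strips so between-stratum heterogeneity dominates
per-transect Poisson noise; with sparse counts the summed-SE total CV can
favor pooling, which is a property of the convention, not a bug.

## Design choices on genuinely open points

- The published survey's confidence-interval method is unstated; the
  log-normal interval is used and labelled as this package's assumption
  (it does not reproduce the published bounds, which appear to involve
  stratum-level lower bounds).
- Angles beyond abeam (> 90°) are rejected rather than folded; the search
  protocol makes them recording errors.
- Duplicate identification between platforms is taken as given in the
  input (`duplicate_of`); no time/position re-matching is attempted.
- Optional distance binning is omitted entirely rather than half-supported;
  exact distances are the estimator's input.
- The total CV follows the summed-SE convention literally, with no
  covariance terms between cells.

## Known limitations

- The g(0) rule assumes equal platform-level trackline detection; see
  above.
- Pooled detection fits assume a common distance law across habitats and
  strata; a strong habitat-detection interaction would bias cell densities.
- Single-survey scope: no trend estimation, no spatial density surface.
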