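# Methods note

This note records the statistical model implemented by `mpameta`, its
assumptions, the default parameter values and why they were chosen, what
the synthetic data generator does and does not emulate, and the numerical
choices inside the estimators. No empirical claim here goes beyond what
the test suite and `scripts/acceptance.py` actually compute.

## 1. Effect sizes (`mpameta.effects`)

For each MPA *j*, ecosystem, survey year *i* and species target status,
the effect of protection is the log response ratio of replicate-mean
biomass,

    Y_ji = ln( X̄_inside / X̄_outside ).

**Zero adjustment.** Reference sites occasionally yield all-zero samples,
leaving Y undefined. Before taking ratios, any pair containing a zero mean
has a small constant added to *both* members: 10% of the mean of all
values in the (ecosystem, year, protection level, side) stratum, each side
receiving its own side's stratum constant (adding to one side only would
bias the ratio). Pairs whose stratum is itself all zeros are excluded as
insufficiently sampled rather than forced to Y = 0. Because biomass is
computed separately per target status, status-specific tables use
status-specific strata; diversity tables carry a single pooled status, so
their strata are exactly the four keys above. A `stratum_wide` mode that
adjusts every pair is available for sensitivity analysis.

**Within-study variance.** The default (`as_printed`) form is

    v = sd_in² / (n_in · X̄_in) + sd_out² / (n_out · X̄_out),

with first-power means in the denominators. This form is **not** invariant
to the measurement scale; it is retained as the default because it is the
form the downstream weighting is defined with. The standard delta-method
variance of a log ratio (means squared in the denominators), which is
scale-invariant and has nominal coverage properties, is available as
method `"delta"` and is what the calibration tests use. The method used is
recorded on every effect row.

**Most-recent-year filter.** When an MPA × ecosystem is surveyed in
several years, cross-sectional pooling keeps only the latest year
(longest protection duration); the feature model instead uses all annual
rows, since year is a model term.

## 2. Random-effects pooling (`mpameta.pooling`)

Effects are pooled with inverse-variance random-effects weights:

    R̄ = Σ wᵢYᵢ / Σ wᵢ,   wᵢ = 1/(vᵢ + τ²),
    Q  = Σ wᵢ(Yᵢ − R̄w)²  (fixed-effect weights 1/v),
    τ² = max(0, (Q − (k−1)) / (k−1)),
    se = √(1/Σ wᵢ),  95% CI = R̄ ± 1.96·se,  two-sided normal p-value.

The weights, Q and τ² are mutually defined, so the estimator runs in the
conventional two-pass order: Q under fixed-effect weights, τ² from Q, then
random-effects weights. Note the τ² denominator is k − 1, not the
DerSimonian–Laird constant Σw − Σw²/Σw; with k − 1 the estimator inflates
τ² somewhat under homogeneity, making the pooled test mildly conservative
(measured type-I error ≈ 3.2% at nominal 5% in the calibration test with
delta variances, k = 10 studies of n = 25 lognormal replicates per side;
CI coverage ≈ 96.8%). A Student-t reference with k − 1 df is available via
`use_t`.

Pooling runs at four scales — single MPA (pooling its ecosystems),
ecosystem, region, network — always stratified by target status ×
protection level. A single-study group passes through with se = √v.

**Variance floor.** A zero within-study variance would give one effect
infinite weight; zero variances are replaced by 0.1 × the smallest
positive variance in the pooling group (fallback 1e-6 if the whole group
is degenerate). The number of floored effects is reported.

## 3. Biomass assembly (`mpameta.assembly`)

Individual fish weights come from the allometric law W = a·L^b (grams for
lengths in cm); counts without recorded lengths fall back to the species'
mean length. Replicates with no fish of a status get explicit zero rows so
replicate means include true zeros. The pipeline converts replicate
biomass from grams to kilograms before pairing: the `as_printed` variance
is scale-dependent, and kilogram replicate totals keep means of order one
so meta-analytic weights are on a sensible scale.

Target status is classified from fisheries catch volumes in two stages
(any positive catch → targeted; at/below a bycatch threshold →
nontargeted) with explicit overrides applied last. Protection is per MPA ×
ecosystem: an MPA allowing some take is still *de facto* no-take for an
ecosystem when that take cannot affect the ecosystem's resident species
(e.g. an SMCA allowing only salmon take is no-take for all four focal
ecosystems).

## 4. Biodiversity (`mpameta.biodiversity`)

Richness and Shannon diversity H = −Σ pᵢ ln pᵢ are computed at the MPA
level (abundances summed across replicates, because sampling is
depth-stratified and replicate-level composition is not comparable).
Inside/outside contrasts are log response ratios with the same stratified
zero adjustment as biomass, and each ecosystem × metric is tested with a
two-tailed one-sample t-test of the ratios against zero, keeping one
(most recent) response per MPA to avoid pseudo-replication. Under a null
with identical composition on both sides the tests reject at ≈ 5%
(verified in the acceptance suite).

## 5. Feature model (`mpameta.gam`)

Annual no-take targeted effects are modelled as an additive function of
eight MPA features (age, size, habitat diversity, habitat richness,
proportion rock, pre-implementation landings, ecosystem-specific and total
larval settlement) plus a cyclic cubic spline in survey year. Observations
are weighted by w = 1/(v + τ²) with τ² from the network-level pool of the
same stratum.

The fit is penalized weighted least squares: cubic B-spline bases with
second-derivative penalties (basis dimension 5 by default; features with
fewer than 5 distinct values fall back to a centered linear term), the
cyclic year basis with its last column dropped for identifiability.
Smoothing parameters minimize

    GCV = n · RSS_w / (n − EDF)²

by Nelder–Mead over log-smoothing-parameters (two starts, 0 and 4;
bounded at ±15; a ~1e-9 relative ridge stabilizes the normal equations).
Weights are normalized to mean 1, so the fit is invariant to rescaling all
weights. Term EDFs are block traces of the hat-matrix analogue; term
p-values are approximate Wald χ² tests with rank rounded from the EDF.
The implementation is cross-checked against R `mgcv`'s cubic regression
spline GAM with GCV smoothing in the test suite (fitted values agree to
r > 0.99 on a common benchmark).

**Forward selection.** Starting from intercept + year, the candidate
smooth that most reduces GCV is added greedily; selection stops when the
best addition improves GCV by less than a relative tolerance, default
**1e-2**. The tolerance is deliberately not tiny: adding one pure-noise
smooth changes GCV by roughly (Z² − 2)/(n − d) in relative terms with
Z² ~ χ²₁, so with 8 candidates and a near-zero tolerance the null model
would admit at least one spurious term in most runs. At n ≈ 300, 1e-2
keeps per-candidate false inclusion near 2.5% while true drivers at the
generator's default slopes reduce GCV by ≳ 10% (the acceptance suite
verifies ≥ 80% power for both true features and a majority-empty null).

## 6. Synthetic generator (`mpameta.synthetic`)

All randomness flows from one seed; stages draw from
`default_rng([seed, stage])` (0 = species pool, 1 = network, 2 = surveys).

**What it emulates.** Four regions, four ecosystems, paired inside/outside
sites, replicate units with per-species counts and individual lognormal
body lengths; targeted vs. nontargeted species with allometric parameters
drawn in recorded bounds (a log-uniform on [0.005, 0.05], b uniform on
[2.5, 3.5]); the protection effect on targeted abundance

    effect = β₀ + β_age·age + β_habdiv·habitat_diversity + u,  u ~ N(0, σ),

with defaults β₀ = 0.2, β_age = 0.03, β_habdiv = 0.3, σ = 0.2 (chosen so
a typical ~10-year-old MPA has a realistic effect near ln(2) and features
are recoverable at the default network size); nontargeted species respond
with an attenuated multiple (0.25) of the same effect; counts are negative
binomial (dispersion 1.5, var = μ + μ²/1.5 — survey counts are
overdispersed); inside means are outside means × exp(effect) in no-take
MPAs only; outside replicates are all-zero with probability 0.05 (heavily
fished reference sites); hook-and-line gear on the shallow reef has zero
catchability for nontargeted species, so they never appear there and their
shallow-reef strata are excluded structurally downstream; all-zero
replicates are registered with an explicit count-0 row.

**What it does not emulate.** Spatial autocorrelation between nearby MPAs,
temporal autocorrelation of counts within a site, species interactions,
observer or gear calibration error, length-dependent protection effects
(an optional inside length-shift knob exists but defaults to 0), and any
real coastline geography. Feature columns other than age and habitat
diversity are pure noise with respect to the true effect, which is exactly
what the selection-specificity tests require.

## 7. Limitations

- The `as_printed` variance is scale-dependent; results of the default
  pipeline depend on the kg measurement scale, which is why the
  calibration guarantees are stated (and tested) for the `delta` method.
- τ² with denominator k − 1 is conservative under homogeneity (see §2) and
  is not the standard DerSimonian–Laird estimator.
- Wald χ² term p-values in the additive model ignore smoothing-parameter
  uncertainty.
- The normal-reference pooled p-value understates uncertainty at very
  small k; `use_t` is provided but not the default.
- Forward selection on GCV inherits GCV's known tendency to occasional
  undersmoothing; the stopping tolerance trades a little power for null
  specificity.
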