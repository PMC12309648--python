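# mpameta

Meta-analytic evaluation of a marine protected area (MPA) network's
conservation performance, with a fully synthetic, seeded data generator for
testing and calibration.

## The scientific problem

Coastal MPA networks are monitored by paired surveys: replicate sampling
units (seine hauls, transects, hook-and-line cells) inside each MPA and at
a matched reference site outside it, across four ecosystems (surf zone,
kelp forest, shallow reef, deep reef). The question is whether biomass of
fished ("targeted") species is higher inside than outside, how that effect
varies across MPAs, ecosystems and regions, and which MPA features (age,
size, habitat, larval settlement, pre-implementation fishing pressure)
drive it. Nontargeted species act as a quasi-control: they should respond
much less to protection.

## Core model

1. **Effect sizes.** For each MPA × ecosystem × year × target status, the
   effect of protection is the log response ratio
   `Y = ln(mean_inside / mean_outside)` of replicate-mean biomass, with a
   within-study sampling variance `v` attached. Pairs containing a zero
   mean are first adjusted by adding a small stratum constant (10% of the
   (ecosystem, year, protection, side) stratum mean) to both sides.
2. **Random-effects pooling.** Effects are pooled at four scales (MPA,
   ecosystem, region, network), stratified by target status × protection
   level, with inverse-variance weights `w = 1/(v + τ²)`. The
   between-study variance τ² comes from the heterogeneity statistic Q via
   `τ² = max(0, (Q − (k−1))/(k−1))`.
3. **Biodiversity.** Species richness and Shannon diversity are computed
   at the MPA level (replicates pooled), contrasted as log response
   ratios, and tested per ecosystem with one-sample t-tests.
4. **Feature model.** Annual no-take targeted effects are regressed on
   eight MPA features with a weighted penalized additive model (cubic
   spline smooths, cyclic spline in year); smoothing parameters minimize
   GCV and model terms are chosen by greedy forward selection on GCV.

See [docs/methods.md](docs/methods.md) for assumptions, parameter defaults
and numerical choices.

## Worked example

Pooling two effect sizes by hand-checkable arithmetic:

```python
from mpameta import pooled_effect

pe = pooled_effect([0.0, 2.0], [1.0, 1.0])
print(pe.R_bar, pe.Q, pe.tau2, pe.se)
# 1.0 2.0 1.0 1.0
```

(Fixed-effect weights 1/v = 1 each give the mean 1, so
Q = (0−1)² + (2−1)² = 2; τ² = (2 − 1)/1 = 1; random-effects weights
1/(1+1) = 0.5 each give the pooled mean 1.0 and se √(1/Σw) = 1.0.)

Running the full pipeline on a simulated network (50 MPAs, default
generator settings, seed 1):

```bash
mpameta all --seed 1 --outdir out
```

which writes every stage's CSV plus `manifest.json` to `out/`. With seed 1
the network-scale pooled effects are:

| stratum | k | R̄ | se | p |
|---|---|---|---|---|
| targeted, no-take | 96 | 1.054 | 0.267 | 8.0e-05 |
| nontargeted, no-take | 70 | 0.209 | 0.242 | 0.39 |
| targeted, partial-take | 49 | −0.081 | 0.326 | 0.80 |

i.e. a strong positive effect of full protection on targeted biomass, an
attenuated and nonsignificant response of nontargeted species, and no
effect in partial-take MPAs — exactly the structure the generator encodes.

## Reproduction

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the entire pipeline from a single seed and writes the headline
quantities (network/ecosystem pooled effects, heterogeneity statistics,
per-MPA significance proportion, diversity tests, additive-model fit
summary) as JSON; all randomness flows from `--seed`, so results are
reproducible bit-for-bit. Identical config and seed also give
byte-identical pipeline output directories (tested).
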