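# pmrnhier

Hierarchical Bayesian estimation of **probabilistic maturation reaction
norms** (PMRNs) from sparse fish survey data.

A PMRN gives the probability that an immature fish *first* matures as a
function of its age and size, separating genuine change in maturation
schedules from the plastic effect of faster or slower growth.  Estimating
PMRNs per cohort is the standard way to ask whether a harvested population
is evolving toward earlier maturation — and whether closing a fishery
reverses the trend — but classical estimators collapse when a cohort has
too few immature fish.  `pmrnhier` fits a joint hierarchical Bayesian
model of maturity, growth, and body condition in which cohort-level
coefficients share a common hyperdistribution, so sparse cohorts borrow
strength instead of being dropped.

The model, for fish *i* of cohort *c* (covariates z-scored):

    y_i ~ Bernoulli(o_i),
    logit o_i = β1[c] + β2[c]·a + β3[c]·l + β4[c]·w + β5[c]·a·l
              + β6[c]·a·w + β7·f + β8[c]·t + β9[c]·p
    l_mm,i ~ Normal(φ[c] + γ[c]·ln a,  τ)              (growth, mm)
    w_z,i ~ Normal(ω1[c] + ω2[c]·a + ω3[c]·l + ω4[c]·a·l,  ζ)  (condition)

with βk[c] ~ N(μk, σk) hierarchies (β7, the fishery indicator effect, is
global), μk ~ N(0,10), σ ~ half-Cauchy(0,5), and N(100,20) hyperpriors on
the growth means.  Body condition is indexed by relative weight,
Wr = 100·W / Ws(TL) with log10 Ws = −5.386 + 3.230·log10 TL.

From each posterior draw the probability of first maturation is

    m = (o − o_prev) / (1 − o_prev),  floored at 0,

where o_prev evaluates the fish's reconstructed previous-year state (age
a−1, length l−Δl from the growth model, condition w−Δw, lagged
environment).  Per cohort × age class, a logistic regression of m on
length yields the midpoint **Lp50 = −intercept/slope** — the length at 50%
first-maturation probability — per draw, giving full posterior
distributions of Lp50 with principled exclusion rules (cells with < 2
fish, non-positive slopes, or > 5% excluded draws are flagged).

Sampling uses a built-in No-U-Turn HMC kernel with analytic gradients;
convergence is checked by split R-hat (< 1.1) and bulk effective sample
size for every parameter.  A synthetic-cohort generator runs the same
equations forward with known parameters for validation and demos.
See `docs/methods.md` for the full model account.

## Worked example

```sh
# 1. simulate a survey with a fishery closure and known ground truth
pmrnhier simulate --seed 5 --out simdata

# 2. fit the joint model (here a reduced protocol; default is 3 x 4000)
cat > fit.yaml <<'YAML'
fit: {chains: 3, iterations: 1000, warmup: 500}
pmrn:
  ages: [2, 3, 4]
  groups:
    early: [1982, 1983, 1984]
    late: [2000, 2001, 2002]
YAML
pmrnhier fit --config fit.yaml --fish simdata/fish.csv \
    --env simdata/environment.csv --seed 5 --out posterior

# 3. midpoints and cohort-group overlap
pmrnhier pmrn --config fit.yaml --fish simdata/fish.csv \
    --env simdata/environment.csv --posterior posterior --out pmrn_out
pmrnhier report --midpoints pmrn_out/midpoints.csv \
    --overlap pmrn_out/overlap.csv --diagnostics posterior/diagnostics.csv
```

The fit step prints its convergence verdict:

    fitting 3780 fish, 25 cohorts, 3x1000 iterations
    convergence PASS: max split R-hat 1.0082 (beta[1,2000]), threshold 1.1; min bulk ESS 315

(split R-hat near 1 means within- and between-chain variation agree for
every parameter), and the report summarizes the midpoint series:

    75 cohort x age cells, 66 retained
      age 2: Lp50 median 160 mm (1980) -> 199 mm (2004)
      age 3: Lp50 median 171 mm (1980) -> 199 mm (2004)
      age 4: Lp50 median 130 mm (1981) -> 205 mm (2004)
      overlap age 2: early vs late = 0.006
      overlap age 3: early vs late = 0.817
      overlap age 4: early vs late = 0.901
      max split R-hat 1.0082, min bulk ESS 315

Each retained cell carries a posterior median and 95% credible interval
of Lp50 in mm; `midpoints.csv` lists every cell with its exclusion
bookkeeping, and `overlap.csv` gives the proportion of shared posterior
mass between cohort groups (near 1 = indistinguishable midpoints, near 0
= clearly separated).  The default generator includes a positive fishing
effect, so midpoints rise after the mid-series closure — clearly for the
young age class here (overlap 0.006 between early and late cohorts),
while older ages stay statistically indistinguishable in this
realization.  Scenarios with a built-in schedule shift at every age (see
`shifted_midpoint_scenario`) drive the pre/post overlap below 0.1.

The same pipeline is available as library calls (`build_design`, `fit`,
`estimate_midpoints`, `posterior_overlap`) for scripted analyses.

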