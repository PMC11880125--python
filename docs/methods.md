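# Methods

## The estimation problem

Probabilistic maturation reaction norms (PMRNs) describe the probability
that an *immature* fish first matures as a function of its age and size,
after stripping out the purely plastic effect of growth on maturation
timing.  The classical demographic estimators need many immature and mature
fish per cohort and age class; long-running surveys rarely deliver that for
every cohort.  `pmrnhier` addresses the sparse-data case with a
hierarchical Bayesian model in which cohorts share statistical strength:
cohort-level coefficients are drawn from hyperdistributions, so thinly
sampled cohorts are shrunk toward the population mean instead of being
dropped or fitted unstably.

## Joint model

One posterior couples three submodels, so every posterior draw is a
coherent parameter set for maturity, growth, and condition simultaneously.

**Maturity.**  For fish *i* of cohort *c*, maturity status
y ~ Bernoulli(o) with

    logit o = b1[c] + b2[c]*a + b3[c]*l + b4[c]*w
            + b5[c]*a*l + b6[c]*a*w + b7*f + b8[c]*t + b9[c]*p

on z-scored age (a), total length (l), relative weight (w), growing degree
days (t), and total phosphorus (p); f is the raw 0/1 commercial-fishing
indicator.  All coefficients except b7 vary by cohort with
b_k[c] ~ N(mu_k, sigma_k); the fishing coefficient is global because a
binary covariate confounded with calendar time cannot support a
cohort-level hierarchy.

**Growth.**  length_mm ~ N(phi[c] + gamma[c] * ln(age), tau), on raw
scales (mm, years).  The linear-log form tracks length-at-age about as
well as a von Bertalanffy curve over the ages of interest while keeping
the increment algebra closed-form:
delta_l(a) = gamma[c] * (ln a - ln(a-1)).

**Condition.**  z-scored relative weight ~ N(theta, zeta) with
theta = w1[c] + w2[c]*a + w3[c]*l + w4[c]*a*l; cohort is a fixed effect
here (priors N(0,1)), not hierarchical.

**Priors.**  mu_k ~ N(0,10); sigma_k ~ half-Cauchy(0,5); mu_phi, mu_gamma ~
N(100,20) (mm scale); sigma_phi, sigma_gamma, tau, zeta ~ half-Cauchy(0,5);
omega ~ N(0,1).  Half-Cauchy means the positive half of the Cauchy
distribution.

Two scale conventions deserve a note.  The growth submodel operates on raw
millimetres — the N(100, 20) hyperpriors only make sense there — while the
condition submodel standardizes its response, because N(0,1) coefficient
priors would be absurd against a response centred near 100.  Raw-scale
condition predictions are recovered through the stored standardization.

## Sampling

The posterior is explored with an in-package No-U-Turn sampler: analytic
gradients of the joint log density, dual-averaging step-size adaptation
(target acceptance 0.8), and Stan-style expanding windows for a diagonal
mass matrix.  Parameter geometry choices:

* cohort-varying maturation coefficients are **non-centered**
  (b_k[c] = mu_k + sigma_k * z_kc): each coefficient is weakly informed
  per cohort, the regime where non-centering avoids the sigma funnel;
* growth coefficients phi[c], gamma[c] are **centered**: with tens of fish
  per cohort the growth likelihood identifies them strongly, and centering
  removed the long trajectories the non-centered form needed (a ~2.5x
  speedup in wall time at equal effective sample size);
* the fishing hyper-mean mu7 is **marginalized analytically**.  The
  likelihood informs only b7, so sampling (mu7, sigma7, b7) directly
  creates a ridge (sigma7 -> 0 pins mu7 to b7) that stalled short chains.
  By normal conjugacy b7 ~ N(0, sqrt(100 + sigma7^2)) marginally, and
  mu7 | b7, sigma7 is Gaussian in closed form; the sampler sees only b7,
  log sigma7, and an independent N(0,1) latent from which mu7 is
  reconstructed deterministically;
* standard deviations are sampled as logs with Jacobian corrections, and
  log-scales beyond |30| are rejected outright so a scale can never
  underflow to an exactly-zero value (which would make its likelihood
  term spuriously infinite).

Defaults follow the survey protocol: 3 chains x 4000 iterations, first
2000 discarded, 6000 retained draws.  Tests and the acceptance script use
3 x 1000 (500 warmup), which the convergence diagnostics show is ample for
the synthetic problem sizes exercised there; warmup below ~300 iterations
leaves the mass matrix poorly adapted and is not recommended.  Trees are
capped at depth 6 (64 leapfrog steps); adapted chains for this model
family terminate well below the cap, and the cap bounds worst-case cost.
Reproducibility: chain r of a run with seed s uses the deterministic
stream `default_rng([s, r])`; identical seeds give identical draws.

Convergence is assessed with split R-hat (threshold 1.1) and bulk
effective sample size for every scalar parameter, computed by arviz
(rank-normalized split R-hat).  Parameters with zero variance across all
draws are reported as R-hat 1.0.

## From posterior to PMRN midpoints

For each draw and each fish of age >= 2, the probability of being mature
now (o) and in the reconstructed previous-year state (o_prev) give the
first-maturation probability m = (o - o_prev) / (1 - o_prev), floored at
zero.  The previous state uses age a-1, length l - delta_l with the draw's
gamma[c], condition w - delta_w from the condition submodel, and the
lagged calendar-year environment (f, t, p of obs_year - 1).  Fish of age 1
have no observable previous state and are excluded (logged).

Within each cohort x age cell, m is regressed on z-scored length per draw.
Because m is a fractional response in [0,1] (a logit transform would fail
at m = 0), the fit maximizes the Bernoulli-type quasi-likelihood by Newton
iteration — logistic regression accepting non-integer responses.  The
midpoint is Lp50 = -intercept/slope, mapped back to millimetres exactly
through the stored standardization.  A draw is excluded from a cell when
the cell has fewer than two usable fish, the fitted slope is non-positive
(first maturation apparently declining with length — the cell's fish have
likely already matured), or the Newton iteration fails to converge; the
three causes are counted identically.  Cells losing more than 5% of draws
are flagged `retained = False` but still reported with their bookkeeping.

Cohort-group differences are summarized by the overlapping coefficient of
pooled Lp50 draws: 100 equal-width histogram bins spanning the pooled
range, summing min(relative frequency A, relative frequency B).  It is
symmetric, lies in [0,1], equals 1 for identical samples and 0 for
disjoint ones; the bin count trades smoothing against resolution and 100
bins is stable for the thousands of draws produced here.

## Synthetic surveys

`simulate` runs the model's own generative equations forward with known
parameters: cohort coefficients from the true hyperdistributions, lengths
from the growth curve, condition from the condition model mapped to a raw
Wr scale (mean 100, scale 10), weights back-computed through the standard
weight formula so the data module's Wr computation round-trips exactly,
and maturity as Bernoulli draws from the maturation logit evaluated on
dataset z-scores — the same standardization the fitting pipeline
recomputes.  The environment emulates survey covariates: GDD as a
stationary AR(1) (mean 2600, sd 150, autocorrelation 0.7), total
phosphorus as a declining trend (8 -> 4 ug/L) with noise, and the fishing
flag switching 1 -> 0 at the closure year.

The default scenario spans 25 cohorts with uneven cohort sample sizes
drawn from 60-240 fish, ages 1-6 with a decreasing age distribution,
growth around phi = 100 mm, gamma = 80 mm per ln-year, tau = 20 mm, and
maturation hyper-means (-1, 0.5, 3.0, 0, -0.4, 0, 1.5, 0.3, 0.2) with
cohort sds of 0.3 — moderate cohort heterogeneity around a strong length
effect, a modest age effect, and a positive fishing effect, the qualitative
pattern a maturation survey of a harvested percid would show.  Tests and
the acceptance script scale this down to 10 cohorts x ~100 fish so a full
fit-and-recover cycle completes in about a minute.

`shifted_midpoint_scenario` constructs a survey whose *true* age-3 Lp50
sits near 160 mm while the fishery is open and near 240 mm after closure.
The maturation intercept and fishing coefficient are solved by Brent
root-finding on the generating first-maturation probability using the
scenario's population covariate moments, so the target midpoints are a
property of the construction, not of any fitted result.  `true_midpoints`
then verifies the realized values by root-finding on the generating model
with the realized dataset standardization.

Maturity is simulated as a per-observation Bernoulli draw from the
current-state probability — matching the fitted likelihood — rather than
as an irreversible life-history process.  Real surveys differ in ways the
generator does not emulate: gear selectivity, ageing error, measurement
error in length and weight, immigration/emigration, and maturity that
persists within individuals across years.  Passing recovery tests
therefore demonstrate that the estimator inverts its own data-generating
process at realistic sample sizes, not that it is robust to those field
complications.

## Numerical choices and edge cases

* z-scores use the sample standard deviation (n-1); forward and inverse
  transforms are exact inverses and tested to 1e-10.
* Weight imputation fits per-year log10-log10 least squares; a year with
  missing weights but fewer than two weighed fish cannot support the
  regression, so its weightless records are dropped with a logged warning
  and the year is flagged on the output.
* The standard-weight equation is applied at all lengths, including
  outside the range it was developed for; relative weight enters only as
  a z-scored covariate, so an affine bias at extreme lengths is absorbed.
* o_prev within 1e-12 of 1 leaves m undefined; that fish x draw
  combination is marked invalid and counts as an excluded draw in its
  cell.
* Newton steps in the Lp50 fits are clipped to +-10 per iteration and
  coefficients beyond |50| (on z-scale) are declared non-converged.
* Cohorts with fewer than 5 fish are retained — shrinkage through the
  hierarchy is the point of the model — but logged as sparse.
* Missing environment years are a hard error by default; an optional flag
  enables linear interpolation (fishing carried forward), because silent
  gap-filling can bias the lagged covariates.
* The closure year is read from the environment table's fishing column,
  never hard-coded.

## Limitations

* The maturity likelihood treats each observation independently given its
  covariates; individual identity across years is not modelled.
* Only female fish are modelled by default (male survey catches are
  typically mature-dominated and uninformative about maturation size).
* PMRN output covers the 50% midpoint only, ages 2-5 by default; no
  envelope percentiles and no length x condition midpoint surfaces.
* No gear-selectivity or ageing-error corrections are applied.
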