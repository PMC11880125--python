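"""Synthetic multi-cohort survey data with known ground truth.

Runs the joint model's own generative equations forward: cohort-level
parameters are drawn from the true hyperdistributions, lengths from the
linear-log growth model, relative weight from the condition model (mapped
to a raw Wr scale around 100), and maturity as a Bernoulli draw from the
maturation logit evaluated on dataset-standardized covariates.  The
environment series emulates survey covariates: growing degree days as an
AR(1) process, total phosphorus as a declining trend with noise, and a
binary fishing indicator that switches from 1 to 0 at the closure year.

Because the generator knows every parameter, the true per-cohort, per-age
Lp50 can be computed by root-finding on the generating first-maturation
probability -- the reference for parameter- and midpoint-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .data import Standardization, standard_weight
from .model import FISHING_K, VARYING_K

#: default maturation hyper-means, in coefficient order (intercept, age,
#: length, Wr, age*length, age*Wr, fishing, GDD, TP) on the z-scale
DEFAULT_MU = (-1.0, 0.5, 3.0, 0.0, -0.4, 0.0, 1.5, 0.3, 0.2)
DEFAULT_SIGMA = (0.3,) * 9


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic survey.

    Defaults describe a 25-cohort survey with uneven cohort sample sizes in
    the tens-to-hundreds, a fishery closure mid-series, growth around
    phi=100 mm / gamma=80 mm per ln-year, and moderate cohort-to-cohort
    variation (sd 0.3) around the maturation hyper-means.
    """

    first_cohort: int = 1980
    n_cohorts: int = 25
    closure_year: int = 1997
    ages: tuple = (1, 2, 3, 4, 5, 6)
    age_weights: tuple = (0.18, 0.27, 0.25, 0.15, 0.10, 0.05)
    fish_per_cohort: tuple = (60, 240)   # uniform range, or dict cohort -> n
    mu: tuple = DEFAULT_MU
    sigma: tuple = DEFAULT_SIGMA
    mu_phi: float = 100.0
    sigma_phi: float = 10.0
    mu_gamma: float = 80.0
    sigma_gamma: float = 8.0
    tau: float = 20.0
    omega_mean: tuple = (0.0, 0.2, 0.5, 0.0)
    omega_sd: float = 0.2
    zeta: float = 0.8
    wr_mean: float = 100.0
    wr_scale: float = 10.0
    gdd_mean: float = 2600.0
    gdd_sd: float = 150.0
    gdd_rho: float = 0.7
    tp_start: float = 8.0
    tp_end: float = 4.0
    tp_sd: float = 0.5
    length_floor: float = 30.0

    def __post_init__(self):
        if self.n_cohorts < 1:
            raise ValueError("need at least one cohort")
        if abs(sum(self.age_weights) - 1.0) > 1e-9:
            raise ValueError("age_weights must sum to 1")
        if len(self.age_weights) != len(self.ages):
            raise ValueError("ages and age_weights length mismatch")
        # zero is allowed (noiseless limit useful for testing); negative is not
        for name in ("sigma_phi", "sigma_gamma", "tau", "zeta", "omega_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(s < 0 for s in self.sigma):
            raise ValueError("all sigma must be non-negative")
        first_year, last_year = self.year_span
        if not (first_year < self.closure_year <= last_year + 1):
            raise ValueError("closure_year must fall inside the year span")

    @property
    def cohorts(self) -> np.ndarray:
        return np.arange(self.first_cohort, self.first_cohort + self.n_cohorts)

    @property
    def year_span(self) -> tuple:
        # covers obs_year - 1 for the earliest possible observation
        return (self.first_cohort, self.first_cohort + self.n_cohorts - 1
                + max(self.ages))

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d


@dataclass
class GroundTruth:
    """The generating parameters of one synthetic dataset."""

    config: ScenarioConfig
    beta: np.ndarray          # (C, 9); column 6 identical across cohorts
    phi: np.ndarray
    gamma: np.ndarray
    omega: np.ndarray         # (C, 4)
    standardization: Standardization
    cohorts: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.cohorts is None:
            self.cohorts = self.config.cohorts

    def save(self, path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "beta": self.beta.tolist(),
            "phi": self.phi.tolist(),
            "gamma": self.gamma.tolist(),
            "omega": self.omega.tolist(),
            "standardization": self.standardization.to_dict(),
            "cohorts": [int(c) for c in self.cohorts],
        }
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def load(cls, path) -> "GroundTruth":
        payload = yaml.safe_load(Path(path).read_text())
        cfg = dict(payload["config"])
        for key, value in cfg.items():
            if isinstance(value, list):
                cfg[key] = tuple(value)
        return cls(
            config=ScenarioConfig(**cfg),
            beta=np.array(payload["beta"]),
            phi=np.array(payload["phi"]),
            gamma=np.array(payload["gamma"]),
            omega=np.array(payload["omega"]),
            standardization=Standardization.from_dict(payload["standardization"]),
            cohorts=np.array(payload["cohorts"]),
        )


def generate_environment(config: ScenarioConfig, seed: int = 0) -> pd.DataFrame:
    """Annual environment series over the scenario's year span.

    Fishing is 1 strictly before the closure year and 0 from it on; GDD is
    a stationary AR(1) around its mean; TP declines linearly with noise.
    """
    rng = np.random.default_rng([seed, 101])
    first, last = config.year_span
    years = np.arange(first, last + 1)
    n = len(years)
    gdd = np.empty(n)
    gdd[0] = config.gdd_mean + config.gdd_sd * rng.normal()
    innov_sd = config.gdd_sd * np.sqrt(1.0 - config.gdd_rho ** 2)
    for i in range(1, n):
        gdd[i] = (config.gdd_mean
                  + config.gdd_rho * (gdd[i - 1] - config.gdd_mean)
                  + innov_sd * rng.normal())
    trend = np.linspace(config.tp_start, config.tp_end, n)
    tp = np.maximum(trend + config.tp_sd * rng.normal(size=n), 0.5)
    return pd.DataFrame({
        "year": years, "gdd": gdd, "tp": tp,
        "fishing": (years < config.closure_year).astype(int),
    })


def generate_population(config: ScenarioConfig, env: pd.DataFrame,
                        seed: int = 0):
    """Simulate the survey; returns ``(fish_table, GroundTruth)``.

    Covariate z-scores for the maturity draw use the generated dataset's own
    sample means/sds -- the same standardization the fitting pipeline will
    recompute, so generated and fitted models see identical scales.
    """
    rng = np.random.default_rng([seed, 202])
    cohorts = config.cohorts
    C = len(cohorts)
    mu = np.asarray(config.mu, dtype=float)
    sigma = np.asarray(config.sigma, dtype=float)

    beta = np.empty((C, 9))
    for k in VARYING_K:
        beta[:, k] = mu[k] + sigma[k] * rng.normal(size=C)
    beta[:, FISHING_K] = mu[FISHING_K] + sigma[FISHING_K] * rng.normal()
    phi = config.mu_phi + config.sigma_phi * rng.normal(size=C)
    gamma = config.mu_gamma + config.sigma_gamma * rng.normal(size=C)
    omega = (np.asarray(config.omega_mean, dtype=float)
             + config.omega_sd * rng.normal(size=(C, 4)))

    if isinstance(config.fish_per_cohort, dict):
        n_per = np.array([config.fish_per_cohort[c] for c in cohorts])
    else:
        lo, hi = config.fish_per_cohort
        n_per = rng.integers(lo, hi + 1, size=C)
    ci = np.repeat(np.arange(C), n_per)
    n = len(ci)
    age = rng.choice(np.asarray(config.ages), size=n,
                     p=np.asarray(config.age_weights))
    obs_year = cohorts[ci] + age
    length = np.maximum(
        rng.normal(phi[ci] + gamma[ci] * np.log(age), config.tau),
        config.length_floor)

    env_idx = env.set_index("year")
    gdd = env_idx.loc[obs_year, "gdd"].to_numpy()
    tp = env_idx.loc[obs_year, "tp"].to_numpy()
    fishing = env_idx.loc[obs_year, "fishing"].to_numpy(dtype=float)

    # condition model on z-scored age/length; Wr mapped to its raw scale
    a_z0 = (age - age.mean()) / age.std(ddof=1)
    l_z0 = (length - length.mean()) / length.std(ddof=1)
    theta = (omega[ci, 0] + omega[ci, 1] * a_z0 + omega[ci, 2] * l_z0
             + omega[ci, 3] * a_z0 * l_z0)
    cond_z = rng.normal(theta, config.zeta)
    wr = np.maximum(config.wr_mean + config.wr_scale * cond_z, 20.0)
    weight = standard_weight(length) * wr / 100.0

    std = Standardization.from_arrays(
        age=age, length=length, rel_weight=wr, gdd=gdd, tp=tp)
    a_z = std.zscore("age", age)
    l_z = std.zscore("length", length)
    w_z = std.zscore("rel_weight", wr)
    t_z = std.zscore("gdd", gdd)
    p_z = std.zscore("tp", tp)
    eta = (beta[ci, 0] + beta[ci, 1] * a_z + beta[ci, 2] * l_z
           + beta[ci, 3] * w_z + beta[ci, 4] * a_z * l_z
           + beta[ci, 5] * a_z * w_z + beta[ci, 6] * fishing
           + beta[ci, 7] * t_z + beta[ci, 8] * p_z)
    mature = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    fish = pd.DataFrame({
        "id": [f"F{i:06d}" for i in range(n)],
        "obs_year": obs_year.astype(int),
        "age": age.astype(int),
        "length_mm": length,
        "weight_g": weight,
        "mature": mature,
        "sex": "F",
    })
    truth = GroundTruth(config=config, beta=beta, phi=phi, gamma=gamma,
                        omega=omega, standardization=std, cohorts=cohorts)
    return fish, truth


def _m_true(l_mm, cohort_idx: int, age: int, truth: GroundTruth,
            env_idx: pd.DataFrame, obs_year: int):
    """Generating first-maturation probability at length(s) l_mm."""
    cfg = truth.config
    std = truth.standardization
    b = truth.beta[cohort_idx]
    om = truth.omega[cohort_idx]
    gamma_c = truth.gamma[cohort_idx]
    l_mm = np.asarray(l_mm, dtype=float)

    def eta(a, l, year):
        a_z = std.zscore("age", a)
        l_z = std.zscore("length", l)
        theta = om[0] + om[1] * a_z + om[2] * l_z + om[3] * a_z * l_z
        w_z = std.zscore("rel_weight", cfg.wr_mean + cfg.wr_scale * theta)
        f = float(env_idx.loc[year, "fishing"])
        t_z = std.zscore("gdd", env_idx.loc[year, "gdd"])
        p_z = std.zscore("tp", env_idx.loc[year, "tp"])
        return (b[0] + b[1] * a_z + b[2] * l_z + b[3] * w_z
                + b[4] * a_z * l_z + b[5] * a_z * w_z + b[6] * f
                + b[7] * t_z + b[8] * p_z)

    dl = gamma_c * (np.log(age) - np.log(age - 1))
    o_curr = 1.0 / (1.0 + np.exp(-eta(age, l_mm, obs_year)))
    o_prev = 1.0 / (1.0 + np.exp(-eta(age - 1, l_mm - dl, obs_year - 1)))
    return np.clip((o_curr - o_prev) / (1.0 - o_prev), 0.0, 1.0)


def true_midpoints(truth: GroundTruth, env: pd.DataFrame, age: int,
                   length_range=(40.0, 420.0), grid: int = 800) -> pd.DataFrame:
    """True Lp50 per cohort at one age, by grid scan plus Brent root-finding
    on the generating model; NaN where m never crosses 0.5 in range."""
    if age < 2:
        raise ValueError("midpoints require age >= 2 (previous state needed)")
    env_idx = env.set_index("year")
    ls = np.linspace(*length_range, grid)
    rows = []
    for c_idx, cohort in enumerate(truth.cohorts):
        obs_year = int(cohort) + age
        if obs_year not in env_idx.index or obs_year - 1 not in env_idx.index:
            rows.append({"cohort": int(cohort), "age": age,
                         "lp50_true_mm": np.nan})
            continue
        m = _m_true(ls, c_idx, age, truth, env_idx, obs_year)
        crossing = np.flatnonzero((m[:-1] < 0.5) & (m[1:] >= 0.5))
        if crossing.size == 0:
            lp50 = np.nan
        else:
            i = crossing[0]
            lp50 = brentq(
                lambda l: _m_true(l, c_idx, age, truth, env_idx, obs_year) - 0.5,
                ls[i], ls[i + 1], xtol=1e-6)
        rows.append({"cohort": int(cohort), "age": age, "lp50_true_mm": lp50})
    return pd.DataFrame(rows)


def shifted_midpoint_scenario(pre_mid: float = 160.0, post_mid: float = 240.0,
                              age: int = 3, first_cohort: int = 1988,
                              n_cohorts: int = 14, closure_year: int = 1995,
                              ) -> ScenarioConfig:
    """A scenario whose true age-``age`` Lp50 sits near ``pre_mid`` mm while
    the fishery is open and near ``post_mid`` mm after the closure.

    The maturation intercept and the fishing coefficient are solved by Brent
    root-finding on the generating first-maturation probability, using the
    scenario's population covariate moments for the z-scale (cohort sds are
    kept small so every cohort shares essentially one curve).  The fishing
    coefficient comes out positive: fishing pushes maturation to smaller
    sizes, as expected under fisheries-induced selection.
    """
    ages = (1, 2, 3, 4, 5)
    weights = (0.15, 0.25, 0.30, 0.20, 0.10)
    mu_phi, mu_gamma, tau = 110.0, 85.0, 28.0
    b_age, b_len = 0.5, 4.0

    w = np.asarray(weights)
    a = np.asarray(ages, dtype=float)
    mean_a = float(w @ a)
    sd_a = float(np.sqrt(w @ (a - mean_a) ** 2))
    mu_len = mu_phi + mu_gamma * np.log(a)
    mean_l = float(w @ mu_len)
    sd_l = float(np.sqrt(w @ ((mu_len - mean_l) ** 2) + tau ** 2))

    def m_of(l, b1, b7, f):
        z = lambda x: (x - mean_l) / sd_l
        za = lambda x: (x - mean_a) / sd_a
        dl = mu_gamma * (np.log(age) - np.log(age - 1))
        e_curr = b1 + b_age * za(age) + b_len * z(l) + b7 * f
        e_prev = b1 + b_age * za(age - 1) + b_len * z(l - dl) + b7 * f
        # m = 1 - (1-o_curr)/(1-o_prev), stable for large linear predictors
        log_sf = lambda e: -np.logaddexp(0.0, e)
        return 1.0 - np.exp(log_sf(e_curr) - log_sf(e_prev))

    b1 = brentq(lambda b: m_of(post_mid, b, 0.0, 0.0) - 0.5, -40.0, 40.0)
    b7 = brentq(lambda b: m_of(pre_mid, b1, b, 1.0) - 0.5, -40.0, 40.0)

    return ScenarioConfig(
        first_cohort=first_cohort, n_cohorts=n_cohorts,
        closure_year=closure_year, ages=ages, age_weights=weights,
        fish_per_cohort=(110, 170),
        mu=(b1, b_age, b_len, 0.0, 0.0, 0.0, b7, 0.0, 0.0),
        sigma=(0.05,) * 9,
        mu_phi=mu_phi, sigma_phi=5.0, mu_gamma=mu_gamma, sigma_gamma=4.0,
        tau=tau,
    )
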