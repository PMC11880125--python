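"""Joint hierarchical Bayesian model of maturation, growth, and condition.

Three submodels share one posterior so that every draw is a coherent
parameter set:

* maturity (Bernoulli): logit o = beta1[c] + beta2[c]*a + beta3[c]*l +
  beta4[c]*w + beta5[c]*a*l + beta6[c]*a*w + beta7*f + beta8[c]*t +
  beta9[c]*p, on z-scored covariates; the fishing coefficient beta7 is
  global (a binary indicator confounded with time cannot support a
  cohort hierarchy), all others are cohort-specific with Normal(mu_k,
  sigma_k) hierarchy;
* growth (Normal): length_mm ~ N(phi[c] + gamma[c]*ln(age), tau), on the
  raw mm / year scales;
* condition (Normal): z-scored relative weight ~ N(omega1[c] +
  omega2[c]*a + omega3[c]*l + omega4[c]*a*l, zeta), cohort as a fixed
  effect.

Hyperpriors: mu_k ~ N(0,10); sigma_k ~ half-Cauchy(0,5); mu_phi, mu_gamma ~
N(100,20); sigma_phi, sigma_gamma, tau, zeta ~ half-Cauchy(0,5); omega ~
N(0,1).  Sampling uses the in-package NUTS kernel on an unconstrained
vector: hierarchical coefficients are non-centered and standard deviations
are log-transformed with Jacobian corrections.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hmc
from .data import Standardization, maturation_design_matrix

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)

#: indices (0-based) of maturation coefficients that vary by cohort;
#: index 6 (fishing) is global.
VARYING_K = (0, 1, 2, 3, 4, 5, 7, 8)
FISHING_K = 6


@dataclass
class SamplerConfig:
    """MCMC protocol: defaults follow 3 chains x 4000 iterations with the
    first 2000 discarded, giving 6000 retained draws."""

    chains: int = 3
    iterations: int = 4000
    warmup: int = 2000
    seed: int = 0
    target_accept: float = 0.8
    max_depth: int = 6

    @property
    def n_draws(self) -> int:
        return self.chains * (self.iterations - self.warmup)


class HierarchicalMaturationModel:
    """Log-posterior (with analytic gradient) of the joint model.

    The unconstrained parameter vector is laid out as::

        mu[9] | log_sigma[9] | zbeta[C,8] | beta7 | mu_phi mu_gamma |
        log_sigma_phi log_sigma_gamma log_tau | phi[C] | gamma[C] |
        omega[C,4] | log_zeta

    where C is the number of cohorts and zbeta columns follow
    ``VARYING_K`` order.  The cohort-varying maturation coefficients are
    non-centered (beta_k[c] = mu_k + sigma_k * z) because each is only
    weakly informed per cohort; the growth coefficients and the global
    fishing coefficient are strongly data-informed, so they stay centered
    with their hierarchical prior evaluated directly.  The fishing
    hyper-mean mu7 is marginalized analytically: with mu7 ~ N(0, 10) and
    beta7 ~ N(mu7, sigma7), conjugacy gives beta7 ~ N(0, sqrt(100 +
    sigma7^2)) marginally, and mu7 | beta7, sigma7 is Normal with mean
    100*beta7/(100+sigma7^2) and sd 10*sigma7/sqrt(100+sigma7^2).  Slot 6
    of the mu block stores the unit-normal latent of that conditional, so
    mu7 is reconstructed deterministically and the sampler never sees the
    mu7-sigma7 ridge (the likelihood informs beta7 only).
    """

    def __init__(self, design: pd.DataFrame, standardization: Standardization):
        self.std = standardization
        self.cohorts = np.sort(design["cohort"].unique())
        self.n_cohorts = len(self.cohorts)
        self.n_fish = len(design)

        # fish sorted by cohort so per-cohort sums are contiguous reduceats
        design = design.sort_values("cohort_index", kind="stable")
        self.X = maturation_design_matrix(design)
        self.y = design["mature"].to_numpy(dtype=float)
        self.ci = design["cohort_index"].to_numpy(dtype=np.intp)
        self.length_mm = design["length_mm"].to_numpy(dtype=float)
        self.log_age = np.log(design["age"].to_numpy(dtype=float))
        self.wz = design["relw_z"].to_numpy(dtype=float)
        a, l = design["age_z"].to_numpy(), design["length_z"].to_numpy()
        self.Xc = np.column_stack([np.ones(self.n_fish), a, l, a * l])
        counts = np.bincount(self.ci, minlength=self.n_cohorts)
        if (counts == 0).any():
            raise ValueError("cohort index is not dense")
        self._starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        if not (np.isfinite(self.X).all() and np.isfinite(self.length_mm).all()
                and np.isfinite(self.wz).all()):
            raise ValueError("non-finite covariates in design table")

        C = self.n_cohorts
        sizes = {
            "mu": 9, "log_sigma": 9, "zbeta": 8 * C, "beta7": 1,
            "mu_phi": 1, "mu_gamma": 1,
            "log_sigma_phi": 1, "log_sigma_gamma": 1, "log_tau": 1,
            "phi": C, "gamma": C, "omega": 4 * C, "log_zeta": 1,
        }
        self.slices: dict[str, slice] = {}
        pos = 0
        for name, size in sizes.items():
            self.slices[name] = slice(pos, pos + size)
            pos += size
        self.dim = pos

    # -- parameter handling -------------------------------------------------

    def unpack(self, x: np.ndarray) -> dict:
        """Natural-scale parameters for one unconstrained vector."""
        C = self.n_cohorts
        s = self.slices
        mu = x[s["mu"]].copy()
        sigma = np.exp(x[s["log_sigma"]])
        # slot 6 of mu is the unit latent of mu7 | beta7, sigma7
        mu[FISHING_K] = _reconstruct_mu7(
            x[s["beta7"]][0], sigma[FISHING_K], x[s["mu"]][FISHING_K])
        zbeta = x[s["zbeta"]].reshape(C, 8)
        beta = np.empty((C, 9))
        for j, k in enumerate(VARYING_K):
            beta[:, k] = mu[k] + sigma[k] * zbeta[:, j]
        beta[:, FISHING_K] = x[s["beta7"]][0]
        sigma_phi = np.exp(x[s["log_sigma_phi"]][0])
        sigma_gamma = np.exp(x[s["log_sigma_gamma"]][0])
        return {
            "beta": beta, "mu": mu, "sigma": sigma,
            "phi": x[s["phi"]].copy(),
            "gamma": x[s["gamma"]].copy(),
            "mu_phi": x[s["mu_phi"]][0], "sigma_phi": sigma_phi,
            "mu_gamma": x[s["mu_gamma"]][0], "sigma_gamma": sigma_gamma,
            "tau": np.exp(x[s["log_tau"]][0]),
            "omega": x[s["omega"]].reshape(C, 4),
            "zeta": np.exp(x[s["log_zeta"]][0]),
        }

    def initial_point(self, rng: np.random.Generator, jitter: float = 0.1) -> np.ndarray:
        """Start near the hyperprior centers with mild jitter on the z-scales."""
        x = np.zeros(self.dim)
        s = self.slices
        x[s["mu_phi"]] = np.mean(self.length_mm)
        x[s["mu_gamma"]] = 50.0
        x[s["phi"]] = np.mean(self.length_mm)
        x[s["gamma"]] = 50.0
        x[s["log_sigma_phi"]] = np.log(5.0)
        x[s["log_sigma_gamma"]] = np.log(5.0)
        x[s["log_tau"]] = np.log(max(np.std(self.length_mm), 1.0))
        return x + jitter * rng.normal(size=self.dim)

    # -- densities ----------------------------------------------------------

    @staticmethod
    def _half_cauchy_logpdf(value: float, scale: float = 5.0) -> float:
        # density of |Cauchy(0, scale)|
        return np.log(2.0 / (np.pi * scale)) - np.log1p((value / scale) ** 2)

    def log_posterior(self, x: np.ndarray) -> float:
        return self.logp_and_grad(x)[0]

    def logp_and_grad(self, x: np.ndarray):
        """Joint log posterior density (including the log-transform
        Jacobians) and its gradient with respect to the unconstrained
        vector."""
        C = self.n_cohorts
        s = self.slices
        # reject log-scale excursions before exp() under/overflows: a scale
        # collapsing to exactly 0 would make -n*log(scale) spuriously +inf
        log_scales = np.concatenate([
            x[s["log_sigma"]], x[s["log_sigma_phi"]], x[s["log_sigma_gamma"]],
            x[s["log_tau"]], x[s["log_zeta"]]])
        if not np.all(np.isfinite(x)) or np.any(np.abs(log_scales) > 30.0):
            return -np.inf, np.zeros(self.dim)
        p = self.unpack(x)
        zbeta = x[s["zbeta"]].reshape(C, 8)
        grad = np.zeros(self.dim)

        # --- maturity likelihood (Bernoulli via logit) ---
        eta = np.einsum("nk,nk->n", self.X, p["beta"][self.ci])
        logp = float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
        r = self.y - _sigmoid(eta)
        G = np.add.reduceat(r[:, None] * self.X, self._starts, axis=0)
        g_beta = G.sum(axis=0)                     # d logp / d beta summed per k
        g_mu = g_beta.copy()
        g_mu[FISHING_K] = 0.0                      # mu7 enters only via the prior
        grad[s["mu"]] += g_mu
        g_sigma = np.zeros(9)
        gzbeta = grad[s["zbeta"]].reshape(C, 8)
        for j, k in enumerate(VARYING_K):
            g_sigma[k] = np.dot(G[:, k], zbeta[:, j])
            gzbeta[:, j] += G[:, k] * p["sigma"][k]
        grad[s["beta7"]] += g_beta[FISHING_K]
        grad[s["log_sigma"]] += p["sigma"] * g_sigma

        # --- growth likelihood (Normal, raw mm scale) ---
        tau = p["tau"]
        mu_len = p["phi"][self.ci] + p["gamma"][self.ci] * self.log_age
        resid = self.length_mm - mu_len
        logp += float(-self.n_fish * (np.log(tau) + 0.5 * _LOG_2PI)
                      - 0.5 * np.sum(resid ** 2) / tau ** 2)
        u = resid / tau ** 2
        grad[s["phi"]] += np.bincount(self.ci, weights=u, minlength=C)
        grad[s["gamma"]] += np.bincount(self.ci, weights=u * self.log_age,
                                        minlength=C)
        grad[s["log_tau"]] += -self.n_fish + np.sum(resid ** 2) / tau ** 2

        # --- condition likelihood (Normal, z-scored Wr response) ---
        zeta = p["zeta"]
        theta = np.einsum("nk,nk->n", self.Xc, p["omega"][self.ci])
        resid_c = self.wz - theta
        logp += float(-self.n_fish * (np.log(zeta) + 0.5 * _LOG_2PI)
                      - 0.5 * np.sum(resid_c ** 2) / zeta ** 2)
        v = resid_c / zeta ** 2
        dOmega = np.add.reduceat(v[:, None] * self.Xc, self._starts, axis=0)
        grad[s["omega"]] += dOmega.reshape(-1)
        grad[s["log_zeta"]] += -self.n_fish + np.sum(resid_c ** 2) / zeta ** 2

        # --- priors ---
        # standard-normal non-centered latents of the maturation hierarchy
        z = x[s["zbeta"]]
        logp += float(-0.5 * np.sum(z ** 2) - 0.5 * z.size * _LOG_2PI)
        grad[s["zbeta"]] += -z
        # fishing block: mu7 marginalized by conjugacy; the sampler sees
        # beta7 ~ N(0, sqrt(100 + sigma7^2)) and an independent N(0,1)
        # latent u7 for the conditional mu7 | beta7, sigma7
        u7 = x[s["mu"]][FISHING_K]
        beta7 = x[s["beta7"]][0]
        sig7 = p["sigma"][FISHING_K]
        v7 = 100.0 + sig7 ** 2
        logp += float(-0.5 * u7 ** 2 - 0.5 * _LOG_2PI)
        logp += float(-0.5 * beta7 ** 2 / v7 - 0.5 * np.log(v7)
                      - 0.5 * _LOG_2PI)
        grad[s["beta7"]] += -beta7 / v7
        grad[s["log_sigma"]][FISHING_K] += \
            sig7 ** 2 * (beta7 ** 2 / v7 ** 2 - 1.0 / v7)
        # phi_c ~ N(mu_phi, sigma_phi), gamma_c ~ N(mu_gamma, sigma_gamma)
        for pname, mname, sname in (("phi", "mu_phi", "log_sigma_phi"),
                                    ("gamma", "mu_gamma", "log_sigma_gamma")):
            vals = x[s[pname]]
            mval = x[s[mname]][0]
            sval = np.exp(x[s[sname]][0])
            dev = vals - mval
            logp += float(-0.5 * np.sum((dev / sval) ** 2)
                          - C * (np.log(sval) + 0.5 * _LOG_2PI))
            grad[s[pname]] += -dev / sval ** 2
            grad[s[mname]] += np.sum(dev) / sval ** 2
            grad[s[sname]] += -C + np.sum((dev / sval) ** 2)
        # omega ~ N(0, 1) fixed-effect prior
        om = x[s["omega"]]
        logp += float(-0.5 * np.sum(om ** 2) - 0.5 * om.size * _LOG_2PI)
        grad[s["omega"]] += -om
        # mu_k ~ N(0, 10) for the cohort-varying slots (mu7 handled above)
        mu_raw = x[s["mu"]].copy()
        mu_raw[FISHING_K] = 0.0
        logp += float(-0.5 * np.sum((mu_raw / 10.0) ** 2)
                      - 8 * (np.log(10.0) + 0.5 * _LOG_2PI))
        gmu = -mu_raw / 100.0
        gmu[FISHING_K] = -u7
        grad[s["mu"]] += gmu
        # mu_phi, mu_gamma ~ N(100, 20)
        for name in ("mu_phi", "mu_gamma"):
            m = x[s[name]][0]
            logp += float(-0.5 * ((m - 100.0) / 20.0) ** 2
                          - np.log(20.0) - 0.5 * _LOG_2PI)
            grad[s[name]] += -(m - 100.0) / 400.0
        # half-Cauchy(0,5) scales, log-transformed (+ Jacobian log sigma)
        for name, value in (("log_sigma", p["sigma"]),
                            ("log_sigma_phi", p["sigma_phi"]),
                            ("log_sigma_gamma", p["sigma_gamma"]),
                            ("log_tau", p["tau"]),
                            ("log_zeta", p["zeta"])):
            val = np.atleast_1d(value)
            logp += float(np.sum(self._half_cauchy_logpdf(val) + np.log(val)))
            grad[s[name]] += 1.0 - 2.0 * val ** 2 / (25.0 + val ** 2)

        return logp, grad


def _sigmoid(eta):
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


def _reconstruct_mu7(beta7, sigma7, u7):
    """mu7 from its conditional posterior given (beta7, sigma7) and the
    sampled unit-normal latent u7 (conjugate normal factorization of
    mu7 ~ N(0,10), beta7 ~ N(mu7, sigma7))."""
    v = 100.0 + sigma7 ** 2
    return 100.0 * beta7 / v + (10.0 * sigma7 / np.sqrt(v)) * u7


# -- elementary model operations (single cohort, single draw) ---------------

def maturity_logit(covariates, beta_c) -> float:
    """Linear predictor of the maturation logit for one fish.

    ``covariates`` is the 9-vector (1, a, l, w, a*l, a*w, f, t, p) on the
    model (z) scale; ``beta_c`` the cohort's coefficient vector.  The
    maturity probability is the inverse logit of the returned value.
    """
    covariates = np.asarray(covariates, dtype=float)
    beta_c = np.asarray(beta_c, dtype=float)
    if covariates.shape != (9,) or beta_c.shape != (9,):
        raise ValueError("covariates and beta must be 9-vectors")
    return float(covariates @ beta_c)


def growth_mean(age, phi_c: float, gamma_c: float) -> float:
    """Mean length at age: phi_c + gamma_c * ln(age), in mm (natural log)."""
    if age < 1:
        raise ValueError("growth model requires age >= 1")
    return float(phi_c + gamma_c * np.log(age))


def growth_increment(age, gamma_c: float) -> float:
    """Mean length gain from age-1 to age: gamma_c * (ln a - ln(a-1)) mm.

    Positive for gamma_c > 0 and decreasing in age (concavity of ln).
    """
    if age < 2:
        raise ValueError("growth increment requires age >= 2")
    return float(gamma_c * (np.log(age) - np.log(age - 1)))


def condition_mean(age_z: float, length_z: float, omega_c) -> float:
    """Mean (z-scored) relative weight at standardized age and length."""
    omega_c = np.asarray(omega_c, dtype=float)
    if omega_c.shape != (4,):
        raise ValueError("omega must be a 4-vector")
    return float(omega_c @ [1.0, age_z, length_z, age_z * length_z])


def delta_condition(age, length_mm, dl_mm, omega_c, std) -> float:
    """Condition change over the last year on the z scale:
    theta(a, l) - theta(a-1, l - dl), with raw age/length mapped through
    the stored Standardization."""
    if age < 2:
        raise ValueError("condition increment requires age >= 2")
    a_z = float(std.zscore("age", age))
    a_prev_z = float(std.zscore("age", age - 1))
    l_z = float(std.zscore("length", length_mm))
    l_prev_z = float(std.zscore("length", length_mm - dl_mm))
    return (condition_mean(a_z, l_z, omega_c)
            - condition_mean(a_prev_z, l_prev_z, omega_c))


@dataclass
class PosteriorDraws:
    """Posterior draws of the joint model on the natural parameter scale.

    Arrays are draw-major with chains concatenated in order; ``chain``
    gives the chain id of each draw.  ``beta`` has shape (D, C, 9) with
    cohort order matching ``cohorts``.
    """

    beta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    phi: np.ndarray
    gamma: np.ndarray
    mu_phi: np.ndarray
    sigma_phi: np.ndarray
    mu_gamma: np.ndarray
    sigma_gamma: np.ndarray
    tau: np.ndarray
    omega: np.ndarray
    zeta: np.ndarray
    chain: np.ndarray
    cohorts: np.ndarray
    standardization: Standardization
    diagnostics: pd.DataFrame | None = None
    sampler_meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.tau)

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain))

    def cohort_index(self, cohort) -> int:
        i = int(np.searchsorted(self.cohorts, cohort))
        if i >= len(self.cohorts) or self.cohorts[i] != cohort:
            raise KeyError(f"unknown cohort {cohort!r}")
        return i

    def parameter_arrays(self) -> dict[str, np.ndarray]:
        """Every scalar parameter exactly once, as name -> (D,) array.

        beta7 appears once (it is shared across cohorts); cohort-varying
        coefficients appear per cohort with 1-based coefficient numbers.
        """
        out: dict[str, np.ndarray] = {}
        for j, k in enumerate(range(9)):
            out[f"mu[{k + 1}]"] = self.mu[:, k]
            out[f"sigma[{k + 1}]"] = self.sigma[:, k]
        for c_idx, c in enumerate(self.cohorts):
            for k in VARYING_K:
                out[f"beta[{k + 1},{c}]"] = self.beta[:, c_idx, k]
        out["beta[7]"] = self.beta[:, 0, FISHING_K]
        for c_idx, c in enumerate(self.cohorts):
            out[f"phi[{c}]"] = self.phi[:, c_idx]
            out[f"gamma[{c}]"] = self.gamma[:, c_idx]
            for k in range(4):
                out[f"omega[{k + 1},{c}]"] = self.omega[:, c_idx, k]
        out["mu_phi"] = self.mu_phi
        out["sigma_phi"] = self.sigma_phi
        out["mu_gamma"] = self.mu_gamma
        out["sigma_gamma"] = self.sigma_gamma
        out["tau"] = self.tau
        out["zeta"] = self.zeta
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per draw x parameter."""
        params = self.parameter_arrays()
        names = list(params)
        D = self.n_draws
        return pd.DataFrame({
            "draw": np.repeat(np.arange(D), len(names)),
            "chain": np.repeat(self.chain, len(names)),
            "parameter": np.tile(np.array(names, dtype=object), D),
            "value": np.column_stack([params[n] for n in names]).reshape(-1),
        })

    def save(self, directory) -> None:
        """Write draws, diagnostics, and metadata as plain-text files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "posterior.csv", index=False)
        if self.diagnostics is not None:
            self.diagnostics.to_csv(directory / "diagnostics.csv", index=False)
        meta = {
            "cohorts": [int(c) for c in self.cohorts],
            "standardization": self.standardization.to_dict(),
            "sampler": self.sampler_meta,
        }
        with open(directory / "posterior_meta.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        directory = Path(directory)
        frame = pd.read_csv(directory / "posterior.csv")
        with open(directory / "posterior_meta.yaml") as fh:
            meta = yaml.safe_load(fh)
        cohorts = np.array(meta["cohorts"])
        std = Standardization.from_dict(meta["standardization"])
        wide = frame.pivot(index="draw", columns="parameter", values="value")
        chain = frame.drop_duplicates("draw").set_index("draw")["chain"] \
            .loc[wide.index].to_numpy()
        D, C = len(wide), len(cohorts)
        beta = np.empty((D, C, 9))
        phi = np.empty((D, C))
        gamma = np.empty((D, C))
        omega = np.empty((D, C, 4))
        mu = np.column_stack([wide[f"mu[{k}]"] for k in range(1, 10)])
        sigma = np.column_stack([wide[f"sigma[{k}]"] for k in range(1, 10)])
        for c_idx, c in enumerate(cohorts):
            for k in VARYING_K:
                beta[:, c_idx, k] = wide[f"beta[{k + 1},{c}]"]
            beta[:, c_idx, FISHING_K] = wide["beta[7]"]
            phi[:, c_idx] = wide[f"phi[{c}]"]
            gamma[:, c_idx] = wide[f"gamma[{c}]"]
            for k in range(4):
                omega[:, c_idx, k] = wide[f"omega[{k + 1},{c}]"]
        diag_path = directory / "diagnostics.csv"
        diagnostics = pd.read_csv(diag_path) if diag_path.exists() else None
        return cls(
            beta=beta, mu=mu, sigma=sigma, phi=phi, gamma=gamma,
            mu_phi=wide["mu_phi"].to_numpy(), sigma_phi=wide["sigma_phi"].to_numpy(),
            mu_gamma=wide["mu_gamma"].to_numpy(),
            sigma_gamma=wide["sigma_gamma"].to_numpy(),
            tau=wide["tau"].to_numpy(), omega=omega,
            zeta=wide["zeta"].to_numpy(), chain=chain, cohorts=cohorts,
            standardization=std, diagnostics=diagnostics,
            sampler_meta=meta.get("sampler", {}),
        )


def fit(design: pd.DataFrame, standardization: Standardization,
        config: SamplerConfig | None = None) -> PosteriorDraws:
    """Sample the joint posterior; returns draws with diagnostics populated.

    Runs ``config.chains`` NUTS chains (seeded deterministically from
    ``config.seed``), discards warmup, maps the unconstrained draws to the
    natural scale, and attaches split R-hat / effective sample size per
    parameter.
    """
    from .diagnostics import convergence_table

    config = config or SamplerConfig()
    model = HierarchicalMaturationModel(design, standardization)
    kept_per_chain = config.iterations - config.warmup
    if kept_per_chain <= 0:
        raise ValueError("warmup must be smaller than iterations")

    all_draws = []
    meta_chains = []
    for chain_id in range(config.chains):
        rng = np.random.default_rng([config.seed, chain_id])
        x0 = model.initial_point(rng)
        result = hmc.sample_chain(
            model.logp_and_grad, x0, config.iterations, config.warmup, rng,
            target_accept=config.target_accept, max_depth=config.max_depth,
        )
        if result.n_divergent > 0.1 * kept_per_chain:
            raise RuntimeError(
                f"chain {chain_id}: {result.n_divergent}/{kept_per_chain} "
                "divergent transitions; posterior unreliable"
            )
        logger.info("chain %d: accept %.3f, step %.4g, %d divergent",
                    chain_id, result.accept_rate, result.step_size,
                    result.n_divergent)
        all_draws.append(result.draws)
        meta_chains.append({
            "chain": chain_id, "accept_rate": float(result.accept_rate),
            "step_size": float(result.step_size),
            "n_divergent": int(result.n_divergent),
        })

    stacked = np.concatenate(all_draws, axis=0)
    chain_ids = np.repeat(np.arange(config.chains), kept_per_chain)
    draws = _unpack_draws(model, stacked, chain_ids, standardization)
    draws.sampler_meta = {
        "chains": config.chains, "iterations": config.iterations,
        "warmup": config.warmup, "seed": config.seed,
        "chain_stats": meta_chains,
    }
    draws.diagnostics = convergence_table(draws)
    return draws


def _unpack_draws(model: HierarchicalMaturationModel, stacked: np.ndarray,
                  chain_ids: np.ndarray, std: Standardization) -> PosteriorDraws:
    C = model.n_cohorts
    s = model.slices
    D = len(stacked)
    mu = stacked[:, s["mu"]].copy()
    sigma = np.exp(stacked[:, s["log_sigma"]])
    mu[:, FISHING_K] = _reconstruct_mu7(
        stacked[:, s["beta7"]][:, 0], sigma[:, FISHING_K],
        stacked[:, s["mu"]][:, FISHING_K])
    zbeta = stacked[:, s["zbeta"]].reshape(D, C, 8)
    beta = np.empty((D, C, 9))
    for j, k in enumerate(VARYING_K):
        beta[:, :, k] = mu[:, None, k] + sigma[:, None, k] * zbeta[:, :, j]
    beta[:, :, FISHING_K] = stacked[:, s["beta7"]]
    return PosteriorDraws(
        beta=beta, mu=mu, sigma=sigma,
        phi=stacked[:, s["phi"]].copy(),
        gamma=stacked[:, s["gamma"]].copy(),
        mu_phi=stacked[:, s["mu_phi"]][:, 0],
        sigma_phi=np.exp(stacked[:, s["log_sigma_phi"]][:, 0]),
        mu_gamma=stacked[:, s["mu_gamma"]][:, 0],
        sigma_gamma=np.exp(stacked[:, s["log_sigma_gamma"]][:, 0]),
        tau=np.exp(stacked[:, s["log_tau"]][:, 0]),
        omega=stacked[:, s["omega"]].reshape(D, C, 4),
        zeta=np.exp(stacked[:, s["log_zeta"]][:, 0]),
        chain=chain_ids, cohorts=model.cohorts, standardization=std,
    )


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping, for output provenance."""
    payload = yaml.safe_dump(obj, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
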