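import numpy as np
import pandas as pd
import pytest

from pmrnhier import data as pdata
from pmrnhier import simulate
from pmrnhier.data import Standardization
from pmrnhier.model import PosteriorDraws


@pytest.fixture(scope="session")
def small_scenario():
    return simulate.ScenarioConfig(
        first_cohort=1990, n_cohorts=6, closure_year=1994,
        fish_per_cohort=(40, 70))


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    env = simulate.generate_environment(small_scenario, seed=42)
    fish, truth = simulate.generate_population(small_scenario, env, seed=42)
    design, std = pdata.build_design(fish, env)
    return {"config": small_scenario, "env": env, "fish": fish,
            "truth": truth, "design": design, "std": std}


def make_posterior_draws(beta_by_draw, cohorts, std, gamma=60.0, phi=100.0,
                         omega=None, n_chains=2):
    """Hand-built PosteriorDraws: beta_by_draw is (D, 9) applied to every
    cohort, growth/condition parameters held constant across draws."""
    beta_by_draw = np.asarray(beta_by_draw, dtype=float)
    D = len(beta_by_draw)
    C = len(cohorts)
    beta = np.broadcast_to(beta_by_draw[:, None, :], (D, C, 9)).copy()
    om = np.zeros(4) if omega is None else np.asarray(omega, dtype=float)
    return PosteriorDraws(
        beta=beta,
        mu=beta_by_draw.copy(),
        sigma=np.full((D, 9), 0.1),
        phi=np.full((D, C), phi),
        gamma=np.full((D, C), gamma),
        mu_phi=np.full(D, phi), sigma_phi=np.full(D, 5.0),
        mu_gamma=np.full(D, gamma), sigma_gamma=np.full(D, 5.0),
        tau=np.full(D, 20.0),
        omega=np.broadcast_to(om, (D, C, 4)).copy(),
        zeta=np.full(D, 1.0),
        chain=np.arange(D) % n_chains,
        cohorts=np.asarray(cohorts),
        standardization=std,
    )


@pytest.fixture
def simple_std():
    """Identity-friendly standardization: age N(3,1.5), length N(200,40),
    Wr N(100,10), GDD N(2600,150), TP N(6,1.5)."""
    return Standardization(
        mean={"age": 3.0, "length": 200.0, "rel_weight": 100.0,
              "gdd": 2600.0, "tp": 6.0},
        sd={"age": 1.5, "length": 40.0, "rel_weight": 10.0,
            "gdd": 150.0, "tp": 1.5},
    )


@pytest.fixture
def flat_env():
    years = np.arange(1985, 2010)
    return pd.DataFrame({
        "year": years,
        "gdd": np.full(len(years), 2600.0),
        "tp": np.full(len(years), 6.0),
        "fishing": (years < 1995).astype(int),
    })
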