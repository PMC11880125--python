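"""MCMC convergence diagnostics: split R-hat and effective sample size.

The convergence criterion is split R-hat < 1.1 for every parameter, i.e.
approximately equal variation within and among chains.  Computation is
delegated to arviz (rank-normalized split R-hat, bulk ESS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

RHAT_THRESHOLD = 1.1


def _per_chain(values: np.ndarray, chain: np.ndarray) -> np.ndarray:
    """(D,) draw-major array -> (n_chains, draws_per_chain)."""
    chains = np.unique(chain)
    return np.stack([values[chain == c] for c in chains])


def convergence_table(draws) -> pd.DataFrame:
    """Split R-hat and bulk ESS for every scalar parameter, one row each."""
    import arviz as az

    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")
    arrays = {name: _per_chain(v, draws.chain)
              for name, v in draws.parameter_arrays().items()}
    names = list(arrays)
    # one (chain, draw, param) block keeps the arviz overhead to a single call
    block = np.stack([arrays[n] for n in names], axis=-1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(block)
        rhat = az.rhat(ds)["x"].to_numpy()
        ess = az.ess(ds)["x"].to_numpy()
    # a parameter constant over every draw has no variation to diagnose
    constant = np.array([np.ptp(block[..., i]) == 0.0
                         for i in range(block.shape[-1])])
    rhat = np.where(constant & ~np.isfinite(rhat), 1.0, rhat)
    return pd.DataFrame({"parameter": names, "rhat": rhat, "ess_bulk": ess})


@dataclass
class ConvergenceReport:
    table: pd.DataFrame
    threshold: float = RHAT_THRESHOLD

    @property
    def passed(self) -> bool:
        return bool((self.table["rhat"] < self.threshold).all())

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())

    @property
    def worst_parameter(self) -> str:
        return str(self.table.loc[self.table["rhat"].idxmax(), "parameter"])

    def summary(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return (f"convergence {status}: max split R-hat {self.max_rhat:.4f} "
                f"({self.worst_parameter}), threshold {self.threshold}; "
                f"min bulk ESS {self.table['ess_bulk'].min():.0f}")


def check_convergence(draws, threshold: float = RHAT_THRESHOLD) -> ConvergenceReport:
    """Diagnostic report over all parameters; ``passed`` iff every split
    R-hat is below ``threshold``."""
    table = draws.diagnostics if draws.diagnostics is not None \
        else convergence_table(draws)
    return ConvergenceReport(table=table, threshold=threshold)
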