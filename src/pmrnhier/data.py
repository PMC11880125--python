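"""Domain types, file I/O, condition indices, and covariate standardization.

The fish table is one row per fish (id, obs_year, age, length_mm, weight_g,
mature, sex); the environment table is one row per calendar year (year, gdd,
tp, fishing).  Cohort is always derived as ``obs_year - age``.  Body
condition is indexed by relative weight, Wr = 100 * W / Ws(TL), where the
standard weight Ws comes from the percid inter-population length-weight
regression log10(Ws) = -5.386 + 3.230 log10(TL).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FISH_COLUMNS = ["id", "obs_year", "age", "length_mm", "weight_g", "mature", "sex"]
ENV_COLUMNS = ["year", "gdd", "tp", "fishing"]

#: Continuous covariates that are z-scored before modelling.
STANDARDIZED_COVARIATES = ("age", "length", "rel_weight", "gdd", "tp")

# Standard-weight regression coefficients (log10 grams on log10 mm TL).
_WS_INTERCEPT = -5.386
_WS_SLOPE = 3.230


class InvalidInputError(ValueError):
    """Raised when an input value violates a domain precondition."""


@dataclass(frozen=True)
class FishRecord:
    """A single observed fish.

    ``cohort`` is the spawning year, derived as ``obs_year - age``;
    ``mature`` is 1 for mature and 0 for immature.
    """

    id: str
    obs_year: int
    age: int
    length_mm: float
    weight_g: float | None
    mature: int
    sex: str
    rel_weight: float | None = None

    @property
    def cohort(self) -> int:
        return self.obs_year - self.age

    def __post_init__(self):
        if self.age < 1:
            raise InvalidInputError(f"age must be >= 1, got {self.age}")
        if self.length_mm <= 0:
            raise InvalidInputError(f"length_mm must be positive, got {self.length_mm}")
        if self.mature not in (0, 1):
            raise InvalidInputError(f"mature must be 0 or 1, got {self.mature}")


def standard_weight(length_mm):
    """Standard weight Ws in grams for a total length in mm.

    Ws = 10 ** (-5.386 + 3.230 * log10(TL)); strictly increasing in TL.
    """
    length_mm = np.asarray(length_mm, dtype=float)
    if np.any(length_mm <= 0):
        raise InvalidInputError("length_mm must be positive")
    out = 10.0 ** (_WS_INTERCEPT + _WS_SLOPE * np.log10(length_mm))
    return out.item() if out.ndim == 0 else out


def relative_weight(weight_g, length_mm):
    """Relative weight Wr = 100 * W / Ws(TL), a dimensionless condition index."""
    weight_g = np.asarray(weight_g, dtype=float)
    if np.any(weight_g <= 0):
        raise InvalidInputError("weight_g must be positive")
    out = 100.0 * weight_g / standard_weight(length_mm)
    return out.item() if out.ndim == 0 else out


def impute_weights(fish: pd.DataFrame) -> pd.DataFrame:
    """Fill missing weights from year-specific length-weight regressions.

    For each observation year with missing weights, fits log10(W) on
    log10(TL) by least squares over that year's weighed fish and predicts
    the missing values.  Years with missing weights but fewer than two
    weighed fish cannot support a regression; their weightless records are
    dropped with a warning and flagged in the ``excluded_weight_year``
    attribute of the returned frame.
    """
    fish = fish.copy()
    missing = fish["weight_g"].isna()
    if not missing.any():
        fish.attrs["excluded_weight_year"] = []
        return fish

    excluded_years = []
    drop_idx = []
    for year, grp in fish.groupby("obs_year"):
        miss = grp["weight_g"].isna()
        if not miss.any():
            continue
        obs = grp[~miss]
        if len(obs) < 2:
            logger.warning(
                "obs_year %s has %d weighed fish; cannot fit length-weight "
                "regression, excluding %d weightless records",
                year, len(obs), int(miss.sum()),
            )
            excluded_years.append(int(year))
            drop_idx.extend(grp.index[miss])
            continue
        slope, intercept = np.polyfit(
            np.log10(obs["length_mm"]), np.log10(obs["weight_g"]), 1
        )
        pred = 10.0 ** (intercept + slope * np.log10(grp.loc[miss, "length_mm"]))
        fish.loc[grp.index[miss], "weight_g"] = pred.to_numpy()

    if drop_idx:
        fish = fish.drop(index=drop_idx)
    fish.attrs["excluded_weight_year"] = excluded_years
    return fish


@dataclass
class Standardization:
    """Raw-scale means and standard deviations for the z-scored covariates.

    The sample standard deviation (n-1 denominator) is used throughout.
    ``zscore`` and ``inverse`` are exact inverses.
    """

    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    @classmethod
    def from_arrays(cls, **arrays) -> "Standardization":
        mean, sd = {}, {}
        for name, x in arrays.items():
            x = np.asarray(x, dtype=float)
            m, s = float(np.mean(x)), float(np.std(x, ddof=1))
            if not s > 0:
                raise InvalidInputError(f"covariate {name!r} has zero variance")
            mean[name], sd[name] = m, s
        return cls(mean=mean, sd=sd)

    def zscore(self, name: str, x):
        return (np.asarray(x, dtype=float) - self.mean[name]) / self.sd[name]

    def inverse(self, name: str, z):
        return np.asarray(z, dtype=float) * self.sd[name] + self.mean[name]

    def to_dict(self) -> dict:
        return {"mean": dict(self.mean), "sd": dict(self.sd)}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardization":
        return cls(mean={k: float(v) for k, v in d["mean"].items()},
                   sd={k: float(v) for k, v in d["sd"].items()})


def _validate_fish(fish: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in FISH_COLUMNS if c not in fish.columns]
    if missing_cols:
        raise InvalidInputError(f"fish table missing columns: {missing_cols}")
    bad = fish[(fish["age"] < 1) | (fish["length_mm"] <= 0)
               | (~fish["mature"].isin([0, 1]))]
    if len(bad):
        raise InvalidInputError(
            f"{len(bad)} fish rows violate age>=1 / length>0 / mature in {{0,1}}; "
            f"first bad id: {bad['id'].iloc[0]!r}"
        )
    fish = fish.copy()
    if "cohort" in fish.columns:
        mismatch = fish["cohort"] != fish["obs_year"] - fish["age"]
        if mismatch.any():
            raise InvalidInputError(
                f"{int(mismatch.sum())} rows have cohort != obs_year - age"
            )
    else:
        fish["cohort"] = fish["obs_year"] - fish["age"]
    return fish


def read_fish_table(path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a fish observation table; derives the cohort column."""
    fish = pd.read_csv(path, sep=sep, comment="#")
    fish["weight_g"] = pd.to_numeric(fish["weight_g"], errors="coerce")
    return _validate_fish(fish)


def read_env_table(path, sep: str = ",") -> pd.DataFrame:
    """Read an annual environment table (year, gdd, tp, fishing)."""
    env = pd.read_csv(path, sep=sep, comment="#")
    missing_cols = [c for c in ENV_COLUMNS if c not in env.columns]
    if missing_cols:
        raise InvalidInputError(f"environment table missing columns: {missing_cols}")
    if not env["fishing"].isin([0, 1]).all():
        raise InvalidInputError("fishing must be 0 or 1")
    if env["year"].duplicated().any():
        raise InvalidInputError("duplicate years in environment table")
    return env.sort_values("year").reset_index(drop=True)


def write_fish_table(fish: pd.DataFrame, path, sep: str = ",", header_lines=()) -> None:
    _write_table(fish[[c for c in FISH_COLUMNS if c in fish.columns]], path, sep, header_lines)


def write_env_table(env: pd.DataFrame, path, sep: str = ",", header_lines=()) -> None:
    _write_table(env[ENV_COLUMNS], path, sep, header_lines)


def _write_table(df: pd.DataFrame, path, sep, header_lines) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)


def check_env_coverage(fish: pd.DataFrame, env: pd.DataFrame,
                       interpolate: bool = False) -> pd.DataFrame:
    """Verify the environment series covers every obs_year and obs_year - 1.

    Lagged covariates for the earliest observation year require a record for
    that year minus one.  Missing years are a hard error unless
    ``interpolate`` is set, in which case gdd/tp are linearly interpolated
    and fishing is carried forward.
    """
    needed = set(fish["obs_year"]) | set(fish["obs_year"] - 1)
    have = set(env["year"])
    missing = sorted(needed - have)
    if not missing:
        return env
    if not interpolate:
        raise InvalidInputError(f"environment table missing years: {missing}")
    logger.warning("interpolating environment for missing years %s", missing)
    full = pd.DataFrame({"year": sorted(needed | have)})
    full = full.merge(env, on="year", how="left").sort_values("year")
    full["gdd"] = full["gdd"].interpolate(limit_direction="both")
    full["tp"] = full["tp"].interpolate(limit_direction="both")
    full["fishing"] = full["fishing"].ffill().bfill().astype(int)
    return full.reset_index(drop=True)


def build_design(fish: pd.DataFrame, env: pd.DataFrame, sex: str | None = "F",
                 interpolate_env: bool = False):
    """Assemble the modelling design table and its Standardization.

    Filters to one sex (females by default), merges the per-year environment,
    computes relative weight, and z-scores age, length, Wr, GDD and TP over
    the modelling dataset.  The fishing indicator stays on its raw 0/1 scale.
    Returns ``(design, standardization)`` where ``design`` carries both raw
    and z-scored columns plus a dense 0-based cohort index.
    """
    fish = _validate_fish(fish)
    if sex is not None:
        fish = fish[fish["sex"] == sex]
    if len(fish) == 0:
        raise InvalidInputError("no fish left after sex filter")
    if fish["weight_g"].isna().any():
        raise InvalidInputError("missing weights; run impute_weights first")

    env = check_env_coverage(fish, env, interpolate=interpolate_env)
    env_idx = env.set_index("year")

    d = fish.copy().reset_index(drop=True)
    d["rel_weight"] = relative_weight(d["weight_g"].to_numpy(),
                                      d["length_mm"].to_numpy())
    d["gdd"] = env_idx.loc[d["obs_year"], "gdd"].to_numpy()
    d["tp"] = env_idx.loc[d["obs_year"], "tp"].to_numpy()
    d["fishing"] = env_idx.loc[d["obs_year"], "fishing"].to_numpy().astype(float)

    std = Standardization.from_arrays(
        age=d["age"], length=d["length_mm"], rel_weight=d["rel_weight"],
        gdd=d["gdd"], tp=d["tp"],
    )
    d["age_z"] = std.zscore("age", d["age"])
    d["length_z"] = std.zscore("length", d["length_mm"])
    d["relw_z"] = std.zscore("rel_weight", d["rel_weight"])
    d["gdd_z"] = std.zscore("gdd", d["gdd"])
    d["tp_z"] = std.zscore("tp", d["tp"])

    cohorts = np.sort(d["cohort"].unique())
    cindex = {c: i for i, c in enumerate(cohorts)}
    d["cohort_index"] = d["cohort"].map(cindex)

    sparse = d["cohort"].value_counts()
    for c, n in sparse[sparse < 5].items():
        logger.warning("cohort %s has only %d fish; retained (hierarchy shrinks it)", c, n)
    return d, std


def maturation_design_matrix(design: pd.DataFrame) -> np.ndarray:
    """n x 9 covariate matrix for the maturation logit, in coefficient order:
    intercept, age, length, Wr, age*length, age*Wr, fishing, GDD, TP
    (all continuous columns z-scored; interactions are products of z-scores).
    """
    a = design["age_z"].to_numpy()
    l = design["length_z"].to_numpy()
    w = design["relw_z"].to_numpy()
    return np.column_stack([
        np.ones(len(design)), a, l, w, a * l, a * w,
        design["fishing"].to_numpy(), design["gdd_z"].to_numpy(),
        design["tp_z"].to_numpy(),
    ])
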