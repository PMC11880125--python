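"""PMRN estimation: first-maturation probabilities and Lp50 midpoints.

For every posterior draw, each fish's probability of being mature in its
current state (o) and in its reconstructed previous-year state (o_prev) give
the probability of *first* maturation

    m = (o - o_prev) / (1 - o_prev),   floored at zero.

The previous state uses age a-1, length l - dl (growth-model increment),
condition w - dw (condition-model increment), and the lagged calendar-year
environment.  Within each cohort x age cell, a logistic regression of m on
length is fitted per draw; its midpoint Lp50 = -intercept/slope is the
length at 50% first-maturation probability.  Cells are excluded per draw
when they hold fewer than two usable fish, the fitted slope is
non-positive, or the fit does not converge; cohort x age cells with more
than 5% of draws excluded are flagged as unreliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Standardization

logger = logging.getLogger(__name__)

DEFAULT_AGES = (2, 3, 4, 5)
EXCLUSION_THRESHOLD = 0.05
_O_PREV_CAP = 1.0 - 1e-12


@dataclass(frozen=True)
class PreviousState:
    """A fish's model-predicted state in the year before observation."""

    age_prev: int
    length_prev_mm: float
    length_prev_z: float
    cond_prev_z: float
    fishing_prev: float
    gdd_prev_z: float
    tp_prev_z: float


def first_maturation_probability(o_curr, o_prev):
    """m = (o_curr - o_prev) / (1 - o_prev), floored at 0.

    The floor encodes that a fish more likely to have been mature last year
    than this year cannot be first-maturing now.  Undefined at o_prev = 1.
    """
    o_curr = np.asarray(o_curr, dtype=float)
    o_prev = np.asarray(o_prev, dtype=float)
    if np.any(o_prev >= 1.0):
        raise ValueError("o_prev = 1 leaves first maturation undefined")
    m = np.clip((o_curr - o_prev) / (1.0 - o_prev), 0.0, 1.0)
    return m.item() if m.ndim == 0 else m


def _sigmoid(eta):
    return 0.5 * (1.0 + np.tanh(0.5 * np.clip(eta, -500, 500)))


def previous_state(fish_row, draw_params: dict, env: pd.DataFrame,
                   std: Standardization) -> PreviousState:
    """Reconstruct one fish's previous-year state under one posterior draw.

    ``draw_params`` holds single-draw arrays ``gamma`` (per cohort, mm per
    ln-year) and ``omega`` (per cohort, 4) plus the ``cohorts`` index.
    """
    age = int(fish_row["age"])
    if age < 2:
        raise ValueError("previous state requires age >= 2")
    year_prev = int(fish_row["obs_year"]) - 1
    env_idx = env.set_index("year")
    if year_prev not in env_idx.index:
        raise ValueError(f"environment table missing lagged year {year_prev}")
    cohorts = list(draw_params["cohorts"])
    c = cohorts.index(fish_row["cohort"])
    gamma_c = float(np.asarray(draw_params["gamma"])[c])
    omega_c = np.asarray(draw_params["omega"])[c]

    dl = gamma_c * (np.log(age) - np.log(age - 1))
    l_prev_mm = float(fish_row["length_mm"]) - dl
    l_prev_z = float(std.zscore("length", l_prev_mm))
    a_z = float(std.zscore("age", age))
    a_prev_z = float(std.zscore("age", age - 1))
    l_z = float(std.zscore("length", fish_row["length_mm"]))
    theta_curr = omega_c @ np.array([1.0, a_z, l_z, a_z * l_z])
    theta_prev = omega_c @ np.array([1.0, a_prev_z, l_prev_z, a_prev_z * l_prev_z])
    w_z = float(std.zscore("rel_weight", fish_row["rel_weight"]))
    return PreviousState(
        age_prev=age - 1,
        length_prev_mm=l_prev_mm,
        length_prev_z=l_prev_z,
        cond_prev_z=w_z - (theta_curr - theta_prev),
        fishing_prev=float(env_idx.loc[year_prev, "fishing"]),
        gdd_prev_z=float(std.zscore("gdd", env_idx.loc[year_prev, "gdd"])),
        tp_prev_z=float(std.zscore("tp", env_idx.loc[year_prev, "tp"])),
    )


@dataclass
class MDrawSet:
    """First-maturation probabilities per posterior draw for the PMRN subset."""

    m: np.ndarray            # (D, n) first-maturation probabilities
    valid: np.ndarray        # (D, n) usable fish x draw combinations
    design: pd.DataFrame     # the PMRN fish subset, index reset
    n_excluded_fish: int     # fish dropped before m (age < 2)


def compute_m_draws(design: pd.DataFrame, draws, env: pd.DataFrame,
                    ages=DEFAULT_AGES, chunk: int = 250) -> MDrawSet:
    """Per-draw first-maturation probability for every eligible fish.

    Fish below age 2 have no previous observable state and are excluded
    (logged).  Draw x fish combinations where o_prev reaches 1 numerically
    are marked invalid and later count as excluded draws in their cell.
    """
    ages = [a for a in ages if a >= 2]
    sub = design[design["age"].isin(ages)].reset_index(drop=True)
    n_young = int((design["age"] < 2).sum())
    if n_young:
        logger.info("%d fish below age 2 excluded from PMRN (no previous state)",
                    n_young)
    if len(sub) == 0:
        raise ValueError("no fish in the requested PMRN age range")

    std = draws.standardization
    env_idx = env.set_index("year")
    year_prev = sub["obs_year"].to_numpy() - 1
    missing = sorted(set(year_prev) - set(env_idx.index))
    if missing:
        raise ValueError(f"environment table missing lagged years: {missing}")

    age = sub["age"].to_numpy(dtype=float)
    l_mm = sub["length_mm"].to_numpy()
    a_z = sub["age_z"].to_numpy()
    l_z = sub["length_z"].to_numpy()
    w_z = sub["relw_z"].to_numpy()
    f_curr = sub["fishing"].to_numpy()
    t_z = sub["gdd_z"].to_numpy()
    p_z = sub["tp_z"].to_numpy()
    ci = sub["cohort_index"].to_numpy(dtype=np.intp)
    a_prev_z = std.zscore("age", age - 1.0)
    f_prev = env_idx.loc[year_prev, "fishing"].to_numpy(dtype=float)
    t_prev_z = std.zscore("gdd", env_idx.loc[year_prev, "gdd"].to_numpy())
    p_prev_z = std.zscore("tp", env_idx.loc[year_prev, "tp"].to_numpy())
    log_ratio = np.log(age) - np.log(age - 1.0)

    D = draws.n_draws
    n = len(sub)
    m = np.empty((D, n))
    valid = np.empty((D, n), dtype=bool)
    for lo in range(0, D, chunk):
        hi = min(lo + chunk, D)
        beta = draws.beta[lo:hi][:, ci, :]          # (d, n, 9)
        gamma = draws.gamma[lo:hi][:, ci]           # (d, n)
        omega = draws.omega[lo:hi][:, ci, :]        # (d, n, 4)

        eta_curr = (beta[..., 0] + beta[..., 1] * a_z + beta[..., 2] * l_z
                    + beta[..., 3] * w_z + beta[..., 4] * (a_z * l_z)
                    + beta[..., 5] * (a_z * w_z) + beta[..., 6] * f_curr
                    + beta[..., 7] * t_z + beta[..., 8] * p_z)

        dl = gamma * log_ratio                      # mm
        l_prev_z = std.zscore("length", l_mm - dl)
        theta_curr = (omega[..., 0] + omega[..., 1] * a_z + omega[..., 2] * l_z
                      + omega[..., 3] * (a_z * l_z))
        theta_prev = (omega[..., 0] + omega[..., 1] * a_prev_z
                      + omega[..., 2] * l_prev_z
                      + omega[..., 3] * (a_prev_z * l_prev_z))
        w_prev_z = w_z - (theta_curr - theta_prev)
        eta_prev = (beta[..., 0] + beta[..., 1] * a_prev_z
                    + beta[..., 2] * l_prev_z + beta[..., 3] * w_prev_z
                    + beta[..., 4] * (a_prev_z * l_prev_z)
                    + beta[..., 5] * (a_prev_z * w_prev_z)
                    + beta[..., 6] * f_prev + beta[..., 7] * t_prev_z
                    + beta[..., 8] * p_prev_z)

        o_curr = _sigmoid(eta_curr)
        o_prev = _sigmoid(eta_prev)
        ok = o_prev < _O_PREV_CAP
        valid[lo:hi] = ok
        safe_prev = np.where(ok, o_prev, 0.0)
        m[lo:hi] = np.where(
            ok, np.clip((o_curr - safe_prev) / (1.0 - safe_prev), 0.0, 1.0), 0.0)
    return MDrawSet(m=m, valid=valid, design=sub, n_excluded_fish=n_young)


def fit_lp50(length_z: np.ndarray, m: np.ndarray, max_iter: int = 100,
             tol: float = 1e-10):
    """Logistic regression of fractional responses m on length (one cell,
    one draw).

    Maximizes the Bernoulli-type quasi-likelihood by Newton iteration, which
    accepts non-integer responses in [0, 1] (logit-transforming m would fail
    at m = 0).  Returns ``(intercept, slope, lp50_z)`` or ``None`` when the
    cell must be excluded: fewer than two fish, non-positive slope, or no
    convergence.
    """
    length_z = np.asarray(length_z, dtype=float)
    m = np.asarray(m, dtype=float)
    if len(length_z) < 2:
        return None
    res = _irls_batch(length_z, m[None, :], np.ones((1, len(m)), dtype=bool),
                      max_iter=max_iter, tol=tol)
    b0, b1, converged = res[0][0], res[1][0], res[2][0]
    if not converged or b1 <= 0:
        return None
    return float(b0), float(b1), float(-b0 / b1)


def _irls_batch(x: np.ndarray, M: np.ndarray, mask: np.ndarray,
                max_iter: int = 100, tol: float = 1e-10):
    """Newton/IRLS for D simultaneous 2-parameter logistic quasi-fits.

    x: (n,) shared predictor; M: (D, n) fractional responses; mask: (D, n)
    usable points.  Returns (b0, b1, converged) each (D,).
    """
    D = M.shape[0]
    b0 = np.zeros(D)
    b1 = np.zeros(D)
    active = mask.sum(axis=1) >= 2
    converged = np.zeros(D, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active & ~converged)
        if idx.size == 0:
            break
        eta = np.clip(b0[idx, None] + b1[idx, None] * x, -35.0, 35.0)
        p = _sigmoid(eta)
        wmask = mask[idx]
        r = np.where(wmask, M[idx] - p, 0.0)
        w = np.where(wmask, p * (1.0 - p), 0.0)
        g0 = r.sum(axis=1)
        g1 = r @ x
        h00 = w.sum(axis=1)
        h01 = w @ x
        h11 = w @ (x * x)
        det = h00 * h11 - h01 * h01
        bad = (det < 1e-12) | ~np.isfinite(det)
        det = np.where(bad, 1.0, det)
        d0 = np.clip((h11 * g0 - h01 * g1) / det, -10.0, 10.0)
        d1 = np.clip((h00 * g1 - h01 * g0) / det, -10.0, 10.0)
        b0[idx] += np.where(bad, 0.0, d0)
        b1[idx] += np.where(bad, 0.0, d1)
        diverged = bad | (np.abs(b0[idx]) > 50.0) | (np.abs(b1[idx]) > 50.0)
        active[idx[diverged]] = False
        step = np.maximum(np.abs(d0), np.abs(d1))
        converged[idx[~diverged & (step < tol)]] = True
    return b0, b1, converged & active


@dataclass
class MidpointResult:
    """Per cohort x age Lp50 posterior summaries plus per-draw values.

    ``table`` columns: cohort, age, n_fish, n_draws_retained,
    excluded_fraction, lp50_median_mm, lp50_lo95_mm, lp50_hi95_mm, retained.
    ``lp50_draws`` maps (cohort, age) to a (D,) mm array with NaN at
    excluded draws.
    """

    table: pd.DataFrame
    lp50_draws: dict


def estimate_midpoints(design: pd.DataFrame, draws, env: pd.DataFrame,
                       ages=DEFAULT_AGES,
                       exclusion_threshold: float = EXCLUSION_THRESHOLD,
                       chunk: int = 250) -> MidpointResult:
    """Full midpoint pipeline: m per draw, per-cell logistic fits, summaries.

    Every cohort x age cell in range is reported with its exclusion
    bookkeeping; ``retained`` is False when more than ``exclusion_threshold``
    of draws were excluded (n < 2 fish, non-positive slope, or
    non-convergence -- all three count identically).
    """
    mset = compute_m_draws(design, draws, env, ages=ages, chunk=chunk)
    std = draws.standardization
    sub = mset.design
    D = draws.n_draws
    rows = []
    lp50_draws = {}
    for (cohort, age), grp in sub.groupby(["cohort", "age"], sort=True):
        j = grp.index.to_numpy()
        lp50_mm = np.full(D, np.nan)
        if len(j) < 2:
            logger.info("cell cohort=%s age=%s: %d fish < 2, all draws excluded",
                        cohort, age, len(j))
            excluded_fraction = 1.0
        else:
            x = sub.loc[j, "length_z"].to_numpy()
            b0, b1, conv = _irls_batch(x, mset.m[:, j], mset.valid[:, j])
            ok = conv & (b1 > 0)
            lp50_mm[ok] = std.inverse("length", -b0[ok] / b1[ok])
            excluded_fraction = 1.0 - ok.mean()
        retained = excluded_fraction <= exclusion_threshold
        kept = lp50_mm[~np.isnan(lp50_mm)]
        if kept.size:
            med = float(np.median(kept))
            lo, hi = (float(v) for v in np.percentile(kept, [2.5, 97.5]))
        else:
            med = lo = hi = np.nan
        rows.append({
            "cohort": cohort, "age": age, "n_fish": len(j),
            "n_draws_retained": int(kept.size),
            "excluded_fraction": float(excluded_fraction),
            "lp50_median_mm": med, "lp50_lo95_mm": lo, "lp50_hi95_mm": hi,
            "retained": retained,
        })
        lp50_draws[(cohort, age)] = lp50_mm
    return MidpointResult(table=pd.DataFrame(rows), lp50_draws=lp50_draws)


def posterior_overlap(draws_a: np.ndarray, draws_b: np.ndarray,
                      bins: int = 100) -> float:
    """Overlapping coefficient of two empirical distributions.

    Sum over shared equal-width histogram bins (spanning the pooled range)
    of min(relative frequency a, relative frequency b); symmetric, in
    [0, 1], 1 for identical samples and 0 for disjoint supports.
    """
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("posterior_overlap requires non-empty draw sets")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    fa = np.histogram(a, bins=edges)[0] / a.size
    fb = np.histogram(b, bins=edges)[0] / b.size
    return float(np.minimum(fa, fb).sum())


def overlap_table(result: MidpointResult, groups: dict, ages=DEFAULT_AGES,
                  bins: int = 100) -> pd.DataFrame:
    """Pairwise posterior overlap of pooled Lp50 draws between cohort groups.

    ``groups`` maps a label to a list of cohorts; only retained cells
    contribute.  Group pairs with no retained draws at an age are skipped.
    """
    retained = result.table[result.table["retained"]]
    labels = list(groups)
    rows = []
    for age in ages:
        pooled = {}
        for label in labels:
            cells = [result.lp50_draws[(c, age)] for c in groups[label]
                     if ((retained["cohort"] == c) & (retained["age"] == age)).any()]
            if cells:
                v = np.concatenate(cells)
                pooled[label] = v[~np.isnan(v)]
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                if la in pooled and lb in pooled:
                    rows.append({
                        "group_a": la, "group_b": lb, "age": age,
                        "overlap_proportion": posterior_overlap(
                            pooled[la], pooled[lb], bins=bins),
                    })
    return pd.DataFrame(rows, columns=["group_a", "group_b", "age",
                                       "overlap_proportion"])
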