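"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained gradient-based MCMC kernel operating on an unconstrained
parameter vector.  The model supplies ``logp_and_grad(x) -> (float, ndarray)``;
constrained parameters (standard deviations) are handled by the model through
log transforms with Jacobian corrections, so the sampler itself is
unconstrained Euclidean NUTS (multiplicative step-size adaptation targeting a
given acceptance statistic, Stan-style expanding adaptation windows for the
diagonal metric).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_MAX_DELTA = 1000.0  # energy error beyond which a trajectory is divergent


@dataclass
class ChainResult:
    draws: np.ndarray          # (n_kept, dim), post-warmup
    accept_rate: float
    n_divergent: int
    step_size: float
    mass_diag: np.ndarray


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    def __init__(self, eps0: float, target: float = 0.8,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.t = 0

    def update(self, accept_stat: float) -> float:
        self.t += 1
        eta = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** -self.kappa
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return np.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _find_initial_step(logp_grad, x, inv_mass, rng) -> float:
    """Heuristic: double/halve eps until one leapfrog step crosses 50% accept."""
    eps = 1.0
    lp, grad = logp_grad(x)
    p = rng.normal(size=x.size) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(p * p * inv_mass)
    x1, p1, lp1, _ = _leapfrog(logp_grad, x, p, grad, eps, inv_mass)
    h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
    if not np.isfinite(h1):
        direction = -1
    else:
        direction = 1 if (h1 - h0) > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        x1, p1, lp1, _ = _leapfrog(logp_grad, x, p, grad, eps, inv_mass)
        h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
        crossed = np.isfinite(h1) and ((h1 - h0) > np.log(0.5)) == (direction < 0)
        if crossed:
            break
    return max(eps, 1e-8)


def _leapfrog(logp_grad, x, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    x = x + eps * inv_mass * p
    lp, grad = logp_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, lp, grad


class _NutsTree:
    """One NUTS trajectory, built by recursive doubling with slice sampling."""

    def __init__(self, logp_grad, eps, inv_mass, rng, max_depth):
        self.logp_grad = logp_grad
        self.eps = eps
        self.inv_mass = inv_mass
        self.rng = rng
        self.max_depth = max_depth
        self.divergent = False
        self.sum_accept = 0.0
        self.n_accept = 0

    def _kinetic(self, p):
        return 0.5 * np.sum(p * p * self.inv_mass)

    def _build(self, x, p, grad, log_u, direction, depth, h0):
        if depth == 0:
            x1, p1, lp1, grad1 = _leapfrog(
                self.logp_grad, x, p, grad, direction * self.eps, self.inv_mass)
            h1 = lp1 - self._kinetic(p1) if np.isfinite(lp1) else -np.inf
            delta = h1 - h0
            self.sum_accept += min(1.0, np.exp(min(delta, 0.0)))
            self.n_accept += 1
            if log_u > delta + _MAX_DELTA or not np.isfinite(h1):
                self.divergent = True
                return x1, p1, grad1, x1, p1, grad1, x1, 0, False
            n_valid = int(log_u <= delta)
            return x1, p1, grad1, x1, p1, grad1, x1, n_valid, True

        (xm, pm, gm, xp, pp, gp, xs, n1, ok) = self._build(
            x, p, grad, log_u, direction, depth - 1, h0)
        if not ok:
            return xm, pm, gm, xp, pp, gp, xs, n1, False
        if direction == -1:
            (xm, pm, gm, _, _, _, xs2, n2, ok2) = self._build(
                xm, pm, gm, log_u, direction, depth - 1, h0)
        else:
            (_, _, _, xp, pp, gp, xs2, n2, ok2) = self._build(
                xp, pp, gp, log_u, direction, depth - 1, h0)
        if ok2 and (n1 + n2) > 0 and self.rng.random() < n2 / (n1 + n2):
            xs = xs2
        ok = ok2 and self._no_u_turn(xm, pm, xp, pp)
        return xm, pm, gm, xp, pp, gp, xs, n1 + n2, ok

    def _no_u_turn(self, xm, pm, xp, pp):
        dx = xp - xm
        return (np.dot(dx, self.inv_mass * pm) >= 0
                and np.dot(dx, self.inv_mass * pp) >= 0)

    def sample(self, x, lp, grad):
        p0 = self.rng.normal(size=x.size) / np.sqrt(self.inv_mass)
        h0 = lp - self._kinetic(p0)
        # slice variable kept in log space for stability
        log_u = np.log(self.rng.random())
        xm = xp = x
        pm = pp = p0
        gm = gp = grad
        sample = x
        n = 1
        ok = True
        depth = 0
        while ok and depth < self.max_depth:
            direction = 1 if self.rng.random() < 0.5 else -1
            if direction == -1:
                xm, pm, gm, _, _, _, xs, n2, ok2 = self._build(
                    xm, pm, gm, log_u, direction, depth, h0)
            else:
                _, _, _, xp, pp, gp, xs, n2, ok2 = self._build(
                    xp, pp, gp, log_u, direction, depth, h0)
            if ok2 and n2 > 0 and self.rng.random() < min(1.0, n2 / n):
                sample = xs
            n += n2
            ok = ok2 and self._no_u_turn(xm, pm, xp, pp)
            depth += 1
        accept_stat = self.sum_accept / max(self.n_accept, 1)
        return sample, accept_stat, self.divergent


def _adaptation_windows(n_warmup: int):
    """Stan-style schedule: initial fast phase, expanding slow windows, final fast."""
    init = min(75, int(0.15 * n_warmup))
    term = min(50, int(0.1 * n_warmup))
    slow_total = n_warmup - init - term
    windows = []
    w = max(25, slow_total // 8)
    pos = 0
    while pos < slow_total:
        if pos + 2 * w >= slow_total:
            w = slow_total - pos
        windows.append((init + pos, init + pos + w))
        pos += w
        w *= 2
    return init, windows, n_warmup - term


def sample_chain(logp_grad, x0: np.ndarray, n_iter: int, n_warmup: int,
                 rng: np.random.Generator, target_accept: float = 0.8,
                 max_depth: int = 8) -> ChainResult:
    """Run one NUTS chain; returns the ``n_iter - n_warmup`` post-warmup draws."""
    dim = x0.size
    inv_mass = np.ones(dim)
    x = np.asarray(x0, dtype=float).copy()
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log posterior")

    eps = _find_initial_step(logp_grad, x, inv_mass, rng)
    da = _DualAveraging(eps, target=target_accept)
    init, slow_windows, term_start = _adaptation_windows(n_warmup)
    window_iter = iter(slow_windows)
    window = next(window_iter, None)
    welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)

    kept = np.empty((n_iter - n_warmup, dim))
    n_div = 0
    n_acc = 0.0
    for it in range(n_iter):
        tree = _NutsTree(logp_grad, eps, inv_mass, rng, max_depth)
        x, accept_stat, divergent = tree.sample(x, lp, grad)
        lp, grad = logp_grad(x)
        if divergent and it >= n_warmup:
            n_div += 1
        if it < n_warmup:
            eps = da.update(accept_stat)
            if window and window[0] <= it < window[1]:
                welford_n += 1
                d = x - welford_mean
                welford_mean += d / welford_n
                welford_m2 += d * (x - welford_mean)
                if it == window[1] - 1:
                    if welford_n > 1:
                        var = welford_m2 / (welford_n - 1)
                        # regularize towards unit metric as Stan does
                        inv_mass = (welford_n / (welford_n + 5.0)) * var \
                            + 1e-3 * (5.0 / (welford_n + 5.0))
                    welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)
                    eps = _find_initial_step(logp_grad, x, inv_mass, rng)
                    da = _DualAveraging(eps, target=target_accept)
                    window = next(window_iter, None)
            if it == n_warmup - 1:
                eps = da.adapted
        else:
            n_acc += accept_stat
            kept[it - n_warmup] = x
    return ChainResult(
        draws=kept,
        accept_rate=n_acc / max(n_iter - n_warmup, 1),
        n_divergent=n_div,
        step_size=eps,
        mass_diag=1.0 / inv_mass,
    )
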