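"""Hamiltonian Monte Carlo with dual-averaging step-size and diagonal mass
adaptation.

A deliberately compact sampler for the smooth, fully-differentiable
posteriors in this package: standard leapfrog HMC with a Metropolis accept
step, the Nesterov dual-averaging scheme for the step size during warmup
(target acceptance 0.8 by default), and a diagonal mass matrix re-estimated
once mid-warmup from the warmup draws. The number of leapfrog steps is
jittered uniformly on ``1..max_leapfrog`` each iteration to avoid periodic
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class ChainResult:
    draws: np.ndarray  # (n_draws, dim), post-warmup
    accept_prob: float  # mean post-warmup acceptance probability
    divergences: int  # post-warmup divergent transitions
    step_size: float
    inv_mass: np.ndarray


def _leapfrog(logp_grad: LogpGrad, z, p, grad, eps, n_steps, inv_mass):
    for _ in range(n_steps):
        p = p + 0.5 * eps * grad
        z = z + eps * inv_mass * p
        lp, grad = logp_grad(z)
        if not np.isfinite(lp):
            return z, p, lp, grad
        p = p + 0.5 * eps * grad
    return z, p, lp, grad


def _find_initial_step(logp_grad: LogpGrad, z0, inv_mass, rng) -> float:
    """Heuristic: double/halve until the one-step acceptance crosses 0.5."""
    eps = 0.1
    lp0, grad0 = logp_grad(z0)
    p0 = rng.standard_normal(len(z0)) / np.sqrt(inv_mass)
    h0 = lp0 - 0.5 * np.sum(inv_mass * p0**2)

    def h_after(eps):
        z, p, lp, _ = _leapfrog(logp_grad, z0.copy(), p0.copy(), grad0.copy(), eps, 1, inv_mass)
        if not np.isfinite(lp):
            return -np.inf
        return lp - 0.5 * np.sum(inv_mass * p**2)

    direction = 1.0 if h_after(eps) - h0 > np.log(0.5) else -1.0
    for _ in range(50):
        eps_new = eps * 2.0**direction
        if direction > 0 and h_after(eps_new) - h0 <= np.log(0.5):
            break
        if direction < 0 and h_after(eps_new) - h0 > np.log(0.5):
            eps = eps_new
            break
        eps = eps_new
        if eps < 1e-10 or eps > 1e3:
            break
    return eps


def sample_chain(
    logp_grad: LogpGrad,
    z0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    max_leapfrog: int = 32,
    target_accept: float = 0.8,
) -> ChainResult:
    """Run one HMC chain; returns post-warmup draws and sampler statistics."""
    dim = len(z0)
    inv_mass = np.ones(dim)
    z = np.asarray(z0, dtype=float).copy()
    lp, grad = logp_grad(z)
    if not np.isfinite(lp):
        raise RuntimeError("non-finite log density at the initial point")

    eps = _find_initial_step(logp_grad, z, inv_mass, rng)

    # dual averaging state (Hoffman & Gelman defaults)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma_da, t0, kappa = 0.05, 10.0, 0.75

    # warmup window used to estimate the diagonal mass matrix
    win_lo = max(1, int(0.25 * n_warmup))
    win_hi = max(win_lo + 1, int(0.75 * n_warmup))
    win_draws: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    accepts: list[float] = []
    divergences = 0
    da_iter = 0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p0**2)
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        z_new, p_new, lp_new, grad_new = _leapfrog(
            logp_grad, z.copy(), p0.copy(), grad.copy(), eps, n_steps, inv_mass
        )
        if np.isfinite(lp_new):
            h_new = lp_new - 0.5 * np.sum(inv_mass * p_new**2)
            log_accept = min(0.0, h_new - h0)
            divergent = (h0 - h_new) > 1000.0
        else:
            log_accept = -np.inf
            divergent = True
        accept_prob = np.exp(log_accept)
        if np.log(rng.uniform()) < log_accept:
            z, lp, grad = z_new, lp_new, grad_new

        if warming:
            da_iter += 1
            h_bar = (1 - 1 / (da_iter + t0)) * h_bar + (target_accept - accept_prob) / (da_iter + t0)
            log_eps = mu - np.sqrt(da_iter) / gamma_da * h_bar
            w = da_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = np.exp(log_eps)
            if win_lo <= it < win_hi:
                win_draws.append(z.copy())
            if it == win_hi - 1 and len(win_draws) >= 10:
                var = np.var(np.asarray(win_draws), axis=0)
                n_win = len(win_draws)
                # regularize toward unit scale (Stan-style shrinkage)
                inv_mass = (n_win / (n_win + 5.0)) * var + (5.0 / (n_win + 5.0)) * 1e-3
                inv_mass = np.clip(inv_mass, 1e-8, 1e8)
                # restart step-size adaptation around the current step
                eps = _find_initial_step(logp_grad, z, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            accepts.append(accept_prob)
            if divergent:
                divergences += 1
            draws[it - n_warmup] = z

    return ChainResult(
        draws=draws,
        accept_prob=float(np.mean(accepts)) if accepts else float("nan"),
        divergences=divergences,
        step_size=float(eps),
        inv_mass=inv_mass,
    )
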