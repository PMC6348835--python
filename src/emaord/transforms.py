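"""Order-preserving and simplex transforms for constrained parameters.

The sampler works on an unconstrained vector; constrained blocks are mapped
through these bijections with their log-Jacobian terms added to the target:

* ordered vector (cumulative cutpoints): first element free, remaining
  elements are cumulative sums of exponentiated increments;
* unit simplex (stereotype score increments): logistic stick-breaking with
  the centering offsets that make the zero vector map to the uniform simplex.

Each transform exposes forward/inverse maps, the log |det Jacobian| and the
chain-rule helpers that pull a gradient with respect to the constrained
parameters (plus the Jacobian term) back to the unconstrained scale.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


# -- ordered vector ---------------------------------------------------------


def ordered_from_unconstrained(z: np.ndarray) -> np.ndarray:
    """Map R^{K} -> strictly increasing vector of length K."""
    out = np.empty_like(z, dtype=float)
    out[0] = z[0]
    if len(z) > 1:
        with np.errstate(over="ignore"):  # inf cutpoints reject upstream
            out[1:] = z[0] + np.cumsum(np.exp(z[1:]))
    return out


def unconstrained_from_ordered(alpha: np.ndarray) -> np.ndarray:
    """Inverse of :func:`ordered_from_unconstrained` (requires strict order)."""
    alpha = np.asarray(alpha, dtype=float)
    d = np.diff(alpha)
    if np.any(d <= 0):
        raise ValueError("ordered transform requires strictly increasing input")
    return np.concatenate(([alpha[0]], np.log(d)))


def ordered_log_jac(z: np.ndarray) -> float:
    return float(np.sum(z[1:]))


def ordered_chain_grad(z: np.ndarray, grad_alpha: np.ndarray) -> np.ndarray:
    """d/dz of f(alpha(z)) + log|J|(z), given df/dalpha."""
    gz = np.empty_like(grad_alpha)
    # alpha_c depends on z_0 for all c, and on z_k (k>=1) for c >= k.
    rev_cum = np.cumsum(grad_alpha[::-1])[::-1]
    gz[0] = rev_cum[0]
    if len(z) > 1:
        gz[1:] = np.exp(z[1:]) * rev_cum[1:] + 1.0  # +1 from d(log jac)/dz_k
    return gz


# -- unit simplex (stick-breaking) ------------------------------------------


def simplex_from_unconstrained(z: np.ndarray) -> np.ndarray:
    """Map R^{K-1} -> interior of the K-simplex; z = 0 gives the uniform simplex."""
    K = len(z) + 1
    gamma = np.empty(K, dtype=float)
    stick = 1.0
    v = expit(z - np.log(np.arange(K - 1, 0, -1)))
    for k in range(K - 1):
        gamma[k] = stick * v[k]
        stick *= 1.0 - v[k]
    gamma[K - 1] = stick
    return gamma


def unconstrained_from_simplex(gamma: np.ndarray) -> np.ndarray:
    gamma = np.asarray(gamma, dtype=float)
    K = len(gamma)
    if np.any(gamma <= 0) or abs(gamma.sum() - 1.0) > 1e-8:
        raise ValueError("stick-breaking inverse requires an interior simplex point")
    z = np.empty(K - 1, dtype=float)
    stick = 1.0
    for k in range(K - 1):
        v = gamma[k] / stick
        z[k] = np.log(v / (1.0 - v)) + np.log(K - 1 - k)
        stick -= gamma[k]
    return z


def _sticks(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (v, gamma, remaining-stick R) for the stick-breaking map."""
    K = len(z) + 1
    v = expit(z - np.log(np.arange(K - 1, 0, -1)))
    R = np.empty(K, dtype=float)  # R[k] = stick remaining before break k
    gamma = np.empty(K, dtype=float)
    stick = 1.0
    for k in range(K - 1):
        R[k] = stick
        gamma[k] = stick * v[k]
        stick *= 1.0 - v[k]
    R[K - 1] = stick
    gamma[K - 1] = stick
    return v, gamma, R


def simplex_log_jac(z: np.ndarray) -> float:
    v, gamma, R = _sticks(z)
    K = len(z) + 1
    with np.errstate(divide="ignore"):
        # v == 0 or 1 to machine precision maps to -inf (zero Jacobian),
        # which the sampler treats as a rejected point
        return float(np.sum(np.log(v) + np.log1p(-v) + np.log(R[: K - 1])))


def simplex_chain_grad(z: np.ndarray, grad_gamma: np.ndarray) -> np.ndarray:
    """d/dz of f(gamma(z)) + log|J|(z), given df/dgamma."""
    v, gamma, R = _sticks(z)
    K = len(z) + 1
    gg = gamma * grad_gamma
    # suffix sums S_k = sum_{j > k} gamma_j * grad_gamma_j
    S = np.concatenate((np.cumsum(gg[::-1])[::-1][1:], [0.0]))
    ks = np.arange(K - 1)
    grad_f = v * ((1.0 - v) * R[: K - 1] * grad_gamma[: K - 1] - S[: K - 1])
    grad_jac = (1.0 - v) - v * (K - 1 - ks)
    return grad_f + grad_jac
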