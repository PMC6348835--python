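"""Likelihood core for the four ordinal model variants.

Two ordinal families are supported, each with homogeneous (population-level
slopes only) or heterogeneous (patient-specific slopes) variants:

* **Cumulative (proportional-odds / ordered) logit.** The log odds of
  observing rank <= c is ``alpha_c - x.beta`` with ordered cutpoints
  ``alpha_1 <= ... <= alpha_{C-1}``, so
  ``P(rank <= c) = logistic(alpha_c - x.beta)`` and category probabilities
  are successive differences. Positive slopes push probability toward
  higher categories.

* **Stereotype logit.** Category c's log odds against the baseline
  (last) category are ``alpha_c + phi_c * x.beta`` with ``alpha_1 = 0`` and
  monotone category scores ``0 = phi_1 <= ... <= phi_C = 1``. The scores are
  constructed as the cumulative sum of a simplex ``gamma`` (length C-1), so
  a Dirichlet prior on ``gamma`` keeps ``phi`` ordinal by construction.

The prior hierarchy (variance sigma^2 fixed, 100 by default):

    delta_p   ~ Normal(mu_p, sigma^2),  mu_p in {-1, +1}  (sign of the
                hypothesised item effect: worry negative, the rest positive)
    alpha_c   ~ Normal(0, sigma^2)   (free cutpoints / intercepts)
    gamma     ~ Dirichlet(A, ..., A) (stereotype scores; A = 1 by default)
    beta_j    ~ Normal(delta, sigma^2)  (heterogeneous variant only)
    Y_jt      ~ Categorical(theta_jt)
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import gammaln, log_expit, logsumexp, softmax

from .data import EMADataset, PREDICTORS

logger = logging.getLogger(__name__)

Family = Literal["cumulative", "stereotype"]

FAMILIES = ("cumulative", "stereotype")

#: Tolerance for simplex / monotonicity constraint checks.
_CONSTRAINT_TOL = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """Which of the four model variants to use.

    ``family`` selects the ordinal link (cumulative or stereotype);
    ``heterogeneous`` adds patient-specific slope vectors ``beta_j`` drawn
    around the population slopes ``delta``.
    """

    family: Family = "cumulative"
    heterogeneous: bool = False
    n_categories: int = 10
    n_predictors: int = 5

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")

    @property
    def label(self) -> str:
        het = "heterogeneous" if self.heterogeneous else "homogeneous"
        return f"{het}_{self.family}"


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the prior hierarchy.

    ``slope_prior_means`` are the hypothesised effect signs (+1/-1) used as
    weak prior means for ``delta``; with ``prior_variance`` = 100 the data
    dominates. ``dirichlet_concentration`` is the symmetric Dirichlet
    parameter A for the stereotype score increments.
    """

    slope_prior_means: tuple[float, ...] = (1.0, -1.0, 1.0, 1.0, 1.0)
    prior_variance: float = 100.0
    dirichlet_concentration: float = 1.0

    def __post_init__(self):
        if self.prior_variance <= 0:
            raise ValueError("prior_variance must be > 0")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")

    @property
    def mu(self) -> np.ndarray:
        return np.asarray(self.slope_prior_means, dtype=float)


@dataclass
class ParameterSet:
    """One realization of all model parameters.

    Fields not used by a family are None. For homogeneous variants ``beta``
    may be None (the population slopes ``delta`` apply to every patient) or
    a J x 5 matrix with identical rows.

    ``alpha`` is the length C-1 nondecreasing cutpoint vector (cumulative)
    or the length C intercept vector with ``alpha[0] = 0`` (stereotype).
    ``gamma`` is the length C-1 simplex of score increments and ``phi`` the
    derived length-C score vector (stereotype only).
    """

    family: Family
    delta: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray | None = None
    gamma: np.ndarray | None = None
    phi: np.ndarray | None = None

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.beta is not None:
            self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
        if self.family == "stereotype" and self.phi is None and self.gamma is not None:
            self.phi = phi_from_gamma(self.gamma)
        if self.phi is not None:
            self.phi = np.asarray(self.phi, dtype=float)

    @property
    def n_categories(self) -> int:
        return len(self.alpha) + 1 if self.family == "cumulative" else len(self.alpha)

    def validate(self) -> list[str]:
        """Return a list of violated invariants (empty when valid)."""
        problems: list[str] = []
        if self.family == "cumulative":
            if np.any(np.diff(self.alpha) < 0):
                problems.append("cumulative cutpoints are not nondecreasing")
        else:
            if abs(self.alpha[0]) > _CONSTRAINT_TOL:
                problems.append("stereotype intercept alpha[0] must be 0")
            if self.phi is None:
                problems.append("stereotype parameters require phi (or gamma)")
            else:
                phi = self.phi
                if (
                    abs(phi[0]) > _CONSTRAINT_TOL
                    or abs(phi[-1] - 1.0) > _CONSTRAINT_TOL
                    or np.any(np.diff(phi) < -_CONSTRAINT_TOL)
                ):
                    problems.append("phi must be nondecreasing from 0 to 1")
            if self.gamma is not None:
                if np.any(self.gamma < -_CONSTRAINT_TOL) or abs(self.gamma.sum() - 1.0) > 1e-6:
                    problems.append("gamma must be a simplex")
        if self.beta is not None and self.beta.shape[1] != self.delta.shape[0]:
            problems.append("beta column count must match delta length")
        return problems

    def slopes_for(self, patient_row: int | None) -> np.ndarray:
        """Slope vector for one patient (row of beta) or delta when absent."""
        if patient_row is None or self.beta is None:
            return self.delta
        return self.beta[patient_row]

    # -- JSON round-trip for fixtures and recovery tests ----------------------

    def to_json(self) -> str:
        payload = {"family": self.family}
        for name in ("delta", "alpha", "beta", "gamma", "phi"):
            v = getattr(self, name)
            payload[name] = None if v is None else np.asarray(v).tolist()
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        d = json.loads(text)
        return cls(
            family=d["family"],
            delta=np.asarray(d["delta"], dtype=float),
            alpha=np.asarray(d["alpha"], dtype=float),
            beta=None if d.get("beta") is None else np.asarray(d["beta"], dtype=float),
            gamma=None if d.get("gamma") is None else np.asarray(d["gamma"], dtype=float),
            phi=None if d.get("phi") is None else np.asarray(d["phi"], dtype=float),
        )


# ---------------------------------------------------------------------------
# Category probabilities
# ---------------------------------------------------------------------------


def olm_category_probs(x, slopes, cutpoints) -> np.ndarray:
    """Cumulative-logit category probabilities for one predictor profile.

    ``P(rank <= c) = logistic(cutpoints[c] - x.slopes)``; the returned
    length-C vector holds the successive differences (padded with 0 and 1 at
    the ends) and sums to 1.
    """
    x = np.asarray(x, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    cutpoints = np.asarray(cutpoints, dtype=float)
    if np.any(np.diff(cutpoints) < 0):
        raise ValueError("cutpoints must be nondecreasing")
    eta = float(x @ slopes)
    cdf = np.concatenate(([0.0], _expit_stable(cutpoints - eta), [1.0]))
    p = np.diff(cdf)
    return np.clip(p, 0.0, 1.0)


def stereotype_category_probs(x, slopes, intercepts, scores) -> np.ndarray:
    """Stereotype-logit category probabilities for one predictor profile.

    ``P(rank = c)`` is proportional to ``exp(intercepts[c] + scores[c] *
    x.slopes)``; computed with max-subtraction so arbitrarily large linear
    predictors do not overflow.
    """
    x = np.asarray(x, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    intercepts = np.asarray(intercepts, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if intercepts.shape != scores.shape:
        raise ValueError("intercepts and scores must have equal length C")
    if abs(intercepts[0]) > _CONSTRAINT_TOL:
        raise ValueError("stereotype intercepts must satisfy alpha[0] = 0")
    if (
        abs(scores[0]) > _CONSTRAINT_TOL
        or abs(scores[-1] - 1.0) > _CONSTRAINT_TOL
        or np.any(np.diff(scores) < -_CONSTRAINT_TOL)
    ):
        raise ValueError("scores must be nondecreasing with phi[0]=0, phi[-1]=1")
    eta = float(x @ slopes)
    return softmax(intercepts + scores * eta)


def phi_from_gamma(gamma) -> np.ndarray:
    """Stereotype scores from simplex increments: ``phi = (0, cumsum(gamma))``.

    The last entry is forced to exactly 1 so the endpoint constraint holds
    to machine precision.
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < -_CONSTRAINT_TOL) or abs(gamma.sum() - 1.0) > 1e-9:
        raise ValueError("gamma must be a nonnegative vector summing to 1")
    phi = np.concatenate(([0.0], np.cumsum(gamma)))
    phi[-1] = 1.0
    return phi


def _expit_stable(a: np.ndarray) -> np.ndarray:
    return np.exp(log_expit(a))


# ---------------------------------------------------------------------------
# Vectorized log-likelihood (shared with the sampler)
# ---------------------------------------------------------------------------


def _log_diff_expit(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log(sigmoid(a) - sigmoid(b)) for a >= b, stable for large |a|, |b|.

    Uses the identity ``sigmoid(a) - sigmoid(b) = sigmoid(a) * sigmoid(-b) *
    (1 - exp(b - a))``, which degrades gracefully at the +/-inf padding used
    for the first and last category (sigmoid(+inf)=1, sigmoid(-inf)=0).
    """
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        gap = np.exp(b - a)
        gap = np.where(np.isnan(gap), 0.0, gap)  # b = a = +/-inf padding
        out = log_expit(a) + log_expit(-b) + np.log1p(-gap)
    return out


def cumulative_log_probs(eta: np.ndarray, alpha: np.ndarray, y: np.ndarray) -> np.ndarray:
    """log P(Y=y | eta) under the cumulative logit, vectorized over records."""
    pad = np.concatenate(([-np.inf], alpha, [np.inf]))
    upper = pad[y] - eta  # alpha_y - eta (y is 1-based; pad[y] = alpha_y)
    lower = pad[y - 1] - eta
    return _log_diff_expit(upper, lower)


def stereotype_log_probs(eta: np.ndarray, alpha: np.ndarray, phi: np.ndarray, y: np.ndarray) -> np.ndarray:
    """log P(Y=y | eta) under the stereotype logit, vectorized over records."""
    logits = alpha[None, :] + phi[None, :] * eta[:, None]
    return logits[np.arange(len(y)), y - 1] - logsumexp(logits, axis=1)


def linear_predictor(X: np.ndarray, pidx: np.ndarray, params: ParameterSet, heterogeneous: bool) -> np.ndarray:
    """Per-record x.beta, using the patient's slope row when heterogeneous."""
    if heterogeneous:
        if params.beta is None:
            raise ValueError("heterogeneous evaluation requires patient slopes beta")
        if pidx.max() >= params.beta.shape[0]:
            raise ValueError(
                f"patient index {int(pidx.max())} out of range for beta with "
                f"{params.beta.shape[0]} rows"
            )
        return np.einsum("np,np->n", X, params.beta[pidx])
    return X @ params.delta


def pointwise_log_likelihood(spec: ModelSpec, params: ParameterSet, dataset: EMADataset) -> np.ndarray:
    """Per-record log P(Y_jt | x_jt, params), length N.

    Uses the patient's own slope row ``beta_j`` under a heterogeneous spec
    and the population slopes ``delta`` otherwise. The dataset must be
    complete (no missing scores).
    """
    X, y, pidx, _ = dataset.design_arrays()
    eta = linear_predictor(X, pidx, params, spec.heterogeneous)
    if spec.family == "cumulative":
        if np.any(np.diff(params.alpha) < 0):
            raise ValueError("cutpoints must be nondecreasing")
        return cumulative_log_probs(eta, params.alpha, y)
    phi = params.phi if params.phi is not None else phi_from_gamma(params.gamma)
    return stereotype_log_probs(eta, params.alpha, phi, y)


# ---------------------------------------------------------------------------
# Prior density
# ---------------------------------------------------------------------------


def _normal_logpdf(x, mean, var):
    x = np.asarray(x, dtype=float)
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def log_prior_density(spec: ModelSpec, prior: PriorConfig, params: ParameterSet) -> float:
    """Joint log prior of one parameter realization under the model hierarchy.

    Sums Normal(mu, sigma^2) terms for delta, Normal(0, sigma^2) for the
    free intercepts/cutpoints, Normal(delta, sigma^2) for each patient slope
    row (heterogeneous only) and a symmetric Dirichlet(A) term for gamma
    (stereotype only). Returns ``-inf`` when the parameters violate their
    support (e.g. decreasing cutpoints).
    """
    problems = params.validate()
    if problems:
        logger.info("log_prior_density: zero support (%s)", "; ".join(problems))
        return -np.inf
    var = prior.prior_variance
    total = float(np.sum(_normal_logpdf(params.delta, prior.mu, var)))
    if spec.family == "cumulative":
        free_alpha = params.alpha
    else:
        free_alpha = params.alpha[1:]  # alpha_1 fixed at 0
    total += float(np.sum(_normal_logpdf(free_alpha, 0.0, var)))
    if spec.heterogeneous:
        if params.beta is None:
            raise ValueError("heterogeneous spec requires patient slopes beta")
        total += float(np.sum(_normal_logpdf(params.beta, params.delta[None, :], var)))
    if spec.family == "stereotype":
        if params.gamma is None:
            raise ValueError("stereotype spec requires simplex gamma")
        A = prior.dirichlet_concentration
        K = len(params.gamma)
        total += float(gammaln(K * A) - K * gammaln(A))
        if A != 1.0:
            with np.errstate(divide="ignore"):
                total += float((A - 1.0) * np.sum(np.log(params.gamma)))
    return total
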