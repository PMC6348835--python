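"""Synthetic EMA cohorts with known ground-truth parameters.

The generator emulates the structure the analysis assumes: J patients each
contributing a run of complete diary days; five ordinal predictors drawn
independently from configurable marginals (uniform over 1..C by default);
patient-specific slope vectors drawn around population slopes; and the
outcome drawn from the chosen ordinal family's category probabilities. The
default design is 130 patients and 2326 observations (116
patients with 18 diary days and 14 with 17).

Ground truth is kept in :class:`TrueParameters` (serializable to JSON) so
parameter-recovery and model-comparison experiments can score the fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, softmax
from scipy.stats import norm

from .data import EMADataset, OUTCOME, PREDICTORS
from .likelihood import ParameterSet, phi_from_gamma

#: Reference cohort totals: J patients, N complete observations.
REFERENCE_J = 130
REFERENCE_N = 2326

#: Default population slopes on the raw 1..10 predictor scale: modest
#: positive effects for mood, sleep, enjoyed activities and social contact,
#: a negative effect for worry (the hypothesised signs).
DEFAULT_SLOPE_MEANS = (0.4, -0.3, 0.2, 0.3, 0.2)

#: Default per-slope between-patient SD for heterogeneous cohorts.
DEFAULT_HETEROGENEITY_SD = 1.0


@dataclass
class CohortDesign:
    """Size and sampling design of a synthetic cohort.

    ``obs_per_patient`` may be an int, a length-J vector, or None for the
    reference allocation (18 diary days for 116 patients, 17 for the
    remaining 14, totalling 2326 when J = 130; for other J the same
    ~N/J split is used). ``predictor_marginals`` maps item name -> length-C
    probability vector (uniform when omitted).
    """

    n_patients: int = REFERENCE_J
    obs_per_patient: int | np.ndarray | None = None
    n_categories: int = 10
    predictor_marginals: dict[str, np.ndarray] | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        counts = self.counts()
        if np.any(counts < 1):
            raise ValueError("every obs_per_patient must be >= 1")
        if self.predictor_marginals is not None:
            for name, p in self.predictor_marginals.items():
                p = np.asarray(p, dtype=float)
                if len(p) != self.n_categories or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                    raise ValueError(f"marginal for {name!r} is not a length-C simplex")

    def counts(self) -> np.ndarray:
        """Per-patient observation counts (length J)."""
        J = self.n_patients
        if self.obs_per_patient is None:
            base = int(round(REFERENCE_N / REFERENCE_J))  # 18
            counts = np.full(J, base, dtype=int)
            # trim a few patients by one day to match the 2326-total ratio
            deficit = int(round(J * (base - REFERENCE_N / REFERENCE_J)))
            counts[:deficit] -= 1
            return counts
        if np.isscalar(self.obs_per_patient):
            return np.full(J, int(self.obs_per_patient), dtype=int)
        counts = np.asarray(self.obs_per_patient, dtype=int)
        if len(counts) != J:
            raise ValueError("obs_per_patient vector must have length n_patients")
        return counts

    @property
    def n_obs(self) -> int:
        return int(self.counts().sum())

    def marginal(self, name: str) -> np.ndarray:
        if self.predictor_marginals and name in self.predictor_marginals:
            return np.asarray(self.predictor_marginals[name], dtype=float)
        return np.full(self.n_categories, 1.0 / self.n_categories)


@dataclass
class TrueParameters:
    """Generative ground truth for one synthetic cohort."""

    family: str
    delta: np.ndarray
    beta: np.ndarray  # J x 5 patient slopes (rows equal delta when sd = 0)
    alpha: np.ndarray
    heterogeneity_sd: np.ndarray
    gamma: np.ndarray | None = None
    phi: np.ndarray | None = None

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.heterogeneity_sd = np.asarray(self.heterogeneity_sd, dtype=float)
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
        if self.phi is None and self.gamma is not None:
            self.phi = phi_from_gamma(self.gamma)

    def as_parameter_set(self) -> ParameterSet:
        return ParameterSet(
            family=self.family, delta=self.delta, alpha=self.alpha,
            beta=self.beta, gamma=self.gamma, phi=self.phi,
        )

    def to_json(self) -> str:
        payload = {"family": self.family}
        for name in ("delta", "beta", "alpha", "heterogeneity_sd", "gamma", "phi"):
            v = getattr(self, name)
            payload[name] = None if v is None else np.asarray(v).tolist()
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TrueParameters":
        d = json.loads(text)
        return cls(
            family=d["family"],
            delta=np.asarray(d["delta"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            alpha=np.asarray(d["alpha"], dtype=float),
            heterogeneity_sd=np.asarray(d["heterogeneity_sd"], dtype=float),
            gamma=None if d.get("gamma") is None else np.asarray(d["gamma"], dtype=float),
            phi=None if d.get("phi") is None else np.asarray(d["phi"], dtype=float),
        )


def _eta_moments(design: CohortDesign, slope_means, heterogeneity_sd) -> tuple[float, float]:
    """Mean and SD of the linear predictor over patients and predictor draws."""
    C = design.n_categories
    mean_sq = np.empty(len(PREDICTORS))
    mean_x = np.empty(len(PREDICTORS))
    for p, name in enumerate(PREDICTORS):
        probs = design.marginal(name)
        scores = np.arange(1, C + 1)
        mean_x[p] = probs @ scores
        mean_sq[p] = probs @ scores**2
    var_x = mean_sq - mean_x**2
    d = np.asarray(slope_means, dtype=float)
    s = np.asarray(heterogeneity_sd, dtype=float)
    mean_eta = float(d @ mean_x)
    var_eta = float(np.sum((d**2 + s**2) * (var_x + mean_x**2) - d**2 * mean_x**2))
    return mean_eta, max(np.sqrt(var_eta), 1e-6)


def draw_true_parameters(
    design: CohortDesign,
    family: str = "cumulative",
    slope_means=DEFAULT_SLOPE_MEANS,
    heterogeneity_sd=DEFAULT_HETEROGENEITY_SD,
    rng: np.random.Generator | None = None,
) -> TrueParameters:
    """Draw one generative parameter realization for a cohort design.

    Patient slope rows are Normal(slope_means, heterogeneity_sd^2); with
    zero heterogeneity every row equals ``slope_means`` exactly. Cumulative
    cutpoints are drawn around quantile-spaced centers of the induced
    linear-predictor distribution and sorted, so outcomes spread over all C
    categories. Stereotype scores come from a symmetric Dirichlet draw
    (cumulative-sum construction), and the intercepts are centered so the
    average patient is not pinned to an extreme category.
    """
    rng = rng or np.random.default_rng(design.seed)
    P = len(PREDICTORS)
    d = np.broadcast_to(np.asarray(slope_means, dtype=float), (P,)).copy()
    s = np.broadcast_to(np.asarray(heterogeneity_sd, dtype=float), (P,)).copy()
    if np.any(s < 0):
        raise ValueError("heterogeneity_sd must be nonnegative")
    J, C = design.n_patients, design.n_categories
    beta = d[None, :] + s[None, :] * rng.standard_normal((J, P))
    mean_eta, sd_eta = _eta_moments(design, d, s)
    if family == "cumulative":
        centers = mean_eta + sd_eta * norm.ppf(np.arange(1, C) / C)
        alpha = np.sort(centers + 0.1 * sd_eta * rng.standard_normal(C - 1))
        return TrueParameters(
            family=family, delta=d, beta=beta, alpha=alpha, heterogeneity_sd=s
        )
    if family == "stereotype":
        gamma = rng.dirichlet(np.ones(C - 1))
        phi = phi_from_gamma(gamma)
        alpha = -phi * mean_eta
        alpha[1:] += 0.5 * rng.standard_normal(C - 1)
        alpha -= alpha[0]  # keep the identification constraint alpha[0] = 0
        return TrueParameters(
            family=family, delta=d, beta=beta, alpha=alpha,
            heterogeneity_sd=s, gamma=gamma, phi=phi,
        )
    raise ValueError(f"unknown family {family!r}")


def simulate_dataset(
    params: TrueParameters,
    design: CohortDesign,
    rng: np.random.Generator | None = None,
) -> EMADataset:
    """Simulate a complete diary dataset from ground-truth parameters.

    Predictors are drawn independently from the design's marginals; each
    record's outcome is drawn from the family's category probabilities at
    the patient's own slope row. The result always passes
    ``filter_complete`` unchanged.
    """
    rng = rng or np.random.default_rng(design.seed)
    J, C = design.n_patients, design.n_categories
    if params.beta.shape != (J, len(PREDICTORS)):
        raise ValueError(
            f"beta has shape {params.beta.shape}, expected ({J}, {len(PREDICTORS)})"
        )
    counts = design.counts()
    N = int(counts.sum())
    pidx = np.repeat(np.arange(J), counts)
    X = np.empty((N, len(PREDICTORS)))
    scores = np.arange(1, C + 1)
    for p, name in enumerate(PREDICTORS):
        X[:, p] = rng.choice(scores, size=N, p=design.marginal(name))
    eta = np.einsum("np,np->n", X, params.beta[pidx])
    if params.family == "cumulative":
        cdf = expit(params.alpha[None, :] - eta[:, None])  # N x (C-1)
        u = rng.uniform(size=N)
        y = 1 + (u[:, None] > cdf).sum(axis=1)
    else:
        phi = params.phi if params.phi is not None else phi_from_gamma(params.gamma)
        probs = softmax(params.alpha[None, :] + phi[None, :] * eta[:, None], axis=1)
        u = rng.uniform(size=N)
        y = 1 + (u[:, None] > np.cumsum(probs, axis=1)[:, :-1]).sum(axis=1)
    width = len(str(J))
    frame = pd.DataFrame(
        {
            "patient_id": [f"P{j + 1:0{width}d}" for j in pidx],
            "time_index": np.concatenate([np.arange(c) for c in counts]),
        }
    )
    for p, name in enumerate(PREDICTORS):
        frame[name] = X[:, p].astype(int)
    frame[OUTCOME] = y.astype(int)
    return EMADataset(frame, n_categories=C, validate=False)


def make_cohort(
    design: CohortDesign | None = None,
    family: str = "cumulative",
    slope_means=DEFAULT_SLOPE_MEANS,
    heterogeneity_sd=DEFAULT_HETEROGENEITY_SD,
    seed: int | None = None,
) -> tuple[EMADataset, TrueParameters]:
    """Draw parameters and simulate a cohort in one call (seeded)."""
    design = design or CohortDesign()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    params = draw_true_parameters(
        design, family=family, slope_means=slope_means,
        heterogeneity_sd=heterogeneity_sd, rng=rng,
    )
    return simulate_dataset(params, design, rng=rng), params
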