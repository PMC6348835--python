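"""Bayesian estimation of the ordinal diary models.

`OrdinalEMAModel` binds a complete :class:`~emaord.data.EMADataset` to one of
the four model variants (cumulative or stereotype family, with or without
patient-specific slopes) and `fit()` draws from the posterior with the
package's Hamiltonian Monte Carlo sampler, returning an
:class:`OrdinalEMAResults` that carries the thinned post-warmup draws, the
pointwise log-likelihood matrix used by WAIC/DIC, parameter summaries and
convergence diagnostics.

Constrained blocks are sampled on unconstrained scales (ordered cutpoints
via log-increments, the stereotype score simplex via stick-breaking) with
the appropriate Jacobian terms, so the posterior over the constrained
parameters is exactly likelihood x prior. Gradients are analytic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln, log_expit, logsumexp, logit

from .data import EMADataset, PREDICTORS
from .hmc import sample_chain
from .likelihood import (
    ModelSpec,
    ParameterSet,
    PriorConfig,
    _log_diff_expit,
    _normal_logpdf,
    cumulative_log_probs,
    phi_from_gamma,
    stereotype_log_probs,
)
from .transforms import (
    ordered_chain_grad,
    ordered_from_unconstrained,
    ordered_log_jac,
    simplex_chain_grad,
    simplex_from_unconstrained,
    simplex_log_jac,
    unconstrained_from_ordered,
)

logger = logging.getLogger(__name__)

_FULL_PROFILE_ITERS = (60000, 30000, 20)


@dataclass
class MCMCConfig:
    """Sampler settings.

    The full-scale default is 4 chains of 60,000 iterations with draws
    stored every 20th from the final 30,000. The *desk
    profile* (``MCMCConfig.desk()``) is a reduced preset — 4 chains x 2,000
    iterations (1,000 warmup), no thinning — suitable for tests, simulation
    studies and quick exploration.
    """

    chains: int = 4
    total_iterations: int = 60000
    post_warmup_iterations: int = 30000
    thin: int = 20
    seed: int = 0
    desk_profile: bool = False
    max_leapfrog: int = 32
    target_accept: float = 0.8

    def __post_init__(self):
        if self.desk_profile and (
            self.total_iterations,
            self.post_warmup_iterations,
            self.thin,
        ) == _FULL_PROFILE_ITERS:
            self.total_iterations, self.post_warmup_iterations, self.thin = 2000, 1000, 1
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 < self.post_warmup_iterations <= self.total_iterations:
            raise ValueError("need 0 < post_warmup_iterations <= total_iterations")

    @classmethod
    def desk(cls, seed: int = 0, **kwargs) -> "MCMCConfig":
        return cls(desk_profile=True, seed=seed, **kwargs)

    @property
    def n_warmup(self) -> int:
        return self.total_iterations - self.post_warmup_iterations

    @property
    def draws_per_chain(self) -> int:
        return self.post_warmup_iterations // self.thin


class _Layout:
    """Index layout of the unconstrained parameter vector."""

    def __init__(self, spec: ModelSpec, n_patients: int):
        P, C = spec.n_predictors, spec.n_categories
        self.spec = spec
        self.J = n_patients
        i = 0
        self.sl_delta = slice(i, i + P)
        i += P
        self.sl_beta = None
        if spec.heterogeneous:
            self.sl_beta = slice(i, i + n_patients * P)
            i += n_patients * P
        self.sl_alpha = slice(i, i + C - 1)  # cutpoints or free intercepts
        i += C - 1
        self.sl_gamma = None
        if spec.family == "stereotype":
            self.sl_gamma = slice(i, i + C - 2)
            i += C - 2
        self.dim = i

    def unpack(self, z: np.ndarray) -> ParameterSet:
        spec = self.spec
        P = spec.n_predictors
        delta = z[self.sl_delta].copy()
        beta = None
        if self.sl_beta is not None:
            beta = z[self.sl_beta].reshape(self.J, P).copy()
        if spec.family == "cumulative":
            alpha = ordered_from_unconstrained(z[self.sl_alpha])
            return ParameterSet(family="cumulative", delta=delta, alpha=alpha, beta=beta)
        alpha = np.concatenate(([0.0], z[self.sl_alpha]))
        gamma = simplex_from_unconstrained(z[self.sl_gamma])
        return ParameterSet(
            family="stereotype", delta=delta, alpha=alpha, beta=beta,
            gamma=gamma, phi=phi_from_gamma(gamma),
        )


def _make_logp_grad(layout, prior, X, y, pidx, likelihood_scale=1.0):
    spec = layout.spec
    P, C = spec.n_predictors, spec.n_categories
    J = layout.J
    N = len(y)
    yidx = y - 1
    mu = prior.mu
    var = prior.prior_variance
    A = prior.dirichlet_concentration
    scale = float(likelihood_scale)
    het = spec.heterogeneous
    rows = np.arange(N)
    # records whose upper / lower cutpoint is finite (y < C / y > 1)
    iu = np.flatnonzero(yidx <= C - 2)
    il = np.flatnonzero(yidx >= 1)
    yu = yidx[iu]
    yl = yidx[il] - 1

    def logp_grad(z: np.ndarray):
        g = np.zeros_like(z)
        delta = z[layout.sl_delta]
        if het:
            B = z[layout.sl_beta].reshape(J, P)
            eta = np.einsum("np,np->n", X, B[pidx])
        else:
            eta = X @ delta
        lp = 0.0

        if spec.family == "cumulative":
            zalpha = z[layout.sl_alpha]
            alpha = ordered_from_unconstrained(zalpha)
            pad = np.concatenate(([-np.inf], alpha, [np.inf]))
            a = pad[y] - eta
            b = pad[y - 1] - eta
            with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
                la = log_expit(a)
                lna = log_expit(-a)
                lb = log_expit(b)
                lnb = log_expit(-b)
                gap = np.exp(b - a)
                logp_i = la + lnb + np.log1p(-gap)
            if not np.all(np.isfinite(logp_i)):
                return -np.inf, g
            lp += scale * float(logp_i.sum())
            with np.errstate(invalid="ignore"):
                wa = np.exp(la + lna - logp_i)
                wb = np.exp(lb + lnb - logp_i)
            wa[np.isinf(a)] = 0.0
            wb[np.isinf(b)] = 0.0
            g_eta = scale * (wb - wa)
            g_alpha = (
                np.bincount(yu, weights=wa[iu], minlength=C - 1)
                - np.bincount(yl, weights=wb[il], minlength=C - 1)
            )
            g_alpha *= scale
            lp += float(np.sum(_normal_logpdf(alpha, 0.0, var)))
            g_alpha += -alpha / var
            lp += ordered_log_jac(zalpha)
            g[layout.sl_alpha] = ordered_chain_grad(zalpha, g_alpha)
        else:
            alpha_free = z[layout.sl_alpha]
            alpha = np.concatenate(([0.0], alpha_free))
            zgam = z[layout.sl_gamma]
            gamma = simplex_from_unconstrained(zgam)
            phi = np.concatenate(([0.0], np.cumsum(gamma)))
            logits = alpha[None, :] + phi[None, :] * eta[:, None]
            m = logits.max(axis=1)
            E = np.exp(logits - m[:, None])
            S = E.sum(axis=1)
            logp_i = logits[rows, yidx] - m - np.log(S)
            lp += scale * float(logp_i.sum())
            Pm = E / S[:, None]
            diff = -Pm
            diff[rows, yidx] += 1.0
            g_alpha_full = scale * diff.sum(axis=0)
            g_phi = scale * (eta @ diff)
            g_eta = scale * (phi[yidx] - Pm @ phi)
            lp += float(np.sum(_normal_logpdf(alpha_free, 0.0, var)))
            g[layout.sl_alpha] = g_alpha_full[1:] - alpha_free / var
            # phi_c = sum_{k < c} gamma_k  =>  dphi/dgamma is lower-triangular ones
            g_gamma = np.cumsum(g_phi[::-1])[::-1][1:]
            K = C - 1
            lp += float(gammaln(K * A) - K * gammaln(A))
            if A != 1.0:
                lp += float((A - 1.0) * np.sum(np.log(gamma)))
                g_gamma = g_gamma + (A - 1.0) / gamma
            lp += simplex_log_jac(zgam)
            g[layout.sl_gamma] = simplex_chain_grad(zgam, g_gamma)

        if het:
            gB = -(B - delta[None, :]) / var
            W = X * g_eta[:, None]
            for p in range(P):
                gB[:, p] += np.bincount(pidx, weights=W[:, p], minlength=J)
            g[layout.sl_beta] = gB.ravel()
            g_delta = (B - delta[None, :]).sum(axis=0) / var + (mu - delta) / var
            lp += float(np.sum(_normal_logpdf(B, delta[None, :], var)))
        else:
            g_delta = X.T @ g_eta + (mu - delta) / var
        lp += float(np.sum(_normal_logpdf(delta, mu, var)))
        g[layout.sl_delta] = g_delta
        if not np.isfinite(lp):
            return -np.inf, np.zeros_like(z)
        return lp, g

    return logp_grad


def _initial_point(layout, y: np.ndarray, data_informed: bool) -> np.ndarray:
    """Start near the prior mode with cutpoints matched to the outcome marginals."""
    spec = layout.spec
    C = spec.n_categories
    z0 = np.zeros(layout.dim)
    if spec.family == "cumulative":
        if data_informed and len(y) > 0:
            freq = np.bincount(y, minlength=C + 1)[1:]
            cum = np.clip(np.cumsum(freq)[: C - 1] / len(y), 1e-3, 1 - 1e-3)
            al = logit(cum)
            al = np.maximum.accumulate(al) + 1e-3 * np.arange(C - 1)
        else:
            al = np.linspace(-2.0, 2.0, C - 1)
        z0[layout.sl_alpha] = unconstrained_from_ordered(al)
    return z0


@dataclass
class PosteriorSamples:
    """Thinned post-warmup draws from all chains plus per-draw diagnostics.

    ``pointwise_loglik`` is the draws x N matrix of per-record log
    likelihoods on the training data, the raw material for WAIC and DIC.
    ``z`` keeps the unconstrained coordinates of every stored draw so that
    posterior means of constrained parameters can be taken on the
    unconstrained scale (as DIC's plug-in deviance requires).
    """

    spec: ModelSpec
    prior: PriorConfig
    mcmc: MCMCConfig
    z: np.ndarray
    chain_id: np.ndarray
    delta: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray | None
    gamma: np.ndarray | None
    phi: np.ndarray | None
    pointwise_loglik: np.ndarray
    patient_ids: list[str]
    diagnostics: dict

    @property
    def n_draws(self) -> int:
        return self.z.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1 if len(self.chain_id) else 0

    def parameter_set(self, i: int) -> ParameterSet:
        return ParameterSet(
            family=self.spec.family,
            delta=self.delta[i],
            alpha=self.alpha[i],
            beta=None if self.beta is None else self.beta[i],
            gamma=None if self.gamma is None else self.gamma[i],
            phi=None if self.phi is None else self.phi[i],
        )

    def scalar_frame(self) -> pd.DataFrame:
        """One row per draw, one column per scalar parameter."""
        cols: dict[str, np.ndarray] = {}
        for p, name in enumerate(PREDICTORS):
            cols[f"delta[{name}]"] = self.delta[:, p]
        if self.beta is not None:
            for j, pid in enumerate(self.patient_ids):
                for p, name in enumerate(PREDICTORS):
                    cols[f"beta[{pid},{name}]"] = self.beta[:, j, p]
        if self.spec.family == "cumulative":
            for c in range(self.alpha.shape[1]):
                cols[f"alpha[{c + 1}]"] = self.alpha[:, c]
        else:
            # alpha[1] is fixed at 0 for identification; report the free ones
            for c in range(1, self.alpha.shape[1]):
                cols[f"alpha[{c + 1}]"] = self.alpha[:, c]
        if self.gamma is not None:
            for c in range(self.gamma.shape[1]):
                cols[f"gamma[{c + 1}]"] = self.gamma[:, c]
        if self.phi is not None:
            # phi[1]=0 and phi[C]=1 are fixed by construction; report the free ones
            for c in range(1, self.phi.shape[1] - 1):
                cols[f"phi[{c + 1}]"] = self.phi[:, c]
        return pd.DataFrame(cols)

    def to_inference_data(self):
        """Convert to an :class:`arviz.InferenceData` (chain, draw, ...) layout."""
        import arviz as az

        frame = self.scalar_frame()
        n_chains = self.n_chains
        per = self.n_draws // n_chains
        data = {
            c: frame[c].to_numpy().reshape(n_chains, per) for c in frame.columns
        }
        ll = self.pointwise_loglik.reshape(n_chains, per, -1)
        return az.from_dict(posterior=data, log_likelihood={"y": ll})

    def to_csv(self, path) -> None:
        self.scalar_frame().to_csv(path, index=False)


def fit_model(
    spec: ModelSpec,
    prior: PriorConfig,
    dataset: EMADataset,
    mcmc: MCMCConfig | None = None,
    prior_only: bool = False,
) -> PosteriorSamples:
    """Draw from the posterior of one model variant by HMC.

    The dataset must be complete and non-empty. With ``prior_only`` the
    likelihood term is switched off and the sampler targets the prior
    hierarchy exactly (useful for prior predictive checks and calibration).
    """
    mcmc = mcmc or MCMCConfig()
    if dataset is None or dataset.n_obs == 0:
        raise ValueError("fit_model requires a non-empty dataset")
    if spec.n_categories != dataset.n_categories:
        raise ValueError("spec.n_categories does not match the dataset")
    X, y, pidx, patient_ids = dataset.design_arrays()
    layout = _Layout(spec, len(patient_ids))
    logp_grad = _make_logp_grad(
        layout, prior, X, y, pidx, likelihood_scale=0.0 if prior_only else 1.0
    )
    z0 = _initial_point(layout, y, data_informed=not prior_only)

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    all_z, chain_ids = [], []
    diag = {"chains": []}
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        z_init = z0 + 0.1 * rng.standard_normal(layout.dim)
        res = sample_chain(
            logp_grad,
            z_init,
            n_warmup=mcmc.n_warmup,
            n_draws=mcmc.post_warmup_iterations,
            rng=rng,
            max_leapfrog=mcmc.max_leapfrog,
            target_accept=mcmc.target_accept,
        )
        kept = res.draws[mcmc.thin - 1 :: mcmc.thin]
        all_z.append(kept)
        chain_ids.append(np.full(len(kept), c))
        diag["chains"].append(
            {
                "accept_prob": res.accept_prob,
                "divergences": res.divergences,
                "step_size": res.step_size,
            }
        )
        logger.info(
            "%s chain %d: accept=%.2f, step=%.3g, divergences=%d",
            spec.label, c, res.accept_prob, res.step_size, res.divergences,
        )
    diag["divergences"] = int(sum(c["divergences"] for c in diag["chains"]))
    Z = np.vstack(all_z)
    chain_id = np.concatenate(chain_ids)

    D = Z.shape[0]
    P, C = spec.n_predictors, spec.n_categories
    delta = np.empty((D, P))
    beta = np.empty((D, layout.J, P)) if spec.heterogeneous else None
    alpha = np.empty((D, C - 1 if spec.family == "cumulative" else C))
    gamma = np.empty((D, C - 1)) if spec.family == "stereotype" else None
    phi = np.empty((D, C)) if spec.family == "stereotype" else None
    loglik = np.empty((D, len(y)))
    for i in range(D):
        ps = layout.unpack(Z[i])
        delta[i] = ps.delta
        alpha[i] = ps.alpha
        if beta is not None:
            beta[i] = ps.beta
        if gamma is not None:
            gamma[i] = ps.gamma
            phi[i] = ps.phi
        loglik[i] = _pointwise(spec, ps, X, y, pidx)
    if not np.all(np.isfinite(loglik)):
        raise RuntimeError("non-finite pointwise log-likelihood in stored draws")

    return PosteriorSamples(
        spec=spec, prior=prior, mcmc=mcmc,
        z=Z, chain_id=chain_id,
        delta=delta, alpha=alpha, beta=beta, gamma=gamma, phi=phi,
        pointwise_loglik=loglik, patient_ids=list(patient_ids), diagnostics=diag,
    )


def _pointwise(spec, params: ParameterSet, X, y, pidx) -> np.ndarray:
    if spec.heterogeneous:
        eta = np.einsum("np,np->n", X, params.beta[pidx])
    else:
        eta = X @ params.delta
    if spec.family == "cumulative":
        return cumulative_log_probs(eta, params.alpha, y)
    return stereotype_log_probs(eta, params.alpha, params.phi, y)


# ---------------------------------------------------------------------------
# Summaries and diagnostics
# ---------------------------------------------------------------------------


def summarize_parameters(
    samples: PosteriorSamples, interval: float = 0.95, method: str = "eti"
) -> pd.DataFrame:
    """Per-parameter median, lower/upper credible bounds, significance flag.

    ``method='eti'`` (default) uses equal-tailed quantiles, e.g. the
    2.5%/97.5% bounds for a 95% interval; ``method='hdi'`` uses the
    highest-density interval. A parameter is flagged significant when its
    interval excludes zero.
    """
    if samples.n_draws < 2:
        raise ValueError("summaries require at least 2 draws")
    if not 0 < interval < 1:
        raise ValueError("interval must be in (0, 1)")
    frame = samples.scalar_frame()
    lo_q = (1 - interval) / 2
    if method == "eti":
        lower = frame.quantile(lo_q)
        upper = frame.quantile(1 - lo_q)
    elif method == "hdi":
        import arviz as az

        bounds = {c: az.hdi(frame[c].to_numpy(), hdi_prob=interval) for c in frame.columns}
        lower = pd.Series({c: b[0] for c, b in bounds.items()})
        upper = pd.Series({c: b[1] for c, b in bounds.items()})
    else:
        raise ValueError("method must be 'eti' or 'hdi'")
    out = pd.DataFrame(
        {
            "median": frame.median(),
            "lower": lower,
            "upper": upper,
        }
    )
    out["significant"] = (out["lower"] > 0) | (out["upper"] < 0)
    return out


def convergence_diagnostics(samples: PosteriorSamples, rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Rank-normalized split R-hat and effective sample size per parameter.

    Returns one row per scalar parameter with columns ``rhat``, ``ess_bulk``
    and ``flagged`` (R-hat above threshold). With a single chain R-hat is
    not defined across chains; a warning is issued and split statistics
    within the chain are used by arviz where possible.
    """
    import arviz as az

    if samples.n_draws < samples.n_chains * 4:
        raise ValueError("diagnostics require at least 4 draws per chain")
    if samples.n_chains < 2:
        warnings.warn(
            "convergence diagnostics with a single chain: between-chain R-hat "
            "unavailable; interpret with care",
            UserWarning,
            stacklevel=2,
        )
    idata = samples.to_inference_data()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = {}
    for name in rhat.data_vars:
        rows[name] = {
            "rhat": float(rhat[name].values),
            "ess_bulk": float(ess[name].values),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["flagged"] = out["rhat"] > rhat_threshold
    return out


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


class OrdinalEMAModel:
    """A Bayesian ordinal diary model bound to a complete EMA dataset.

    Parameters
    ----------
    dataset
        Complete :class:`EMADataset` (apply ``filter_complete`` first).
    family
        ``"cumulative"`` (proportional-odds) or ``"stereotype"``.
    heterogeneous
        Add patient-specific slope vectors partially pooled around the
        population slopes.
    prior
        :class:`PriorConfig`; defaults to the weak +/-1-mean, variance-100
        hierarchy.

    Examples
    --------
    >>> model = OrdinalEMAModel(dataset, family="stereotype", heterogeneous=True)
    >>> results = model.fit(MCMCConfig.desk(seed=7))
    >>> results.summary().loc["delta[mood]"]
    """

    def __init__(
        self,
        dataset: EMADataset,
        family: str = "cumulative",
        heterogeneous: bool = False,
        prior: PriorConfig | None = None,
    ):
        if dataset.n_obs == 0:
            raise ValueError("cannot build a model from an empty dataset")
        if not dataset.is_complete():
            raise ValueError("dataset has missing scores; apply filter_complete first")
        self.dataset = dataset
        self.spec = ModelSpec(
            family=family,
            heterogeneous=heterogeneous,
            n_categories=dataset.n_categories,
        )
        self.prior = prior or PriorConfig()

    @classmethod
    def from_csv(cls, path, **kwargs) -> "OrdinalEMAModel":
        from .data import filter_complete, load_ema_csv

        return cls(filter_complete(load_ema_csv(path)), **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, n_categories: int = 10, **kwargs) -> "OrdinalEMAModel":
        from .data import filter_complete

        return cls(filter_complete(EMADataset(frame, n_categories=n_categories)), **kwargs)

    def fit(self, mcmc: MCMCConfig | None = None, prior_only: bool = False) -> "OrdinalEMAResults":
        samples = fit_model(self.spec, self.prior, self.dataset, mcmc, prior_only=prior_only)
        return OrdinalEMAResults(self, samples)


class OrdinalEMAResults:
    """Posterior draws plus the quantities the analysis reports.

    Thin object-oriented layer over the functional API: parameter summary
    table, convergence diagnostics, WAIC/DIC, posterior predictions for new
    diary rows and the per-patient slope figure.
    """

    def __init__(self, model: OrdinalEMAModel, samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    def summary(self, interval: float = 0.95, method: str = "eti") -> pd.DataFrame:
        return summarize_parameters(self.samples, interval=interval, method=method)

    def diagnostics(self) -> pd.DataFrame:
        return convergence_diagnostics(self.samples)

    def waic(self) -> float:
        from .evaluate import waic

        return waic(self.samples.pointwise_loglik)

    def dic(self) -> float:
        from .evaluate import dic

        return dic(self.samples, self.model.dataset)

    def predict(self, dataset: EMADataset | None = None):
        from .evaluate import posterior_predictive

        return posterior_predictive(self.samples, dataset or self.model.dataset)

    def plot_patient_slopes(self, path):
        from .plots import plot_patient_slopes

        return plot_patient_slopes(self.samples, path)

    def to_inference_data(self):
        return self.samples.to_inference_data()
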