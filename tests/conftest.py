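import numpy as np
import pandas as pd
import pytest

from emaord.data import EMADataset, OUTCOME, PREDICTORS
from emaord.likelihood import ModelSpec, PriorConfig, phi_from_gamma
from emaord.model import MCMCConfig, PosteriorSamples, fit_model
from emaord.simulate import CohortDesign, make_cohort


def make_frame(rows):
    """Build a diary DataFrame from (patient_id, time_index, m, w, s, e, c, y) tuples;
    None marks a missing score."""
    cols = ["patient_id", "time_index", *PREDICTORS, OUTCOME]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def toy_frame():
    return make_frame(
        [
            ("A", 0, 5, 3, 6, 7, 4, 6),
            ("A", 1, 6, 2, 5, 8, 5, 7),
            ("B", 0, 2, 8, 3, 2, 1, 2),
        ]
    )


#: Reduced sampler settings for unit tests (well within mixing needs of the
#: tiny fixtures below).
MICRO_MCMC = dict(chains=2, total_iterations=600, post_warmup_iterations=300, thin=1)


@pytest.fixture(scope="session")
def hom_cum_fit():
    """Homogeneous cumulative fit on a small zero-heterogeneity cohort."""
    design = CohortDesign(n_patients=12, obs_per_patient=10, seed=101)
    dataset, truth = make_cohort(design, family="cumulative", heterogeneity_sd=0.0, seed=101)
    spec = ModelSpec(family="cumulative", heterogeneous=False)
    samples = fit_model(spec, PriorConfig(), dataset, MCMCConfig(seed=7, **MICRO_MCMC))
    return dataset, truth, samples


@pytest.fixture(scope="session")
def het_stereo_fit():
    """Heterogeneous stereotype fit on a small heterogeneous cohort."""
    design = CohortDesign(n_patients=8, obs_per_patient=8, seed=202)
    dataset, truth = make_cohort(design, family="stereotype", heterogeneity_sd=1.0, seed=202)
    spec = ModelSpec(family="stereotype", heterogeneous=True)
    samples = fit_model(spec, PriorConfig(), dataset, MCMCConfig(seed=8, **MICRO_MCMC))
    return dataset, truth, samples


def build_samples(spec, delta, alpha, beta=None, gamma=None, loglik=None, patient_ids=None):
    """Hand-assemble a PosteriorSamples object from raw draw arrays."""
    delta = np.asarray(delta, dtype=float)
    D = delta.shape[0]
    phi = None
    if gamma is not None:
        gamma = np.asarray(gamma, dtype=float)
        phi = np.stack([phi_from_gamma(g) for g in gamma])
    if loglik is None:
        loglik = np.zeros((D, 1))
    return PosteriorSamples(
        spec=spec,
        prior=PriorConfig(),
        mcmc=MCMCConfig(seed=0, **MICRO_MCMC),
        z=np.zeros((D, 1)),
        chain_id=np.zeros(D, dtype=int),
        delta=delta,
        alpha=np.asarray(alpha, dtype=float),
        beta=None if beta is None else np.asarray(beta, dtype=float),
        gamma=gamma,
        phi=phi,
        pointwise_loglik=np.asarray(loglik, dtype=float),
        patient_ids=patient_ids or ["P1"],
        diagnostics={"chains": [], "divergences": 0},
    )
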