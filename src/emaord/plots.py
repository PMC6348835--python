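"""Figure analogues: predicted-vs-observed and per-patient slope distributions."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .data import PREDICTORS
from .model import PosteriorSamples


def plot_predictions(observed, predicted, path) -> None:
    """Observed self-esteem (sorted ascending, drawn as a line) with paired
    predictions as crosses.

    The sort is stable, so records with equal observed values keep their
    original relative order.
    """
    observed = np.asarray(observed)
    predicted = np.asarray(predicted)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    order = np.argsort(observed, kind="stable")
    fig, ax = plt.subplots(figsize=(8, 4))
    xs = np.arange(len(observed))
    ax.plot(xs, observed[order], color="black", lw=1.2, label="observed")
    ax.plot(xs, predicted[order], "x", color="tab:red", ms=4, alpha=0.6, label="predicted")
    ax.set_xlabel("test records (sorted by observed self-esteem)")
    ax.set_ylabel("self-esteem score")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_patient_slopes(samples: PosteriorSamples, path) -> None:
    """Per-predictor panels of patient-level slope posteriors.

    Each panel shows, per patient, the posterior median and 95% interval of
    that patient's slope, patients sorted by posterior mean *within the
    panel* (so positions are not comparable across predictors), with a zero
    reference line. Requires a heterogeneous fit.
    """
    if samples.beta is None:
        raise ValueError(
            "per-patient slope plot requires a heterogeneous model fit; "
            "homogeneous fits carry no patient-level slopes"
        )
    n_pred = len(PREDICTORS)
    fig, axes = plt.subplots(n_pred, 1, figsize=(9, 2.2 * n_pred), sharex=True)
    for p, (name, ax) in enumerate(zip(PREDICTORS, np.atleast_1d(axes))):
        draws = samples.beta[:, :, p]  # draws x J
        means = draws.mean(axis=0)
        order = np.argsort(means)
        med = np.median(draws, axis=0)[order]
        lo = np.quantile(draws, 0.025, axis=0)[order]
        hi = np.quantile(draws, 0.975, axis=0)[order]
        xs = np.arange(len(means))
        ax.vlines(xs, lo, hi, color="tab:blue", alpha=0.5, lw=1)
        ax.plot(xs, med, ".", color="tab:blue", ms=3)
        ax.axhline(0.0, color="black", lw=0.8)
        ax.set_ylabel(name, fontsize=8)
    np.atleast_1d(axes)[-1].set_xlabel("patients (sorted by posterior mean within panel)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
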