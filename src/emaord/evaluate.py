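"""Patient-stratified cross-validation and the model-comparison measure suite.

Prediction quality is scored by RMSE and MAE of point predictions pooled
over the folds of a patient-stratified k-fold split (every patient with at
least k diary days contributes observations to every fold, so each test
fold contains only patients the model has already seen). Model fit and
complexity are scored by DIC and WAIC on a full-data fit. Two baselines
anchor the comparison: the *mean model* (global training mean of the
outcome) and the *mean individual model* (per-patient training mean).
Paired differences in absolute error are tested with the two-sided Wilcoxon
signed-rank test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import wilcoxon

from .data import EMADataset, OUTCOME
from .likelihood import ModelSpec, PriorConfig
from .model import MCMCConfig, PosteriorSamples, fit_model, _pointwise

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    """Fold labels (0..k-1) per record of a dataset."""

    labels: np.ndarray
    k: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if set(np.unique(self.labels)) - set(range(self.k)):
            raise ValueError("fold labels must lie in 0..k-1")

    def test_mask(self, fold: int) -> np.ndarray:
        return self.labels == fold


def stratified_folds(dataset: EMADataset, k: int, rng: np.random.Generator) -> FoldAssignment:
    """Patient-stratified k-fold assignment.

    Within each patient the observations are shuffled and dealt round-robin
    (from a random starting fold) across the k folds, so per-patient counts
    differ by at most one between folds and every patient with >= k
    observations appears in all k folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > dataset.n_obs:
        raise ValueError(f"k={k} exceeds the number of observations ({dataset.n_obs})")
    labels = np.empty(dataset.n_obs, dtype=int)
    pid = dataset.frame["patient_id"].to_numpy()
    for patient in dataset.patient_ids:
        idx = np.flatnonzero(pid == patient)
        order = rng.permutation(len(idx))
        start = int(rng.integers(k))
        labels[idx[order]] = (start + np.arange(len(idx))) % k
    return FoldAssignment(labels=labels, k=k)


# ---------------------------------------------------------------------------
# Posterior prediction
# ---------------------------------------------------------------------------


@dataclass
class PredictiveDistribution:
    """Draw-averaged category probabilities per test record."""

    probs: np.ndarray  # N x C, rows sum to 1
    n_categories: int

    def point(self, rule: str = "median") -> np.ndarray:
        return point_predictions(self, rule=rule)


def posterior_predictive(samples: PosteriorSamples, test: EMADataset) -> PredictiveDistribution:
    """Posterior predictive category probabilities for the test records.

    Per record the category probabilities are averaged over all stored
    draws, using the patient's own slope draws under a heterogeneous model.
    Patients unseen in training fall back to the population slopes
    ``delta`` — the stated strategy for brand-new patients, for whom no
    individual parameters exist yet.
    """
    from .likelihood import cumulative_log_probs, stereotype_log_probs  # noqa: F401

    spec = samples.spec
    X, _, _, _ = test.design_arrays()
    C = spec.n_categories
    N = X.shape[0]
    train_code = {p: i for i, p in enumerate(samples.patient_ids)}
    test_pids = test.frame["patient_id"].to_numpy()
    row_code = np.array([train_code.get(p, -1) for p in test_pids])
    n_new = int((row_code < 0).sum())
    if n_new and spec.heterogeneous:
        logger.info(
            "posterior_predictive: %d records from unseen patients use the "
            "population slopes delta", n_new,
        )
    D = samples.n_draws
    acc = np.zeros((N, C))
    seen = row_code >= 0
    for d in range(D):
        if spec.heterogeneous:
            eta = np.empty(N)
            slopes = samples.beta[d]
            eta[seen] = np.einsum("np,np->n", X[seen], slopes[row_code[seen]])
            eta[~seen] = X[~seen] @ samples.delta[d]
        else:
            eta = X @ samples.delta[d]
        if spec.family == "cumulative":
            from scipy.special import expit

            cdf = np.concatenate(
                (np.zeros((N, 1)), expit(samples.alpha[d][None, :] - eta[:, None]), np.ones((N, 1))),
                axis=1,
            )
            acc += np.diff(cdf, axis=1)
        else:
            logits = samples.alpha[d][None, :] + samples.phi[d][None, :] * eta[:, None]
            acc += np.exp(logits - logsumexp(logits, axis=1, keepdims=True))
    probs = acc / D
    return PredictiveDistribution(probs=probs, n_categories=C)


def point_predictions(pred: PredictiveDistribution, rule: str = "median") -> np.ndarray:
    """Reduce predictive simplexes to integer categories.

    ``median``: smallest category whose cumulative probability reaches 0.5
    (the optimal point prediction under absolute error). ``mode``: highest-
    probability category, ties broken toward the lower category.
    """
    p = pred.probs
    if rule == "median":
        return 1 + (np.cumsum(p, axis=1) < 0.5).sum(axis=1)
    if rule == "mode":
        return 1 + np.argmax(p, axis=1)
    raise ValueError("rule must be 'median' or 'mode'")


def sample_predictions(
    pred: PredictiveDistribution, rng: np.random.Generator
) -> np.ndarray:
    """Draw one category per record from its predictive distribution."""
    u = rng.uniform(size=pred.probs.shape[0])
    return 1 + (u[:, None] > np.cumsum(pred.probs, axis=1)[:, :-1]).sum(axis=1)


# ---------------------------------------------------------------------------
# Error metrics and information criteria
# ---------------------------------------------------------------------------


def error_metrics(observed, predicted) -> tuple[float, float]:
    """(RMSE, MAE) of predictions against observed outcomes."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if observed.size == 0:
        raise ValueError("error metrics require at least one record")
    err = predicted - observed
    return float(np.sqrt(np.mean(err**2))), float(np.mean(np.abs(err)))


def dic_from_deviances(deviance_draws, deviance_at_mean: float) -> float:
    """DIC from per-draw deviances and the plug-in deviance.

    ``p_D = mean(D) - D(theta_bar)``; ``DIC = mean(D) + p_D``.
    """
    deviance_draws = np.asarray(deviance_draws, dtype=float)
    if deviance_draws.size < 1 or not np.all(np.isfinite(deviance_draws)):
        raise RuntimeError("DIC requires finite deviance draws")
    d_bar = float(np.mean(deviance_draws))
    p_d = d_bar - float(deviance_at_mean)
    return d_bar + p_d


def dic(samples: PosteriorSamples, dataset: EMADataset) -> float:
    """Deviance information criterion of a fit.

    The plug-in deviance is evaluated at the posterior mean taken on the
    unconstrained scale and transformed back, which respects the ordered
    cutpoint and simplex constraints.
    """
    from .model import _Layout

    if samples.n_draws < 2:
        raise ValueError("DIC requires at least 2 draws")
    X, y, pidx, _ = dataset.design_arrays()
    dev_draws = -2.0 * samples.pointwise_loglik.sum(axis=1)
    layout = _Layout(samples.spec, len(samples.patient_ids))
    z_bar = samples.z.mean(axis=0)
    params_bar = layout.unpack(z_bar)
    dev_at_mean = -2.0 * float(_pointwise(samples.spec, params_bar, X, y, pidx).sum())
    if not np.isfinite(dev_at_mean):
        raise RuntimeError("non-finite plug-in deviance")
    return dic_from_deviances(dev_draws, dev_at_mean)


def waic(pointwise_loglik: np.ndarray) -> float:
    """Widely applicable information criterion from a draws x N log-lik matrix.

    ``lppd = sum_i log mean_d exp(loglik_di)`` (computed with logsumexp);
    ``p_waic = sum_i var_d(loglik_di)``; ``WAIC = -2 (lppd - p_waic)``.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 1 or ll.shape[1] < 1:
        raise ValueError("pointwise_loglik must be a draws x N matrix")
    if not np.all(np.isfinite(ll)):
        raise RuntimeError("WAIC requires finite log-likelihood entries")
    D = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(D)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1))) if D > 1 else 0.0
    return -2.0 * (lppd - p_waic)


# ---------------------------------------------------------------------------
# Baselines and error comparison
# ---------------------------------------------------------------------------


def mean_baselines(train: EMADataset, test: EMADataset) -> tuple[np.ndarray, np.ndarray]:
    """(mean-model, mean-individual-model) predictions for the test records.

    The mean model predicts the global training mean of the outcome for
    every test record; the mean individual model predicts each patient's own
    training mean. Test patients absent from training fall back to the
    global mean (logged). Predictions are real-valued arithmetic means, not
    rounded.
    """
    if train.n_obs == 0:
        raise ValueError("mean baselines require a non-empty training set")
    y_train = train.frame[OUTCOME].to_numpy(dtype=float)
    global_mean = float(np.mean(y_train))
    per_patient = train.frame.groupby("patient_id", sort=False)[OUTCOME].mean()
    test_pids = test.frame["patient_id"].to_numpy()
    unseen = [p for p in dict.fromkeys(test_pids) if p not in per_patient.index]
    if unseen:
        logger.warning(
            "mean_baselines: %d test patient(s) absent from training use the "
            "global mean", len(unseen),
        )
    indiv = np.array([float(per_patient.get(p, global_mean)) for p in test_pids])
    return np.full(len(test_pids), global_mean), indiv


def compare_errors_wilcoxon(abs_errors_a, abs_errors_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired absolute errors.

    Zero differences are dropped (Wilcoxon's original treatment); if every
    pair is tied the test is degenerate and ``p = 1.0`` is returned by
    convention. The statistic is the signed-rank sum of the a-minus-b
    differences.
    """
    a = np.asarray(abs_errors_a, dtype=float)
    b = np.asarray(abs_errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("error vectors must have equal length")
    diff = a - b
    if np.all(diff == 0):
        return 0.0, 1.0
    res = wilcoxon(diff, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Cross-validation driver and report
# ---------------------------------------------------------------------------

BASELINE_MEAN = "mean_model"
BASELINE_INDIVIDUAL = "mean_individual_model"


@dataclass
class EvaluationReport:
    """Model-comparison table plus paired error tests.

    ``models`` maps a model label to its RMSE/MAE/DIC/WAIC; ``baselines``
    carries RMSE/MAE for the two mean baselines (no likelihood, so no
    DIC/WAIC); ``wilcoxon`` maps ``"a|b"`` pairs to two-sided p-values on
    the paired absolute errors. ``abs_errors`` retains the pooled per-record
    absolute error vectors for further testing.
    """

    models: dict[str, dict[str, float]] = field(default_factory=dict)
    baselines: dict[str, dict[str, float]] = field(default_factory=dict)
    wilcoxon: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    abs_errors: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def validate(self) -> None:
        for name, row in {**self.models, **self.baselines}.items():
            if not (row["rmse"] >= row["mae"] >= 0):
                raise ValueError(f"metrics for {name!r} violate RMSE >= MAE >= 0")

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for name, m in self.models.items():
            rows[name] = {
                "RMSE": m["rmse"], "MAE": m["mae"], "DIC": m["dic"], "WAIC": m["waic"],
            }
        for name, m in self.baselines.items():
            rows[name] = {"RMSE": m["rmse"], "MAE": m["mae"], "DIC": np.nan, "WAIC": np.nan}
        return pd.DataFrame.from_dict(rows, orient="index")

    def to_markdown(self) -> str:
        """Model-comparison table with '-' for the baselines' DIC/WAIC."""
        frame = self.to_frame()
        lines = ["| Model | RMSE | MAE | DIC | WAIC |", "| --- | --- | --- | --- | --- |"]
        for name, row in frame.iterrows():
            cells = [
                f"{row['RMSE']:.2f}", f"{row['MAE']:.2f}",
                "-" if np.isnan(row["DIC"]) else f"{row['DIC']:.2f}",
                "-" if np.isnan(row["WAIC"]) else f"{row['WAIC']:.2f}",
            ]
            lines.append("| " + " | ".join([name] + cells) + " |")
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "models": self.models,
            "baselines": self.baselines,
            "wilcoxon": self.wilcoxon,
            "config": self.config,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        d = json.loads(text)
        return cls(
            models=d["models"], baselines=d["baselines"],
            wilcoxon=d["wilcoxon"], config=d.get("config", {}),
        )

    def merge(self, other: "EvaluationReport") -> "EvaluationReport":
        out = EvaluationReport(
            models={**self.models, **other.models},
            baselines={**self.baselines, **other.baselines},
            wilcoxon={**self.wilcoxon, **other.wilcoxon},
            config=self.config or other.config,
            abs_errors={**self.abs_errors, **other.abs_errors},
        )
        return out


def cross_validate(
    spec: ModelSpec,
    prior: PriorConfig,
    dataset: EMADataset,
    k: int = 10,
    mcmc: MCMCConfig | None = None,
    rng: np.random.Generator | None = None,
    folds: FoldAssignment | None = None,
    point_rule: str = "median",
    information_criteria: bool = True,
) -> EvaluationReport:
    """Patient-stratified k-fold CV of one model variant, with baselines.

    The model is refit on each training split and its point predictions
    pooled over the k test folds before RMSE/MAE are computed; DIC and WAIC
    come from one fit on the full dataset. Baseline predictions use the
    same splits. The fold RNG is separate from the MCMC seed (recorded in
    ``config``) so splits and chains are independently reproducible.
    """
    mcmc = mcmc or MCMCConfig()
    rng = rng or np.random.default_rng(0)
    folds = folds or stratified_folds(dataset, k, rng)
    y_all = dataset.frame[OUTCOME].to_numpy(dtype=float)
    N = dataset.n_obs
    pred_model = np.full(N, np.nan)
    pred_mean = np.full(N, np.nan)
    pred_indiv = np.full(N, np.nan)
    for fold in range(folds.k):
        test_mask = folds.test_mask(fold)
        train = dataset.subset(~test_mask)
        test = dataset.subset(test_mask)
        logger.info(
            "%s: fold %d/%d (train %d, test %d)",
            spec.label, fold + 1, folds.k, train.n_obs, test.n_obs,
        )
        samples = fit_model(spec, prior, train, mcmc)
        pred = posterior_predictive(samples, test)
        pred_model[test_mask] = point_predictions(pred, rule=point_rule)
        m, i = mean_baselines(train, test)
        pred_mean[test_mask] = m
        pred_indiv[test_mask] = i
    assert not np.any(np.isnan(pred_model))

    rmse, mae = error_metrics(y_all, pred_model)
    row = {"rmse": rmse, "mae": mae, "dic": np.nan, "waic": np.nan}
    if information_criteria:
        full = fit_model(spec, prior, dataset, mcmc)
        row["dic"] = dic(full, dataset)
        row["waic"] = waic(full.pointwise_loglik)
    report = EvaluationReport(config={
        "k": folds.k, "mcmc_seed": mcmc.seed, "point_rule": point_rule,
        "n_obs": N, "n_patients": dataset.n_patients,
    })
    report.models[spec.label] = row
    abs_model = np.abs(pred_model - y_all)
    report.abs_errors[spec.label] = abs_model
    for name, preds in ((BASELINE_MEAN, pred_mean), (BASELINE_INDIVIDUAL, pred_indiv)):
        b_rmse, b_mae = error_metrics(y_all, preds)
        report.baselines[name] = {"rmse": b_rmse, "mae": b_mae}
        abs_b = np.abs(preds - y_all)
        report.abs_errors[name] = abs_b
        _, p = compare_errors_wilcoxon(abs_model, abs_b)
        report.wilcoxon[f"{spec.label}|{name}"] = p
    report.validate()
    return report


def evaluate_models(
    specs: list[ModelSpec],
    prior: PriorConfig,
    dataset: EMADataset,
    k: int = 10,
    mcmc: MCMCConfig | None = None,
    rng: np.random.Generator | None = None,
    point_rule: str = "median",
) -> EvaluationReport:
    """Cross-validate several model variants on shared folds and merge reports.

    Adds Wilcoxon p-values for every model-model and model-baseline pair of
    pooled absolute-error vectors (the errors are paired record by record
    because all models share the same fold assignment).
    """
    rng = rng or np.random.default_rng(0)
    folds = stratified_folds(dataset, k, rng)
    report = EvaluationReport()
    for spec in specs:
        part = cross_validate(
            spec, prior, dataset, k=k, mcmc=mcmc, folds=folds, point_rule=point_rule,
        )
        report = report.merge(part)
    labels = [s.label for s in specs]
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            _, p = compare_errors_wilcoxon(report.abs_errors[a], report.abs_errors[b])
            report.wilcoxon[f"{a}|{b}"] = p
    report.validate()
    return report
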