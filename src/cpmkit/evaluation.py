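"""Model-performance metrics dispatched by model type.

Continuous models are scored with Pearson r and mean squared error, binary
classifiers with the ROC AUC (Mann–Whitney formulation on predicted
probabilities), categorical classifiers with a macro-averaged one-vs-rest AUC,
and survival models with Harrell's concordance index on linear predictors.
All AUC-type metrics count ties as ½.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pearson_r",
    "mse",
    "auc_binary",
    "auc_multinomial_ovr",
    "c_index",
    "AssessmentReport",
    "assess",
]


def pearson_r(pred: np.ndarray, actual: np.ndarray) -> float:
    """Pearson correlation between predictions and observations.

    A constant vector makes r undefined; NaN is returned with a warning.
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.ndim != 1:
        raise ValueError("pred and actual must be equal-length vectors")
    if len(pred) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(pred) == 0 or np.ptp(actual) == 0:
        warnings.warn("constant vector: Pearson r is undefined, reporting NaN")
        return float("nan")
    pc = pred - pred.mean()
    ac = actual - actual.mean()
    return float((pc @ ac) / np.sqrt((pc @ pc) * (ac @ ac)))


def mse(pred: np.ndarray, actual: np.ndarray) -> float:
    """Mean squared error."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.ndim != 1:
        raise ValueError("pred and actual must be equal-length vectors")
    return float(np.mean((pred - actual) ** 2))


def auc_binary(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the rank (Mann–Whitney) formulation.

    AUC = P(score⁺ > score⁻) + ½·P(tie), which equals the trapezoidal area
    under the ROC curve. ``labels`` must contain both classes (0/1 coding or
    booleans).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_multinomial_ovr(prob_matrix: np.ndarray, labels: np.ndarray) -> float:
    """Macro-averaged one-vs-rest AUC for ≥3-class outcomes.

    For each class c the binary AUC of P(class = c) against the indicator
    label == c is computed; classes absent from ``labels`` are skipped with a
    warning; the unweighted mean over the remaining classes is returned.
    """
    P = np.asarray(prob_matrix, dtype=float)
    labels = np.asarray(labels).astype(int)
    if P.ndim != 2 or P.shape[0] != len(labels):
        raise ValueError("prob_matrix must be n × L aligned with labels")
    if P.shape[1] < 3:
        raise ValueError("multinomial AUC needs ≥3 classes")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    aucs = []
    for c in range(P.shape[1]):
        indicator = (labels == c).astype(int)
        if indicator.sum() == 0:
            warnings.warn(f"class {c} absent from labels; skipped in OVR AUC")
            continue
        if indicator.sum() == len(labels):
            warnings.warn(f"class {c} is the only class present; skipped in OVR AUC")
            continue
        aucs.append(auc_binary(P[:, c], indicator))
    if not aucs:
        raise ValueError("no class admits a one-vs-rest AUC")
    return float(np.mean(aucs))


def c_index(linear_predictor: np.ndarray, time: np.ndarray, status: np.ndarray) -> float:
    """Harrell's concordance index for right-censored data.

    Permissible pairs are (i, j) with time_i < time_j and status_i = 1 (the
    earlier subject's event was observed). A pair is concordant when the
    earlier-event subject has the higher predicted risk; ties in the predictor
    count ½. Invariant to strictly monotone transforms of the predictor.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    time = np.asarray(time, dtype=float)
    status = np.asarray(status).astype(int)
    earlier_event = (time[:, None] < time[None, :]) & (status[:, None] == 1)
    n_perm = int(earlier_event.sum())
    if n_perm == 0:
        raise ValueError("no permissible pairs; C-index undefined")
    higher = lp[:, None] > lp[None, :]
    tied = lp[:, None] == lp[None, :]
    concordant = (earlier_event & higher).sum() + 0.5 * (earlier_event & tied).sum()
    return float(concordant / n_perm)


@dataclass(frozen=True)
class AssessmentReport:
    """Pooled held-out metrics per prediction stream, plus per-fold values."""

    model: str
    metrics: dict[str, dict[str, float]]
    per_fold: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stream": stream, "metric": name, "value": value}
            for stream, d in self.metrics.items()
            for name, value in d.items()
        ]
        return pd.DataFrame(rows)


def _stream_metrics(model: str, pred, actual) -> dict[str, float]:
    if model == "linear":
        return {"r": pearson_r(pred, actual), "MSE": mse(pred, actual)}
    if model == "logistic":
        return {"AUC": auc_binary(pred, actual)}
    if model == "multinom":
        return {"AUC": auc_multinomial_ovr(pred, actual)}
    if model == "cox":
        time, status = actual
        return {"cindex": c_index(pred, time, status)}
    raise ValueError(f"unknown model type {model!r}")


def assess(run_result) -> AssessmentReport:
    """Score a pipeline :class:`~cpmkit.pipeline.RunResult`.

    The primary report is computed on the pooled held-out predictions (every
    subject predicted exactly once across folds); per-fold metric
    distributions are also returned, with folds too small or too degenerate
    for a metric reported as NaN.
    """
    model = run_result.config.model
    if model == "cox":
        actual = (run_result.actual_time, run_result.actual_status)
    else:
        actual = run_result.actuals
    metrics = {}
    for stream, pred in run_result.predictions.items():
        try:
            metrics[stream] = _stream_metrics(model, pred, actual)
        except ValueError as exc:
            warnings.warn(f"stream {stream!r}: {exc}")
            metrics[stream] = {}

    rows = []
    for fold_id in sorted(set(run_result.fold_of_subject)):
        mask = run_result.fold_of_subject == fold_id
        for stream, pred in run_result.predictions.items():
            if model == "cox":
                fold_actual = (run_result.actual_time[mask], run_result.actual_status[mask])
            else:
                fold_actual = run_result.actuals[mask]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    vals = _stream_metrics(model, pred[mask], fold_actual)
            except ValueError:
                vals = {}
            for name, value in vals.items():
                rows.append({"fold": fold_id, "stream": stream, "metric": name, "value": value})
    per_fold = pd.DataFrame(rows, columns=["fold", "stream", "metric", "value"])
    return AssessmentReport(model=model, metrics=metrics, per_fold=per_fold)
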