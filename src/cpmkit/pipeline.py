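"""End-to-end orchestration of the two pipeline arms.

For every cross-validation fold, marginal screening runs on the training
subjects only (no leakage), the design is built per arm — scalar summary
predictors in the original arm, the full selected-edge block in the penalized
arm — the model is fitted on the training fold, and the held-out subjects are
predicted. With ``edge="separate"`` the positive-set and negative-set models
are fitted independently and reported as two prediction streams;
``edge="combined"`` fits one model on the union. Folds whose selected edge set
comes up empty fall back to a covariate-only model (flagged, not fatal).
External validation refits once on all training subjects and predicts a
held-out cohort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConnectomeStack, CovariateTable, EdgeIndex, Outcome, vectorize_upper_triangle
from .design import DesignMatrix, assemble_design, build_summary_predictors
from .glm import FamilySpec, fit_glm, predict_glm
from .cox import fit_cox, predict_cox_linear_predictor
from .penalized import PenaltySpec, fit_penalized, predict_penalized, select_lambda
from .screening import (
    ScreeningResult,
    encode_outcome_for_screening,
    screen_edges_correlation,
    screen_edges_cox,
)

__all__ = ["RunConfig", "RunResult", "assign_folds", "run_cpm", "external_validate", "write_run_result"]

_MODEL_FAMILY = {
    "linear": "continuous",
    "logistic": "binary",
    "multinom": "categorical",
    "cox": "survival",
}
_FAMILY_MODEL = {v: k for k, v in _MODEL_FAMILY.items()}


@dataclass(frozen=True)
class RunConfig:
    """Run parameters with the documented defaults.

    Defaults: leave-one-out CV, Pearson screening at p < 0.01, separate
    positive/negative models, lasso penalty with α = 0.95 (α weights the
    squared-L2 term; see :mod:`cpmkit.penalized`), seed 1220, consensus
    fold threshold 0.5.
    """

    arm: str = "original"
    model: str | None = None
    cv: str = "loocv"
    k: int | None = None
    correlation: str = "pearson"
    thresh: float = 0.01
    edge: str = "separate"
    type: str = "lasso"
    alpha: float = 0.95
    lambda_: object = "auto"
    seed: int = 1220
    fold_threshold: float = 0.5
    inner_folds: int = 10
    stratify: bool = True

    def __post_init__(self) -> None:
        if self.arm not in ("original", "penalized"):
            raise ValueError(f"arm must be 'original' or 'penalized', got {self.arm!r}")
        if self.cv not in ("loocv", "k-fold", "kfold"):
            raise ValueError(f"cv must be 'loocv' or 'k-fold', got {self.cv!r}")
        if not 0 < self.thresh <= 1:
            raise ValueError(f"thresh must be in (0, 1], got {self.thresh}")
        if self.edge not in ("separate", "combined"):
            raise ValueError(f"edge must be 'separate' or 'combined', got {self.edge!r}")
        if self.model is not None and self.model not in _MODEL_FAMILY:
            raise ValueError(f"model must be one of {sorted(_MODEL_FAMILY)}, got {self.model!r}")

    def penalty(self) -> PenaltySpec:
        return PenaltySpec(type=self.type, alpha=self.alpha, lambda_=self.lambda_)


@dataclass(frozen=True)
class FoldRecord:
    """Per-fold, per-stream bookkeeping for reporting and consensus."""

    fold: int
    stream: str
    positive_edges: np.ndarray
    negative_edges: np.ndarray
    active_edges: np.ndarray | None
    consensus_positive: np.ndarray
    consensus_negative: np.ndarray
    coefficients: np.ndarray
    column_names: tuple[str, ...]
    lambda_: float | None
    degenerate: bool
    stat: np.ndarray


@dataclass(frozen=True)
class RunResult:
    """Pooled held-out predictions plus per-fold selections and provenance."""

    config: RunConfig
    subject_ids: tuple[str, ...]
    fold_of_subject: np.ndarray
    predictions: dict[str, np.ndarray]
    actuals: np.ndarray | None
    actual_time: np.ndarray | None
    actual_status: np.ndarray | None
    levels: tuple[str, ...]
    records: tuple[FoldRecord, ...]
    edge_index: EdgeIndex
    provenance: dict

    @property
    def n_folds(self) -> int:
        return int(self.fold_of_subject.max()) + 1

    def stream_selections(self, stream: str) -> list[tuple[np.ndarray, np.ndarray]]:
        """(positive, negative) consensus-eligible edge sets per fold."""
        recs = sorted(
            (r for r in self.records if r.stream == stream), key=lambda r: r.fold
        )
        return [(r.consensus_positive, r.consensus_negative) for r in recs]

    def stream_stats(self, stream: str) -> list[np.ndarray]:
        recs = sorted(
            (r for r in self.records if r.stream == stream), key=lambda r: r.fold
        )
        return [r.stat for r in recs]


def assign_folds(
    n: int,
    cv: str = "loocv",
    k: int | None = None,
    seed: int = 1220,
    stratify_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic fold ids (0..k−1) per subject; sizes differ by ≤ 1.

    LOOCV is k-fold with k = n. When ``stratify_labels`` is given, members of
    each stratum are spread across folds as evenly as possible.
    """
    if cv == "loocv":
        k = n
    if k is None:
        raise ValueError("k-fold CV requires k")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError(f"need k ≥ 2, got k={k}")
    rng = np.random.default_rng(seed)
    if stratify_labels is None:
        order = rng.permutation(n)
    else:
        labels = np.asarray(stratify_labels)
        order = []
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            rng.shuffle(members)
            order.extend(members.tolist())
        order = np.asarray(order)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k
    return folds


# ---------------------------------------------------------------------------
# Per-fold model fitting helpers
# ---------------------------------------------------------------------------

def _null_predictions(model: str, outcome_train: Outcome, n_test: int, L: int):
    """Training-marginal predictions when a fold has no usable predictors."""
    if model == "linear":
        return np.full(n_test, float(outcome_train.y.mean()))
    if model == "logistic":
        return np.full(n_test, float(outcome_train.y.mean()))
    if model == "multinom":
        freq = np.bincount(outcome_train.y, minlength=L).astype(float)
        freq /= freq.sum()
        return np.tile(freq, (n_test, 1))
    return np.zeros(n_test)  # cox: flat risk


def _fit_and_predict_original(
    model: str,
    design_tr: DesignMatrix,
    design_te: DesignMatrix,
    outcome_tr: Outcome,
):
    if model == "cox":
        fit = fit_cox(design_tr, outcome_tr.time, outcome_tr.status)
        pred = predict_cox_linear_predictor(fit, design_te)
        return fit, pred, np.concatenate([[0.0], fit.beta])
    fit = fit_glm(design_tr, outcome_tr)
    pred = predict_glm(fit, design_te).values
    return fit, pred, fit.beta


def _screen(edge_tr: np.ndarray, outcome_tr: Outcome, config: RunConfig) -> ScreeningResult:
    if outcome_tr.family == "survival":
        return screen_edges_cox(edge_tr, outcome_tr.time, outcome_tr.status, config.thresh)
    y = encode_outcome_for_screening(outcome_tr)
    return screen_edges_correlation(edge_tr, y, config.correlation, config.thresh)


def _stream_edge_sets(screening: ScreeningResult, edge_mode: str) -> dict[str, np.ndarray]:
    if edge_mode == "separate":
        return {"positive": screening.positive_edges, "negative": screening.negative_edges}
    return {"combined": screening.selected}


def _edge_names(edge_index: EdgeIndex, cols: np.ndarray) -> tuple[str, ...]:
    pairs = edge_index.pairs
    return tuple(f"edge_{pairs[e, 0] + 1}_{pairs[e, 1] + 1}" for e in cols)


def _validate_inputs(stack, outcome, covariates):
    if outcome.n != stack.N:
        raise ValueError(f"outcome has {outcome.n} rows but stack has N={stack.N}")
    if covariates is not None and covariates.values.shape[0] != stack.N:
        raise ValueError(
            f"covariates have {covariates.values.shape[0]} rows but stack has N={stack.N}"
        )


def _resolve_model(config: RunConfig, outcome: Outcome) -> str:
    inferred = _FAMILY_MODEL[outcome.family]
    if config.model is not None and config.model != inferred:
        raise ValueError(
            f"config.model={config.model!r} does not match outcome family "
            f"{outcome.family!r} (expected {inferred!r})"
        )
    return inferred


def run_cpm(
    stack: ConnectomeStack,
    outcome: Outcome,
    covariates: CovariateTable | None = None,
    config: RunConfig | None = None,
) -> RunResult:
    """Run the full cross-validated pipeline and pool held-out predictions.

    Every subject is predicted exactly once, by the model trained on the folds
    that exclude it. Returns the :class:`RunResult` consumed by
    :func:`cpmkit.evaluation.assess` and :mod:`cpmkit.network`.
    """
    config = config or RunConfig()
    _validate_inputs(stack, outcome, covariates)
    model = _resolve_model(config, outcome)
    edge_matrix, edge_index = vectorize_upper_triangle(stack)
    n = stack.N
    L = len(outcome.levels)

    strat = None
    if config.stratify:
        if outcome.family in ("binary", "categorical"):
            strat = outcome.y
        elif outcome.family == "survival":
            strat = outcome.status
    folds = assign_folds(n, config.cv, config.k, config.seed, strat)
    n_folds = int(folds.max()) + 1

    streams = ("positive", "negative") if config.edge == "separate" else ("combined",)
    predictions: dict[str, np.ndarray] = {}
    for s in streams:
        predictions[s] = (
            np.zeros((n, L)) if model == "multinom" else np.zeros(n)
        )
    records: list[FoldRecord] = []
    degenerate_folds = 0

    for f in range(n_folds):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        outcome_tr = outcome.subset(train)
        cov_tr = cov_te = None
        if covariates is not None:
            cov_tr = CovariateTable(covariates.values[train], covariates.names)
            cov_te = CovariateTable(covariates.values[test], covariates.names)
        screening = _screen(edge_matrix[train], outcome_tr, config)
        edge_sets = _stream_edge_sets(screening, config.edge)

        for stream, cols in edge_sets.items():
            rec, pred = _run_stream(
                f, stream, cols, screening, edge_matrix, train, test,
                outcome, outcome_tr, cov_tr, cov_te, config, model, edge_index, L,
            )
            predictions[stream][test] = pred
            records.append(rec)
            if rec.degenerate:
                degenerate_folds += 1

    if covariates is None and degenerate_folds == len(records):
        raise ValueError(
            "every fold was degenerate (no edges selected) and no covariates "
            "are available to fall back on"
        )

    import scipy
    provenance = {
        "config": _config_dict(config),
        "n_subjects": n,
        "n_nodes": stack.M,
        "n_folds": n_folds,
        "model": model,
        "versions": {
            "cpmkit": _version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    return RunResult(
        config=replace(config, model=model),
        subject_ids=stack.subject_ids,
        fold_of_subject=folds,
        predictions=predictions,
        actuals=None if model == "cox" else outcome.y.astype(float),
        actual_time=outcome.time if model == "cox" else None,
        actual_status=outcome.status if model == "cox" else None,
        levels=outcome.levels,
        records=tuple(records),
        edge_index=edge_index,
        provenance=provenance,
    )


def _run_stream(
    f, stream, cols, screening, edge_matrix, train, test,
    outcome, outcome_tr, cov_tr, cov_te, config, model, edge_index, L,
):
    cols = np.asarray(cols, dtype=int)
    degenerate = len(cols) == 0
    lam = None
    active = None

    if degenerate:
        warnings.warn(
            f"fold {f}, stream {stream!r}: no edges selected; "
            + ("falling back to covariate-only model" if cov_tr is not None else "predicting the training marginal")
        )

    if degenerate and cov_tr is None:
        pred = _null_predictions(model, outcome_tr, len(test), L)
        coefs = np.zeros(0)
        names = ()
    elif config.arm == "original" or degenerate:
        if degenerate:
            a_tr = a_te = None
            edge_names = None
        elif config.edge == "separate":
            a_tr = edge_matrix[np.ix_(train, cols)].sum(axis=1)
            a_te = edge_matrix[np.ix_(test, cols)].sum(axis=1)
            edge_names = (f"a_{stream}",)
        else:
            a_tr = edge_matrix[np.ix_(train, cols)].sum(axis=1)
            a_te = edge_matrix[np.ix_(test, cols)].sum(axis=1)
            edge_names = ("a_combined",)
        design_tr = assemble_design(a_tr, cov_tr, edge_names)
        design_te = assemble_design(a_te, cov_te, edge_names)
        _, pred, coefs = _fit_and_predict_original(model, design_tr, design_te, outcome_tr)
        names = design_tr.column_names
    else:
        edge_names = _edge_names(edge_index, cols)
        design_tr = assemble_design(edge_matrix[np.ix_(train, cols)], cov_tr, edge_names)
        design_te = assemble_design(edge_matrix[np.ix_(test, cols)], cov_te, edge_names)
        penalty = config.penalty()
        lam_spec = config.lambda_
        inner_seed = (config.seed + 7919 * f + 104729 * _stream_id(stream)) % (2**31)
        if isinstance(lam_spec, str) and lam_spec == "auto":
            lam, _, _ = select_lambda(
                design_tr, outcome_tr, penalty=penalty,
                inner_folds=config.inner_folds, seed=inner_seed,
            )
        elif np.ndim(lam_spec) > 0:
            lam, _, _ = select_lambda(
                design_tr, outcome_tr, penalty=penalty,
                inner_folds=config.inner_folds, seed=inner_seed,
                lambdas=np.asarray(lam_spec, dtype=float),
            )
        else:
            lam = float(lam_spec)
        fit = fit_penalized(design_tr, outcome_tr, penalty=penalty, lambda_value=lam)
        pred = predict_penalized(fit, design_te)
        # fit.active_edges indexes the design's edge block, whose column order
        # is exactly `cols`; map back to flat edge ids
        active = cols[fit.active_edges] if len(fit.active_edges) else np.array([], dtype=int)
        coefs = fit.beta
        names = design_tr.column_names

    pos = np.asarray(screening.positive_edges, dtype=int)
    neg = np.asarray(screening.negative_edges, dtype=int)
    if stream == "positive":
        sel_pos, sel_neg = pos, np.array([], dtype=int)
    elif stream == "negative":
        sel_pos, sel_neg = np.array([], dtype=int), neg
    else:
        sel_pos, sel_neg = pos, neg

    # consensus rule: lasso/EN keep edges with nonzero fitted coefficients;
    # ridge and the original arm keep the screened sets
    if config.arm == "penalized" and config.type in ("lasso", "EN") and active is not None:
        cons_pos = np.intersect1d(active, sel_pos)
        cons_neg = np.intersect1d(active, sel_neg)
    else:
        cons_pos, cons_neg = sel_pos, sel_neg

    return (
        FoldRecord(
            fold=f,
            stream=stream,
            positive_edges=sel_pos,
            negative_edges=sel_neg,
            active_edges=active,
            consensus_positive=cons_pos,
            consensus_negative=cons_neg,
            coefficients=np.asarray(coefs, dtype=float),
            column_names=tuple(names),
            lambda_=lam,
            degenerate=degenerate,
            stat=screening.stat,
        ),
        pred,
    )


def _stream_id(stream: str) -> int:
    return {"positive": 0, "negative": 1, "combined": 2}[stream]


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    if np.ndim(d["lambda_"]) > 0:
        d["lambda_"] = list(np.asarray(d["lambda_"], dtype=float))
    return d


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("cpmkit")
    except Exception:
        return "unknown"


# ---------------------------------------------------------------------------
# External validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExternalValidation:
    """Models fitted on the full training cohort plus external predictions."""

    models: dict[str, object]
    predictions: dict[str, np.ndarray]
    screening: ScreeningResult
    edge_index: EdgeIndex


def external_validate(
    stack: ConnectomeStack,
    outcome: Outcome,
    covariates: CovariateTable | None,
    config: RunConfig,
    external_stack: ConnectomeStack,
    external_covariates: CovariateTable | None = None,
) -> ExternalValidation:
    """Screen and fit once on all training subjects; predict an external cohort.

    Fitted models are returned only on this path (internal CV never exposes
    fold models). Node counts and covariate column names must match.
    """
    config = config or RunConfig()
    _validate_inputs(stack, outcome, covariates)
    if external_stack.M != stack.M:
        raise ValueError(
            f"external stack has M={external_stack.M}, training has M={stack.M}"
        )
    if (covariates is None) != (external_covariates is None):
        raise ValueError("covariates must be supplied for both cohorts or neither")
    if covariates is not None and covariates.names != external_covariates.names:
        raise ValueError(
            f"covariate columns differ: {covariates.names} vs {external_covariates.names}"
        )
    model = _resolve_model(config, outcome)
    edge_matrix, edge_index = vectorize_upper_triangle(stack)
    ext_matrix, _ = vectorize_upper_triangle(external_stack)
    screening = _screen(edge_matrix, outcome, config)
    edge_sets = _stream_edge_sets(screening, config.edge)

    models: dict[str, object] = {}
    preds: dict[str, np.ndarray] = {}
    for stream, cols in edge_sets.items():
        cols = np.asarray(cols, dtype=int)
        if len(cols) == 0:
            warnings.warn(f"stream {stream!r}: no edges selected on the full training set")
            preds[stream] = _null_predictions(
                model, outcome, ext_matrix.shape[0], len(outcome.levels)
            )
            models[stream] = None
            continue
        if config.arm == "original":
            name = (f"a_{stream}",) if config.edge == "separate" else ("a_combined",)
            design_tr = assemble_design(edge_matrix[:, cols].sum(axis=1), covariates, name)
            design_ex = assemble_design(ext_matrix[:, cols].sum(axis=1), external_covariates, name)
            if model == "cox":
                fit = fit_cox(design_tr, outcome.time, outcome.status)
                preds[stream] = predict_cox_linear_predictor(fit, design_ex)
            else:
                fit = fit_glm(design_tr, outcome)
                preds[stream] = predict_glm(fit, design_ex).values
            models[stream] = fit
        else:
            edge_names = _edge_names(edge_index, cols)
            design_tr = assemble_design(edge_matrix[:, cols], covariates, edge_names)
            design_ex = assemble_design(ext_matrix[:, cols], external_covariates, edge_names)
            penalty = config.penalty()
            lam_spec = config.lambda_
            if isinstance(lam_spec, str) and lam_spec == "auto":
                lam, _, _ = select_lambda(
                    design_tr, outcome, penalty=penalty,
                    inner_folds=config.inner_folds, seed=config.seed,
                )
            elif np.ndim(lam_spec) > 0:
                lam, _, _ = select_lambda(
                    design_tr, outcome, penalty=penalty,
                    inner_folds=config.inner_folds, seed=config.seed,
                    lambdas=np.asarray(lam_spec, dtype=float),
                )
            else:
                lam = float(lam_spec)
            fit = fit_penalized(design_tr, outcome, penalty=penalty, lambda_value=lam)
            preds[stream] = predict_penalized(fit, design_ex)
            models[stream] = fit
    return ExternalValidation(models, preds, screening, edge_index)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def write_run_result(run: RunResult, outdir) -> Path:
    """Write predictions.csv, selected_edges.csv, lambdas.csv, provenance.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    frame = pd.DataFrame({"subject_id": run.subject_ids, "fold": run.fold_of_subject})
    if run.config.model == "cox":
        frame["actual_time"] = run.actual_time
        frame["actual_status"] = run.actual_status
    else:
        frame["actual"] = run.actuals
    for stream, pred in run.predictions.items():
        if pred.ndim == 2:
            for c, level in enumerate(run.levels):
                frame[f"{stream}_prob_{level}"] = pred[:, c]
        else:
            frame[f"{stream}_pred"] = pred
    frame.to_csv(outdir / "predictions.csv", index=False)

    pairs = run.edge_index.pairs
    rows = []
    for rec in run.records:
        for sign, edges in ((1, rec.consensus_positive), (-1, rec.consensus_negative)):
            for e in np.asarray(edges, dtype=int):
                rows.append(
                    {
                        "fold": rec.fold,
                        "stream": rec.stream,
                        "edge_i": int(pairs[e, 0]) + 1,
                        "edge_j": int(pairs[e, 1]) + 1,
                        "sign": sign,
                        "stat": float(rec.stat[e]),
                    }
                )
    pd.DataFrame(rows, columns=["fold", "stream", "edge_i", "edge_j", "sign", "stat"]).to_csv(
        outdir / "selected_edges.csv", index=False
    )

    lam_rows = [
        {"fold": rec.fold, "stream": rec.stream, "lambda": rec.lambda_}
        for rec in run.records
        if rec.lambda_ is not None
    ]
    pd.DataFrame(lam_rows, columns=["fold", "stream", "lambda"]).to_csv(
        outdir / "lambdas.csv", index=False
    )

    with open(outdir / "provenance.json", "w") as fh:
        json.dump(run.provenance, fh, indent=2, default=str)
    return outdir
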