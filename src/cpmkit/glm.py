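"""Unpenalized generalized linear models for the original pipeline arm.

Three exponential-family instances are realized, each with its canonical link:
gaussian/identity (continuous outcomes), binomial/logit (binary outcomes),
and multinomial logit with a reference level (categorical outcomes, fitted as
L−1 logit contrasts against the first declared level).

Fitting is Newton–Raphson (equivalently IRLS for these canonical links) with
step halving, so the log-likelihood is non-decreasing across iterations; the
per-iteration trace is kept on the fitted model for inspection. Convergence is
max |Δβ| < 1e-8 within 100 iterations. The intercept is always included and is
never screened or penalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Outcome
from .design import DesignMatrix

__all__ = ["FamilySpec", "FittedModel", "GLMPrediction", "fit_glm", "predict_glm"]

_TOL = 1e-8
_MAX_ITER = 100


class RankDeficientError(np.linalg.LinAlgError):
    """Design is rank deficient; the penalized arm handles such designs."""


@dataclass(frozen=True)
class FamilySpec:
    """Outcome family with its canonical link.

    ``family`` is one of ``gaussian`` (identity link), ``binomial`` (logit),
    ``multinomial`` (logit contrasts vs ``reference_level``, which defaults to
    the first declared factor level).
    """

    family: str
    reference_level: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial", "multinomial"):
            raise ValueError(f"unknown family {self.family!r}")

    @classmethod
    def for_outcome(cls, outcome: Outcome) -> "FamilySpec":
        if outcome.family == "continuous":
            return cls("gaussian")
        if outcome.family == "binary":
            return cls("binomial")
        if outcome.family == "categorical":
            return cls("multinomial", reference_level=outcome.levels[0])
        raise ValueError("survival outcomes use the Cox model, not a GLM")


@dataclass(frozen=True)
class FittedModel:
    """Fitted GLM: intercept-first coefficients, convergence flags, levels.

    For the multinomial family ``beta`` has shape (L−1, K+J+1): one
    intercept-first row per non-reference level, in declared level order.
    """

    family: FamilySpec
    beta: np.ndarray
    levels: tuple[str, ...]
    column_names: tuple[str, ...]
    converged: bool
    n_iter: int
    ll_trace: tuple[float, ...] = field(default=(), repr=False)


@dataclass(frozen=True)
class GLMPrediction:
    """Predictions: linear predictor, mean-scale values, and hard labels."""

    eta: np.ndarray
    values: np.ndarray
    labels: np.ndarray | None = None


def _with_intercept(X: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((X.shape[0], 1)), X])


def _check_rank(X1: np.ndarray) -> None:
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise RankDeficientError(
            "design matrix is rank deficient; use the penalized arm"
        )


def fit_glm(design: DesignMatrix, outcome: Outcome, family: FamilySpec | None = None) -> FittedModel:
    """Maximum-likelihood fit of the family matching the outcome."""
    family = family or FamilySpec.for_outcome(outcome)
    X1 = _with_intercept(design.X_star)
    names = ("(intercept)",) + design.column_names

    if family.family == "gaussian":
        if outcome.family != "continuous":
            raise ValueError("gaussian family requires a continuous outcome")
        y = outcome.y
        if X1.shape[0] <= X1.shape[1] - 1:
            raise ValueError(
                f"n={X1.shape[0]} too small for {X1.shape[1]} coefficients; "
                "use the penalized arm"
            )
        _check_rank(X1)
        beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
        resid = y - X1 @ beta
        n = len(y)
        sigma2 = max(float(resid @ resid) / n, 1e-300)
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        return FittedModel(family, beta, (), names, True, 1, (ll,))

    if family.family == "binomial":
        if outcome.family != "binary":
            raise ValueError("binomial family requires a binary outcome")
        _check_rank(X1)
        y = outcome.y.astype(float)
        beta, converged, n_iter, trace = _newton_logistic(X1, y)
        if not converged and np.max(np.abs(beta)) > 15:
            warnings.warn(
                "logistic fit did not converge and coefficients diverged; "
                "data may be completely separated",
                RuntimeWarning,
            )
        return FittedModel(family, beta, outcome.levels, names, converged, n_iter, trace)

    # multinomial
    if outcome.family != "categorical":
        raise ValueError("multinomial family requires a categorical outcome")
    _check_rank(X1)
    levels = outcome.levels
    ref = family.reference_level or levels[0]
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} not among outcome levels")
    family = FamilySpec("multinomial", reference_level=ref)
    beta, converged, n_iter, trace = _newton_multinomial(X1, outcome.y, len(levels), levels.index(ref))
    return FittedModel(family, beta, levels, names, converged, n_iter, trace)


def _newton_logistic(X1: np.ndarray, y: np.ndarray):
    n, p = X1.shape
    beta = np.zeros(p)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = X1 @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = X1.T @ (y - mu)
        H = X1.T @ (X1 * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving keeps the log-likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_c = X1 @ cand
            ll_c = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
            if ll_c >= ll - 1e-12:
                break
            scale *= 0.5
        trace.append(ll)
        delta = scale * step
        beta = beta + delta
        if np.max(np.abs(delta)) < _TOL:
            converged = True
            break
    eta = X1 @ beta
    trace.append(float(y @ eta - np.logaddexp(0.0, eta).sum()))
    return beta, converged, it, tuple(trace)


def _multinomial_ll(X1: np.ndarray, codes: np.ndarray, B: np.ndarray, ref: int, L: int) -> float:
    eta = np.zeros((X1.shape[0], L))
    nonref = [c for c in range(L) if c != ref]
    for r, c in enumerate(nonref):
        eta[:, c] = X1 @ B[r]
    lse = np.logaddexp.reduce(eta, axis=1)
    return float(eta[np.arange(len(codes)), codes].sum() - lse.sum())


def _newton_multinomial(X1: np.ndarray, codes: np.ndarray, L: int, ref: int):
    n, p = X1.shape
    nonref = [c for c in range(L) if c != ref]
    R = len(nonref)
    B = np.zeros((R, p))
    trace: list[float] = []
    converged = False
    it = 0
    Y = np.zeros((n, L))
    Y[np.arange(n), codes] = 1.0
    for it in range(1, _MAX_ITER + 1):
        ll = _multinomial_ll(X1, codes, B, ref, L)
        eta = np.zeros((n, L))
        for r, c in enumerate(nonref):
            eta[:, c] = X1 @ B[r]
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)
        grad = np.concatenate([X1.T @ (Y[:, c] - P[:, c]) for c in nonref])
        H = np.zeros((R * p, R * p))
        for a, ca in enumerate(nonref):
            for b, cb in enumerate(nonref):
                w = P[:, ca] * ((ca == cb) - P[:, cb])
                H[a * p : (a + 1) * p, b * p : (b + 1) * p] = X1.T @ (X1 * w[:, None])
        H[np.diag_indices_from(H)] += 1e-10
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        step = step.reshape(R, p)
        scale = 1.0
        for _ in range(30):
            cand = B + scale * step
            if _multinomial_ll(X1, codes, cand, ref, L) >= ll - 1e-12:
                break
            scale *= 0.5
        trace.append(ll)
        delta = scale * step
        B = B + delta
        if np.max(np.abs(delta)) < _TOL:
            converged = True
            break
    trace.append(_multinomial_ll(X1, codes, B, ref, L))
    return B, converged, it, tuple(trace)


def predict_glm(model: FittedModel, design: DesignMatrix) -> GLMPrediction:
    """Predict on a design with the training column layout.

    Gaussian returns ŷ = η; binomial returns event probabilities plus hard
    labels at 0.5; multinomial returns softmax class probabilities (columns in
    declared level order, reference included) plus argmax labels with ties
    broken toward the lowest class index.
    """
    if design.column_names != model.column_names[1:]:
        raise ValueError(
            "design columns do not match training layout: "
            f"{design.column_names} vs {model.column_names[1:]}"
        )
    X1 = _with_intercept(design.X_star)
    fam = model.family.family
    if fam == "gaussian":
        eta = X1 @ model.beta
        return GLMPrediction(eta=eta, values=eta)
    if fam == "binomial":
        eta = X1 @ model.beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        labels = np.asarray(model.levels)[(prob >= 0.5).astype(int)]
        return GLMPrediction(eta=eta, values=prob, labels=labels)
    # multinomial
    L = len(model.levels)
    ref = model.levels.index(model.family.reference_level)
    nonref = [c for c in range(L) if c != ref]
    eta = np.zeros((X1.shape[0], L))
    for r, c in enumerate(nonref):
        eta[:, c] = X1 @ model.beta[r]
    shifted = eta - eta.max(axis=1, keepdims=True)
    P = np.exp(shifted)
    P /= P.sum(axis=1, keepdims=True)
    labels = np.asarray(model.levels)[P.argmax(axis=1)]
    return GLMPrediction(eta=eta, values=P, labels=labels)
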