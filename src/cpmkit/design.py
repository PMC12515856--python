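"""Model design matrices for both pipeline arms.

The original arm collapses each subject's selected edges into scalar summary
predictors (sum of edge weights over the positive set, the negative set, or
the combined set); the penalized arm keeps the full selected-edge block. Either
way, the edge-derived columns are concatenated with non-imaging covariates into
one predictor matrix X* = (A, X), and a penalty mask records which columns are
eligible for shrinkage (edges) and which are exempt (covariates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CovariateTable
from .screening import ScreeningResult

__all__ = ["DesignMatrix", "SummaryPredictors", "build_summary_predictors", "assemble_design"]


@dataclass(frozen=True)
class DesignMatrix:
    """Predictor matrix X* = [edge block A | covariates X] with penalty mask.

    ``penalty_mask`` is 1 on edge columns (penalized) and 0 on covariate
    columns (exempt). The intercept is handled by the model layer and never
    appears as a column here.
    """

    X_star: np.ndarray
    edge_block_cols: np.ndarray
    covariate_cols: np.ndarray
    penalty_mask: np.ndarray
    column_names: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X_star, dtype=float)
        object.__setattr__(self, "X_star", X)
        if X.ndim != 2 or X.shape[1] == 0:
            raise ValueError("design must be n × (K+J) with K+J ≥ 1")
        if not np.all(np.isfinite(X)):
            raise ValueError("design contains missing/non-finite values")
        mask = np.zeros(X.shape[1])
        mask[np.asarray(self.edge_block_cols, dtype=int)] = 1.0
        if not np.array_equal(mask, np.asarray(self.penalty_mask, dtype=float)):
            raise ValueError("penalty_mask must be 1 exactly on edge columns")
        if len(self.column_names) != X.shape[1]:
            raise ValueError("column_names length mismatch")

    @property
    def n(self) -> int:
        return self.X_star.shape[0]

    @property
    def K(self) -> int:
        return len(self.edge_block_cols)

    @property
    def J(self) -> int:
        return len(self.covariate_cols)


@dataclass(frozen=True)
class SummaryPredictors:
    """Named length-n summary vectors plus degeneracy flags.

    ``streams`` maps ``"positive"``/``"negative"`` (separate mode) or
    ``"combined"`` to a vector; ``degenerate`` names streams whose selected
    edge set was empty (zero vector returned, fallback handled downstream).
    """

    streams: dict[str, np.ndarray]
    degenerate: frozenset[str]


def build_summary_predictors(
    edge_matrix: np.ndarray,
    screening: ScreeningResult,
    edge_mode: str = "separate",
) -> SummaryPredictors:
    """Sum selected edge weights per subject.

    ``separate`` produces one summary per signed set (a_pos, a_neg);
    ``combined`` sums over the union without distinguishing sign. An empty
    selected set yields a zero vector and a degeneracy flag rather than an
    error — the pipeline falls back to a covariate-only model.
    """
    edge_matrix = np.asarray(edge_matrix, dtype=float)
    if edge_mode not in ("separate", "combined"):
        raise ValueError(f"edge_mode must be 'separate' or 'combined', got {edge_mode!r}")

    def _sum(idx: np.ndarray) -> np.ndarray:
        if len(idx) == 0:
            return np.zeros(edge_matrix.shape[0])
        return edge_matrix[:, np.asarray(idx, dtype=int)].sum(axis=1)

    if edge_mode == "separate":
        streams = {
            "positive": _sum(screening.positive_edges),
            "negative": _sum(screening.negative_edges),
        }
        degenerate = frozenset(
            name
            for name, idx in (
                ("positive", screening.positive_edges),
                ("negative", screening.negative_edges),
            )
            if len(idx) == 0
        )
    else:
        streams = {"combined": _sum(screening.selected)}
        degenerate = frozenset(["combined"] if len(screening.selected) == 0 else [])
    return SummaryPredictors(streams, degenerate)


def assemble_design(
    edge_features: np.ndarray | None,
    covariates: CovariateTable | None = None,
    edge_names: tuple[str, ...] | None = None,
) -> DesignMatrix:
    """Concatenate edge-derived columns with covariates and set the mask.

    ``edge_features`` is an n×K matrix (a single summary vector may be passed
    as shape (n,) or (n, 1)); ``None`` or zero columns means a covariate-only
    design (degenerate-fold fallback). Columns are ordered [edges | covariates].
    """
    blocks, names = [], []
    if edge_features is not None:
        A = np.asarray(edge_features, dtype=float)
        if A.ndim == 1:
            A = A[:, None]
        if A.shape[1] > 0:
            blocks.append(A)
            names.extend(edge_names or [f"edge_{k}" for k in range(A.shape[1])])
    K = blocks[0].shape[1] if blocks else 0
    if covariates is not None and covariates.J > 0:
        blocks.append(covariates.values)
        names.extend(covariates.names)
    if not blocks:
        raise ValueError("design has zero columns (no edges and no covariates)")
    rows = {b.shape[0] for b in blocks}
    if len(rows) > 1:
        raise ValueError(f"row count mismatch between edge block and covariates: {rows}")
    X = np.hstack(blocks)
    total = X.shape[1]
    mask = np.zeros(total)
    mask[:K] = 1.0
    return DesignMatrix(
        X_star=X,
        edge_block_cols=np.arange(K),
        covariate_cols=np.arange(K, total),
        penalty_mask=mask,
        column_names=tuple(names),
    )
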