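"""Edge-wise marginal screening.

Each edge is tested individually for association with the outcome; edges whose
two-sided p-value falls strictly below the threshold advance, partitioned into
positively and negatively associated sets by the sign of the statistic.

For continuous/binary/categorical outcomes the statistic is a correlation
coefficient (Pearson by default; Spearman and Kendall offered). For survival
outcomes each edge is screened with a univariate Cox proportional-hazards fit
and the Wald p-value of its coefficient. No multiple-testing correction is
applied — the threshold is a raw p cutoff, and ``thresh = 1`` means every
non-degenerate edge advances (no preselection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import EdgeIndex, Outcome

__all__ = [
    "ScreeningResult",
    "screen_edges_correlation",
    "screen_edges_cox",
    "encode_outcome_for_screening",
]


@dataclass(frozen=True)
class ScreeningResult:
    """Per-edge statistics and the signed selected sets.

    ``stat`` carries the correlation coefficient (correlation methods) or the
    fitted univariate Cox coefficient (survival); ``p`` the two-sided p-value.
    Selection is strict: an edge is selected iff ``p < thresh``; degenerate
    (zero-variance) edges get ``p = 1`` and are never selected.
    """

    stat: np.ndarray
    p: np.ndarray
    positive_edges: np.ndarray
    negative_edges: np.ndarray
    method: str
    thresh: float

    @property
    def selected(self) -> np.ndarray:
        """All selected flat edge indices, sorted."""
        return np.sort(np.concatenate([self.positive_edges, self.negative_edges]))

    def to_frame(self, edge_index: EdgeIndex) -> pd.DataFrame:
        """Export per-edge results with 1-based node pairs."""
        pairs = edge_index.pairs
        sel = np.zeros(edge_index.E, dtype=bool)
        sel[self.selected.astype(int)] = True
        return pd.DataFrame(
            {
                "edge_i": pairs[:, 0] + 1,
                "edge_j": pairs[:, 1] + 1,
                "stat": self.stat,
                "p": self.p,
                "selected": sel,
                "sign": np.sign(self.stat).astype(int),
            }
        )


def _partition(stat: np.ndarray, p: np.ndarray, thresh: float) -> tuple[np.ndarray, np.ndarray]:
    if not 0 < thresh <= 1:
        raise ValueError(f"thresh must be in (0, 1], got {thresh}")
    hit = p < thresh
    pos = np.flatnonzero(hit & (stat > 0))
    neg = np.flatnonzero(hit & (stat < 0))
    return pos, neg


def _corr_t_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t transform t = r·sqrt((n−2)/(1−r²)), df = n−2."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def _pearson_vector(edge_matrix: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of y against every column; zero-variance columns get r = 0."""
    xc = edge_matrix - edge_matrix.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum(axis=0))
    sy = np.sqrt((yc * yc).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[sx == 0] = 0.0
    return np.clip(r, -1.0, 1.0)


def screen_edges_correlation(
    edge_matrix: np.ndarray,
    y: np.ndarray,
    method: str = "pearson",
    thresh: float = 0.01,
) -> ScreeningResult:
    """Correlate every edge with a numeric outcome and threshold the p-values.

    Pearson and Spearman p-values use the t transform with n−2 degrees of
    freedom (Spearman on ranks); Kendall uses the normal approximation for
    tau-b. Requires n ≥ 4 and a non-constant outcome.
    """
    edge_matrix = np.asarray(edge_matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    n, E = edge_matrix.shape
    if n < 4:
        raise ValueError(f"need at least 4 subjects for screening, got n={n}")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; screening undefined")

    degenerate = np.ptp(edge_matrix, axis=0) == 0
    if method == "pearson":
        r = _pearson_vector(edge_matrix, y)
        p = _corr_t_pvalue(r, n)
    elif method == "spearman":
        ranks = stats.rankdata(edge_matrix, axis=0)
        r = _pearson_vector(ranks, stats.rankdata(y))
        p = _corr_t_pvalue(r, n)
    elif method == "kendall":
        r = np.zeros(E)
        p = np.ones(E)
        for k in range(E):
            if degenerate[k]:
                continue
            res = stats.kendalltau(edge_matrix[:, k], y)
            r[k] = 0.0 if np.isnan(res.statistic) else res.statistic
            p[k] = 1.0 if np.isnan(res.pvalue) else res.pvalue
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    r[degenerate] = 0.0
    p[degenerate] = 1.0
    pos, neg = _partition(r, p, thresh)
    return ScreeningResult(r, p, pos, neg, method, float(thresh))


def encode_outcome_for_screening(outcome: Outcome) -> np.ndarray:
    """Numeric coding of a non-survival outcome for correlation screening.

    Continuous outcomes pass through; binary/categorical become integer codes
    0..L−1 in declared level order. For nominal (unordered) categories this
    coding is order-dependent — a documented convention, since rank
    correlation against arbitrary codes has no canonical ordering.
    """
    if outcome.family == "survival":
        raise ValueError("survival outcomes are screened with screen_edges_cox")
    return outcome.y.astype(float)


# ---------------------------------------------------------------------------
# Univariate Cox screening (vectorized Newton across edges)
# ---------------------------------------------------------------------------

def _breslow_risk_layout(time: np.ndarray, status: np.ndarray):
    """Sort descending by time; return order, risk-set end per row, event rows.

    With time sorted descending, the risk set of the event at sorted position
    k is rows 0..riskend[k], where riskend[k] is the last row tied with
    time[k] (ties share a risk set; right-continuous convention).
    """
    order = np.argsort(-time, kind="stable")
    t_sorted = time[order]
    n = len(time)
    riskend = np.empty(n, dtype=int)
    j = 0
    while j < n:
        k = j
        while k + 1 < n and t_sorted[k + 1] == t_sorted[j]:
            k += 1
        riskend[j : k + 1] = k
        j = k + 1
    return order, riskend, t_sorted


def screen_edges_cox(
    edge_matrix: np.ndarray,
    time: np.ndarray,
    status: np.ndarray,
    thresh: float = 0.01,
) -> ScreeningResult:
    """Screen each edge with a univariate Cox proportional-hazards fit.

    A single-covariate Newton–Raphson is run for every edge simultaneously on
    internally standardized columns (the Wald z is invariant to scaling); the
    statistic is the fitted coefficient on the original scale and the p-value
    the two-sided Wald test from the observed information.
    """
    edge_matrix = np.asarray(edge_matrix, dtype=float)
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    n, E = edge_matrix.shape
    n_events = int(status.sum())
    if n_events == 0:
        raise ValueError("no observed events; Cox screening undefined")
    if n_events < 2:
        raise ValueError(f"need ≥2 observed events, got {n_events}")

    sd = edge_matrix.std(axis=0)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)
    X = (edge_matrix - edge_matrix.mean(axis=0)) / sd_safe  # n × E, standardized

    order, riskend, _ = _breslow_risk_layout(time, status)
    Xs = X[order]
    ev = status[order] == 1

    beta = np.zeros(E)
    info = np.full(E, np.nan)
    for _ in range(40):
        eta = Xs * beta  # n × E
        w = np.exp(np.clip(eta, -30, 30))
        cs0 = np.cumsum(w, axis=0)
        cs1 = np.cumsum(Xs * w, axis=0)
        cs2 = np.cumsum(Xs * Xs * w, axis=0)
        S0 = cs0[riskend[ev]]
        S1 = cs1[riskend[ev]]
        S2 = cs2[riskend[ev]]
        mean1 = S1 / S0
        U = (Xs[ev] - mean1).sum(axis=0)
        info = (S2 / S0 - mean1 * mean1).sum(axis=0)
        step = np.where(info > 1e-12, U / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = np.clip(beta + step, -20.0, 20.0)
        if np.max(np.abs(step)) < 1e-10:
            break

    with np.errstate(divide="ignore", invalid="ignore"):
        se = 1.0 / np.sqrt(info)
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(np.isfinite(p), p, 1.0)
    stat = beta / sd_safe  # back to original edge scale
    stat[degenerate] = 0.0
    p[degenerate] = 1.0
    pos, neg = _partition(stat, p, thresh)
    return ScreeningResult(stat, p, pos, neg, "cox-univariate", float(thresh))
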