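"""Fold-consensus edge selection and network-level aggregation.

Edges selected repeatedly across cross-validation folds are retained by a
fraction rule — an edge survives when its selection count is at least
ceil(fold_threshold × number of folds) — and the retained edges are
aggregated into symmetric network × network count matrices (one for
positively, one for negatively associated edges) using a node → network
atlas assignment, then rendered as red/blue heatmaps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AtlasNetworkMap, EdgeIndex

__all__ = ["ConsensusEdges", "NetworkMatrix", "consensus_edges", "aggregate_to_networks", "render_heatmap"]


@dataclass(frozen=True)
class ConsensusEdges:
    """Per-edge selection counts across folds and the retained set.

    ``table`` maps flat edge index → (selection_count, sign, mean_stat);
    ``retained`` holds edges with count ≥ ceil(fold_threshold·fold_count),
    with the sign decided by majority across folds (ties excluded with a
    warning).
    """

    counts: dict[int, int]
    signs: dict[int, int]
    mean_stat: dict[int, float]
    retained: np.ndarray
    fold_count: int
    fold_threshold: float


def consensus_edges(
    per_fold_selections,
    fold_threshold: float = 0.5,
    per_fold_stats=None,
) -> ConsensusEdges:
    """Aggregate per-fold signed selections into a consensus edge set.

    ``per_fold_selections`` is a sequence over folds of ``(positive, negative)``
    edge-index collections. ``per_fold_stats`` optionally supplies the length-E
    screening statistic vector of each fold, used for the retained edges' mean
    statistic (coloring intensity downstream).
    """
    if not 0 < fold_threshold <= 1:
        raise ValueError(f"fold_threshold must be in (0, 1], got {fold_threshold}")
    folds = list(per_fold_selections)
    if not folds:
        raise ValueError("need at least one fold")
    K = len(folds)
    counts: dict[int, int] = {}
    signsum: dict[int, int] = {}
    for pos, neg in folds:
        for e in np.asarray(list(pos), dtype=int):
            counts[int(e)] = counts.get(int(e), 0) + 1
            signsum[int(e)] = signsum.get(int(e), 0) + 1
        for e in np.asarray(list(neg), dtype=int):
            counts[int(e)] = counts.get(int(e), 0) + 1
            signsum[int(e)] = signsum.get(int(e), 0) - 1

    need = math.ceil(fold_threshold * K)
    signs: dict[int, int] = {}
    retained = []
    for e, c in counts.items():
        s = signsum[e]
        if s == 0:
            if c >= need:
                warnings.warn(f"edge {e}: tied sign across folds, excluded from consensus")
            continue
        signs[e] = 1 if s > 0 else -1
        if c >= need:
            retained.append(e)

    mean_stat: dict[int, float] = {}
    if per_fold_stats is not None:
        stats_arr = [np.asarray(s, dtype=float) for s in per_fold_stats]
        for e in counts:
            sel_vals = []
            for (pos, neg), sv in zip(folds, stats_arr):
                if e in set(map(int, pos)) or e in set(map(int, neg)):
                    sel_vals.append(sv[e])
            if sel_vals:
                mean_stat[e] = float(np.mean(sel_vals))
    return ConsensusEdges(
        counts=counts,
        signs=signs,
        mean_stat=mean_stat,
        retained=np.array(sorted(retained), dtype=int),
        fold_count=K,
        fold_threshold=float(fold_threshold),
    )


@dataclass(frozen=True)
class NetworkMatrix:
    """Symmetric L×L retained-edge counts per network pair, split by sign.

    Within-network edges sit on the diagonal. ``mean_stat_positive`` /
    ``mean_stat_negative`` carry the mean screening statistic per cell for
    intensity coloring (NaN where no edge).
    """

    positive: np.ndarray
    negative: np.ndarray
    network_names: tuple[str, ...]
    mean_stat_positive: np.ndarray
    mean_stat_negative: np.ndarray

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        names = list(self.network_names)
        return (
            pd.DataFrame(self.positive, index=names, columns=names),
            pd.DataFrame(self.negative, index=names, columns=names),
        )


def aggregate_to_networks(
    consensus: ConsensusEdges,
    atlas: AtlasNetworkMap,
    edge_index: EdgeIndex,
) -> NetworkMatrix:
    """Count retained edges per unordered network pair, split by sign."""
    atlas.check_nodes(edge_index.M)
    codes = atlas.network_codes()
    L = atlas.L
    pos = np.zeros((L, L), dtype=int)
    neg = np.zeros((L, L), dtype=int)
    stat_sum = {1: np.zeros((L, L)), -1: np.zeros((L, L))}
    for e in consensus.retained:
        i, j = edge_index.pair(int(e))
        a, b = codes[i], codes[j]
        sign = consensus.signs[int(e)]
        target = pos if sign > 0 else neg
        target[a, b] += 1
        if a != b:
            target[b, a] += 1
        s = consensus.mean_stat.get(int(e), np.nan)
        if np.isfinite(s):
            stat_sum[sign][a, b] += s
            if a != b:
                stat_sum[sign][b, a] += s
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_pos = np.where(pos > 0, stat_sum[1] / np.maximum(pos, 1), np.nan)
        mean_neg = np.where(neg > 0, stat_sum[-1] / np.maximum(neg, 1), np.nan)
    return NetworkMatrix(pos, neg, atlas.network_names, mean_pos, mean_neg)


def render_heatmap(matrix: NetworkMatrix, out_path) -> Path:
    """Write the paired red/blue network heatmap plus numeric CSV exports.

    Positive-edge counts use a red gradient, negative a blue one; network
    labels appear on both axes. Next to the image, ``*_pos.csv`` and
    ``*_neg.csv`` hold the numeric matrices.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    names = list(matrix.network_names)
    L = len(names)
    fig, axes = plt.subplots(1, 2, figsize=(3.2 + 0.55 * L, 2.4 + 0.45 * L))
    for ax, mat, cmap, title in (
        (axes[0], matrix.positive, "Reds", "positive edges"),
        (axes[1], matrix.negative, "Blues", "negative edges"),
    ):
        vmax = max(int(mat.max()), 1)
        im = ax.imshow(mat, cmap=cmap, vmin=0, vmax=vmax)
        ax.set_xticks(range(L), names, rotation=90, fontsize=7)
        ax.set_yticks(range(L), names, fontsize=7)
        ax.set_title(title, fontsize=9)
        fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    pos_frame, neg_frame = matrix.to_frames()
    stem = out_path.with_suffix("")
    pos_frame.to_csv(f"{stem}_pos.csv")
    neg_frame.to_csv(f"{stem}_neg.csv")
    return out_path
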