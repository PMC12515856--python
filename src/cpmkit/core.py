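"""Connectome data model, edge indexing, and file I/O.

A connectome study is a stack of N symmetric M×M connectivity matrices
(functional connectivity correlations or structural fiber densities), one per
subject, together with an outcome and optional non-imaging covariates. Because
the matrices are symmetric and self-connections carry no information, the
feature space is the strict upper triangle: E = M(M−1)/2 edges per subject.

This module owns the validated containers (:class:`ConnectomeStack`,
:class:`Outcome`, :class:`CovariateTable`, :class:`AtlasNetworkMap`), the
stable edge indexing (:class:`EdgeIndex`), and the readers for the on-disk
formats: per-subject delimited text matrices (with an optional manifest),
stacked NPY arrays, and HDF5 datasets.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SYMMETRY_TOL",
    "ConnectomeStack",
    "EdgeIndex",
    "CovariateTable",
    "Outcome",
    "AtlasNetworkMap",
    "load_connectome_stack",
    "vectorize_upper_triangle",
    "embed_upper_triangle",
    "load_network_map",
]

#: Absolute tolerance for per-subject symmetry checks. Violations are rejected
#: rather than silently symmetrized: an asymmetric matrix indicates an upstream
#: preprocessing bug that averaging would hide.
SYMMETRY_TOL = 1e-8

_DEFAULT_NETWORK_MAP = "shen268_10networks_synthetic.csv"


class ConnectomeError(ValueError):
    """Invalid connectome input (dimension, symmetry, or value errors)."""


@dataclass(frozen=True)
class ConnectomeStack:
    """N symmetric M×M connectivity matrices with subject identifiers.

    ``values`` is stored node × node × subject (M, M, N). The diagonal is
    ignored by every downstream computation.
    """

    values: np.ndarray
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))
        if values.ndim != 3 or values.shape[0] != values.shape[1]:
            raise ConnectomeError(
                f"connectome stack must be M×M×N, got shape {values.shape}"
            )
        M, _, N = values.shape
        if M < 2:
            raise ConnectomeError(f"need at least 2 nodes, got M={M}")
        if N < 3:
            raise ConnectomeError(f"need at least 3 subjects, got N={N}")
        if len(self.subject_ids) != N:
            raise ConnectomeError(
                f"{len(self.subject_ids)} subject ids for {N} matrices"
            )
        if len(set(self.subject_ids)) != N:
            raise ConnectomeError("subject ids are not unique")
        off = ~np.eye(M, dtype=bool)
        for s in range(N):
            slab = values[:, :, s]
            if not np.all(np.isfinite(slab[off])):
                i, j = _first_bad_cell(~np.isfinite(slab) & off)
                raise ConnectomeError(
                    f"subject {self.subject_ids[s]!r}: non-finite value at "
                    f"cell ({i + 1}, {j + 1})"
                )
            asym = np.abs(slab - slab.T)
            if np.nanmax(asym) > SYMMETRY_TOL:
                i, j = _first_bad_cell(asym > SYMMETRY_TOL)
                raise ConnectomeError(
                    f"subject {self.subject_ids[s]!r}: matrix not symmetric at "
                    f"cell ({i + 1}, {j + 1}): {slab[i, j]!r} vs {slab[j, i]!r}"
                )

    @property
    def M(self) -> int:
        return self.values.shape[0]

    @property
    def N(self) -> int:
        return self.values.shape[2]


def _first_bad_cell(mask: np.ndarray) -> tuple[int, int]:
    i, j = np.argwhere(mask)[0]
    return int(i), int(j)


@dataclass(frozen=True)
class EdgeIndex:
    """Bijection between flat edge indices 0..E−1 and strict-upper-triangle
    node pairs (i, j), i < j, in row-major order.

    Node indices are 0-based internally; reports are 1-based (atlas
    convention).
    """

    M: int

    @property
    def E(self) -> int:
        return self.M * (self.M - 1) // 2

    @property
    def pairs(self) -> np.ndarray:
        """(E, 2) array of 0-based (i, j) pairs, i < j, row-major order."""
        iu = np.triu_indices(self.M, k=1)
        return np.column_stack(iu)

    def flat(self, i: int, j: int) -> int:
        """Flat index of edge between nodes i < j (0-based)."""
        if not 0 <= i < j < self.M:
            raise ValueError(f"require 0 <= i < j < M={self.M}, got ({i}, {j})")
        # row-major upper triangle: edges in rows 0..i-1 come first
        return i * self.M - i * (i + 1) // 2 + (j - i - 1)

    def pair(self, k: int) -> tuple[int, int]:
        """0-based (i, j) node pair of flat edge k."""
        if not 0 <= k < self.E:
            raise ValueError(f"flat index {k} out of range for E={self.E}")
        i, j = self.pairs[k]
        return int(i), int(j)


@dataclass(frozen=True)
class CovariateTable:
    """n×J numeric non-imaging covariates, row order aligned to subjects."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(str(c) for c in self.names))
        if values.ndim != 2:
            raise ValueError("covariates must be a 2-D matrix")
        if values.shape[1] != len(self.names):
            raise ValueError(
                f"{len(self.names)} names for {values.shape[1]} columns"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("covariate names are not unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("covariates contain missing/non-finite values")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CovariateTable":
        return cls(frame.to_numpy(dtype=float), tuple(frame.columns))

    @property
    def J(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Outcome:
    """Study outcome: continuous, binary, categorical, or survival.

    For binary/categorical families ``y`` holds integer codes into ``levels``
    (declared level order). Survival outcomes carry ``time`` (positive) and
    ``status`` (1 = event, 0 = censored) instead of ``y``.
    """

    family: str
    y: np.ndarray | None = None
    levels: tuple[str, ...] = ()
    time: np.ndarray | None = None
    status: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in ("continuous", "binary", "categorical", "survival"):
            raise ValueError(f"unknown outcome family {self.family!r}")
        if self.family == "survival":
            time = np.asarray(self.time, dtype=float)
            status = np.asarray(self.status, dtype=int)
            if time.shape != status.shape or time.ndim != 1:
                raise ValueError("time and status must be equal-length vectors")
            if np.any(time <= 0):
                raise ValueError("survival times must be positive")
            if not set(np.unique(status)) <= {0, 1}:
                raise ValueError("status values must be 0/1")
            object.__setattr__(self, "time", time)
            object.__setattr__(self, "status", status)
        else:
            y = np.asarray(self.y)
            if y.ndim != 1:
                raise ValueError("y must be a vector")
            if self.family == "continuous":
                object.__setattr__(self, "y", y.astype(float))
            else:
                levels = self.levels
                if not levels:
                    levels = tuple(str(v) for v in pd.unique(y.astype(str)))
                codes = pd.Categorical(
                    y.astype(str), categories=[str(l) for l in levels]
                ).codes
                if np.any(codes < 0):
                    raise ValueError("y contains values outside declared levels")
                if self.family == "binary" and len(levels) != 2:
                    raise ValueError(
                        f"binary outcome needs exactly 2 levels, got {len(levels)}"
                    )
                if self.family == "categorical" and len(levels) < 3:
                    raise ValueError(
                        f"categorical outcome needs ≥3 levels, got {len(levels)}"
                    )
                object.__setattr__(self, "y", codes.astype(int))
                object.__setattr__(self, "levels", tuple(str(l) for l in levels))

    # -- constructors ------------------------------------------------------
    @classmethod
    def continuous(cls, y: Sequence[float]) -> "Outcome":
        return cls("continuous", y=np.asarray(y, dtype=float))

    @classmethod
    def binary(cls, y: Sequence, levels: Sequence[str] | None = None) -> "Outcome":
        return cls("binary", y=np.asarray(y), levels=tuple(levels or ()))

    @classmethod
    def categorical(cls, y: Sequence, levels: Sequence[str] | None = None) -> "Outcome":
        return cls("categorical", y=np.asarray(y), levels=tuple(levels or ()))

    @classmethod
    def survival(cls, time: Sequence[float], status: Sequence[int]) -> "Outcome":
        return cls("survival", time=np.asarray(time), status=np.asarray(status))

    @property
    def n(self) -> int:
        return len(self.time) if self.family == "survival" else len(self.y)

    def subset(self, idx: np.ndarray) -> "Outcome":
        """Row subset preserving family and declared levels."""
        idx = np.asarray(idx)
        if self.family == "survival":
            return Outcome.survival(self.time[idx], self.status[idx])
        sub = Outcome.__new__(Outcome)
        object.__setattr__(sub, "family", self.family)
        object.__setattr__(sub, "y", self.y[idx])
        object.__setattr__(sub, "levels", self.levels)
        object.__setattr__(sub, "time", None)
        object.__setattr__(sub, "status", None)
        return sub


@dataclass(frozen=True)
class AtlasNetworkMap:
    """Node → functional-network assignment for network-level aggregation."""

    node_to_network: tuple[str, ...]
    network_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.node_to_network)
        object.__setattr__(self, "node_to_network", labels)
        names = self.network_names or tuple(pd.unique(np.asarray(labels)))
        missing = set(labels) - set(names)
        if missing:
            raise ValueError(f"labels missing from network_names: {sorted(missing)}")
        object.__setattr__(self, "network_names", tuple(str(n) for n in names))

    @property
    def M(self) -> int:
        return len(self.node_to_network)

    @property
    def L(self) -> int:
        return len(self.network_names)

    def network_codes(self) -> np.ndarray:
        """0-based network index per node, in network_names order."""
        lookup = {name: i for i, name in enumerate(self.network_names)}
        return np.array([lookup[l] for l in self.node_to_network], dtype=int)

    def check_nodes(self, M: int) -> None:
        if self.M != M:
            raise ValueError(
                f"network map covers {self.M} nodes but stack has M={M}"
            )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _read_matrix(path: Path, subject: str) -> np.ndarray:
    """Read one delimited (comma/tab/space) square numeric matrix, no header."""
    text = Path(path).read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        mat = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ConnectomeError(
            f"subject {subject!r}: non-numeric cell in {path} ({exc})"
        ) from exc
    if mat.shape[0] != mat.shape[1]:
        raise ConnectomeError(
            f"subject {subject!r}: matrix in {path} is {mat.shape[0]}×{mat.shape[1]}, "
            "not square"
        )
    return mat


def load_connectome_stack(path: str | os.PathLike, layout: str = "per-subject-files") -> ConnectomeStack:
    """Load a validated :class:`ConnectomeStack` from disk.

    Parameters
    ----------
    path
        For ``layout="per-subject-files"``: a manifest CSV with columns
        ``subject_id, path``, or a directory of per-subject ``.csv``/``.tsv``/
        ``.txt`` matrices (subject order is lexicographic by filename, subject
        id is the file stem). For ``layout="stacked-container"``: an ``.npy``
        file shaped (M, M, N), or an HDF5 file whose ``connectome`` dataset
        carries a ``subject_ids`` attribute.
    layout
        ``"per-subject-files"`` or ``"stacked-container"``.
    """
    path = Path(path)
    if layout == "per-subject-files":
        if path.is_dir():
            files = sorted(
                p for p in path.iterdir() if p.suffix in (".csv", ".tsv", ".txt")
            )
            entries = [(p.stem, p) for p in files]
        else:
            manifest = pd.read_csv(path)
            if not {"subject_id", "path"} <= set(manifest.columns):
                raise ConnectomeError(
                    "manifest must have columns 'subject_id' and 'path'"
                )
            base = path.parent
            entries = [
                (str(r.subject_id), base / str(r.path))
                for r in manifest.itertuples()
            ]
        if not entries:
            raise ConnectomeError(f"no connectome files found under {path}")
        mats, ids = [], []
        for subject, fp in entries:
            mat = _read_matrix(fp, subject)
            if mats and mat.shape != mats[0].shape:
                raise ConnectomeError(
                    f"subject {subject!r}: dimension {mat.shape[0]}×{mat.shape[1]} "
                    f"does not match first subject "
                    f"({mats[0].shape[0]}×{mats[0].shape[1]})"
                )
            mats.append(mat)
            ids.append(subject)
        values = np.stack(mats, axis=2)
        return ConnectomeStack(values, tuple(ids))
    if layout == "stacked-container":
        if path.suffix == ".npy":
            values = np.load(path)
            ids = tuple(f"s{i + 1:04d}" for i in range(values.shape[2]))
            return ConnectomeStack(values, ids)
        import h5py

        with h5py.File(path, "r") as h5:
            ds = h5["connectome"]
            values = np.asarray(ds)
            raw = ds.attrs.get("subject_ids")
            if raw is None:
                ids = tuple(f"s{i + 1:04d}" for i in range(values.shape[2]))
            else:
                ids = tuple(
                    s.decode() if isinstance(s, bytes) else str(s) for s in raw
                )
        return ConnectomeStack(values, ids)
    raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# Edge vectorization
# ---------------------------------------------------------------------------

def vectorize_upper_triangle(stack: ConnectomeStack) -> tuple[np.ndarray, EdgeIndex]:
    """Flatten each subject's strict upper triangle to a feature row.

    Returns the n × E edge matrix (column k = edge ``pairs[k]``) and the
    :class:`EdgeIndex` that fixes the column order for the whole run.
    """
    index = EdgeIndex(stack.M)
    iu = np.triu_indices(stack.M, k=1)
    edge_matrix = stack.values[iu[0], iu[1], :].T.copy()
    return edge_matrix, index


def embed_upper_triangle(edge_row: np.ndarray, M: int) -> np.ndarray:
    """Inverse of vectorization for one subject: symmetric M×M, zero diagonal."""
    edge_row = np.asarray(edge_row, dtype=float)
    index = EdgeIndex(M)
    if edge_row.shape != (index.E,):
        raise ValueError(f"expected {index.E} edge values, got {edge_row.shape}")
    out = np.zeros((M, M))
    iu = np.triu_indices(M, k=1)
    out[iu] = edge_row
    return out + out.T


# ---------------------------------------------------------------------------
# Network map
# ---------------------------------------------------------------------------

def load_network_map(path: str | os.PathLike | None = None) -> AtlasNetworkMap:
    """Load a node→network table (CSV: ``node`` 1-based, ``network``).

    With ``path=None`` the bundled 268-node, 10-network table is returned.
    The bundled table is a synthetic stand-in: it has the Shen268 atlas shape
    (268 nodes grouped into the 10 canonical functional networks MF, FP, DM,
    MOT, V1, V2, VA, LIM, BG, CER) but not the published per-node assignment;
    supply your own CSV for real analyses.
    """
    if path is None:
        from importlib.resources import files

        source = files("cpmkit.data").joinpath(_DEFAULT_NETWORK_MAP)
        with source.open("r") as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    if not {"node", "network"} <= set(table.columns):
        raise ValueError("network map needs columns 'node' and 'network'")
    table = table.sort_values("node")
    nodes = table["node"].to_numpy()
    if not np.array_equal(nodes, np.arange(1, len(nodes) + 1)):
        raise ValueError("node column must enumerate 1..M exactly once")
    return AtlasNetworkMap(tuple(table["network"].astype(str)))
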