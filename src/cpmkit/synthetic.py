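"""Synthetic connectome studies with planted signal edges.

The generator emulates the shapes of a real connectome study — functional-
connectivity-like edge weights in [−1, 1], demographic-style covariates, and
an outcome of any supported family — while keeping the ground truth (which
edges carry signal, with what effect) available for recovery tests.

Edge weights are independent across edges by default (which makes
false-positive calibration exact); an optional block-correlation mode adds a
shared latent factor within contiguous edge blocks for stress tests. A latent
score s_i = effect_size·(Σ positive-signal weights − Σ negative-signal
weights) + covariate term drives the outcome: gaussian adds normal noise
(``noise_sd="auto"`` matches the noise to the signal spread, giving R² ≈ 0.5),
binary draws Bernoulli through the logit, categorical samples from a softmax
over per-class scores, and survival draws exponential proportional-hazards
times with hazard exp(s_i) under independent uniform censoring tuned to the
target censoring rate. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import ConnectomeStack, CovariateTable, EdgeIndex, Outcome, embed_upper_triangle

__all__ = ["SyntheticTruth", "SyntheticStudy", "generate_study", "write_study"]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated study (planted edges and effects)."""

    signal_pos_edges: np.ndarray
    signal_neg_edges: np.ndarray
    effect_size: float
    covariate_effects: np.ndarray
    noise_scale: float
    family: str
    censoring_rate: float
    latent_score: np.ndarray


@dataclass(frozen=True)
class SyntheticStudy:
    stack: ConnectomeStack
    outcome: Outcome
    covariates: CovariateTable | None
    truth: SyntheticTruth


def generate_study(
    M: int = 20,
    n: int = 200,
    n_signal_pos: int = 5,
    n_signal_neg: int = 5,
    effect_size: float = 1.0,
    family: str = "gaussian",
    n_covariates: int = 2,
    covariate_effects=None,
    noise_sd="auto",
    n_classes: int = 3,
    censoring_rate: float = 0.3,
    seed: int = 0,
    block_correlation: bool = False,
) -> SyntheticStudy:
    """Generate a connectome study with planted signal edges.

    See the module docstring for the generative model. ``noise_sd`` applies to
    the gaussian family only; ``n_classes`` to categorical; ``censoring_rate``
    (fraction of subjects censored, in [0, 1)) to survival.
    """
    if M < 2 or n < 3:
        raise ValueError("need M ≥ 2 and n ≥ 3")
    index = EdgeIndex(M)
    E = index.E
    if n_signal_pos + n_signal_neg >= E:
        raise ValueError(
            f"{n_signal_pos + n_signal_neg} signal edges requested but only E={E} exist"
        )
    rng = np.random.default_rng(seed)

    W = rng.normal(0.0, 0.3, size=(n, E))
    if block_correlation:
        block = 10
        for start in range(0, E, block):
            shared = rng.normal(0.0, 0.3, size=n)
            W[:, start : start + block] += 0.6 * shared[:, None]
    W = np.clip(W, -1.0, 1.0)

    chosen = rng.choice(E, size=n_signal_pos + n_signal_neg, replace=False)
    pos_edges = np.sort(chosen[:n_signal_pos])
    neg_edges = np.sort(chosen[n_signal_pos:])

    cov_table = None
    cov_term = np.zeros(n)
    effects = np.zeros(0)
    if n_covariates > 0:
        cols, names = [], []
        for j in range(n_covariates):
            if j == 1:
                cols.append(rng.integers(0, 2, size=n).astype(float))  # sex-like
                names.append("sex")
            else:
                cols.append(rng.normal(0.0, 1.0, size=n))  # age-like / generic
                names.append("age" if j == 0 else f"cov{j + 1}")
        X = np.column_stack(cols)
        effects = (
            np.full(n_covariates, 0.5)
            if covariate_effects is None
            else np.asarray(covariate_effects, dtype=float)
        )
        if len(effects) != n_covariates:
            raise ValueError("covariate_effects length must equal n_covariates")
        cov_term = X @ effects
        cov_table = CovariateTable(X, tuple(names))

    edge_part = np.zeros(n)
    if n_signal_pos:
        edge_part += W[:, pos_edges].sum(axis=1)
    if n_signal_neg:
        edge_part -= W[:, neg_edges].sum(axis=1)
    s = effect_size * edge_part + cov_term
    s_c = s - s.mean()

    noise_scale = 0.0
    if family == "gaussian":
        sd = float(np.std(s_c)) if noise_sd == "auto" else float(noise_sd)
        sd = max(sd, 1e-12)
        y = s_c + rng.normal(0.0, sd, size=n)
        outcome = Outcome.continuous(y)
        noise_scale = sd
    elif family == "binary":
        p = 1.0 / (1.0 + np.exp(-s_c))
        y = (rng.random(n) < p).astype(int)
        outcome = Outcome.binary(y.astype(str), levels=("0", "1"))
    elif family == "categorical":
        if n_classes < 3:
            raise ValueError("categorical family needs n_classes ≥ 3")
        gammas = np.linspace(-1.0, 1.0, n_classes)
        scores = s_c[:, None] * gammas[None, :]
        scores -= scores.max(axis=1, keepdims=True)
        P = np.exp(scores)
        P /= P.sum(axis=1, keepdims=True)
        codes = np.array([rng.choice(n_classes, p=P[i]) for i in range(n)])
        levels = tuple(f"c{c}" for c in range(n_classes))
        outcome = Outcome.categorical(np.asarray(levels)[codes], levels=levels)
    elif family == "survival":
        if not 0.0 <= censoring_rate < 1.0:
            raise ValueError(
                f"censoring_rate must be in [0, 1), got {censoring_rate}"
            )
        rate = np.exp(np.clip(s_c, -20, 20))
        T = rng.exponential(1.0 / rate)
        if censoring_rate == 0.0:
            time, status = T, np.ones(n, dtype=int)
        else:
            # uniform(0, u) censoring; E[censored fraction] =
            # mean_i (1 − e^{−λ_i u})/(λ_i u), solved for u
            def expected_censored(u: float) -> float:
                x = rate * u
                return float(np.mean((1.0 - np.exp(-x)) / x)) - censoring_rate

            lo, hi = 1e-9, 1e9
            u = brentq(expected_censored, lo, hi)
            C = rng.uniform(0.0, u, size=n)
            status = (T <= C).astype(int)
            time = np.minimum(T, C)
        time = np.maximum(time, 1e-12)
        outcome = Outcome.survival(time, status)
    else:
        raise ValueError(f"unknown family {family!r}")

    slices = np.empty((M, M, n))
    for i in range(n):
        slices[:, :, i] = embed_upper_triangle(W[i], M)
    stack = ConnectomeStack(slices, tuple(f"sub{i + 1:04d}" for i in range(n)))

    truth = SyntheticTruth(
        signal_pos_edges=pos_edges,
        signal_neg_edges=neg_edges,
        effect_size=float(effect_size),
        covariate_effects=effects,
        noise_scale=noise_scale,
        family=family,
        censoring_rate=float(censoring_rate) if family == "survival" else 0.0,
        latent_score=s_c,
    )
    return SyntheticStudy(stack, outcome, cov_table, truth)


def write_study(study: SyntheticStudy, outdir) -> Path:
    """Write a study in the formats the loaders read (dogfooding the I/O path).

    Produces per-subject matrix CSVs with a ``manifest.csv``, an
    ``outcome.csv``, and (when present) a ``covariates.csv``.
    """
    outdir = Path(outdir)
    mats = outdir / "connectomes"
    mats.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(study.stack.subject_ids):
        rel = f"connectomes/{sid}.csv"
        np.savetxt(outdir / rel, study.stack.values[:, :, i], delimiter=",")
        rows.append({"subject_id": sid, "path": rel})
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)

    out = study.outcome
    if out.family == "survival":
        frame = pd.DataFrame(
            {"subject_id": study.stack.subject_ids, "time": out.time, "status": out.status}
        )
    elif out.family == "continuous":
        frame = pd.DataFrame({"subject_id": study.stack.subject_ids, "y": out.y})
    else:
        frame = pd.DataFrame(
            {"subject_id": study.stack.subject_ids, "y": np.asarray(out.levels)[out.y]}
        )
    frame.to_csv(outdir / "outcome.csv", index=False)

    if study.covariates is not None:
        cov = pd.DataFrame(study.covariates.values, columns=study.covariates.names)
        cov.insert(0, "subject_id", study.stack.subject_ids)
        cov.to_csv(outdir / "covariates.csv", index=False)
    return outdir
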