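"""Standardization, Gram-matrix construction and convex kernel fusion.

Linear and Gaussian (RBF) kernels on standardized feature tables, a
convex combiner ``K = sum_m w_m K_m`` over modalities, and exhaustive
enumeration of the weight simplex on a fixed stride (the grid the fusion
weights are searched on).  The RBF bandwidth defaults to the median
heuristic, gamma = 1 / (2 * median^2) of the pairwise training
distances, recomputed per training fold so no test information leaks in.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations_with_replacement

import numpy as np
from scipy.spatial.distance import cdist, pdist


@dataclass(frozen=True)
class KernelSpec:
    kind: str = "rbf"  # 'linear' | 'rbf'
    gamma: float | None = None  # None -> median heuristic (rbf only)

    def __post_init__(self):
        if self.kind not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive when fixed")


@dataclass
class KernelMatrix:
    """Gram matrix with subject bookkeeping (rows = evaluation subjects,
    columns = reference/training subjects)."""

    values: np.ndarray
    row_ids: list
    col_ids: list
    spec: KernelSpec
    modality: str = ""

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    def to_csv(self, path) -> None:
        """Dense text serialization with subject-id headers, for caching
        per-fold Gram matrices."""
        import pandas as pd

        frame = pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)
        frame.index.name = f"{self.modality}|{self.spec.kind}|{self.spec.gamma}"
        frame.to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "KernelMatrix":
        import pandas as pd

        frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
        modality, kind, gamma = str(frame.index.name).split("|")
        spec = KernelSpec(kind, None if gamma == "None" else float(gamma))
        return cls(
            frame.to_numpy(float),
            [str(i) for i in frame.index],
            [str(c) for c in frame.columns],
            spec,
            modality,
        )


@dataclass
class Scaler:
    mean: np.ndarray
    sd: np.ndarray


def standardize_fit(X_train: np.ndarray) -> Scaler:
    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[0] < 2:
        raise ValueError("need at least two training rows")
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance feature(s) at column(s) {dead[:5].tolist()}")
    return Scaler(mean, sd)


def standardize_apply(scaler: Scaler, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != scaler.mean.shape[0]:
        raise ValueError("feature dimension does not match the scaler")
    return (X - scaler.mean) / scaler.sd


def median_heuristic_gamma(X_train: np.ndarray) -> float:
    """gamma = 1/(2 m^2) with m the median pairwise Euclidean distance."""
    d = pdist(np.asarray(X_train, dtype=float))
    med = np.median(d)
    if med == 0:
        raise ValueError("all training rows identical; median heuristic undefined")
    return 1.0 / (2.0 * med**2)


def compute_gram(
    Xa: np.ndarray,
    Xb: np.ndarray,
    spec: KernelSpec,
    row_ids: list | None = None,
    col_ids: list | None = None,
    modality: str = "",
    train_for_gamma: np.ndarray | None = None,
) -> KernelMatrix:
    """Kernel evaluations between rows of Xa and rows of Xb.

    For the RBF median heuristic the bandwidth comes from
    ``train_for_gamma`` (default: Xb, the reference/training block).
    """
    Xa = np.asarray(Xa, dtype=float)
    Xb = np.asarray(Xb, dtype=float)
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError("feature dimensions differ between the two blocks")
    if spec.kind == "linear":
        values = Xa @ Xb.T
    else:
        gamma = spec.gamma
        if gamma is None:
            gamma = median_heuristic_gamma(Xb if train_for_gamma is None else train_for_gamma)
        values = np.exp(-gamma * cdist(Xa, Xb, "sqeuclidean"))
    row_ids = list(row_ids) if row_ids is not None else list(range(len(Xa)))
    col_ids = list(col_ids) if col_ids is not None else list(range(len(Xb)))
    return KernelMatrix(values, row_ids, col_ids, spec, modality)


def combine_kernels(
    kernels: list[KernelMatrix], weights: np.ndarray
) -> KernelMatrix:
    """Entrywise convex combination; a zero weight drops a modality."""
    weights = np.asarray(weights, dtype=float)
    if len(kernels) != len(weights):
        raise ValueError("one weight per kernel required")
    if np.any(weights < -1e-12) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    first = kernels[0]
    for k in kernels[1:]:
        if k.row_ids != first.row_ids or k.col_ids != first.col_ids:
            raise ValueError("kernel subject orderings differ; refusing to combine")
    values = np.zeros_like(first.values)
    for w, k in zip(weights, kernels):
        if w:
            values += w * k.values
    return KernelMatrix(
        values, first.row_ids, first.col_ids, KernelSpec("linear", 1.0), "combined"
    )


def enumerate_simplex(stride: float, n_modalities: int) -> list[np.ndarray]:
    """All weight vectors on the simplex grid {0, s, 2s, ..., 1}^M, sum 1,
    in deterministic lexicographic order.  Exact rational arithmetic: the
    stride must divide 1."""
    frac = Fraction(stride).limit_denominator(10**6)
    if frac <= 0 or (1 / frac) != int(1 / frac):
        raise ValueError(f"stride {stride} does not divide 1")
    steps = int(1 / frac)
    out = []
    # compositions of `steps` into n_modalities non-negative parts
    for cuts in combinations_with_replacement(range(steps + 1), n_modalities - 1):
        parts = []
        prev = 0
        for c in cuts:
            parts.append(c - prev)
            prev = c
        parts.append(steps - prev)
        out.append(np.array([p / steps for p in parts], dtype=float))
    out.sort(key=lambda w: tuple(w))
    return out
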