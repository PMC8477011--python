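"""Multiple-kernel SVM: dual solver on a precomputed Gram matrix,
decision function, probability calibration and the (weights, C) grid
search on inner cross-validation.

The classifier is the soft-margin SVM dual

    min_a  1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j) - sum_i a_i
    s.t.   sum_i a_i y_i = 0,   0 <= a_i <= C

with K the convex combination ``sum_m w_m K_m`` of per-modality kernels.
The solver is SMO with maximal-violating-pair working-set selection on
the precomputed combined Gram; each pairwise update solves its
two-variable subproblem exactly, so the dual objective never increases.
The offset b* is y_j - sum_i a_i y_i K_ij averaged over unbounded
support vectors (0 < a_j < C) for numerical stability.  Kernel weights
live on the simplex and are searched exhaustively on a fixed-stride
grid, jointly with C, by mean validation AUC over inner folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .kernels import KernelMatrix, combine_kernels, enumerate_simplex

DEFAULT_C_GRID = tuple(float(10.0**e) for e in range(-4, 4))  # 1e-4 .. 1e3

try:  # the SMO inner loop is compiled when numba is available
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in CI
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco


@_njit(cache=True)
def _smo_loop(Kv, y, alpha, G, C, tol, max_passes):
    """Maximal-violating-pair SMO iterations, in place on (alpha, G).

    Selection (LIBSVM WSS1): i = argmax over I_up of -y G, j = argmin
    over I_low; stop when the pair gap falls below ``tol``.  Each update
    moves a_i by +y_i t and a_j by -y_j t with the exact unconstrained
    step clipped to the box, so the dual objective never increases.
    """
    n = y.shape[0]
    for _ in range(max_passes):
        best_i = -1
        best_j = -1
        iv = -1e300
        jv = 1e300
        for t in range(n):
            v = -y[t] * G[t]
            if (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0):
                if v > iv:
                    iv = v
                    best_i = t
            if (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C):
                if v < jv:
                    jv = v
                    best_j = t
        if best_i < 0 or best_j < 0 or iv - jv <= tol:
            break
        i, j = best_i, best_j
        # curvature K_ii + K_jj - 2 K_ij regardless of the label pattern
        quad = Kv[i, i] + Kv[j, j] - 2.0 * Kv[i, j]
        if quad < 1e-12:
            quad = 1e-12
        step = (iv - jv) / quad
        if y[i] > 0:
            if step > C - alpha[i]:
                step = C - alpha[i]
        else:
            if step > alpha[i]:
                step = alpha[i]
        if y[j] > 0:
            if step > alpha[j]:
                step = alpha[j]
        else:
            if step > C - alpha[j]:
                step = C - alpha[j]
        if step <= 0:
            break
        dai = y[i] * step
        daj = -y[j] * step
        alpha[i] += dai
        alpha[j] += daj
        for t in range(n):
            G[t] += y[t] * (Kv[t, i] * y[i] * dai + Kv[t, j] * y[j] * daj)


@dataclass
class TrainConfig:
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    weight_stride: float = 0.1
    inner_folds: int = 5
    tol: float = 1e-6  # KKT violation tolerance of the final fit
    #: tolerance used inside the grid search; validation AUC is a ranking,
    #: so the inner solves need far less precision than the final model
    search_tol: float = 1e-4
    max_passes: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if any(c <= 0 for c in self.c_grid):
            raise ValueError("C values must be positive")
        if self.inner_folds < 2:
            raise ValueError("need at least two inner folds")


@dataclass
class DualSolution:
    alpha: np.ndarray
    b: float
    weights: np.ndarray
    C: float
    support: np.ndarray  # indices with alpha > tol
    objective: float
    train_ids: list = field(default_factory=list)


def solve_dual(K: KernelMatrix | np.ndarray, y: np.ndarray, C: float,
               tol: float = 1e-6, max_passes: int = 100_000,
               weights: np.ndarray | None = None,
               alpha0: np.ndarray | None = None) -> DualSolution:
    """SMO on a precomputed square kernel.

    Stops when the maximal KKT violation (the gap between the most
    violating pair) falls below ``tol``.  ``alpha0`` warm-starts the
    solver from a dual-feasible point (e.g. the solution at a smaller C,
    which stays inside the enlarged box).
    """
    if isinstance(K, KernelMatrix):
        Kv = K.values
        ids = K.row_ids
        if not K.is_square:
            raise ValueError("training kernel must be square")
    else:
        Kv = np.asarray(K, dtype=float)
        ids = list(range(len(Kv)))
        if Kv.shape[0] != Kv.shape[1]:
            raise ValueError("training kernel must be square")
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("labels must be -1/+1 with both classes present")
    n = len(y)
    if alpha0 is not None and alpha0.shape == (n,) and np.all(alpha0 >= 0) \
            and np.all(alpha0 <= C) and abs(alpha0 @ y) < 1e-8:
        alpha = alpha0.copy()
        G = (Kv @ (alpha * y)) * y - 1.0
    else:
        alpha = np.zeros(n)
        # gradient of the dual objective: G_i = sum_j a_j y_i y_j K_ij - 1
        G = -np.ones(n)
    _smo_loop(np.ascontiguousarray(Kv, dtype=np.float64), y, alpha, G,
              float(C), float(tol), int(max_passes))

    ay = alpha * y
    obj = 0.5 * ay @ Kv @ ay - alpha.sum()
    free = (alpha > tol) & (alpha < C - tol)
    if free.any():
        b = float(np.mean(y[free] - Kv[free] @ ay))
    else:
        # no unbounded SVs: midpoint of the feasible b interval
        yG = -y * G
        up = ((y > 0) & (alpha < C)) | ((y < 0) & (alpha > 0))
        low = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < C))
        hi = yG[up].max() if up.any() else 0.0
        lo = yG[low].min() if low.any() else 0.0
        b = float((hi + lo) / 2.0)
    return DualSolution(
        alpha=alpha,
        b=b,
        weights=weights if weights is not None else np.array([1.0]),
        C=float(C),
        support=np.flatnonzero(alpha > tol),
        objective=float(obj),
        train_ids=list(ids),
    )


def decision_scores(sol: DualSolution, K_cross: KernelMatrix | np.ndarray,
                    y_train: np.ndarray) -> np.ndarray:
    """f(x) = sum_i a_i y_i K(x, x_i) + b for each evaluation row."""
    if isinstance(K_cross, KernelMatrix):
        if sol.train_ids and K_cross.col_ids != sol.train_ids:
            raise ValueError("cross-kernel columns misaligned with training subjects")
        Kv = K_cross.values
    else:
        Kv = np.asarray(K_cross, dtype=float)
    if Kv.shape[1] != len(sol.alpha):
        raise ValueError("cross-kernel has wrong number of training columns")
    return Kv @ (sol.alpha * np.asarray(y_train, dtype=float)) + sol.b


def predict(sol: DualSolution, K_cross, y_train) -> np.ndarray:
    s = decision_scores(sol, K_cross, y_train)
    return np.where(s >= 0, 1, -1)


@dataclass
class PlattSigmoid:
    A: float
    B: float
    degenerate: bool = False

    def prob(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        if self.degenerate:
            return np.where(scores >= 0, 0.75, 0.25)
        return 1.0 / (1.0 + np.exp(self.A * scores + self.B))


def fit_platt(scores: np.ndarray, y: np.ndarray,
              max_iter: int = 100) -> PlattSigmoid:
    """Platt scaling: fit P(y=1|s) = 1/(1+exp(A s + B)) by regularized
    maximum likelihood (Newton with backtracking, the standard robust
    formulation).  A < 0 whenever higher scores favor the positive class."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if len(set(np.unique(y))) < 2:
        raise ValueError("both classes required to calibrate")
    if np.ptp(scores) == 0:
        import warnings

        warnings.warn("degenerate (constant) scores; falling back to sign rule")
        return PlattSigmoid(0.0, 0.0, degenerate=True)
    prior1 = float(np.sum(y > 0))
    prior0 = float(np.sum(y <= 0))
    hi = (prior1 + 1.0) / (prior1 + 2.0)
    lo = 1.0 / (prior0 + 2.0)
    t = np.where(y > 0, hi, lo)
    A, B = 0.0, np.log((prior0 + 1.0) / (prior1 + 1.0))

    def nll(A, B):
        f = A * scores + B
        return float(np.sum(np.logaddexp(0.0, f) - (1 - t) * f))

    F = nll(A, B)
    for _ in range(max_iter):
        f = A * scores + B
        p = 1.0 / (1.0 + np.exp(f))
        d1 = t - p  # per-point gradient of the negative log-likelihood
        g_A = float(np.sum(scores * d1))
        g_B = float(np.sum(d1))
        if abs(g_A) < 1e-10 and abs(g_B) < 1e-10:
            break
        w = p * (1 - p)
        h11 = float(np.sum(scores * scores * w)) + 1e-12
        h22 = float(np.sum(w)) + 1e-12
        h12 = float(np.sum(scores * w))
        det = h11 * h22 - h12 * h12
        dA = -(h22 * g_A - h12 * g_B) / det
        dB = -(h11 * g_B - h12 * g_A) / det
        step = 1.0
        while step >= 1e-10:
            F_new = nll(A + step * dA, B + step * dB)
            if F_new < F + 1e-12:
                A, B, F = A + step * dA, B + step * dB, F_new
                break
            step /= 2.0
        else:
            break
    return PlattSigmoid(float(A), float(B))


@dataclass
class GridSearchResult:
    weights: np.ndarray
    C: float
    mean_auc: float
    table: pd.DataFrame  # one row per (weight combo, C): weights, C, mean AUC


def _rank_auc(y: np.ndarray, s: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties (local copy to avoid an
    import cycle with the evaluation module)."""
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    pos = s[y > 0]
    neg = s[y <= 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes")
    from scipy.stats import rankdata

    r = rankdata(np.concatenate([pos, neg]))
    u = r[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def grid_search(
    kernels: list[KernelMatrix],
    y: np.ndarray,
    config: TrainConfig | None = None,
) -> GridSearchResult:
    """Exhaustive (simplex weights x C) search by mean inner-CV AUC.

    Ties are broken deterministically: fewer nonzero weights, then
    smaller C, then lexicographic weight order.
    """
    config = config or TrainConfig()
    config.validate()
    y = np.asarray(y)
    n = len(y)
    for k in kernels:
        if k.values.shape != (n, n):
            raise ValueError("each kernel must be square over the training set")
    simplex = enumerate_simplex(config.weight_stride, len(kernels))
    skf = StratifiedKFold(
        n_splits=config.inner_folds, shuffle=True, random_state=config.seed
    )
    folds = list(skf.split(np.zeros(n), y))
    for tr, va in folds:
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            raise ValueError("an inner fold is single-class; re-stratify")

    c_order = sorted(config.c_grid)
    rows = []
    best = None  # (key tuple, weights, C, mean_auc)
    for w in simplex:
        Kw = combine_kernels(kernels, w).values
        sub = [
            (Kw[np.ix_(tr, tr)], Kw[np.ix_(va, tr)], y[tr], y[va])
            for tr, va in folds
        ]
        warm: list[np.ndarray | None] = [None] * len(folds)
        auc_by_C = {}
        for C in c_order:  # ascending C: previous alpha stays feasible
            aucs = []
            for f, (Ktr, Kva, ytr, yva) in enumerate(sub):
                sol = solve_dual(
                    Ktr, ytr, C,
                    tol=config.search_tol, max_passes=config.max_passes,
                    alpha0=warm[f],
                )
                warm[f] = sol.alpha
                s = Kva @ (sol.alpha * ytr) + sol.b
                aucs.append(_rank_auc(yva, s))
            auc_by_C[C] = float(np.mean(aucs))
        for C in config.c_grid:
            mean_auc = auc_by_C[C]
            rows.append({**{f"w{m}": w[m] for m in range(len(w))},
                         "C": C, "mean_auc": mean_auc})
            key = (-mean_auc, int(np.count_nonzero(w)), C, tuple(w))
            if best is None or key < best[0]:
                best = (key, w, C, mean_auc)
    table = pd.DataFrame(rows)
    return GridSearchResult(weights=best[1], C=best[2], mean_auc=best[3], table=table)
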