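"""All-relevant feature selection with shadow features, plus the
cross-run binomial selection-stability test.

The selector is the shadow-feature scheme: each iteration appends a
row-permuted copy of every column ("shadows"), asks an ensemble
importance provider (by default a random forest's mean-impurity-decrease
scores) for one score per column, and marks a *hit* for every original
feature scoring strictly above the best shadow.  Accumulated hit counts
are tested against Binomial(trials, 1/2): features significantly above
chance are confirmed, significantly below are rejected, and both leave
the pool; the loop stops when nothing is tentative or at the iteration
cap.  Tentative features at the cap count as not selected.

Stability across cross-validation runs is assessed against a binomial
null in which features are picked at random: with N runs and per-run
selected fractions averaging p-hat, a feature's selection count is
referred to Binomial(N, p-hat) (upper tail), Holm-adjusted across the
modality's features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

ImportanceProvider = Callable[[np.ndarray, np.ndarray, np.random.Generator], np.ndarray]


@dataclass
class SelectionConfig:
    max_iterations: int = 100
    #: level of the per-iteration hit test; the canonical reference default.
    #: Each branch (confirm / reject) is tested one-sided at alpha after
    #: Bonferroni over all original features.
    alpha: float = 0.01
    ensemble_size: int = 500  # trees per iteration for the default provider
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class SelectionResult:
    status: np.ndarray  # 'confirmed' | 'rejected' | 'tentative' per feature
    hits: np.ndarray
    trials: np.ndarray
    iterations: int

    @property
    def confirmed(self) -> np.ndarray:
        return np.flatnonzero(self.status == "confirmed")

    @property
    def selected(self) -> np.ndarray:
        """Confirmed features only; tentatives are conservatively dropped."""
        return self.confirmed


@dataclass
class StabilityReport:
    feature_names: list[str]
    frequency: np.ndarray  # selection frequency in [0, 1] over runs
    counts: np.ndarray
    n_runs: int
    p_rate: float  # mean fraction of features selected per run
    p_value: np.ndarray
    p_holm: np.ndarray
    significant: np.ndarray
    intersection: np.ndarray | None = None  # significant in all experiments

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "feature": self.feature_names,
                "frequency": self.frequency,
                "p": self.p_value,
                "p_holm": self.p_holm,
                "significant": self.significant,
            }
        )
        if self.intersection is not None:
            out["intersection"] = self.intersection
        return out


def rf_importance(
    n_trees: int = 500,
) -> ImportanceProvider:
    """Default provider: random-forest mean impurity (Gini) decrease."""

    def provider(X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            n_jobs=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        forest.fit(X, y)
        return forest.feature_importances_

    return provider


def shadow_augment(
    X: np.ndarray, rng: np.random.Generator, min_shadows: int = 1
) -> np.ndarray:
    """Append one independently row-permuted copy of each column.

    With ``min_shadows`` > d, extra shadows are drawn by permuting
    columns cycled from X, so the max-shadow reference never rests on
    too few decoys (the selection loop uses 5, as the reference
    implementations do).
    """
    X = np.asarray(X)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least two rows to permute")
    n_shadows = max(d, min_shadows)
    shadows = np.empty((n, n_shadows), dtype=X.dtype)
    for j in range(n_shadows):  # fixed column order for reproducibility
        shadows[:, j] = X[rng.permutation(n), j % d]
    return np.hstack([X, shadows])


def boruta_run(
    X: np.ndarray,
    y: np.ndarray,
    config: SelectionConfig | None = None,
    importance_provider: ImportanceProvider | None = None,
) -> SelectionResult:
    """Run the shadow-feature selection loop on one training set."""
    config = config or SelectionConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    d = X.shape[1]
    if d == 0:
        return SelectionResult(np.array([], dtype=object), np.zeros(0, int), np.zeros(0, int), 0)
    if np.all(X.std(axis=0) == 0):
        raise ValueError("all features are constant")
    provider = importance_provider or rf_importance(config.ensemble_size)
    rng = np.random.default_rng(config.seed)

    status = np.array(["tentative"] * d, dtype=object)
    hits = np.zeros(d, dtype=int)
    trials = np.zeros(d, dtype=int)
    iteration = 0
    while iteration < config.max_iterations and np.any(status == "tentative"):
        iteration += 1
        active = status == "tentative"
        # confirmed features stay in the model (they shape the forest and
        # its shadows); only rejected ones leave the data
        kept = active | (status == "confirmed")
        Xa = shadow_augment(X[:, kept], rng, min_shadows=5)
        scores = provider(Xa, y, rng)
        if scores.shape[0] != Xa.shape[1]:
            raise ValueError(
                f"importance provider returned {scores.shape[0]} scores "
                f"for {Xa.shape[1]} columns"
            )
        k = int(kept.sum())
        best_shadow = scores[k:].max()
        hit_kept = scores[:k] > best_shadow
        active_in_kept = active[kept]
        hits[active] += hit_kept[active_in_kept]
        trials[active] += 1
        # binomial test of cumulative hits against chance (1/2); confirm
        # and reject branches each one-sided, Bonferroni over all original
        # features (a shrinking denominator would loosen the late-iteration
        # threshold exactly when few, spuriously persistent, features remain)
        thr = config.alpha / d
        idx = np.flatnonzero(active)
        p_up = stats.binom.sf(hits[idx] - 1, trials[idx], 0.5)
        p_dn = stats.binom.cdf(hits[idx], trials[idx], 0.5)
        status[idx[p_dn < thr]] = "rejected"
        status[idx[p_up < thr]] = "confirmed"
    return SelectionResult(status, hits, trials, iteration)


def stability_test(
    selected_sets: Sequence[Sequence[int]],
    modality_dim: int,
    alpha: float = 0.05,
    feature_names: Sequence[str] | None = None,
) -> StabilityReport:
    """Binomial test of per-feature selection frequency across runs.

    ``selected_sets`` holds the selected index set of each of the N runs
    (typically the K folds of one repeated-CV experiment).
    """
    if len(selected_sets) == 0:
        raise ValueError("need at least one run")
    N = len(selected_sets)
    counts = np.zeros(modality_dim, dtype=int)
    for s in selected_sets:
        idx = np.asarray(list(s), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= modality_dim):
            raise ValueError("selected index outside the feature universe")
        counts[idx] += 1
    p_rate = float(np.mean([len(set(s)) / modality_dim for s in selected_sets]))
    # upper tail P(X >= count) under Binomial(N, p_rate)
    p_value = stats.binom.sf(counts - 1, N, p_rate)
    p_value = np.clip(p_value, 0.0, 1.0)
    _, p_holm, _, _ = multipletests(p_value, alpha=alpha, method="holm")
    p_holm = np.maximum(p_holm, p_value)
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"f{j:04d}" for j in range(modality_dim)]
    )
    return StabilityReport(
        feature_names=names,
        frequency=counts / N,
        counts=counts,
        n_runs=N,
        p_rate=p_rate,
        p_value=p_value,
        p_holm=p_holm,
        significant=p_holm < alpha,
    )


def combine_stability(reports: Sequence[StabilityReport]) -> StabilityReport:
    """Intersection rule over independent experiments: a feature is flagged
    only if significant in every experiment's own stability test."""
    if not reports:
        raise ValueError("no reports to combine")
    base = reports[0]
    inter = np.logical_and.reduce([r.significant for r in reports])
    freq = np.mean([r.frequency for r in reports], axis=0)
    return StabilityReport(
        feature_names=base.feature_names,
        frequency=freq,
        counts=np.sum([r.counts for r in reports], axis=0),
        n_runs=sum(r.n_runs for r in reports),
        p_rate=float(np.mean([r.p_rate for r in reports])),
        p_value=np.max([r.p_value for r in reports], axis=0),
        p_holm=np.max([r.p_holm for r in reports], axis=0),
        significant=inter,
        intersection=inter,
    )


def selection_percentages(
    avg_sizes: dict[str, float], pool_sizes: dict[str, int]
) -> dict[str, float]:
    """Average selected-subset size as a percentage of the candidate pool."""
    out = {}
    for m, size in avg_sizes.items():
        pool = pool_sizes[m]
        if pool <= 0:
            raise ValueError(f"empty candidate pool for {m!r}")
        out[m] = 100.0 * size / pool
    return out
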