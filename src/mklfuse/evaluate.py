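"""Metrics and the repeated nested cross-validation protocol.

Outer stratified K-fold (default 10) estimates generalization; within
each outer training fold the feature selector runs per modality, scalers
and kernels are fitted, and the kernel weights and SVM penalty C are
grid-searched on an inner stratified CV (default 5 folds) by mean
validation AUC.  The winning (w, C) is retrained on the full outer
training fold, calibrated by Platt scaling on the inner validation
scores, and evaluated once on the held-out fold.  The whole procedure is
repeated R times (default 10) with fresh fold divisions; all modalities
share the same subject division within a fold, so model comparisons are
paired.  Threshold metrics use the probability cutoff 0.5; AUC is the
rank-based (Mann-Whitney) area with half credit for ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ttest_rel, wilcoxon
from sklearn.model_selection import StratifiedKFold

from .combat import apply_combat, fit_combat
from .kernels import KernelSpec, compute_gram, standardize_apply, standardize_fit
from .mkl import TrainConfig, decision_scores, fit_platt, grid_search, solve_dual
from .selection import (
    SelectionConfig,
    StabilityReport,
    boruta_run,
    combine_stability,
    rf_importance,
    stability_test,
)
from .synthetic import Cohort

#: Kernel assignment of the final fused model: Gaussian kernels for the
#: structural and functional tables, linear for the diffusion table.
DEFAULT_KERNELS = {
    "sMRI": KernelSpec("rbf"),
    "DTI": KernelSpec("linear"),
    "rsfMRI": KernelSpec("rbf"),
}


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float | None = None

    def as_dict(self) -> dict:
        out = {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "f1": self.f1,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def confusion_and_metrics(
    labels: np.ndarray, probabilities: np.ndarray, cutoff: float = 0.5
) -> MetricsReport:
    """Confusion counts and the four threshold metrics at ``cutoff``.

    Condition positive is the case class (+1); a predicted probability
    >= cutoff marks a predicted case.
    """
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=float)
    if labels.size == 0:
        raise ValueError("empty input")
    pred = probabilities >= cutoff
    pos = labels > 0
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    n = tp + tn + fp + fn
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
        f1=2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
    )


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC (normalized Mann-Whitney U, ties half credit)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels > 0]
    neg = scores[labels <= 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC requires both classes")
    r = rankdata(np.concatenate([pos, neg]))
    u = r[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


# ---------------------------------------------------------------------------
# protocol configuration


@dataclass
class CVPlan:
    outer_folds: int = 10
    inner_folds: int = 5
    repeats: int = 10
    seed: int = 0


@dataclass
class PipelineSettings:
    """Everything the per-fold pipeline needs besides the data."""

    kernel_specs: dict[str, KernelSpec] = field(
        default_factory=lambda: dict(DEFAULT_KERNELS)
    )
    harmonize: bool = False
    whole_sample_harmonize: bool = False  # fit ComBat on the whole dataset
    combat_covariates: tuple[str, ...] = ("age_months", "sex")
    select: bool = True
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    train: TrainConfig = field(default_factory=TrainConfig)


@dataclass
class ModelSpec:
    """One row of the comparison table."""

    name: str
    modalities: tuple[str, ...]
    kind: str = "mkl"  # 'mkl' | 'early' | 'oracle'
    kernel: KernelSpec | None = None  # early fusion's single kernel


def default_models(modalities: tuple[str, ...], settings: PipelineSettings,
                   include=("unimodal", "early", "bimodal", "trimodal")) -> list[ModelSpec]:
    models: list[ModelSpec] = []
    if "unimodal" in include:
        for m in modalities:
            for kind in ("linear", "rbf"):
                models.append(
                    ModelSpec(f"{m}+{kind.upper()}SVM", (m,), "mkl", KernelSpec(kind))
                )
    if "early" in include:
        for kind in ("linear", "rbf"):
            models.append(
                ModelSpec(f"early-fusion+{kind.upper()}SVM", modalities, "early",
                          KernelSpec(kind))
            )
    if "bimodal" in include and len(modalities) >= 3:
        for pair in combinations(modalities, 2):
            models.append(ModelSpec("MKL:" + "+".join(pair), pair, "mkl"))
    if "trimodal" in include:
        models.append(ModelSpec("MKL:" + "+".join(modalities), modalities, "mkl"))
    return models


@dataclass
class ExperimentReport:
    per_fold: pd.DataFrame  # repeat, fold, model, metrics, weights, C
    summary: pd.DataFrame  # mean metrics per model over folds x repeats
    stability: dict[str, StabilityReport]  # combined across repeats
    stability_per_repeat: dict[str, list[StabilityReport]]
    weight_grid: pd.DataFrame | None = None  # mean inner AUC per (w, C)


# ---------------------------------------------------------------------------
# per-fold machinery


def _harmonized_tables(cohort: Cohort, settings: PipelineSettings,
                       train_idx: np.ndarray, test_idx: np.ndarray):
    tables = {}
    for m, table in cohort.features.items():
        if not settings.harmonize:
            tables[m] = (
                table.iloc[train_idx].to_numpy(float),
                table.iloc[test_idx].to_numpy(float),
            )
            continue
        cov = cohort.covariates[list(settings.combat_covariates)]
        if settings.whole_sample_harmonize:
            model = fit_combat(table, cohort.batches, cov)
        else:
            model = fit_combat(
                table.iloc[train_idx], cohort.batches[train_idx], cov.iloc[train_idx]
            )
        tables[m] = tuple(
            apply_combat(
                model, table.iloc[idx], cohort.batches[idx], cov.iloc[idx]
            ).to_numpy(float)
            for idx in (train_idx, test_idx)
        )
    return tables


def _select_features(X_tr, y_tr, settings: PipelineSettings, seed: int):
    if not settings.select:
        return np.arange(X_tr.shape[1]), False
    cfg = SelectionConfig(
        max_iterations=settings.selection.max_iterations,
        alpha=settings.selection.alpha,
        ensemble_size=settings.selection.ensemble_size,
        seed=seed,
    )
    res = boruta_run(X_tr, y_tr, cfg, rf_importance(cfg.ensemble_size))
    sel = res.selected
    if sel.size == 0:
        # an empty all-relevant set would zero out the modality entirely;
        # fall back to the full candidate pool and let the weights decide
        return np.arange(X_tr.shape[1]), True
    return sel, False


def run_experiment(
    cohort: Cohort,
    settings: PipelineSettings | None = None,
    plan: CVPlan | None = None,
    models: list[ModelSpec] | None = None,
    collect_weight_grid: bool = False,
) -> ExperimentReport:
    """Repeated nested CV over a list of model specifications.

    All models within a fold share the same subject division, the same
    harmonization and the same per-modality selected features, so
    between-model differences are paired at fold level.
    """
    settings = settings or PipelineSettings()
    plan = plan or CVPlan()
    modalities = tuple(cohort.features.keys())
    if models is None:
        models = default_models(modalities, settings)
    y = cohort.labels
    rows: list[dict] = []
    sel_sets: dict[str, list[list[list[int]]]] = {m: [] for m in modalities}
    grid_acc: dict = {}

    for rep in range(plan.repeats):
        rep_seed = (plan.seed * 1000 + rep) % (2**31 - 1)
        skf = StratifiedKFold(plan.outer_folds, shuffle=True, random_state=rep_seed)
        rep_sets: dict[str, list[list[int]]] = {m: [] for m in modalities}
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            tables = _harmonized_tables(cohort, settings, tr, te)
            Xtr_sel, Xte_sel = {}, {}
            for mi, m in enumerate(modalities):
                X_tr, X_te = tables[m]
                sel, fellback = _select_features(
                    X_tr, y[tr], settings,
                    seed=(rep_seed * 97 + fold * 7 + mi) % (2**31 - 1),
                )
                rep_sets[m].append(sel.tolist() if not fellback else [])
                scaler = standardize_fit(X_tr[:, sel])
                Xtr_sel[m] = standardize_apply(scaler, X_tr[:, sel])
                Xte_sel[m] = standardize_apply(scaler, X_te[:, sel])
            for spec in models:
                row = _fit_eval_model(
                    spec, Xtr_sel, Xte_sel, y[tr], y[te], settings,
                    plan, rep_seed, grid_acc if collect_weight_grid else None,
                )
                row.update({"repeat": rep, "fold": fold, "model": spec.name})
                rows.append(row)
        for m in modalities:
            sel_sets[m].append(rep_sets[m])

    per_fold = pd.DataFrame(rows)
    metric_cols = ["accuracy", "sensitivity", "specificity", "f1", "auc"]
    summary = per_fold.groupby("model")[metric_cols].mean().reset_index()

    stability, per_repeat = {}, {}
    if settings.select:
        for m in modalities:
            reports = [
                stability_test(sets, cohort.features[m].shape[1],
                               feature_names=list(cohort.features[m].columns))
                for sets in sel_sets[m]
            ]
            per_repeat[m] = reports
            stability[m] = combine_stability(reports)

    weight_grid = None
    if grid_acc:
        weight_grid = (
            pd.DataFrame(
                [{**dict(k), "mean_auc": v[0] / v[1]} for k, v in grid_acc.items()]
            )
        )
    return ExperimentReport(per_fold, summary, stability, per_repeat, weight_grid)


def _fit_eval_model(spec, Xtr_sel, Xte_sel, y_tr, y_te, settings,
                    plan, rep_seed, grid_acc) -> dict:
    if spec.kind == "oracle":  # plumbing check: predicts the true label
        probs = (y_te > 0).astype(float)
        rep = confusion_and_metrics(y_te, probs)
        rep.auc = auc_score(y_te, probs)
        return {**rep.as_dict(), "C": np.nan, "weights": ""}

    if spec.kind == "early":
        X_tr = np.hstack([Xtr_sel[m] for m in spec.modalities])
        X_te = np.hstack([Xte_sel[m] for m in spec.modalities])
        blocks = {"all": (X_tr, X_te, spec.kernel)}
    else:
        blocks = {
            m: (Xtr_sel[m], Xte_sel[m],
                spec.kernel if spec.kernel is not None else settings.kernel_specs[m])
            for m in spec.modalities
        }

    train_kernels, cross_kernels = [], []
    for m, (X_tr, X_te, kspec) in blocks.items():
        if kspec.kind == "rbf" and kspec.gamma is None:
            from .kernels import median_heuristic_gamma

            kspec = KernelSpec("rbf", median_heuristic_gamma(X_tr))
        train_kernels.append(compute_gram(X_tr, X_tr, kspec, modality=m))
        cross_kernels.append(compute_gram(X_te, X_tr, kspec, modality=m))

    tcfg = TrainConfig(
        c_grid=settings.train.c_grid,
        weight_stride=settings.train.weight_stride,
        inner_folds=plan.inner_folds,
        tol=settings.train.tol,
        max_passes=settings.train.max_passes,
        seed=rep_seed,
    )
    gs = grid_search(train_kernels, y_tr, tcfg)
    if grid_acc is not None and spec.kind == "mkl" and len(spec.modalities) > 1:
        for _, r in gs.table.iterrows():
            key = tuple(
                [(f"w_{m}", r[f"w{i}"]) for i, m in enumerate(spec.modalities)]
                + [("C", r["C"]), ("model", spec.name)]
            )
            s, c = grid_acc.get(key, (0.0, 0))
            grid_acc[key] = (s + r["mean_auc"], c + 1)

    from .kernels import combine_kernels

    K_train = combine_kernels(train_kernels, gs.weights)
    K_cross = combine_kernels(cross_kernels, gs.weights)
    sol = solve_dual(K_train.values, y_tr, gs.C, tol=tcfg.tol,
                     max_passes=tcfg.max_passes, weights=gs.weights)

    # Platt calibration on inner-fold validation scores at the chosen (w, C)
    skf = StratifiedKFold(plan.inner_folds, shuffle=True, random_state=rep_seed)
    cal_scores = np.empty(len(y_tr))
    for itr, iva in skf.split(np.zeros(len(y_tr)), y_tr):
        isol = solve_dual(K_train.values[np.ix_(itr, itr)], y_tr[itr], gs.C,
                          tol=tcfg.tol, max_passes=tcfg.max_passes)
        cal_scores[iva] = (
            K_train.values[np.ix_(iva, itr)] @ (isol.alpha * y_tr[itr]) + isol.b
        )
    platt = fit_platt(cal_scores, y_tr)

    test_scores = decision_scores(sol, K_cross.values, y_tr)
    probs = platt.prob(test_scores)
    rep = confusion_and_metrics(y_te, probs)
    rep.auc = auc_score(y_te, test_scores)
    out = {**rep.as_dict(), "C": gs.C,
           "weights": "/".join(f"{w:.1f}" for w in gs.weights)}
    for m, w in zip(blocks.keys(), gs.weights):
        out[f"w_{m}"] = w
    return out


def run_baselines(
    cohort: Cohort,
    settings: PipelineSettings | None = None,
    plan: CVPlan | None = None,
    include=("unimodal", "early", "bimodal", "trimodal"),
) -> ExperimentReport:
    """Full paired comparison table: unimodal single-kernel SVMs (linear
    and RBF), early fusion, every bimodal fusion and the trimodal model,
    all on the same fold divisions."""
    settings = settings or PipelineSettings()
    models = default_models(tuple(cohort.features), settings, include=include)
    return run_experiment(cohort, settings, plan, models)


def compare_models(per_fold: pd.DataFrame, model_a: str, model_b: str,
                   metric: str = "auc", test: str = "ttest") -> dict:
    """Paired comparison of two pipelines over fold-level metric values."""
    a = per_fold[per_fold["model"] == model_a].sort_values(["repeat", "fold"])[metric]
    b = per_fold[per_fold["model"] == model_b].sort_values(["repeat", "fold"])[metric]
    a, b = a.to_numpy(), b.to_numpy()
    if len(a) != len(b):
        raise ValueError("fold tables are not paired")
    if test == "ttest":
        stat, p = ttest_rel(a, b)
    elif test == "wilcoxon":
        stat, p = wilcoxon(a, b) if np.any(a != b) else (0.0, 1.0)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"mean_diff": float(np.mean(a - b)), "stat": float(stat), "p": float(p)}
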