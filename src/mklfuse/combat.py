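"""Location-scale empirical-Bayes batch harmonization (parametric ComBat).

Removes additive and multiplicative scanner/batch effects from a
subjects x features table while protecting biological covariates
(age, sex by default).  The model per feature f and subject i of batch b::

    x_ifb = alpha_f + X_i beta_f + gamma_bf + delta_bf * eps_ifb

Batch location ``gamma`` and scale ``delta^2`` are estimated per
(batch, feature) and shrunk toward batch-level priors by empirical
Bayes: a normal prior for gamma and an inverse-gamma prior for delta^2,
hyperparameters by method of moments, conditional posterior means by
fixed-point iteration.  Harmonized values are the standardized residuals
corrected by ``(. - gamma*) / delta*`` with the grand mean and covariate
effects restored.

The diagnosis label must never be passed as a covariate: it would be
treated as a batch-orthogonal effect to protect only if included, and
regressing it out is the one mistake this API makes hard (the ``fit``
signature takes covariates explicitly, not a full design).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CombatModel:
    """Fitted harmonization parameters, reusable on new subjects."""

    batch_levels: list  # batch ids seen at fit time
    grand_mean: np.ndarray  # (d,)
    beta: np.ndarray  # (p, d) covariate coefficients
    var_pooled: np.ndarray  # (d,)
    gamma_star: np.ndarray  # (B, d) EB additive estimates
    delta2_star: np.ndarray  # (B, d) EB multiplicative estimates
    gamma_bar: np.ndarray  # (B,) prior means
    tau2: np.ndarray  # (B,) prior variances for gamma
    a_prior: np.ndarray  # (B,) inverse-gamma shape
    b_prior: np.ndarray  # (B,) inverse-gamma rate
    covariate_names: list[str]
    feature_names: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            # native Python types so integer batch ids survive the round trip
            "batch_levels": [
                b.item() if hasattr(b, "item") else b for b in self.batch_levels
            ],
            "covariate_names": self.covariate_names,
            "feature_names": self.feature_names,
        }
        for key in (
            "grand_mean", "beta", "var_pooled", "gamma_star", "delta2_star",
            "gamma_bar", "tau2", "a_prior", "b_prior",
        ):
            payload[key] = getattr(self, key).tolist()
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CombatModel":
        payload = json.loads(Path(path).read_text())
        arrays = {
            key: np.asarray(payload[key], dtype=float)
            for key in (
                "grand_mean", "beta", "var_pooled", "gamma_star", "delta2_star",
                "gamma_bar", "tau2", "a_prior", "b_prior",
            )
        }
        return cls(
            batch_levels=payload["batch_levels"],
            covariate_names=payload["covariate_names"],
            feature_names=payload["feature_names"],
            **arrays,
        )


def _design_matrix(
    batch: np.ndarray, levels: list, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, np.ndarray]:
    """One indicator column per batch plus numeric covariate columns."""
    B = np.zeros((len(batch), len(levels)))
    for j, lev in enumerate(levels):
        B[:, j] = batch == lev
    if covariates is None or covariates.shape[1] == 0:
        return B, np.zeros((len(batch), 0))
    cov = pd.get_dummies(covariates, drop_first=True).to_numpy(dtype=float)
    return B, cov


def _postmean(g_hat, g_bar, n, d_old, t2):
    return (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(s_data, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=100):
    """Fixed-point iteration for the conditional posterior means."""
    n = float(s_data.shape[0])
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((s_data - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def fit_combat(
    table: pd.DataFrame,
    batch: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> CombatModel:
    """Estimate the harmonization model on a training table.

    Parameters
    ----------
    table : subjects x features, no missing values.
    batch : per-subject batch/scanner id; every batch needs >= 2 subjects.
    covariates : biological covariates to protect (categoricals are
        dummy-coded); never include the diagnosis label.
    """
    X = table.to_numpy(dtype=float)
    batch = np.asarray(batch)
    if np.isnan(X).any():
        raise ValueError("missing values are not supported")
    flat = np.flatnonzero(X.var(axis=0) == 0)
    if flat.size:
        names = [str(table.columns[j]) for j in flat[:5]]
        raise ValueError(f"constant feature(s) within standardization: {names}")
    levels = sorted(pd.unique(batch).tolist())
    counts = {lev: int(np.sum(batch == lev)) for lev in levels}
    singles = [lev for lev, c in counts.items() if c < 2]
    if singles:
        raise ValueError(f"batches with <2 subjects: {singles}")

    Bm, Cm = _design_matrix(batch, levels, covariates)
    design = np.hstack([Bm, Cm])
    n, d = X.shape
    nb = len(levels)
    # joint OLS of batch indicators + covariates, feature-wise
    coef, *_ = np.linalg.lstsq(design, X, rcond=None)
    batch_means = coef[:nb]  # (B, d)
    beta = coef[nb:]  # (p, d)
    frac = np.array([counts[lev] / n for lev in levels])
    grand_mean = frac @ batch_means
    resid = X - design @ coef
    var_pooled = (resid ** 2).mean(axis=0)
    zero_var = np.flatnonzero(var_pooled <= 0)
    if zero_var.size:
        names = [table.columns[j] for j in zero_var[:5]]
        raise ValueError(f"constant feature(s) within standardization: {names}")

    stand_mean = grand_mean[None, :] + Cm @ beta
    s_data = (X - stand_mean) / np.sqrt(var_pooled)[None, :]

    gamma_hat = np.empty((nb, d))
    delta_hat = np.empty((nb, d))
    for j, lev in enumerate(levels):
        rows = batch == lev
        gamma_hat[j] = s_data[rows].mean(axis=0)
        delta_hat[j] = s_data[rows].var(axis=0, ddof=1)

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    m = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    a_prior = (2.0 * s2 + m ** 2) / s2
    b_prior = (m * s2 + m ** 3) / s2

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta_hat)
    if nb == 1:
        # a single batch carries no batch effect to remove; make apply an
        # exact no-op instead of dividing by a noise-level scale estimate
        gamma_star[:] = 0.0
        delta2_star[:] = 1.0
    else:
        for j, lev in enumerate(levels):
            rows = batch == lev
            gamma_star[j], delta2_star[j] = _it_sol(
                s_data[rows], gamma_hat[j], delta_hat[j],
                gamma_bar[j], tau2[j], a_prior[j], b_prior[j],
            )

    cov_names = (
        pd.get_dummies(covariates, drop_first=True).columns.tolist()
        if covariates is not None and covariates.shape[1]
        else []
    )
    return CombatModel(
        batch_levels=levels,
        grand_mean=grand_mean,
        beta=beta,
        var_pooled=var_pooled,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar,
        tau2=tau2,
        a_prior=a_prior,
        b_prior=b_prior,
        covariate_names=cov_names,
        feature_names=table.columns.tolist(),
    )


def apply_combat(
    model: CombatModel,
    table: pd.DataFrame,
    batch: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Harmonize a table with a fitted model (same or held-out subjects).

    Every batch id must have been seen at fit time; there is no
    reference-batch extrapolation for unseen scanners.
    """
    if list(table.columns) != model.feature_names:
        raise ValueError("feature columns do not match the fitted model")
    batch = np.asarray(batch)
    unseen = sorted(set(batch) - set(model.batch_levels))
    if unseen:
        raise ValueError(f"unseen batch id(s): {unseen}")
    X = table.to_numpy(dtype=float)
    if model.covariate_names:
        if covariates is None:
            raise ValueError("model was fitted with covariates; none given")
        # dummy-code without dropping, then align to the fitted columns, so
        # a test split missing a category still maps levels correctly
        Cm = pd.get_dummies(covariates)
        Cm = Cm.reindex(columns=model.covariate_names, fill_value=0.0)
        Cm = Cm.to_numpy(dtype=float)
    else:
        Cm = np.zeros((len(X), 0))
    stand_mean = model.grand_mean[None, :] + Cm @ model.beta
    s = (X - stand_mean) / np.sqrt(model.var_pooled)[None, :]
    out = np.empty_like(s)
    for j, lev in enumerate(model.batch_levels):
        rows = batch == lev
        if not rows.any():
            continue
        out[rows] = (s[rows] - model.gamma_star[j][None, :]) / np.sqrt(
            model.delta2_star[j]
        )[None, :]
    out = out * np.sqrt(model.var_pooled)[None, :] + stand_mean
    return pd.DataFrame(out, index=table.index, columns=table.columns)
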