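"""Plate/batch diagnostics and parametric empirical-Bayes location/scale correction.

The correction follows the classical two-step empirical-Bayes batch model:
per-probe standardization against the grand mean and pooled variance, then
per-batch per-probe location (gamma) and scale (delta^2) effects shrunk
toward batch-level normal and inverse-gamma priors via moment-matched
iterative estimates, and finally removed. Fitting and application are
separated so a model fit on one table can be audited or applied elsewhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .screen import NormalizedTable

__all__ = ["BatchModel", "BatchDiagnostic", "pca_batch_diag", "combat_fit", "combat_adjust", "log2_transform"]


def log2_transform(values: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(value + pseudocount); the scale on which batch correction operates."""
    return np.log2(values + pseudocount)


@dataclass
class BatchDiagnostic:
    """PCA of wells with per-component batch association.

    ``batch_assoc_r2[j]`` is the one-way-ANOVA R^2 of PC j scores on the
    batch label: the fraction of that component's variance explained by
    batch membership.
    """

    pc_scores: pd.DataFrame
    variance_explained: np.ndarray
    batch_assoc_r2: np.ndarray


def pca_batch_diag(
    values: NormalizedTable | pd.DataFrame,
    batches: pd.Series,
    k: int = 5,
    log: bool = True,
) -> BatchDiagnostic:
    """Quantify batch structure: PCA of (log) values, then per-PC batch R^2."""
    mat = values.values if isinstance(values, NormalizedTable) else values
    batches = pd.Series(batches).loc[mat.index]
    if batches.nunique() < 2:
        raise ValueError("batch association requires at least 2 batches")
    if k > min(mat.shape):
        raise ValueError(f"k={k} exceeds min(wells, probes)={min(mat.shape)}")
    X = log2_transform(mat).to_numpy() if log else mat.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    r2 = np.empty(k)
    codes = pd.Categorical(batches).codes
    for j in range(k):
        y = scores[:, j]
        grand = y.mean()
        ss_tot = ((y - grand) ** 2).sum()
        ss_b = sum(
            len(y[codes == b]) * (y[codes == b].mean() - grand) ** 2
            for b in np.unique(codes)
        )
        r2[j] = ss_b / ss_tot if ss_tot > 0 else 0.0
    return BatchDiagnostic(
        pc_scores=pd.DataFrame(
            scores, index=mat.index, columns=[f"PC{j + 1}" for j in range(k)]
        ),
        variance_explained=pca.explained_variance_ratio_,
        batch_assoc_r2=r2,
    )


@dataclass
class BatchModel:
    """Fitted location/scale batch model (standardization + shrunk effects)."""

    grand_mean: pd.Series  # per-probe
    pooled_var: pd.Series  # per-probe, from full-model residuals
    gamma_star: pd.DataFrame  # batch x probe shrunk location
    delta2_star: pd.DataFrame  # batch x probe shrunk scale (>0)
    batch_levels: list[str]
    constant_probes: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "batch_levels": self.batch_levels,
            "constant_probes": self.constant_probes,
            "grand_mean": self.grand_mean.to_dict(),
            "pooled_var": self.pooled_var.to_dict(),
            "gamma_star": self.gamma_star.to_dict(orient="index"),
            "delta2_star": self.delta2_star.to_dict(orient="index"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _aprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (m * s2 + m**3) / s2


def _eb_iterate(
    Z: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Moment-matched iterative EB estimates for one batch (vector over probes)."""
    n = Z.shape[0]
    g_new, d_new = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_old, d_old = g_new, d_new
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        ss = ((Z - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * ss + b) / (n / 2 + a - 1)
        change = max(
            np.abs(g_new - g_old).max(initial=0.0), np.abs(d_new - d_old).max(initial=0.0)
        )
        if change < tol:
            break
    return g_new, d_new


def combat_fit(
    values: pd.DataFrame,
    batches: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> BatchModel:
    """Fit the parametric empirical-Bayes batch model on log-scale values.

    Probes with zero variance are flagged and passed through uncorrected
    (with a warning) rather than failing the run. With a single batch the
    model is the identity: shrinkage targets equal the estimates and there
    is nothing to remove.
    """
    batches = pd.Series(batches).loc[values.index].astype(str)
    levels = sorted(batches.unique())
    sizes = batches.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"batches of size 1 cannot be modeled: {list(small.index)}")

    Y = values.to_numpy(dtype=float)
    n, G = Y.shape
    var_all = Y.var(axis=0)
    constant = values.columns[var_all <= 1e-12]
    if len(constant):
        warnings.warn(
            f"{len(constant)} zero-variance probe(s) pass through uncorrected",
            stacklevel=2,
        )
    keep = values.columns[var_all > 1e-12]

    if len(levels) == 1:
        gm = pd.Series(Y.mean(axis=0), index=values.columns)
        return BatchModel(
            grand_mean=gm,
            pooled_var=pd.Series(np.ones(G), index=values.columns),
            gamma_star=pd.DataFrame(0.0, index=levels, columns=values.columns),
            delta2_star=pd.DataFrame(1.0, index=levels, columns=values.columns),
            batch_levels=levels,
            constant_probes=list(constant),
        )

    Yk = values[keep].to_numpy(dtype=float)
    onehot = pd.get_dummies(batches).loc[:, levels].to_numpy(dtype=float)
    X = onehot if covariates is None else np.hstack([onehot, covariates.to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(X, Yk, rcond=None)
    frac = sizes.loc[levels].to_numpy(dtype=float) / n
    grand = frac @ beta[: len(levels)]  # size-weighted batch means (+0 covariates)
    resid = Yk - X @ beta
    pooled = (resid**2).mean(axis=0)
    pooled = np.maximum(pooled, 1e-12)

    stand_mean = np.outer(np.ones(n), grand)
    if covariates is not None:
        stand_mean = stand_mean + covariates.to_numpy(dtype=float) @ beta[len(levels):]
    Z = (Yk - stand_mean) / np.sqrt(pooled)

    gamma = pd.DataFrame(0.0, index=levels, columns=values.columns)
    delta2 = pd.DataFrame(1.0, index=levels, columns=values.columns)
    for lev in levels:
        Zi = Z[(batches == lev).to_numpy()]
        g_hat = Zi.mean(axis=0)
        d_hat = Zi.var(axis=0, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        if t2 <= 0 or d_hat.var(ddof=1) <= 0:
            # degenerate prior (e.g. a single informative probe): no shrinkage
            g_star, d_star = g_hat, np.maximum(d_hat, 1e-12)
        else:
            a, b = _aprior(d_hat), _bprior(d_hat)
            g_star, d_star = _eb_iterate(Zi, g_hat, np.maximum(d_hat, 1e-12), g_bar, t2, a, b)
        gamma.loc[lev, keep] = g_star
        delta2.loc[lev, keep] = np.maximum(d_star, 1e-12)

    gm = pd.Series(Y.mean(axis=0), index=values.columns)
    gm[keep] = grand
    return BatchModel(
        grand_mean=gm,
        pooled_var=pd.Series(pooled, index=keep).reindex(values.columns, fill_value=1.0),
        gamma_star=gamma,
        delta2_star=delta2,
        batch_levels=levels,
        constant_probes=list(constant),
    )


def combat_adjust(
    values: pd.DataFrame, model: BatchModel, batches: pd.Series
) -> pd.DataFrame:
    """Remove fitted batch effects: back-standardize with shrunk gamma/delta.

    corrected = (Z - gamma*) / sqrt(delta2*) * pooled SD + grand mean; flagged
    constant probes are returned unchanged.
    """
    batches = pd.Series(batches).loc[values.index].astype(str)
    unseen = set(batches.unique()) - set(model.batch_levels)
    if unseen:
        raise ValueError(f"unseen batch label(s): {sorted(unseen)}")
    if len(model.batch_levels) == 1:
        return values.copy()

    keep = [c for c in values.columns if c not in set(model.constant_probes)]
    Y = values[keep].to_numpy(dtype=float)
    gm = model.grand_mean[keep].to_numpy()
    sd = np.sqrt(model.pooled_var[keep].to_numpy())
    Z = (Y - gm) / sd
    out = values.copy()
    arr = out[keep].to_numpy(dtype=float)
    for lev in model.batch_levels:
        mask = (batches == lev).to_numpy()
        if not mask.any():
            continue
        g = model.gamma_star.loc[lev, keep].to_numpy()
        d = model.delta2_star.loc[lev, keep].to_numpy()
        arr[mask] = (Z[mask] - g) / np.sqrt(d) * sd + gm
    out[keep] = arr
    return out
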