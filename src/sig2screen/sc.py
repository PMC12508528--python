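"""Single-cell signature analysis: QC, module scores, stratification and tests.

Cells live in an :class:`anndata.AnnData` with raw counts in ``X`` and
log-normalized expression in ``layers['lognorm']``. The module score is the
binned-control enrichment: mean signature-gene expression minus the mean of
expression-matched control genes, so unstructured data centers at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats

from .ranking import Signature

__all__ = [
    "flag_mito",
    "filter_cells",
    "lognormalize",
    "module_score",
    "stratify",
    "composition_test",
    "group_compare",
    "correlate",
    "patient_aggregate",
    "spot_coexpression",
]


def flag_mito(adata: AnnData, prefixes: tuple[str, ...] = ("MT-", "mt-")) -> None:
    """Flag mitochondrial genes by symbol prefix (case-sensitive), in place."""
    adata.var["mito"] = adata.var_names.str.startswith(prefixes)


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def filter_cells(
    adata: AnnData, min_genes: int = 200, max_mito_frac: float = 0.30
) -> tuple[AnnData, dict]:
    """QC filter: drop cells with few detected genes or high mitochondrial content.

    Keeps cells with detected-gene count >= ``min_genes`` and mitochondrial
    count fraction <= ``max_mito_frac``. Returns the filtered view (copied)
    and a report of cells kept/dropped per criterion. Idempotent.
    """
    if "mito" not in adata.var:
        flag_mito(adata)
    X = _dense(adata.X)
    n_genes = (X > 0).sum(axis=1)
    totals = X.sum(axis=1)
    mito_counts = X[:, adata.var["mito"].to_numpy().astype(bool)].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)
    low_genes = n_genes < min_genes
    high_mito = mito_frac > max_mito_frac
    keep = ~(low_genes | high_mito)
    report = {
        "n_input": int(adata.n_obs),
        "kept": int(keep.sum()),
        "dropped_low_genes": int(low_genes.sum()),
        "dropped_high_mito": int(high_mito.sum()),
    }
    if not keep.any():
        raise ValueError(f"all cells dropped by QC: {report}")
    return adata[keep].copy(), report


def lognormalize(adata: AnnData, scale: float = 1e4) -> AnnData:
    """Library-size normalization: lognorm = ln(1 + scale * count / cell_total)."""
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("zero-total cell(s); run filter_cells first")
    adata.layers["lognorm"] = np.log1p(scale * X / totals[:, None])
    return adata


def _require_lognorm(adata: AnnData) -> np.ndarray:
    if "lognorm" not in adata.layers:
        raise ValueError("run lognormalize first (layers['lognorm'] missing)")
    return np.asarray(adata.layers["lognorm"])


def module_score(
    adata: AnnData,
    signature: Signature | list[str],
    nbin: int = 24,
    nctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control module score per cell.

    All genes are ranked by mean expression across cells and cut into
    ``nbin`` equal-size bins; for each signature gene, ``nctrl`` control
    genes are sampled (seeded) from its bin. The score is the per-cell mean
    over signature genes minus the per-cell mean over the pooled controls.
    """
    genes = signature.genes if isinstance(signature, Signature) else list(signature)
    name = signature.name if isinstance(signature, Signature) else "module"
    if nbin < 2:
        raise ValueError("nbin must be >= 2")
    L = _require_lognorm(adata)
    var_names = adata.var_names
    present = [g for g in genes if g in var_names]
    missing = [g for g in genes if g not in var_names]
    if not present:
        raise ValueError(f"no signature gene found in data; missing: {missing}")
    if missing:
        warnings.warn(f"signature genes absent from data: {missing}", stacklevel=2)

    gene_means = L.mean(axis=0)
    # deterministic equal-size bins: rank genes by mean, tie-break by index
    order = np.lexsort((np.arange(len(gene_means)), gene_means))
    bins = np.empty(len(gene_means), dtype=int)
    bins[order] = (np.arange(len(gene_means)) * nbin) // len(gene_means)

    rng = np.random.default_rng(seed)
    gene_idx = {g: i for i, g in enumerate(var_names)}
    ctrl: set[int] = set()
    for g in present:
        b = bins[gene_idx[g]]
        pool = np.flatnonzero(bins == b)
        take = min(nctrl, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    sig_idx = [gene_idx[g] for g in present]
    ctrl_idx = sorted(ctrl)
    score = L[:, sig_idx].mean(axis=1) - L[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=adata.obs_names, name=f"{name}_score")


def stratify(
    scores: pd.Series, rule: str = "median", threshold: float | None = None
) -> pd.Series:
    """Split units into 'high'/'low' by median (> median is high) or a threshold."""
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise ValueError("need at least 2 units to stratify")
    if rule == "median":
        cut = scores.median()
        if scores.nunique() == 1:
            raise ValueError("all scores identical; use rule='threshold' with a cutoff")
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule requires a cutoff")
        cut = threshold
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return pd.Series(
        np.where(scores > cut, "high", "low"), index=scores.index, name="group"
    )


def composition_test(labels: pd.Series, types: pd.Series) -> dict:
    """Cell-type composition per group with a Pearson chi-square test.

    Returns per-group proportions (each summing to 1), the contingency
    table, the chi-square statistic (no continuity correction), df and p.
    Attaches a warning flag when any expected cell count is below 1.
    """
    labels, types = pd.Series(labels), pd.Series(types)
    tab = pd.crosstab(labels, types)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need >= 2 groups and >= 2 cell types")
    chi2, p, dof, expected = stats.chi2_contingency(tab.to_numpy(), correction=False)
    props = tab.div(tab.sum(axis=1), axis=0)
    return {
        "table": tab,
        "proportions": props,
        "chi2": float(chi2),
        "df": int(dof),
        "p_value": float(p),
        "low_expected": bool((expected < 1).any()),
    }


def group_compare(values: pd.Series, labels: pd.Series) -> dict:
    """Two-sided Mann-Whitney comparison of a value between high and low groups.

    Uses the exact null for small tie-free groups (both n <= 8), the normal
    approximation with tie correction otherwise. Returns U for the 'high'
    group, the p value and the AUC-equivalent U/(n1*n2).
    """
    values, labels = pd.Series(values), pd.Series(labels).loc[pd.Series(values).index]
    x = values[labels == "high"].to_numpy(dtype=float)
    y = values[labels == "low"].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "auc": float(res.statistic) / (len(x) * len(y)),
        "n_high": len(x),
        "n_low": len(y),
        "method": method,
    }


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with its p value."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def patient_aggregate(
    adata: AnnData,
    genes: list[str],
    cell_subset: pd.Series | None = None,
    patient_key: str = "patient",
) -> pd.Series:
    """Per-patient mean log-normalized expression over a gene set and cell subset.

    Patients with no cell in the subset are dropped with a warning, mirroring
    the convention of using each patient's own cells of a given type as that
    patient's expression level.
    """
    L = _require_lognorm(adata)
    idx = [list(adata.var_names).index(g) for g in genes if g in adata.var_names]
    if not idx:
        raise ValueError(f"none of {genes} found in data")
    mask = (
        np.ones(adata.n_obs, dtype=bool)
        if cell_subset is None
        else pd.Series(cell_subset).loc[adata.obs_names].to_numpy(dtype=bool)
    )
    if not mask.any():
        raise ValueError("cell subset is empty")
    vals = L[np.ix_(mask, idx)].mean(axis=1)
    patients = adata.obs[patient_key].to_numpy()[mask]
    out = pd.Series(vals).groupby(patients).mean()
    all_patients = set(adata.obs[patient_key].unique())
    dropped = all_patients - set(out.index)
    if dropped:
        warnings.warn(f"patients with no cell in subset dropped: {sorted(dropped)}", stacklevel=2)
    out.index.name = patient_key
    return out.rename("mean_expression")


def spot_coexpression(spots: pd.DataFrame, gene_a: str, gene_b: str) -> dict:
    """Spatial coexpression: spots where both transcripts are detected.

    A spot is 'both' iff count_a > 0 and count_b > 0; the coexpression
    fraction is |both| / n_spots.
    """
    for g in (gene_a, gene_b):
        if g not in spots.columns:
            raise KeyError(f"gene {g!r} absent from spot matrix")
    a = spots[gene_a].to_numpy() > 0
    b = spots[gene_b].to_numpy() > 0
    labels = np.select(
        [a & b, a & ~b, ~a & b], ["both", "a_only", "b_only"], default="none"
    )
    return {
        "labels": pd.Series(labels, index=spots.index, name="coexpression"),
        "fraction_both": float((a & b).mean()),
        "n_spots": int(len(spots)),
    }
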