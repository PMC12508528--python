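"""Reference-projection cell-type classifier for MDSC identification.

An annotated reference is log-normalized, per-gene standardized and
decomposed by PCA. For each class the informative components — those whose
scores separate the class from the rest (Wilcoxon rank-sum, BH-adjusted) —
feed a one-vs-rest probabilistic linear (logistic) classifier. Query cells
are projected into the frozen reference space (never re-fit) and labeled by
the class with maximal probability, or 'unassigned' when no class clears
the probability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from .sc import lognormalize

__all__ = ["ProjectionModel", "train", "project", "predict"]

UNASSIGNED = "unassigned"


@dataclass
class ProjectionModel:
    """Frozen reference space plus per-class classifiers."""

    gene_list: list[str]
    center: np.ndarray  # per-gene mean of reference lognorm
    scale: np.ndarray  # per-gene SD (floored)
    loadings: np.ndarray  # gene x PC
    selected_pcs: dict[str, list[int]]
    classifiers: dict[str, LogisticRegression]
    classes: list[str]
    prob_threshold: float = 0.55
    training_scores: np.ndarray | None = None


def _lognorm_matrix(adata: AnnData) -> np.ndarray:
    if "lognorm" not in adata.layers:
        lognormalize(adata)
    return np.asarray(adata.layers["lognorm"])


def train(
    reference: AnnData,
    label_key: str = "true_type",
    n_pcs: int = 30,
    pc_select_alpha: float = 0.05,
    prob_threshold: float = 0.55,
    min_cells_per_class: int = 20,
    seed: int = 0,
) -> ProjectionModel:
    """Fit the reference projection space and one-vs-rest classifiers.

    For each class, PCs whose scores differ between the class and the rest
    (two-sided Wilcoxon rank-sum, BH-adjusted p < ``pc_select_alpha``) are
    selected; a logistic classifier is fit on those scores.
    """
    labels = reference.obs[label_key].astype(str)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    small = labels.value_counts()[lambda s: s < min_cells_per_class]
    if len(small):
        raise ValueError(f"classes below {min_cells_per_class} cells: {dict(small)}")

    L = _lognorm_matrix(reference)
    center = L.mean(axis=0)
    scale = np.maximum(L.std(axis=0), 1e-8)
    Z = (L - center) / scale
    n_pcs = min(n_pcs, min(Z.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # gene x PC

    selected: dict[str, list[int]] = {}
    classifiers: dict[str, LogisticRegression] = {}
    for cls in classes:
        mask = (labels == cls).to_numpy()
        pvals = np.array(
            [stats.ranksums(scores[mask, j], scores[~mask, j]).pvalue for j in range(n_pcs)]
        )
        padj = multipletests(pvals, method="fdr_bh")[1]
        pcs = list(np.flatnonzero(padj < pc_select_alpha))
        if not pcs:
            raise ValueError(
                f"no informative PC for class {cls!r}; increase n_pcs or check separation"
            )
        clf = LogisticRegression(max_iter=1000, random_state=seed)
        clf.fit(scores[:, pcs], mask.astype(int))
        selected[cls] = pcs
        classifiers[cls] = clf

    return ProjectionModel(
        gene_list=list(reference.var_names),
        center=center,
        scale=scale,
        loadings=loadings,
        selected_pcs=selected,
        classifiers=classifiers,
        classes=classes,
        prob_threshold=prob_threshold,
        training_scores=scores,
    )


def project(model: ProjectionModel, query: AnnData, min_overlap: float = 0.5) -> np.ndarray:
    """Project query cells into the frozen reference PC space.

    Query expression is aligned to the model's gene list by symbol; genes the
    query lacks contribute 0 after centering (the reference mean). The
    reference centering/scaling and loadings are applied as-is.
    """
    L = _lognorm_matrix(query)
    q_idx = {g: i for i, g in enumerate(query.var_names)}
    present = [g for g in model.gene_list if g in q_idx]
    overlap = len(present) / len(model.gene_list)
    if overlap < min_overlap:
        raise ValueError(
            f"gene overlap {overlap:.1%} below floor {min_overlap:.0%} "
            f"({len(present)}/{len(model.gene_list)} model genes found)"
        )
    Z = np.zeros((query.n_obs, len(model.gene_list)))
    model_pos = {g: i for i, g in enumerate(model.gene_list)}
    cols_q = [q_idx[g] for g in present]
    cols_m = [model_pos[g] for g in present]
    Z[:, cols_m] = (L[:, cols_q] - model.center[cols_m]) / model.scale[cols_m]
    return Z @ model.loadings


def predict(model: ProjectionModel, pc_scores: np.ndarray) -> pd.DataFrame:
    """Per-cell class probabilities and thresholded labels.

    Label = argmax-probability class when that probability reaches the
    model's threshold, else 'unassigned'. One-vs-rest probabilities are
    reported per class and need not sum to 1.
    """
    probs = pd.DataFrame(
        {
            cls: model.classifiers[cls].predict_proba(
                pc_scores[:, model.selected_pcs[cls]]
            )[:, 1]
            for cls in model.classes
        }
    )
    best = probs.to_numpy().argmax(axis=1)
    best_p = probs.to_numpy().max(axis=1)
    labels = np.where(
        best_p >= model.prob_threshold,
        np.array(model.classes, dtype=object)[best],
        UNASSIGNED,
    )
    probs["label"] = labels
    return probs
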