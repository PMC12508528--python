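"""Compound scoring and ranking against same-plate DMSO controls.

Each compound is tested gene-by-gene: its corrected log2 expression values
are compared with the DMSO control wells on the same plate(s) by a pooled
two-sample Student's t test, and the per-gene evidence is combined into a
single score, mean over signature genes of

    (-log10 p) * (-log2FC) * dir,    dir = +1 for a down signature,

so a compound scores high exactly when it moves every signature gene in the
desired direction both strongly (fold change) and reliably (p value). The
combined-score formula is isolated in :func:`score_compound` so alternates
(rank-sum, signed minimum) can be slotted in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .screen import ProbePanel

__all__ = ["Signature", "fold_change", "score_compound", "rank_and_call", "rank_compounds"]

_VAR_FLOOR = 1e-6  # pooled-variance floor keeps t finite on degenerate replicates


@dataclass
class Signature:
    """A named gene set with a regulation direction ('down' or 'up')."""

    name: str
    genes: list[str]
    direction: str = "down"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        if self.direction not in ("down", "up"):
            raise ValueError("direction must be 'down' or 'up'")

    @property
    def sign(self) -> int:
        return 1 if self.direction == "down" else -1

    @classmethod
    def from_json(cls, path: str | Path) -> "Signature":
        d = json.loads(Path(path).read_text())
        return cls(name=d["name"], genes=list(d["genes"]), direction=d.get("direction", "down"))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"name": self.name, "genes": self.genes, "direction": self.direction})
        )


def _gene_values(
    corrected: pd.DataFrame, panel: ProbePanel | None, gene: str
) -> pd.Series:
    """Per-well value for a gene: its probe column, averaged over multi-probe genes."""
    if gene in corrected.columns:
        return corrected[gene]
    if panel is not None:
        probes = [p for p in panel.probes_for_gene(gene) if p in corrected.columns]
        if probes:
            return corrected[probes].mean(axis=1)
    raise KeyError(f"gene {gene!r} not found in corrected table")


def fold_change(
    corrected: pd.DataFrame,
    wells: pd.DataFrame,
    compound: str,
    gene: str,
    panel: ProbePanel | None = None,
) -> dict:
    """Per-gene compound effect versus same-plate DMSO controls.

    log2FC is the mean over treated wells of (value - same-plate DMSO mean).
    The t test pools treated and DMSO values after centering each plate at
    its DMSO mean, so plate offsets cancel; with a single treated replicate
    the test is undefined and reported as t=0, p=1 with a flag.
    """
    treated = wells.index[(wells["compound_id"] == compound) & ~wells["is_dmso"]]
    if len(treated) == 0:
        raise ValueError(f"compound {compound!r} has no wells")
    plates = wells.loc[treated, "plate_id"].unique()
    vals = _gene_values(corrected, panel, gene)

    t_vals, c_vals = [], []
    for plate in plates:
        dmso = wells.index[(wells["plate_id"] == plate) & wells["is_dmso"]]
        if len(dmso) == 0:
            raise ValueError(f"no DMSO controls on plate {plate!r} for compound {compound!r}")
        center = vals.loc[dmso].mean()
        on_plate = [w for w in treated if wells.loc[w, "plate_id"] == plate]
        t_vals.extend(vals.loc[on_plate] - center)
        c_vals.extend(vals.loc[dmso] - center)

    t_arr, c_arr = np.asarray(t_vals), np.asarray(c_vals)
    n1, n2 = len(t_arr), len(c_arr)
    log2fc = float(t_arr.mean())
    if n1 < 2:
        return {
            "log2fc": log2fc, "t_stat": 0.0, "p_value": 1.0,
            "n_treat": n1, "n_ctrl": n2, "single_replicate": True,
        }
    sp2 = ((n1 - 1) * t_arr.var(ddof=1) + (n2 - 1) * c_arr.var(ddof=1)) / (n1 + n2 - 2)
    sp2 = max(sp2, _VAR_FLOOR)
    t_stat = (t_arr.mean() - c_arr.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = float(2 * stats.t.sf(abs(t_stat), df=n1 + n2 - 2))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return {
        "log2fc": log2fc, "t_stat": float(t_stat), "p_value": p,
        "n_treat": n1, "n_ctrl": n2, "single_replicate": False,
    }


def score_compound(per_gene: dict[str, dict], signature: Signature) -> float:
    """Combine per-gene evidence into one ranking score (see module docstring)."""
    missing = [g for g in signature.genes if g not in per_gene]
    if missing:
        raise ValueError(f"per-gene results missing signature gene(s): {missing}")
    terms = [
        (-np.log10(per_gene[g]["p_value"])) * (-per_gene[g]["log2fc"]) * signature.sign
        for g in signature.genes
    ]
    return float(np.mean(terms))


def rank_and_call(results: pd.DataFrame, top_k: int = 10) -> pd.DataFrame:
    """Stable descending sort by score; ties by smaller mean p, then id.

    Adds ``rank`` (1..n) and ``hit`` (True for the first ``top_k``).
    """
    if top_k > len(results):
        raise ValueError("top_k exceeds number of compounds")
    out = results.sort_values(
        ["score", "mean_p", "compound_id"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["hit"] = out["rank"] <= top_k
    return out


def rank_compounds(
    corrected: pd.DataFrame,
    wells: pd.DataFrame,
    signature: Signature,
    panel: ProbePanel | None = None,
    top_k: int = 10,
) -> pd.DataFrame:
    """Full ranking table: per-gene log2FC/t/p, combined score, rank, hit flag.

    A BH-adjusted p column per gene is included for reporting only; ranking
    itself uses raw p values.
    """
    gene_vals = {g: _gene_values(corrected, panel, g) for g in signature.genes}
    dmso_mask = wells["is_dmso"].astype(bool)
    plate_of = wells["plate_id"]

    # precompute per-plate DMSO means and centered DMSO values per gene
    dmso_wells = wells.index[dmso_mask]
    rows = []
    compounds = sorted(wells.loc[~dmso_mask, "compound_id"].unique())
    plate_groups = {p: list(idx) for p, idx in wells.groupby("plate_id").groups.items()}
    dmso_by_plate = {
        p: [w for w in idx if dmso_mask.loc[w]] for p, idx in plate_groups.items()
    }
    centers = {
        g: {p: vals.loc[dmso_by_plate[p]].mean() for p in plate_groups}
        for g, vals in gene_vals.items()
    }
    dmso_centered = {
        g: {
            p: (vals.loc[dmso_by_plate[p]] - centers[g][p]).to_numpy()
            for p in plate_groups
        }
        for g, vals in gene_vals.items()
    }
    wells_by_compound = wells.loc[~dmso_mask].groupby("compound_id").groups

    for cpd in compounds:
        widx = list(wells_by_compound[cpd])
        plates = plate_of.loc[widx]
        per_gene: dict[str, dict] = {}
        for g, vals in gene_vals.items():
            t_arr = (vals.loc[widx] - plates.map(centers[g]).to_numpy()).to_numpy()
            c_arr = np.concatenate([dmso_centered[g][p] for p in plates.unique()])
            n1, n2 = len(t_arr), len(c_arr)
            log2fc = float(t_arr.mean())
            if n1 < 2:
                per_gene[g] = {"log2fc": log2fc, "t_stat": 0.0, "p_value": 1.0,
                               "n_treat": n1, "n_ctrl": n2}
                continue
            sp2 = ((n1 - 1) * t_arr.var(ddof=1) + (n2 - 1) * c_arr.var(ddof=1)) / (n1 + n2 - 2)
            sp2 = max(sp2, _VAR_FLOOR)
            t_stat = (t_arr.mean() - c_arr.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            p = float(2 * stats.t.sf(abs(t_stat), df=n1 + n2 - 2))
            per_gene[g] = {
                "log2fc": log2fc,
                "t_stat": float(t_stat),
                "p_value": min(max(p, np.finfo(float).tiny), 1.0),
                "n_treat": n1,
                "n_ctrl": n2,
            }
        row = {"compound_id": cpd, "score": score_compound(per_gene, signature),
               "mean_p": float(np.mean([per_gene[g]["p_value"] for g in signature.genes]))}
        for g in signature.genes:
            row[f"log2fc_{g}"] = per_gene[g]["log2fc"]
            row[f"t_{g}"] = per_gene[g]["t_stat"]
            row[f"p_{g}"] = per_gene[g]["p_value"]
        rows.append(row)

    table = pd.DataFrame(rows)
    for g in signature.genes:
        table[f"p_adj_{g}"] = multipletests(table[f"p_{g}"], method="fdr_bh")[1]
    return rank_and_call(table, top_k=top_k)
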