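"""Biomarker outcome evaluation: z-scores, ROC, Kaplan-Meier, log-rank, cutoffs.

Survival comparisons use the unweighted (Mantel-Cox) log-rank test with the
standard hypergeometric variance under ties. The automatic cutoff scan
mirrors the common "best cutoff" convention — every unique score between the
25th and 75th percentile is tried and the log-rank-minimizing split is
returned — and the minimized p value is explicitly flagged as optimized,
with an optional permutation-adjusted p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "zscore_signature",
    "roc_auc",
    "ROCResult",
    "KMCurve",
    "km_estimate",
    "logrank",
    "best_cutoff",
    "h_score",
    "tumor_volume",
]


def zscore_signature(values: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Per-sample signature z score: standardize each gene, average over genes.

    Each gene is centered at its across-sample mean and scaled by its sample
    SD so multi-gene averaging is scale-fair; zero-variance genes are dropped
    with a warning.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 samples")
    present = [g for g in genes if g in values.columns]
    if not present:
        raise ValueError(f"no signature gene in matrix: {genes}")
    sub = values[present].astype(float)
    sd = sub.std(ddof=1)
    dead = list(sd.index[sd == 0])
    if dead:
        warnings.warn(f"zero-variance gene(s) dropped: {dead}", stacklevel=2)
        sub = sub.drop(columns=dead)
        if sub.shape[1] == 0:
            raise ValueError("all signature genes have zero variance")
        sd = sd.drop(dead)
    z = (sub - sub.mean()) / sd
    return z.mean(axis=1).rename("z_score")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC; the AUC equals the Mann-Whitney U/(n1*n2) with midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    ranks = stats.rankdata(scores)  # midranks under ties
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    auc = u / (n1 * n0)
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(auc))


@dataclass
class KMCurve:
    """Product-limit survival curve: S non-increasing from S(0)=1."""

    times: np.ndarray  # event times, ascending
    at_risk: np.ndarray
    survival: np.ndarray


def km_estimate(table: pd.DataFrame, group_key: str | None = "group") -> dict[str, KMCurve]:
    """Kaplan-Meier product-limit estimate per group.

    Subjects censored at an event time are counted at risk for that time.
    With ``group_key=None`` a single pooled curve is returned under 'all'.
    """
    groups = (
        {"all": table}
        if group_key is None or group_key not in table
        else {str(g): sub for g, sub in table.groupby(group_key)}
    )
    out: dict[str, KMCurve] = {}
    for name, sub in groups.items():
        if len(sub) == 0:
            raise ValueError(f"empty group {name!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        event_times = np.sort(sub.loc[sub["event"] == 1, "time"].unique())
        surv = kmf.survival_function_at_times(event_times).to_numpy()
        t = sub["time"].to_numpy()
        at_risk = np.array([(t >= et).sum() for et in event_times])
        out[name] = KMCurve(times=event_times, at_risk=at_risk, survival=surv)
    return out


def _logrank_arrays(time, event, is_a) -> tuple[float, float]:
    """(O-E, Var) for group A over pooled event times, ties via hypergeometric."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    is_a = np.asarray(is_a, dtype=bool)
    event_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & is_a).sum()
        d = ((time == t) & (event == 1)).sum()
        d_a = ((time == t) & (event == 1) & is_a).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e, var


def logrank(table: pd.DataFrame, group_key: str = "group") -> dict:
    """Unweighted (Mantel-Cox) log-rank test between two groups."""
    levels = sorted(table[group_key].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {levels}")
    if int(table["event"].sum()) == 0:
        raise ValueError("no events observed")
    is_a = (table[group_key].astype(str) == levels[0]).to_numpy()
    ome, var = _logrank_arrays(table["time"], table["event"], is_a)
    if var == 0:
        chi2 = 0.0
    else:
        chi2 = ome**2 / var
    return {
        "chi2": float(chi2),
        "p_value": float(stats.chi2.sf(chi2, df=1)) if var > 0 else 1.0,
        "observed_minus_expected": float(ome),
        "variance": float(var),
        "groups": levels,
    }


def best_cutoff(
    table: pd.DataFrame,
    score_key: str = "score",
    n_permutations: int = 0,
    seed: int = 0,
) -> dict:
    """Scan score cutoffs in the interquartile window, minimize log-rank p.

    Every unique score between the 25th and 75th percentile is tried as a
    '>' split. The returned ``p_at_cutoff`` is an optimized minimum over the
    scan and is NOT a valid nominal p (``optimized_p`` flag); when
    ``n_permutations`` > 0, a permutation-adjusted p (fraction of
    score-permuted datasets whose minimized p is at least as small) is added.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 subjects for a cutoff scan")
    scores = table[score_key].to_numpy(dtype=float)
    lo, hi = np.percentile(scores, [25, 75])
    candidates = np.unique(scores[(scores >= lo) & (scores <= hi)])
    candidates = candidates[candidates < scores.max()]  # '>' split must keep both sides
    if len(candidates) < 2:
        raise ValueError("fewer than 2 candidate cutoffs in the interquartile window")

    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int)

    def scan(sc: np.ndarray) -> tuple[float, float]:
        best_p, best_c = np.inf, np.nan
        for c in candidates:
            hi_mask = sc > c
            if not hi_mask.any() or hi_mask.all():
                continue
            ome, var = _logrank_arrays(time, event, hi_mask)
            if var <= 0:
                continue
            p = stats.chi2.sf(ome**2 / var, df=1)
            if p < best_p:
                best_p, best_c = p, c
        return best_c, best_p

    cutoff, p_min = scan(scores)
    scan_table = []
    for c in candidates:
        hi_mask = scores > c
        if not hi_mask.any() or hi_mask.all():
            continue
        ome, var = _logrank_arrays(time, event, hi_mask)
        p = float(stats.chi2.sf(ome**2 / var, df=1)) if var > 0 else 1.0
        scan_table.append({"cutoff": float(c), "p_value": p})
    result = {
        "cutoff": float(cutoff),
        "p_at_cutoff": float(p_min),
        "optimized_p": True,  # minimum over a scan, not a nominal p
        "scan": pd.DataFrame(scan_table),
    }
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            _, p_perm = scan(rng.permutation(scores))
            if p_perm <= p_min:
                hits += 1
        result["permutation_p"] = (hits + 1) / (n_permutations + 1)
    return result


def h_score(fractions: dict[int, float] | list[float]) -> float:
    """Immunohistochemistry H-score: sum of intensity (0-3) x percent cells, range 0-300."""
    if isinstance(fractions, dict):
        pct = [float(fractions.get(i, 0.0)) for i in range(4)]
    else:
        pct = [float(x) for x in fractions]
        if len(pct) != 4:
            raise ValueError("expect percentages for intensities 0..3")
    if any(p < 0 for p in pct):
        raise ValueError("negative percentage")
    if abs(sum(pct) - 100) > 0.1:
        raise ValueError(f"percentages sum to {sum(pct)}, expected 100")
    return float(sum(i * p for i, p in enumerate(pct)))


def tumor_volume(width: float, length: float) -> float:
    """Caliper tumor volume in mm^3: width^2 x length / 2 (width is the short axis)."""
    if width <= 0 or length <= 0:
        raise ValueError("dimensions must be positive")
    if width > length:
        warnings.warn(
            f"width {width} > length {length}; swapping to keep width the short axis",
            stacklevel=2,
        )
        width, length = length, width
    return width**2 * length / 2
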