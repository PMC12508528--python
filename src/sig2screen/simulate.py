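"""Synthetic-data generators for every pipeline input, with ground truth.

All generators take an explicit integer seed and are fully deterministic
given it. Each returns the data alongside a :class:`GroundTruth` record so
downstream tests never reconstruct truth from identifiers.

Counts are negative-binomial (gamma-Poisson) with a shared dispersion,
matching overdispersed sequencing data. Plate batch effects are per-plate
per-probe additive shifts on the log2 mean plus a per-plate dispersion
scaling — exactly the location/scale structure the empirical-Bayes batch
correction is designed to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from anndata import AnnData
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.special import expit, logit

from .screen import ProbePanel, ScreenTable

__all__ = [
    "ScreenSimConfig",
    "ScSimConfig",
    "GroundTruth",
    "gen_screen",
    "gen_reads",
    "gen_scrna",
    "gen_survival",
    "gen_response",
]

SIGNATURE_GENES = ("CXCL1", "CXCL2")


@dataclass
class GroundTruth:
    """Simulation truth handed back with each generated dataset."""

    hit_ids: set[str] | None = None
    true_cell_types: pd.Series | None = None
    true_mdsc_fraction: pd.Series | None = None
    true_hazard_ratio: float | None = None
    true_response_prob: pd.Series | None = None


# ---------------------------------------------------------------------------
# plate screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimConfig:
    """Configuration of the simulated plate screen.

    Defaults mirror the screening setup being emulated: 384-well plates with
    per-plate DMSO control columns, a compound library screened at one dose
    with a few replicates per compound, a probe panel containing the two
    signature chemokines plus 33 stable normalization genes, and spiked-in
    "hit" compounds that down-regulate the signature genes by
    ``hit_log2fc`` log2 units.
    """

    n_compounds: int = 2000
    n_hits: int = 10
    hit_log2fc: float = -1.5
    replicates_per_compound: int = 3
    wells_per_plate: int = 384
    n_dmso_per_plate: int = 16
    n_probes: int = 50
    n_stable: int = 33
    batch_shift_sd: float = 0.5
    batch_scale_sd: float = 0.2
    nb_dispersion: float = 0.05
    baseline_mean: float = 300.0
    probe_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_compounds": self.n_compounds,
            "replicates_per_compound": self.replicates_per_compound,
            "wells_per_plate": self.wells_per_plate,
            "n_probes": self.n_probes,
            "n_stable": self.n_stable,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_dmso_per_plate < 2:
            raise ValueError("n_dmso_per_plate must be >= 2 (plate fold-change undefined)")
        if self.n_hits > self.n_compounds:
            raise ValueError("n_hits cannot exceed n_compounds")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_probes < self.n_stable + len(SIGNATURE_GENES):
            raise ValueError("n_probes must cover the stable set plus the signature genes")
        if self.wells_per_plate <= self.n_dmso_per_plate:
            raise ValueError("plate must have room for compound wells")

    @property
    def compound_wells_per_plate(self) -> int:
        return self.wells_per_plate - self.n_dmso_per_plate

    @property
    def n_plates(self) -> int:
        total = self.n_compounds * self.replicates_per_compound
        return -(-total // self.compound_wells_per_plate)


def _random_panel(cfg: ScreenSimConfig, rng: np.random.Generator) -> ProbePanel:
    genes = list(SIGNATURE_GENES)
    genes += [f"STB{i + 1:03d}" for i in range(cfg.n_stable)]
    genes += [f"GENE{i + 1:03d}" for i in range(cfg.n_probes - len(genes))]
    stable = [g.startswith("STB") for g in genes]
    seqs = [
        "".join(rng.choice(list("ACGT"), size=cfg.probe_length))
        for _ in range(cfg.n_probes)
    ]
    return ProbePanel(
        pd.DataFrame(
            {
                "probe_id": [f"P{i + 1:04d}" for i in range(cfg.n_probes)],
                "sequence": seqs,
                "gene": genes,
                "is_stable": stable,
            }
        )
    )


def _nb_counts(mean: np.ndarray, dispersion: float | np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson sample with Var = mu + dispersion * mu^2."""
    r = 1.0 / np.asarray(dispersion, dtype=float)
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def gen_screen(cfg: ScreenSimConfig) -> tuple[ScreenTable, GroundTruth]:
    """Simulate a plate-based screen with spiked signature-down-regulating hits.

    Each plate carries its own per-probe additive log2-mean shift
    ``N(0, batch_shift_sd)`` and a multiplicative dispersion scale
    ``exp(N(0, batch_scale_sd))``. Hit compounds multiply the signature-probe
    means by ``2**hit_log2fc`` in their wells; stable probes never carry
    compound effects. DMSO control wells are flagged per plate.
    """
    rng = np.random.default_rng(cfg.seed)
    panel = _random_panel(cfg, rng)
    genes = panel.table["gene"].to_numpy()
    sig_mask = np.isin(genes, SIGNATURE_GENES)

    # probe-specific baseline abundance, lognormal around the configured mean
    base_mean = cfg.baseline_mean * 2.0 ** rng.normal(0.0, 0.75, size=cfg.n_probes)

    compounds = [f"CPD{i + 1:05d}" for i in range(cfg.n_compounds)]
    hit_ids = set(rng.choice(compounds, size=cfg.n_hits, replace=False).tolist())

    # replicate blocks: replicate r of every compound in block r, so
    # replicates of a compound land on different plates when possible
    queue = [c for _ in range(cfg.replicates_per_compound) for c in compounds]

    n_plates = cfg.n_plates
    shift = rng.normal(0.0, cfg.batch_shift_sd, size=(n_plates, cfg.n_probes))
    disp_scale = np.exp(rng.normal(0.0, cfg.batch_scale_sd, size=n_plates))

    rows, well_meta = [], []
    pos = 0
    for p in range(n_plates):
        plate_id = f"plate{p + 1:02d}"
        block = queue[pos : pos + cfg.compound_wells_per_plate]
        pos += len(block)
        labels = ["DMSO"] * cfg.n_dmso_per_plate + block
        mean_plate = base_mean * 2.0 ** shift[p]
        for w, cpd in enumerate(labels):
            mu = mean_plate.copy()
            if cpd in hit_ids:
                mu = mu * np.where(sig_mask, 2.0 ** cfg.hit_log2fc, 1.0)
            rows.append(_nb_counts(mu, cfg.nb_dispersion * disp_scale[p], rng))
            well_meta.append(
                {
                    "well_id": f"{plate_id}_w{w + 1:03d}",
                    "plate_id": plate_id,
                    "compound_id": cpd,
                    "is_dmso": cpd == "DMSO",
                }
            )

    wells = pd.DataFrame(well_meta).set_index("well_id")
    counts = pd.DataFrame(
        np.vstack(rows), index=wells.index, columns=panel.probe_ids
    )
    table = ScreenTable(counts=counts, wells=wells, panel=panel)
    return table, GroundTruth(hit_ids=hit_ids)


def gen_reads(
    panel: ProbePanel,
    well_counts: ScreenTable,
    mismatch_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, list[SeqRecord]]:
    """Emit per-well reads: probe copies with per-base substitution errors.

    For each well/probe the tabulated number of reads is emitted exactly;
    each read is the probe sequence with independent per-base substitution
    probability ``mismatch_rate`` (substitution-only, no indels). Read ids
    encode the well id as ``<well>|<index>``.
    """
    if not 0 <= mismatch_rate < 0.25:
        raise ValueError("mismatch_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    seqs = panel.table.set_index("probe_id")["sequence"]
    bases = np.array(list("ACGT"))
    out: dict[str, list[SeqRecord]] = {}
    for well_id, row in well_counts.counts.iterrows():
        records: list[SeqRecord] = []
        idx = 0
        for probe_id, n in row.items():
            template = np.array(list(seqs.loc[probe_id]))
            for _ in range(int(n)):
                read = template
                if mismatch_rate > 0:
                    hit = rng.random(len(template)) < mismatch_rate
                    if hit.any():
                        read = template.copy()
                        # substitute to one of the three other bases
                        for j in np.flatnonzero(hit):
                            choices = bases[bases != template[j]]
                            read[j] = rng.choice(choices)
                records.append(
                    SeqRecord(
                        Seq("".join(read)),
                        id=f"{well_id}|{idx}",
                        description="",
                        letter_annotations={"phred_quality": [40] * len(template)},
                    )
                )
                idx += 1
        out[well_id] = records
    return out


# ---------------------------------------------------------------------------
# single-cell data
# ---------------------------------------------------------------------------


@dataclass
class ScSimConfig:
    """Configuration of the synthetic patient scRNA-seq cohort.

    Cell types cover tumor, T, MDSC and other-myeloid programs built from a
    shared lognormal baseline with type-specific marker blocks. Each patient
    has a latent tumor-cell CXCL1/CXCL2 level; the patient's MDSC fraction
    is ``logistic(intercept + mdsc_link_slope * level)``, coupling signature
    expression to MDSC infiltration with a tunable strength.
    """

    n_patients: int = 20
    cells_per_patient: int = 200
    n_genes: int = 1500
    mdsc_link_slope: float = 2.0
    mdsc_intercept: float = logit(0.12)
    markers_per_type: int = 40
    marker_log2fc: float = 3.0
    nb_dispersion: float = 0.3
    baseline_mean: float = 1.0
    cell_type_programs: Mapping[str, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.cells_per_patient <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        if self.n_genes < 4 * self.markers_per_type + 2:
            raise ValueError("n_genes too small for four marker blocks plus CXCL1/2")
        if self.cell_type_programs is not None:
            for name, prog in self.cell_type_programs.items():
                prog = np.asarray(prog)
                if (prog < 0).any():
                    raise ValueError(f"program {name!r} has negative means")
                if not prog.any():
                    raise ValueError(f"program {name!r} is all zeros")


CELL_TYPES = ("tumor", "T", "MDSC", "myeloid")


def _default_programs(cfg: ScSimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, list[str]]:
    gene_names = ["CXCL1", "CXCL2"] + [f"G{i + 1:04d}" for i in range(cfg.n_genes - 2)]
    base = cfg.baseline_mean * 2.0 ** rng.normal(0.0, 1.0, size=cfg.n_genes)
    progs = pd.DataFrame(
        {t: base.copy() for t in CELL_TYPES}, index=gene_names
    )
    fold = 2.0 ** cfg.marker_log2fc
    start = 2  # keep CXCL1/2 out of the marker blocks
    for t in CELL_TYPES:
        block = gene_names[start : start + cfg.markers_per_type]
        progs.loc[block, t] *= fold
        start += cfg.markers_per_type
    # signature chemokines are produced by tumor cells
    progs.loc[["CXCL1", "CXCL2"], :] = 0.05 * cfg.baseline_mean
    progs.loc[["CXCL1", "CXCL2"], "tumor"] = 2.0 * cfg.baseline_mean
    return progs, gene_names


def gen_scrna(cfg: ScSimConfig) -> tuple[AnnData, GroundTruth]:
    """Simulate a patient cohort with signature-coupled MDSC fractions.

    Returns an AnnData with raw counts in ``X`` and per-cell metadata
    (``patient``, ``true_type``), plus ground truth (true labels and
    per-patient MDSC fraction).
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.cell_type_programs is not None:
        progs = pd.DataFrame(cfg.cell_type_programs)
        gene_names = list(progs.index)
        types = list(progs.columns)
    else:
        progs, gene_names = _default_programs(cfg, rng)
        types = list(CELL_TYPES)

    # latent per-patient tumor CXCL1/2 level (log2 units, standardized scale)
    level = rng.normal(0.0, 1.0, size=cfg.n_patients)
    mdsc_frac = expit(cfg.mdsc_intercept + cfg.mdsc_link_slope * level)

    other = np.array([0.5, 0.3, 0.2])  # tumor, T, myeloid share of non-MDSC cells
    X_parts, obs_rows = [], []
    for i in range(cfg.n_patients):
        pid = f"PT{i + 1:03d}"
        probs = {
            "MDSC": mdsc_frac[i],
            "tumor": (1 - mdsc_frac[i]) * other[0],
            "T": (1 - mdsc_frac[i]) * other[1],
            "myeloid": (1 - mdsc_frac[i]) * other[2],
        }
        p = np.array([probs.get(t, 0.0) for t in types])
        p = p / p.sum()
        labels = rng.choice(types, size=cfg.cells_per_patient, p=p)
        mu = progs[labels].to_numpy().T  # cells x genes
        # patient-specific tumor-cell chemokine level
        sig_idx = [gene_names.index(g) for g in ("CXCL1", "CXCL2") if g in gene_names]
        if sig_idx:
            tumor_cells = labels == "tumor"
            mu[np.ix_(tumor_cells, sig_idx)] *= 2.0 ** level[i]
        X_parts.append(_nb_counts(np.maximum(mu, 1e-8), cfg.nb_dispersion, rng))
        for j, lab in enumerate(labels):
            obs_rows.append({"cell_id": f"{pid}_c{j + 1:04d}", "patient": pid, "true_type": lab})

    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    obs["response"] = "none"
    obs["subtype"] = "none"
    var = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    var["mito"] = var.index.str.startswith("MT-")
    adata = AnnData(X=np.vstack(X_parts).astype(np.float32), obs=obs, var=var)
    truth = GroundTruth(
        true_cell_types=obs["true_type"].copy(),
        true_mdsc_fraction=pd.Series(
            mdsc_frac, index=[f"PT{i + 1:03d}" for i in range(cfg.n_patients)], name="mdsc_fraction"
        ),
    )
    return adata, truth


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


def gen_survival(
    n: int,
    hazard_ratio: float,
    censor_rate: float = 0.2,
    seed: int = 0,
    baseline_hazard: float = 0.1,
    score_gap: float = 3.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a two-group survival table with exponential times.

    ``n`` subjects are split evenly into low/high biomarker groups; the high
    group's event hazard is ``hazard_ratio`` times baseline. Censoring is an
    independent exponential calibrated so roughly ``censor_rate`` of subjects
    are censored. Scores are drawn around group-specific centers separated by
    ``score_gap`` so cutoff-scanning methods have a recoverable split at 0.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    n_low = n // 2
    n_high = n - n_low
    if n_low < 2 or n_high < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    group = np.array(["low"] * n_low + ["high"] * n_high)
    hazard = np.where(group == "high", baseline_hazard * hazard_ratio, baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        c_hazard = hazard * censor_rate / (1 - censor_rate)
        censor_time = rng.exponential(1.0 / c_hazard)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    center = np.where(group == "high", score_gap / 2, -score_gap / 2)
    score = rng.normal(center, 0.5)
    table = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "score": score,
            "group": group,
        }
    )
    return table, GroundTruth(true_hazard_ratio=hazard_ratio)


def gen_response(
    n_patients: int, auc_target_slope: float, seed: int = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate signature scores with logistic non-response coupling.

    High signature score means lower response probability
    (``P(response) = logistic(-slope * score)``), matching the direction in
    which high chemokine expression predicts immunotherapy failure.
    """
    if n_patients < 10:
        raise ValueError("need at least 10 patients")
    rng = np.random.default_rng(seed)
    score = rng.normal(0.0, 1.0, size=n_patients)
    prob = expit(-auc_target_slope * score)
    response = (rng.random(n_patients) < prob).astype(int)
    table = pd.DataFrame(
        {
            "patient_id": [f"PT{i + 1:03d}" for i in range(n_patients)],
            "score": score,
            "response": response,
        }
    )
    truth = GroundTruth(
        true_response_prob=pd.Series(prob, index=table["patient_id"], name="response_prob")
    )
    return table, truth
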