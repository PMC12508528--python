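"""Screen quantification: probe panels, read counting and stable-gene normalization.

A pooled-probe screen measures expression of a small gene panel across the
wells of 384-well plates by sequencing. Reads are short fixed-length copies
of capture-probe sequences; quantification assigns each read to the unique
probe at minimal Hamming distance within a mismatch budget, then normalizes
each well by the summed counts of a designated "stable" (housekeeping-like)
probe set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProbePanel",
    "ScreenTable",
    "NormalizedTable",
    "count_reads",
    "count_reads_dir",
    "normalize_stable",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    """Encode an upper-case nucleotide string as uint8; N never matches any base."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass
class ProbePanel:
    """Probe id -> sequence -> gene map with stable-gene flags.

    All sequences must be equal-length upper-case ACGTN strings and probe ids
    unique. ``is_stable`` marks the housekeeping-like probes used as per-well
    size-factor anchors.
    """

    table: pd.DataFrame  # columns: probe_id, sequence, gene, is_stable

    def __post_init__(self) -> None:
        required = {"probe_id", "sequence", "gene", "is_stable"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise ValueError("empty probe panel")
        if self.table["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids in panel")
        lengths = self.table["sequence"].str.len().unique()
        if len(lengths) != 1:
            raise ValueError(f"probe sequences must share one length, got {sorted(lengths)}")
        bad = ~self.table["sequence"].str.fullmatch("[ACGTN]+")
        if bad.any():
            raise ValueError(
                "non-ACGTN probe sequences: " + ", ".join(self.table.loc[bad, "probe_id"])
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    @property
    def read_length(self) -> int:
        return len(self.table["sequence"].iloc[0])

    @property
    def stable_probes(self) -> list[str]:
        return list(self.table.loc[self.table["is_stable"].astype(bool), "probe_id"])

    def gene_of(self, probe_id: str) -> str:
        return self.table.set_index("probe_id")["gene"].loc[probe_id]

    def probes_for_gene(self, gene: str) -> list[str]:
        return list(self.table.loc[self.table["gene"] == gene, "probe_id"])

    def encoded(self) -> np.ndarray:
        """(n_probes, L) uint8 matrix of probe sequences."""
        return np.vstack([_encode(s) for s in self.table["sequence"]])

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(
                Seq(row.sequence),
                id=row.probe_id,
                description=f"gene={row.gene} stable={int(bool(row.is_stable))}",
            )
            for row in self.table.itertuples()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProbePanel":
        rows = []
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = dict(
                kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
            )
            rows.append(
                {
                    "probe_id": rec.id,
                    "sequence": str(rec.seq).upper(),
                    "gene": fields.get("gene", rec.id),
                    "is_stable": bool(int(fields.get("stable", "0"))),
                }
            )
        if not rows:
            raise ValueError(f"no records in panel FASTA {path}")
        return cls(pd.DataFrame(rows))


@dataclass
class ScreenTable:
    """Well x probe counts plus well metadata (plate, compound, DMSO flag)."""

    counts: pd.DataFrame  # index well_id, columns probe_id
    wells: pd.DataFrame  # index well_id; columns plate_id, compound_id, is_dmso
    panel: ProbePanel | None = None
    unassigned: pd.Series | None = None  # per-well discarded-read tally

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.wells.index):
            self.wells = self.wells.loc[self.counts.index]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        for col in ("plate_id", "compound_id", "is_dmso"):
            if col not in self.wells.columns:
                raise ValueError(f"wells metadata missing column {col!r}")

    def require_dmso(self) -> None:
        """Every plate must carry at least one DMSO control well."""
        has = self.wells.groupby("plate_id")["is_dmso"].any()
        if not has.all():
            raise ValueError(f"plates without DMSO wells: {list(has.index[~has])}")


@dataclass
class NormalizedTable:
    """Counts divided by per-well stable-gene size factors."""

    values: pd.DataFrame
    size_factors: pd.Series

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")


def count_reads(
    reads_by_well: Mapping[str, Iterable],
    panel: ProbePanel,
    max_mismatches: int = 3,
    wells: pd.DataFrame | None = None,
) -> ScreenTable:
    """Assign reads to probes by minimal Hamming distance.

    Each read is counted to the unique probe at minimal distance
    ``<= max_mismatches``; reads with no probe in range, or with two or more
    probes tied at the minimum, are discarded into a per-well unassigned
    tally. ``N`` bases never match. Reads whose length differs from the probe
    length are rejected.

    Parameters
    ----------
    reads_by_well
        Mapping well id -> iterable of reads (strings or SeqRecords).
    panel
        Probe panel; all probes share one sequence length.
    max_mismatches
        Hamming-distance budget (0 = exact matching only).
    wells
        Optional well metadata to attach; defaults to bare DMSO-less rows.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    enc = panel.encoded()
    L = enc.shape[1]
    exact = {row.sequence: i for i, row in enumerate(panel.table.itertuples())}
    probe_ids = panel.probe_ids

    count_rows: dict[str, np.ndarray] = {}
    unassigned: dict[str, int] = {}
    for well_id, reads in reads_by_well.items():
        row = np.zeros(len(probe_ids), dtype=np.int64)
        miss = 0
        for read in reads:
            seq = str(read.seq) if isinstance(read, SeqRecord) else str(read)
            seq = seq.upper()
            if len(seq) != L:
                raise ValueError(
                    f"read of length {len(seq)} in well {well_id}; probes are {L} nt "
                    "(trim reads before counting)"
                )
            hit = exact.get(seq)
            if hit is None and max_mismatches > 0:
                d = (enc != _encode(seq)).sum(axis=1)
                m = int(d.min())
                if m <= max_mismatches and (d == m).sum() == 1:
                    hit = int(d.argmin())
            if hit is None:
                miss += 1
            else:
                row[hit] += 1
        count_rows[well_id] = row
        unassigned[well_id] = miss

    counts = pd.DataFrame.from_dict(count_rows, orient="index", columns=probe_ids)
    counts.index.name = "well_id"
    if wells is None:
        wells = pd.DataFrame(
            {"plate_id": "plate1", "compound_id": "NA", "is_dmso": False},
            index=counts.index,
        )
    return ScreenTable(
        counts=counts,
        wells=wells.loc[counts.index],
        panel=panel,
        unassigned=pd.Series(unassigned, name="unassigned"),
    )


def count_reads_dir(
    reads_dir: str | Path,
    panel: ProbePanel,
    max_mismatches: int = 3,
    wells: pd.DataFrame | None = None,
) -> ScreenTable:
    """Count one FASTQ file per well (filename stem = well id); ``.gz`` allowed."""
    import gzip

    reads_dir = Path(reads_dir)
    reads_by_well = {}
    for path in sorted(reads_dir.glob("*.fastq*")):
        well_id = path.name.split(".fastq")[0]
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            reads_by_well[well_id] = [str(r.seq) for r in SeqIO.parse(fh, "fastq")]
    if not reads_by_well:
        raise ValueError(f"no FASTQ files found in {reads_dir}")
    return count_reads(reads_by_well, panel, max_mismatches, wells=wells)


def normalize_stable(
    table: ScreenTable, panel: ProbePanel | None = None, pseudocount: float = 0.0
) -> NormalizedTable:
    """Normalize each well by its summed stable-probe counts.

    The size factor of well *w* is its stable-probe count sum divided by the
    across-well median of those sums, so normalized values stay on the count
    scale and stable-gene totals are equalized across wells.
    """
    panel = panel or table.panel
    if panel is None:
        raise ValueError("a probe panel is required for normalization")
    stable = [p for p in panel.stable_probes if p in table.counts.columns]
    if not stable:
        raise ValueError("panel declares no stable probes present in the count table")
    sums = table.counts[stable].sum(axis=1).astype(float) + pseudocount
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(
            "wells with zero stable-probe counts: " + ", ".join(map(str, zero.index))
        )
    size_factors = sums / float(np.median(sums))
    values = table.counts.div(size_factors, axis=0)
    return NormalizedTable(values=values, size_factors=size_factors.rename("size_factor"))
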