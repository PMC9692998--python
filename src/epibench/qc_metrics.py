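"""Library-level quality statistics.

Covers the four QC readouts used to judge a low-input chromatin library:
carrier (lambda spike-in) contamination, FRiP (fraction of reads in peaks),
binned genome-wide replicate correlation, and the TSS meta-profile.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from epibench.genome_core import (
    GeneModel,
    GenomeModel,
    Peak,
    ReadRecord,
    bin_counts,
    dedup_reads,
    points_in_intervals,
)

__all__ = [
    "QcReport",
    "TssProfile",
    "CorrelationResult",
    "carrier_fraction",
    "frip",
    "replicate_correlation",
    "tss_profile",
    "qc_report",
]


@dataclass(frozen=True)
class QcReport:
    """Summary QC for one library."""

    n_total: int
    n_unique: int
    duplication_rate: float  # 1 - unique/total
    carrier_fraction: float  # percent of unique reads on carrier contigs
    frip: float

    def __post_init__(self):
        if not 0.0 <= self.frip <= 1.0:
            raise ValueError("frip out of [0, 1]")
        if not 0.0 <= self.carrier_fraction <= 100.0:
            raise ValueError("carrier_fraction out of [0, 100]")
        if self.n_unique > self.n_total:
            raise ValueError("n_unique > n_total")

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    def to_tsv(self, path: str | os.PathLike) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            fh.write("\t".join(d) + "\n")
            fh.write("\t".join(f"{v:.6g}" for v in d.values()) + "\n")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of two binned coverage tracks."""

    r: float
    n_bins: int
    binsize: int

    def __post_init__(self):
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| > 1")


@dataclass(frozen=True)
class TssProfile:
    """Average read density around TSSs, oriented 5'->3'.

    ``density[i]`` is the per-gene average of (reads in bin i) / (total
    mapped reads); bin i covers transcription-relative offsets
    ``[-flank + i*binsize, -flank + (i+1)*binsize)``.
    """

    flank: int
    binsize: int
    density: np.ndarray
    per_gene: np.ndarray | None = None  # genes x bins count matrix

    def __post_init__(self):
        if len(self.density) != 2 * self.flank // self.binsize:
            raise ValueError("density length != 2*flank/binsize")

    @property
    def n_bins(self) -> int:
        return len(self.density)

    def bin_offsets(self) -> np.ndarray:
        """Midpoint offset of each bin relative to the TSS, in bp."""
        return -self.flank + self.binsize * (np.arange(self.n_bins) + 0.5)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("offset_midpoint\tdensity\n")
            for off, d in zip(self.bin_offsets(), self.density):
                fh.write(f"{off:.1f}\t{d:.8g}\n")


def _signal_reads(reads: Sequence[ReadRecord]) -> list[ReadRecord]:
    return [r for r in reads if not r.is_carrier]


def carrier_fraction(reads: Sequence[ReadRecord]) -> float:
    """Percent of reads aligned to carrier contigs (lambda spike-in)."""
    if not reads:
        raise ValueError("carrier_fraction of an empty read list")
    n_car = sum(1 for r in reads if r.is_carrier)
    return 100.0 * n_car / len(reads)


def frip(reads: Sequence[ReadRecord], peaks: Sequence[Peak]) -> float:
    """Fraction of (non-carrier, deduplicated) reads whose start lies in a peak.

    Peaks are merged per contig before counting so overlapping or nested
    peaks cannot double-count a read.  Empty peak set gives 0.0.
    """
    sig = _signal_reads(reads)
    if not sig:
        raise ValueError("frip of an empty read list")
    if not peaks:
        return 0.0
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_contig.setdefault(p.contig, []).append((p.start, p.end))
    starts_by_contig: dict[str, list[int]] = {}
    for r in sig:
        starts_by_contig.setdefault(r.contig, []).append(r.start)
    n_in = 0
    for contig, starts in starts_by_contig.items():
        ivs = by_contig.get(contig)
        if not ivs:
            continue
        n_in += int(points_in_intervals(np.asarray(starts), ivs).sum())
    return n_in / len(sig)


def replicate_correlation(
    reads_a: Sequence[ReadRecord],
    reads_b: Sequence[ReadRecord],
    genome: GenomeModel,
    binsize: int = 4000,
) -> CorrelationResult:
    """Pearson r between two libraries binned across the whole genome.

    Both read sets are counted in ``binsize`` bins over all non-carrier
    contigs (4-kb default; 10-kb reproduces coarse methylome comparisons);
    zero bins are retained and counts are not log-transformed.
    """
    va = bin_counts(reads_a, genome, binsize).vector().astype(float)
    vb = bin_counts(reads_b, genome, binsize).vector().astype(float)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("constant track: correlation undefined")
    r, _ = stats.pearsonr(va, vb)
    return CorrelationResult(r=float(r), n_bins=len(va), binsize=binsize)


def tss_profile(
    reads: Sequence[ReadRecord],
    genes: Sequence[GeneModel],
    flank: int = 3000,
    binsize: int = 200,
    keep_per_gene: bool = False,
) -> TssProfile:
    """Average TSS-centred read-density profile.

    For each gene the window [TSS - flank, TSS + flank) is split into
    ``binsize``-bp bins ordered 5'->3' (minus-strand windows are reversed).
    Each gene's bin counts are divided by the total number of mapped
    non-carrier reads, then averaged over genes.  Windows clipped at contig
    edges contribute zero counts in the out-of-contig bins.
    """
    if not genes:
        raise ValueError("tss_profile needs at least one gene")
    if flank % binsize != 0:
        raise ValueError("flank must be a multiple of binsize")
    sig = _signal_reads(reads)
    total = len(sig)
    if total == 0:
        raise ValueError("tss_profile needs at least one mapped read")
    n_bins = 2 * flank // binsize
    starts_by_contig: dict[str, np.ndarray] = {}
    tmp: dict[str, list[int]] = {}
    for r in sig:
        tmp.setdefault(r.contig, []).append(r.start)
    for c, v in tmp.items():
        starts_by_contig[c] = np.sort(np.asarray(v, dtype=np.int64))

    mat = np.zeros((len(genes), n_bins), dtype=np.int64)
    for gi, g in enumerate(genes):
        pos = starts_by_contig.get(g.contig)
        if pos is None:
            continue
        lo, hi = g.tss - flank, g.tss + flank
        i0, i1 = np.searchsorted(pos, [lo, hi])
        if i1 == i0:
            continue
        idx = (pos[i0:i1] - lo) // binsize
        np.add.at(mat[gi], idx, 1)
        if g.strand == "-":
            mat[gi] = mat[gi][::-1]
    density = mat.mean(axis=0) / total
    return TssProfile(
        flank=flank,
        binsize=binsize,
        density=density,
        per_gene=mat if keep_per_gene else None,
    )


def qc_report(
    reads: Sequence[ReadRecord],
    peaks: Sequence[Peak],
    per_barcode_dedup: bool = False,
) -> QcReport:
    """Full QC summary: dedup, carrier contamination and FRiP in one pass.

    Carrier fraction is computed on unique reads; FRiP on unique non-carrier
    reads, per the convention that spike-in material is excluded from signal
    metrics.
    """
    if not reads:
        raise ValueError("qc_report of an empty read list")
    unique = dedup_reads(reads, per_barcode=per_barcode_dedup)
    return QcReport(
        n_total=len(reads),
        n_unique=len(unique),
        duplication_rate=1.0 - len(unique) / len(reads),
        carrier_fraction=carrier_fraction(unique),
        frip=frip(unique, peaks),
    )
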