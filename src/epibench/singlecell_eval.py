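"""Single-cell evaluation: demultiplexing, per-cell sensitivity/precision.

A plate run indexes cells by the Cartesian product of T5 and T7 Tn5
barcodes (8 x 12 = 96 by default).  Against a bulk reference peak set,

- sensitivity of a cell = fraction of reference peaks recovered by (>= 1
  read of) that cell;
- precision = fraction of the cell's reads located inside reference peaks.

A uniform-random read profile of matched depth serves as the control, and
pooling all cells gives a pseudobulk library comparable to bulk data.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from epibench.genome_core import (
    GenomeModel,
    Peak,
    ReadRecord,
    merge_intervals,
    points_in_intervals,
)

__all__ = [
    "CellMetrics",
    "UNDETERMINED",
    "demultiplex",
    "cell_metrics",
    "random_control",
    "expected_random_precision",
    "expected_random_sensitivity",
    "summarize_top_cells",
    "pool_pseudobulk",
    "metrics_table",
]

UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class CellMetrics:
    barcode: str
    n_unique: int
    sensitivity: float
    precision: float
    is_empty: bool = False

    def __post_init__(self):
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.precision <= 1.0):
            raise ValueError("sensitivity/precision out of [0, 1]")
        if self.n_unique < 0:
            raise ValueError("negative read count")


def demultiplex(
    reads: Sequence[ReadRecord],
    t5_barcodes: Sequence[str],
    t7_barcodes: Sequence[str],
    hamming1_rescue: bool = False,
) -> dict[str, list[ReadRecord]]:
    """Partition reads by exact T5+T7 barcode combination.

    Reads whose barcode is not in the T5 x T7 product (including barcodeless
    reads) land in the ``"undetermined"`` bin.  Every valid combination gets
    an entry, possibly empty, so the plate layout is preserved.  Optional
    Hamming-distance-1 rescue reassigns near-miss barcodes when the match is
    unique; it defaults off (exact matching is the standard treatment).
    """
    valid = [t5 + t7 for t5 in t5_barcodes for t7 in t7_barcodes]
    out: dict[str, list[ReadRecord]] = {bc: [] for bc in valid}
    out[UNDETERMINED] = []
    valid_set = set(valid)
    for r in reads:
        bc = r.barcode
        if bc in valid_set:
            out[bc].append(r)
            continue
        if hamming1_rescue and bc is not None:
            matches = [
                v
                for v in valid
                if len(v) == len(bc)
                and sum(a != b for a, b in zip(v, bc)) == 1
            ]
            if len(matches) == 1:
                out[matches[0]].append(r)
                continue
        out[UNDETERMINED].append(r)
    return out


def _peak_hits(
    reads: Sequence[ReadRecord], peaks: Sequence[Peak]
) -> tuple[int, int]:
    """(number of peaks recovered by >= 1 read, number of reads inside >= 1 peak)."""
    starts_by_contig: dict[str, np.ndarray] = {}
    tmp: dict[str, list[int]] = {}
    for r in reads:
        if not r.is_carrier:
            tmp.setdefault(r.contig, []).append(r.start)
    for c, v in tmp.items():
        starts_by_contig[c] = np.sort(np.asarray(v, dtype=np.int64))
    n_peaks_hit = 0
    for p in peaks:
        pos = starts_by_contig.get(p.contig)
        if pos is None:
            continue
        i0, i1 = np.searchsorted(pos, [p.start, p.end])
        if i1 > i0:
            n_peaks_hit += 1
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_contig.setdefault(p.contig, []).append((p.start, p.end))
    n_reads_in = 0
    for c, pos in starts_by_contig.items():
        ivs = by_contig.get(c)
        if ivs:
            n_reads_in += int(points_in_intervals(pos, ivs).sum())
    return n_peaks_hit, n_reads_in


def cell_metrics(
    cell_reads: Sequence[ReadRecord],
    reference_peaks: Sequence[Peak],
    barcode: str = ".",
) -> CellMetrics:
    """Sensitivity and precision of one cell against the reference peaks.

    An empty cell yields zero metrics with ``is_empty`` set (and a warning)
    rather than an error, so whole-plate summaries keep their shape.
    """
    if not reference_peaks:
        raise ValueError("reference peak set is empty")
    n = len(cell_reads)
    if n == 0:
        warnings.warn(f"cell {barcode!r} has no reads; metrics set to 0")
        return CellMetrics(barcode, 0, 0.0, 0.0, is_empty=True)
    n_peaks_hit, n_reads_in = _peak_hits(cell_reads, reference_peaks)
    return CellMetrics(
        barcode=barcode,
        n_unique=n,
        sensitivity=n_peaks_hit / len(reference_peaks),
        precision=n_reads_in / n,
    )


def random_control(
    n_reads: int,
    genome: GenomeModel,
    reference_peaks: Sequence[Peak],
    seed: int = 0,
) -> CellMetrics:
    """Metrics of a simulated random profile: uniform reads at matched depth."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    names = genome.signal_contigs
    lengths = np.array([genome.length(c) for c in names], dtype=np.int64)
    ci = rng.choice(len(names), size=n_reads, p=lengths / lengths.sum())
    pos = (rng.random(n_reads) * lengths[ci]).astype(np.int64)
    reads = [
        ReadRecord(names[c], int(p), "+") for c, p in zip(ci, pos)
    ]
    return cell_metrics(reads, reference_peaks, barcode="random_control")


def _merged_peak_bp(reference_peaks: Sequence[Peak]) -> int:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for p in reference_peaks:
        by_contig.setdefault(p.contig, []).append((p.start, p.end))
    return sum(
        e - s for ivs in by_contig.values() for s, e in merge_intervals(ivs)
    )


def expected_random_precision(
    genome: GenomeModel, reference_peaks: Sequence[Peak]
) -> float:
    """Expected precision of a uniform profile: merged peak bp / genome bp."""
    return _merged_peak_bp(reference_peaks) / genome.total_length()


def expected_random_sensitivity(
    n_reads: int, genome: GenomeModel, reference_peaks: Sequence[Peak]
) -> float:
    """Expected sensitivity of n uniform reads (occupancy closed form).

    Each peak of width w is hit by one uniform read with probability w/G,
    so P(recovered) = 1 - (1 - w/G)^n; the expectation of the recovered
    fraction averages this over peaks.
    """
    G = genome.total_length()
    probs = [1.0 - (1.0 - p.width / G) ** n_reads for p in reference_peaks]
    return float(np.mean(probs))


def summarize_top_cells(
    metrics: Sequence[CellMetrics], fraction: float = 0.05
) -> pd.DataFrame:
    """Mean/median of each metric over the top cells, ranked per metric.

    Cells are ranked independently for sensitivity and for precision; the
    top ``ceil(fraction * n)`` cells of each ranking are summarised, next to
    the all-cell summary.
    """
    if not metrics:
        raise ValueError("no cells to summarize")
    n_top = math.ceil(fraction * len(metrics))
    rows = []
    for name in ("sensitivity", "precision"):
        vals = np.array([getattr(m, name) for m in metrics])
        top = np.sort(vals)[::-1][:n_top]
        rows.append(
            {
                "metric": name,
                "n_cells": len(vals),
                "n_top": n_top,
                "mean_all": vals.mean(),
                "median_all": float(np.median(vals)),
                "mean_top": top.mean(),
                "median_top": float(np.median(top)),
            }
        )
    return pd.DataFrame(rows)


def pool_pseudobulk(
    cells: Mapping[str, Sequence[ReadRecord]] | Sequence[Sequence[ReadRecord]],
) -> list[ReadRecord]:
    """Concatenate per-cell reads into one pseudobulk library.

    Per-cell deduplication is preserved: reads from different cells at the
    same position are kept (they are distinct molecules).  The pooled count
    is therefore the sum of per-cell unique counts.
    """
    if isinstance(cells, Mapping):
        groups = [v for k, v in cells.items() if k != UNDETERMINED]
    else:
        groups = list(cells)
    if not groups:
        raise ValueError("no cells to pool")
    pooled: list[ReadRecord] = []
    for g in groups:
        pooled.extend(g)
    return pooled


def metrics_table(metrics: Sequence[CellMetrics]) -> pd.DataFrame:
    """Per-cell metrics as a DataFrame (barcode, n_unique, sensitivity, precision)."""
    return pd.DataFrame(
        [
            {
                "barcode": m.barcode,
                "n_unique": m.n_unique,
                "sensitivity": m.sensitivity,
                "precision": m.precision,
                "is_empty": m.is_empty,
            }
            for m in metrics
        ]
    )
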