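"""Core data model, file I/O and interval primitives.

Conventions used throughout the package:

- coordinates are 0-based, half-open ``[start, end)`` (BED-native); SAM
  ``POS`` is converted by subtracting 1 on input;
- a read is represented by the single base at its 5' start for binning and
  for peak-membership tests;
- carrier (spike-in) reads are identified by contig name: any read on a
  contig listed in :attr:`GenomeModel.carrier_contigs` (typically the
  48.5-kb phage lambda genome appended to the alignment reference) is
  flagged ``is_carrier`` and excluded from signal metrics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree

__all__ = [
    "GenomeModel",
    "ReadRecord",
    "Peak",
    "GeneModel",
    "BinnedTrack",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_reads",
    "write_reads",
    "read_peaks",
    "write_peaks",
    "read_genes",
    "write_genes",
    "dedup_reads",
    "overlaps",
    "count_overlapping",
    "merge_intervals",
    "subtract_intervals",
    "points_in_intervals",
    "bin_counts",
]

LAMBDA_LENGTH = 48_502  # phage lambda genome (NC_001416.1)


class FormatError(ValueError):
    """A file did not parse under the declared format."""


# ---------------------------------------------------------------------------
# data model


class GenomeModel:
    """Ordered set of contigs with lengths, plus carrier-contig flags.

    Parameters
    ----------
    contigs:
        Iterable of ``(name, length)`` pairs; order is preserved and defines
        the concatenation order used by :class:`BinnedTrack`.
    carrier_contigs:
        Names of contigs holding exogenous carrier DNA (e.g. ``"lambda"``).
        Must be a subset of the contig names.
    """

    def __init__(
        self,
        contigs: Iterable[tuple[str, int]],
        carrier_contigs: Iterable[str] = (),
    ):
        self._names: list[str] = []
        self._lengths: dict[str, int] = {}
        for name, length in contigs:
            if name in self._lengths:
                raise ValueError(f"duplicate contig name: {name!r}")
            length = int(length)
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length {length}")
            self._names.append(name)
            self._lengths[name] = length
        self.carrier_contigs = frozenset(carrier_contigs)
        unknown = self.carrier_contigs - set(self._names)
        if unknown:
            raise ValueError(f"carrier contigs not in genome: {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        return list(self._names)

    @property
    def signal_contigs(self) -> list[str]:
        """Contig names excluding carrier contigs, in genome order."""
        return [n for n in self._names if n not in self.carrier_contigs]

    def length(self, contig: str) -> int:
        try:
            return self._lengths[contig]
        except KeyError:
            raise KeyError(f"unknown contig: {contig!r}") from None

    def __contains__(self, contig: str) -> bool:
        return contig in self._lengths

    def is_carrier(self, contig: str) -> bool:
        return contig in self.carrier_contigs

    def total_length(self, include_carrier: bool = False) -> int:
        names = self._names if include_carrier else self.signal_contigs
        return sum(self._lengths[n] for n in names)

    def items(self) -> Iterator[tuple[str, int]]:
        return ((n, self._lengths[n]) for n in self._names)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeModel):
            return NotImplemented
        return (
            list(self.items()) == list(other.items())
            and self.carrier_contigs == other.carrier_contigs
        )

    def __repr__(self) -> str:
        return (
            f"GenomeModel({len(self._names)} contigs, "
            f"{self.total_length(include_carrier=True):,} bp, "
            f"carrier={sorted(self.carrier_contigs)})"
        )


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """One aligned single-end read, reduced to its 5' start position."""

    contig: str
    start: int  # 0-based
    strand: str  # "+" or "-"
    barcode: str | None = None
    is_carrier: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise ValueError(f"negative read start {self.start}")

    def dedup_key(self, per_barcode: bool = False):
        """Key identifying PCR duplicates: same contig, position, orientation."""
        if per_barcode:
            return (self.contig, self.start, self.strand, self.barcode)
        return (self.contig, self.start, self.strand)


@dataclass(frozen=True, slots=True)
class Peak:
    """Scored genomic interval (narrowPeak/broadPeak semantics).

    ``neglog10_q`` is the -log10 q-value from column 9 of narrowPeak;
    ``None`` means missing (the format's ``-1`` sentinel), and such peaks
    rank last in any q-ranked procedure.
    """

    contig: str
    start: int
    end: int
    neglog10_q: float | None = None
    score: float = 0.0
    name: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"peak start must be < end, got [{self.start}, {self.end})"
            )
        if self.neglog10_q is not None and self.neglog10_q < 0:
            raise ValueError(f"neglog10_q must be >= 0, got {self.neglog10_q}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def q_rank_score(self) -> float:
        """Score used when ranking by significance; missing q ranks last (q=1)."""
        return 0.0 if self.neglog10_q is None else self.neglog10_q


@dataclass(frozen=True)
class GeneModel:
    """Gene with TSS, strand and exon structure.

    ``exons`` are half-open intervals, sorted and non-overlapping, all inside
    ``[start, end)``.  The TSS is the first transcribed base: ``start`` on the
    plus strand, ``end - 1`` on the minus strand.
    """

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start >= self.end:
            raise ValueError("gene start must be < end")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: empty exon [{s}, {e})")
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class BinnedTrack:
    """Per-contig read-start counts in fixed non-overlapping bins.

    Carrier contigs never appear in a track.  The last bin of each contig may
    cover fewer than ``binsize`` bases.
    """

    def __init__(self, genome: GenomeModel, binsize: int):
        if binsize < 1:
            raise ValueError("binsize must be >= 1")
        self.genome = genome
        self.binsize = int(binsize)
        self.counts: dict[str, np.ndarray] = {
            name: np.zeros(-(-genome.length(name) // self.binsize), dtype=np.int64)
            for name in genome.signal_contigs
        }

    def add_read(self, read: ReadRecord) -> None:
        if read.is_carrier:
            return
        self.counts[read.contig][read.start // self.binsize] += 1

    def vector(self) -> np.ndarray:
        """All bins concatenated in genome contig order."""
        return np.concatenate(
            [self.counts[n] for n in self.genome.signal_contigs]
        )

    @property
    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tstart\tend\tcount\n")
            for name in self.genome.signal_contigs:
                length = self.genome.length(name)
                for i, c in enumerate(self.counts[name]):
                    s = i * self.binsize
                    fh.write(f"{name}\t{s}\t{min(s + self.binsize, length)}\t{c}\n")


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(
    path: str | os.PathLike, carrier_contigs: Iterable[str] = ("lambda",)
) -> GenomeModel:
    """Read a two-column ``chrom.sizes`` file.

    Contigs whose name appears in ``carrier_contigs`` are flagged as carrier
    if present; absent names are ignored.
    """
    contigs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'name\\tlength'")
            try:
                contigs.append((parts[0], int(parts[1])))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer length {parts[1]!r}"
                ) from None
    present = {n for n, _ in contigs}
    return GenomeModel(contigs, carrier_contigs=set(carrier_contigs) & present)


def write_chrom_sizes(genome: GenomeModel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in genome.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# reads


def _read_from_bed6_line(
    line: str, lineno: int, genome: GenomeModel, path
) -> ReadRecord | None:
    parts = line.rstrip("\n").split("\t")
    if len(parts) == 1:  # tolerate space-separated input
        parts = line.split()
    if len(parts) < 6:
        raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(parts)}")
    contig, start_s, _end, name, _score, strand = parts[:6]
    if contig not in genome:
        raise FormatError(f"{path}:{lineno}: unknown contig {contig!r}")
    try:
        start = int(start_s)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: bad start {start_s!r}") from None
    if strand not in ("+", "-"):
        raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
    if not 0 <= start < genome.length(contig):
        raise FormatError(
            f"{path}:{lineno}: start {start} outside contig {contig!r}"
        )
    barcode = None if name in (".", "") else name
    return ReadRecord(
        contig, start, strand, barcode=barcode, is_carrier=genome.is_carrier(contig)
    )


def read_reads(
    path: str | os.PathLike,
    genome: GenomeModel,
    format: str | None = None,
    barcode_tag: str = "CB",
) -> list[ReadRecord]:
    """Load aligned single-end reads from SAM or 6-column BED.

    SAM records that are unmapped, secondary or supplementary are dropped.
    The read position is the 5' start: ``reference_start`` for forward reads,
    ``reference_end - 1`` for reverse reads.  Barcodes are taken from the SAM
    tag ``barcode_tag`` when present; in BED6 the name column carries the
    barcode (``"."`` means none).

    Raises :class:`FormatError` on unknown contigs or malformed lines.
    """
    path = os.fspath(path)
    if format is None:
        format = "sam" if path.endswith((".sam", ".bam")) else "bed6"
    if format == "bed6":
        reads = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                rec = _read_from_bed6_line(line, lineno, genome, path)
                if rec is not None:
                    reads.append(rec)
        return reads
    if format != "sam":
        raise ValueError(f"unknown read format: {format!r}")

    reads = []
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            contig = aln.reference_name
            if contig not in genome:
                raise FormatError(f"{path}: unknown contig {contig!r} in SAM")
            if aln.is_reverse:
                strand = "-"
                start = aln.reference_end - 1
            else:
                strand = "+"
                start = aln.reference_start
            barcode = None
            if aln.has_tag(barcode_tag):
                barcode = str(aln.get_tag(barcode_tag))
            reads.append(
                ReadRecord(
                    contig,
                    start,
                    strand,
                    barcode=barcode,
                    is_carrier=genome.is_carrier(contig),
                )
            )
    return reads


def write_reads(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    """Write reads as BED6; the name column carries the barcode (or ``.``)."""
    with open(path, "w") as fh:
        for r in reads:
            name = r.barcode if r.barcode is not None else "."
            fh.write(f"{r.contig}\t{r.start}\t{r.start + 1}\t{name}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# peaks


def read_peaks(
    path: str | os.PathLike, format: str | None = None
) -> list[Peak]:
    """Load peaks from narrowPeak (10 col), broadPeak (9 col) or BED3.

    The -log10 q-value is column 9; the format's ``-1`` sentinel maps to a
    missing q-value.  BED3 peaks always have missing q.
    """
    path = os.fspath(path)
    if format is None:
        if path.endswith(".narrowPeak"):
            format = "narrowPeak"
        elif path.endswith(".broadPeak"):
            format = "broadPeak"
        else:
            format = "bed3"
    ncols = {"narrowPeak": 10, "broadPeak": 9, "bed3": 3}
    if format not in ncols:
        raise ValueError(f"unknown peak format: {format!r}")
    want = ncols[format]
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < want:
                raise FormatError(
                    f"{path}:{lineno}: {format} needs {want} columns, got {len(parts)}"
                )
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            if format == "bed3":
                peaks.append(Peak(contig, start, end))
                continue
            name = parts[3]
            score = float(parts[4])
            q = float(parts[8])
            peaks.append(
                Peak(
                    contig,
                    start,
                    end,
                    neglog10_q=None if q < 0 else q,
                    score=score,
                    name=name,
                )
            )
    return peaks


def write_peaks(
    peaks: Iterable[Peak], path: str | os.PathLike, format: str = "narrowPeak"
) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            q = -1.0 if p.neglog10_q is None else p.neglog10_q
            name = p.name if p.name != "." else f"peak_{i + 1}"
            if format == "bed3":
                fh.write(f"{p.contig}\t{p.start}\t{p.end}\n")
            elif format == "broadPeak":
                fh.write(
                    f"{p.contig}\t{p.start}\t{p.end}\t{name}\t{p.score:g}\t.\t"
                    f"0\t-1\t{q:g}\n"
                )
            elif format == "narrowPeak":
                fh.write(
                    f"{p.contig}\t{p.start}\t{p.end}\t{name}\t{p.score:g}\t.\t"
                    f"0\t-1\t{q:g}\t-1\n"
                )
            else:
                raise ValueError(f"unknown peak format: {format!r}")


# ---------------------------------------------------------------------------
# genes (GTF-lite)


def read_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Read a minimal GTF: ``gene`` rows define spans, ``exon`` rows exons.

    Only ``gene_id`` is parsed from the attribute column.  GTF coordinates
    (1-based, closed) are converted to 0-based half-open.
    """
    spans: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: GTF needs 9 columns")
            contig, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            gid = None
            for token in attrs.split(";"):
                token = token.strip()
                if token.startswith("gene_id"):
                    gid = token.split(None, 1)[1].strip().strip('"')
                    break
            if gid is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            s, e = int(start) - 1, int(end)
            if feature == "gene":
                spans[gid] = (contig, strand, s, e)
                order.append(gid)
            elif feature == "exon":
                exons.setdefault(gid, []).append((s, e))
    genes = []
    for gid in order:
        contig, strand, s, e = spans[gid]
        ex = tuple(sorted(exons.get(gid, [(s, e)])))
        genes.append(GeneModel(gid, contig, strand, s, e, ex))
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.contig}\tepibench\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.contig}\tepibench\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# primitives


def dedup_reads(
    reads: Sequence[ReadRecord], per_barcode: bool = False
) -> list[ReadRecord]:
    """Remove duplicate reads mapped to the same location and orientation.

    Keeps the first occurrence of each ``(contig, start, strand)`` key (plus
    barcode when ``per_barcode``); output order follows the input.
    Idempotent.
    """
    seen = set()
    out = []
    for r in reads:
        key = r.dedup_key(per_barcode)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """Half-open intervals share at least one base."""
    return a[0] < b[1] and b[0] < a[1]


def count_overlapping(
    queries: Sequence[tuple[int, int]], subjects: Sequence[tuple[int, int]]
) -> np.ndarray:
    """For each query interval, the number of subject intervals it overlaps.

    Interval-indexed; exactly equivalent to the all-pairs brute force under
    half-open semantics (same contig namespace assumed).  Duplicate subject
    intervals are counted with multiplicity.
    """
    from collections import Counter

    tree = IntervalTree()
    for (s, e), mult in Counter(subjects).items():
        tree.addi(s, e, mult)
    return np.array(
        [sum(iv.data for iv in tree.overlap(s, e)) for s, e in queries],
        dtype=np.int64,
    )


def merge_intervals(
    intervals: Iterable[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list.

    Book-ended intervals ([0,5) and [5,9)) are merged; they cover adjacent
    bases even though they do not overlap.
    """
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def subtract_intervals(
    a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference of half-open interval unions: bases in ``a`` not in ``b``."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def points_in_intervals(
    points: np.ndarray, intervals: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Boolean mask: which points fall inside the union of the intervals.

    ``intervals`` need not be disjoint; they are merged first.  Runs in
    O((n + m) log m) via binary search on the merged boundaries.
    """
    points = np.asarray(points)
    merged = merge_intervals(intervals)
    if not merged:
        return np.zeros(points.shape, dtype=bool)
    starts = np.array([s for s, _ in merged])
    ends = np.array([e for _, e in merged])
    idx = np.searchsorted(starts, points, side="right") - 1
    inside = idx >= 0
    inside[inside] &= points[inside] < ends[idx[inside]]
    return inside


def bin_counts(
    reads: Sequence[ReadRecord], genome: GenomeModel, binsize: int
) -> BinnedTrack:
    """Count non-carrier read starts in fixed bins of ``binsize`` bp.

    A read at position ``p`` lands in bin ``p // binsize`` of its contig.
    The total count over all bins equals the number of non-carrier reads.
    """
    track = BinnedTrack(genome, binsize)
    by_contig: dict[str, list[int]] = {}
    for r in reads:
        if not r.is_carrier:
            by_contig.setdefault(r.contig, []).append(r.start)
    for contig, starts in by_contig.items():
        idx = np.asarray(starts, dtype=np.int64) // track.binsize
        np.add.at(track.counts[contig], idx, 1)
    return track
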