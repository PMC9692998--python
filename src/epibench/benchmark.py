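"""Gold-standard benchmarking of peak calls against a reference set.

The unit of evaluation is the promoter (2,000 bp upstream to 500 bp
downstream of a TSS).  Promoters overlapping at least one reference (bulk /
ENCODE) peak are the gold-standard positives; the remaining promoters are
the negatives.  A test peak set is then scored per promoter by the best
-log10 q-value of any overlapping peak, which yields coverage/precision at
a fixed call set and a ROC curve under a sweep of q-value cutoffs.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from epibench.genome_core import GeneModel, GenomeModel, Peak

__all__ = [
    "Promoter",
    "GoldStandard",
    "RocResult",
    "make_promoters",
    "build_gold_standard",
    "score_promoters",
    "coverage_precision",
    "roc_curve",
    "select_q_cutoff",
]


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    contig: str
    start: int
    end: int


@dataclass(frozen=True)
class GoldStandard:
    """Promoters partitioned into reference-supported positives and negatives."""

    promoters: tuple[Promoter, ...]
    is_positive: np.ndarray  # bool, aligned with promoters

    def __post_init__(self):
        if len(self.is_positive) != len(self.promoters):
            raise ValueError("label/promoter length mismatch")

    @property
    def n_positive(self) -> int:
        return int(self.is_positive.sum())

    @property
    def n_negative(self) -> int:
        return len(self.promoters) - self.n_positive


@dataclass(frozen=True)
class RocResult:
    """ROC points (q cutoff as -log10 q, TPR, FPR) and trapezoidal AUC.

    Points are ordered from the strictest cutoff to the loosest, anchored at
    (FPR, TPR) = (0, 0) and (1, 1); the anchors carry cutoffs +inf / -inf.
    """

    points: tuple[tuple[float, float, float], ...]  # (neglog10_q, tpr, fpr)
    auc: float

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0 + 1e-12:
            raise ValueError("AUC out of [0, 1]")
        tprs = [t for _, t, _ in self.points]
        fprs = [f for _, _, f in self.points]
        if any(b < a - 1e-12 for a, b in zip(tprs, tprs[1:])):
            raise ValueError("TPR not non-decreasing along the sweep")
        if any(b < a - 1e-12 for a, b in zip(fprs, fprs[1:])):
            raise ValueError("FPR not non-decreasing along the sweep")

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"# auc\t{self.auc:.8g}\n")
            fh.write("neglog10_q_cutoff\tq_cutoff\ttpr\tfpr\n")
            for t, tpr, fpr in self.points:
                q = 0.0 if math.isinf(t) and t > 0 else 10.0 ** (-t)
                fh.write(f"{t:.8g}\t{q:.8g}\t{tpr:.8g}\t{fpr:.8g}\n")

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "auc": self.auc,
                    "points": [
                        {"neglog10_q": t, "tpr": tpr, "fpr": fpr}
                        for t, tpr, fpr in self.points
                    ],
                },
                fh,
                indent=2,
            )
            fh.write("\n")


def make_promoters(
    genes: Sequence[GeneModel],
    upstream: int = 2000,
    downstream: int = 500,
    genome: GenomeModel | None = None,
) -> list[Promoter]:
    """Promoter intervals: ``upstream`` bp before to ``downstream`` bp after each TSS.

    Plus strand: ``[tss - upstream, tss + downstream)``; minus strand is the
    mirror ``[tss - downstream + 1, tss + upstream + 1)``.  Both cover
    ``upstream + downstream`` bases including the TSS base itself.  Intervals
    are clipped to the contig when a ``genome`` is given (and at 0 always).
    """
    out = []
    for g in genes:
        if g.strand == "+":
            s, e = g.tss - upstream, g.tss + downstream
        else:
            s, e = g.tss - downstream + 1, g.tss + upstream + 1
        s = max(0, s)
        if genome is not None:
            e = min(e, genome.length(g.contig))
        out.append(Promoter(g.gene_id, g.contig, s, e))
    return out


def _overlap_any(
    promoters: Sequence[Promoter], peaks: Sequence[Peak]
) -> np.ndarray:
    """Bool per promoter: overlaps >= 1 peak (half-open, >= 1 bp).

    A promoter overlaps some peak iff it intersects the merged peak union,
    which is disjoint and sorted, so a binary search on the union ends
    suffices.
    """
    from epibench.genome_core import merge_intervals

    by_contig: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_contig.setdefault(p.contig, []).append((p.start, p.end))
    merged = {c: merge_intervals(ivs) for c, ivs in by_contig.items()}
    hit = np.zeros(len(promoters), dtype=bool)
    for i, pr in enumerate(promoters):
        ivs = merged.get(pr.contig)
        if not ivs:
            continue
        ends = [e for _, e in ivs]
        j = np.searchsorted(ends, pr.start, side="right")
        hit[i] = j < len(ivs) and ivs[j][0] < pr.end
    return hit


def build_gold_standard(
    reference_peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    upstream: int = 2000,
    downstream: int = 500,
    genome: GenomeModel | None = None,
) -> GoldStandard:
    """Label each promoter positive iff it overlaps >= 1 reference peak."""
    if not reference_peaks:
        raise ValueError("reference peak set is empty")
    promoters = tuple(make_promoters(genes, upstream, downstream, genome))
    labels = _overlap_any(promoters, reference_peaks)
    return GoldStandard(promoters=promoters, is_positive=labels)


def score_promoters(
    test_peaks: Sequence[Peak], gold: GoldStandard
) -> np.ndarray:
    """Per-promoter score: max -log10 q over overlapping test peaks.

    Promoters hit by no test peak score -inf; peaks with a missing q-value
    contribute 0 (q = 1), i.e. they rank last among called peaks.
    """
    by_contig: dict[str, list[tuple[int, int, float]]] = {}
    for p in test_peaks:
        by_contig.setdefault(p.contig, []).append(
            (p.start, p.end, p.q_rank_score)
        )
    # sorted-by-start arrays; a window bounded by the widest peak limits the
    # candidate scan per promoter
    indexed: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
    for contig, triples in by_contig.items():
        triples.sort()
        starts = np.array([t[0] for t in triples], dtype=np.int64)
        ends = np.array([t[1] for t in triples], dtype=np.int64)
        qs = np.array([t[2] for t in triples])
        indexed[contig] = (starts, ends, qs, int((ends - starts).max()))
    scores = np.full(len(gold.promoters), -np.inf)
    for i, pr in enumerate(gold.promoters):
        if pr.contig not in indexed:
            continue
        starts, ends, qs, maxw = indexed[pr.contig]
        lo = np.searchsorted(starts, pr.start - maxw)
        hi = np.searchsorted(starts, pr.end)
        if hi > lo:
            sel = ends[lo:hi] > pr.start
            if sel.any():
                scores[i] = qs[lo:hi][sel].max()
    return scores


def coverage_precision(
    test_peaks: Sequence[Peak],
    gold: GoldStandard,
    all_peaks_denominator: bool = False,
) -> tuple[float, float]:
    """Promoter-level coverage (sensitivity) and precision of a peak set.

    coverage = positive promoters overlapped by >= 1 test peak, over all
    positive promoters.  precision = test peaks overlapping >= 1 positive
    promoter, over test peaks overlapping any promoter (or over all test
    peaks when ``all_peaks_denominator``).
    """
    if gold.n_positive == 0:
        raise ValueError("coverage denominator is zero: no positive promoters")
    pos_promoters = [
        pr for pr, lab in zip(gold.promoters, gold.is_positive) if lab
    ]
    hit_pos = _overlap_any(pos_promoters, test_peaks)
    coverage = float(hit_pos.sum() / len(pos_promoters))

    pos_ivs: dict[str, list[tuple[int, int]]] = {}
    any_ivs: dict[str, list[tuple[int, int]]] = {}
    for pr, lab in zip(gold.promoters, gold.is_positive):
        any_ivs.setdefault(pr.contig, []).append((pr.start, pr.end))
        if lab:
            pos_ivs.setdefault(pr.contig, []).append((pr.start, pr.end))
    n_in_pos = 0
    n_in_any = 0
    for p in test_peaks:
        in_any = any(
            s < p.end and e > p.start for s, e in any_ivs.get(p.contig, ())
        )
        if in_any:
            n_in_any += 1
            if any(
                s < p.end and e > p.start for s, e in pos_ivs.get(p.contig, ())
            ):
                n_in_pos += 1
    denom = len(test_peaks) if all_peaks_denominator else n_in_any
    if denom == 0:
        raise ValueError(
            "precision denominator is zero: no test peaks "
            + ("given" if all_peaks_denominator else "overlap any promoter")
        )
    return coverage, n_in_pos / denom


def roc_curve(test_peaks: Sequence[Peak], gold: GoldStandard) -> RocResult:
    """ROC over q-value cutoffs, one promoter = one instance.

    Each promoter is scored by the best -log10 q of its overlapping test
    peaks; sweeping the cutoff from strict to loose over the unique scores
    yields (TPR, FPR) points.  AUC by the trapezoidal rule with (0,0) and
    (1,1) anchors appended.
    """
    if gold.n_positive == 0 or gold.n_negative == 0:
        raise ValueError("ROC needs both positive and negative promoters")
    scores = score_promoters(test_peaks, gold)
    pos = scores[gold.is_positive]
    neg = scores[~gold.is_positive]
    cutoffs = np.unique(scores[np.isfinite(scores)])[::-1]
    points: list[tuple[float, float, float]] = [(np.inf, 0.0, 0.0)]
    for t in cutoffs:
        tpr = float((pos >= t).mean())
        fpr = float((neg >= t).mean())
        points.append((float(t), tpr, fpr))
    points.append((-np.inf, 1.0, 1.0))
    fprs = np.array([f for _, _, f in points])
    tprs = np.array([t for _, t, _ in points])
    auc = float(np.trapezoid(tprs, fprs))
    return RocResult(points=tuple(points), auc=auc)


def select_q_cutoff(roc: RocResult) -> float:
    """Operating q-value cutoff: the point maximising Youden's J = TPR - FPR.

    Ties resolve to the strictest (largest -log10 q) cutoff.  Returned on
    the q scale, ``q = 10 ** -cutoff``; anchors (J = 0) are never selected
    unless every point has J = 0, in which case the strict anchor wins and
    q = 0 is returned.
    """
    best_t, best_j = np.inf, -np.inf
    for t, tpr, fpr in roc.points:
        j = tpr - fpr
        if j > best_j or (j == best_j and t > best_t):
            best_t, best_j = t, j
    if math.isinf(best_t):
        return 0.0 if best_t > 0 else 1.0
    return 10.0 ** (-best_t)
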