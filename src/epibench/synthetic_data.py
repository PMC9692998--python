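"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure of carrier-assisted
low-input chromatin profiling data:

- reads drawn from a mixture of peak-concentrated signal and uniform
  genomic background, with a configurable in-peak fraction (the generative
  counterpart of FRiP) and a small fraction landing on a carrier (phage
  lambda) contig;
- 96 plate-indexed single cells addressed by the Cartesian product of T5
  and T7 Tn5 barcodes, each cell capturing a Bernoulli subset of the truth
  peaks and receiving a log-normal number of reads;
- two-condition negative-binomial peak-count matrices with planted log2
  fold-change effects, for differential-methylation benchmarking.

No sequence-level simulation is attempted (no FASTQ, no error model, no
mappability); reads are positions, which is all the downstream metrics
consume.  All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from epibench.genome_core import (
    GeneModel,
    GenomeModel,
    LAMBDA_LENGTH,
    Peak,
    ReadRecord,
    merge_intervals,
    subtract_intervals,
)

__all__ = [
    "TruthPeakSet",
    "ScSimConfig",
    "CellTruth",
    "DmrSimConfig",
    "simulate_genome",
    "simulate_annotation",
    "simulate_truth_peaks",
    "simulate_reads",
    "simulate_single_cells",
    "simulate_dmr_counts",
    "DEFAULT_T5_BARCODES",
    "DEFAULT_T7_BARCODES",
]

# 8 x 12 = 96 plate positions; 6-mer Tn5 index sequences.
DEFAULT_T5_BARCODES = (
    "ATCACG", "CGATGT", "TTAGGC", "TGACCA",
    "ACAGTG", "GCCAAT", "CAGATC", "ACTTGA",
)
DEFAULT_T7_BARCODES = (
    "GATCAG", "TAGCTT", "GGCTAC", "CTTGTA",
    "AGTCAA", "AGTTCC", "ATGTCA", "CCGTCC",
    "GTCCGC", "GTGAAA", "GTGGCC", "GTTTCG",
)


@dataclass(frozen=True)
class TruthPeakSet:
    """Non-overlapping truth peaks with per-peak emission weights.

    ``weights`` are relative read-generation intensities (sum to 1);
    ``frip`` is the generative in-peak read fraction f.
    """

    peaks: tuple[Peak, ...]
    weights: np.ndarray
    frip: float

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.peaks):
            raise ValueError("one weight per peak required")
        if len(w) and (np.any(w <= 0) or not np.isclose(w.sum(), 1.0)):
            raise ValueError("weights must be positive and sum to 1")
        if not 0.0 <= self.frip <= 1.0:
            raise ValueError("frip must be in [0, 1]")
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for p in self.peaks:
            by_contig.setdefault(p.contig, []).append((p.start, p.end))
        for contig, ivs in by_contig.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"truth peaks overlap on {contig}")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class ScSimConfig:
    """Plate-based single-cell simulation parameters.

    ``mean_reads_per_cell`` is the arithmetic mean of the log-normal
    per-cell read-count distribution (default 6,500 unique reads, the scale
    the assay achieves per cell); ``capture_rate`` is the per-peak Bernoulli
    probability that a cell captures a given truth peak.
    """

    n_cells: int = 96
    mean_reads_per_cell: float = 6500.0
    sigma_log: float = 0.5
    capture_rate: float = 0.3
    t5_barcodes: tuple[str, ...] = DEFAULT_T5_BARCODES
    t7_barcodes: tuple[str, ...] = DEFAULT_T7_BARCODES

    def __post_init__(self):
        if len(set(self.t5_barcodes)) != len(self.t5_barcodes):
            raise ValueError("duplicate T5 barcodes")
        if len(set(self.t7_barcodes)) != len(self.t7_barcodes):
            raise ValueError("duplicate T7 barcodes")
        if self.n_cells > len(self.t5_barcodes) * len(self.t7_barcodes):
            raise ValueError("n_cells exceeds barcode combinations")
        if not 0.0 < self.capture_rate <= 1.0:
            raise ValueError("capture_rate must be in (0, 1]")

    def barcode(self, i: int) -> str:
        """Barcode of cell ``i``: T5 index = i // |T7|, T7 index = i % |T7|."""
        n7 = len(self.t7_barcodes)
        return self.t5_barcodes[i // n7] + self.t7_barcodes[i % n7]


@dataclass(frozen=True)
class CellTruth:
    """Generator bookkeeping for one simulated cell."""

    barcode: str
    n_reads: int
    captured_peaks: tuple[int, ...]  # indices into TruthPeakSet.peaks
    n_in_peak: int

    @property
    def in_peak_fraction(self) -> float:
        return self.n_in_peak / self.n_reads if self.n_reads else 0.0


@dataclass(frozen=True)
class DmrSimConfig:
    """Two-condition negative-binomial count simulation parameters.

    Counts follow NB(mean mu, dispersion alpha) with Var = mu + alpha*mu^2.
    A fraction ``effect_fraction`` of peaks gets a planted log2 fold change
    of magnitude ``lfc`` in condition 2 (``hyper_fraction`` of those up, the
    rest down).  Two replicates per condition match a typical low-input
    study design.
    """

    n_peaks: int = 2000
    n_replicates: int = 2
    baseline_mean: float = 100.0
    dispersion: float = 0.05
    effect_fraction: float = 0.1
    lfc: float = 2.0
    hyper_fraction: float = 0.5
    peak_width: int = 500

    def __post_init__(self):
        if min(self.n_peaks, self.n_replicates, self.peak_width) < 1:
            raise ValueError("n_peaks, n_replicates, peak_width must be >= 1")
        if self.baseline_mean <= 0 or self.dispersion < 0:
            raise ValueError("baseline_mean must be > 0 and dispersion >= 0")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------


def simulate_genome(
    n_contigs: int = 2,
    contig_length: int = 1_000_000,
    include_carrier: bool = True,
    seed: int = 0,
) -> GenomeModel:
    """A toy genome of equal-length contigs plus an optional lambda carrier."""
    if contig_length < 10_000:
        raise ValueError("contig_length must be >= 10 kb")
    contigs = [(f"chr{i + 1}", contig_length) for i in range(n_contigs)]
    carrier: tuple[str, ...] = ()
    if include_carrier:
        contigs.append(("lambda", LAMBDA_LENGTH))
        carrier = ("lambda",)
    return GenomeModel(contigs, carrier_contigs=carrier)


def _distribute(n: int, sizes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Split n items over bins with probability proportional to size."""
    return rng.multinomial(n, sizes / sizes.sum())


def simulate_annotation(
    genome: GenomeModel, n_genes: int, seed: int = 0
) -> list[GeneModel]:
    """Non-overlapping genes with 2-10 exons each and 50/50 strand mix.

    Genes are laid out left to right per contig with random gaps, so spans
    never overlap; each contig receives genes in proportion to its length.
    """
    rng = np.random.default_rng(seed)
    contigs = genome.signal_contigs
    lengths = np.array([genome.length(c) for c in contigs], dtype=float)
    per_contig = _distribute(n_genes, lengths, rng)
    genes: list[GeneModel] = []
    for contig, n_here in zip(contigs, per_contig):
        clen = genome.length(contig)
        if n_here == 0:
            continue
        # reserve room: mean slot = clen / n, gene uses up to 60% of its slot
        slot = clen // int(n_here)
        pos = 0
        for j in range(int(n_here)):
            slot_end = min(pos + slot, clen)
            max_len = int((slot_end - pos) * 0.6)
            glen = int(rng.integers(2_000, max(2_001, max_len)))
            glen = min(glen, slot_end - pos - 1)
            if glen < 200:
                pos = slot_end
                continue
            start = pos + int(rng.integers(0, slot_end - pos - glen))
            end = start + glen
            n_exons = int(rng.integers(2, 11))
            exons = _draw_exons(start, end, n_exons, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene_{len(genes) + 1:05d}",
                    contig=contig,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                )
            )
            pos = slot_end
    return genes


def _draw_exons(
    start: int, end: int, n_exons: int, rng: np.random.Generator
) -> tuple[tuple[int, int], ...]:
    """n_exons disjoint intervals covering both span ends (first/last exon)."""
    n_cuts = 2 * n_exons - 2
    if end - start - 2 < n_cuts or n_exons == 1:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(start + 1, end - 1), n_cuts, replace=False))
    bounds = [start, *cuts.tolist(), end]
    exons = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons)]
    return tuple((s, e) for s, e in exons if e > s)


def simulate_truth_peaks(
    genome: GenomeModel,
    n_peaks: int = 200,
    frip: float = 0.25,
    seed: int = 0,
    median_width: int = 1000,
    sigma_width: float = 0.5,
    genes: list[GeneModel] | None = None,
    at_promoters: float = 0.0,
) -> TruthPeakSet:
    """Non-overlapping scored peaks with log-normal widths.

    Widths are log-normal with the given median (1 kb resembles H3K4me3
    promoter peaks); emission weights are proportional to width.  When
    ``genes`` are supplied, a fraction ``at_promoters`` of peaks is centred
    on a TSS so TSS-profile tests have promoter-concentrated signal.
    Each peak gets a -log10 q-value increasing with its emission weight.
    """
    rng = np.random.default_rng(seed)
    contigs = genome.signal_contigs
    lengths = np.array([genome.length(c) for c in contigs], dtype=float)
    widths = np.maximum(
        50, rng.lognormal(np.log(median_width), sigma_width, n_peaks)
    ).astype(np.int64)

    n_prom = int(round(at_promoters * n_peaks)) if genes else 0
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    records: list[tuple[str, int, int]] = []

    def try_place(contig: str, start: int, width: int) -> bool:
        end = start + width
        if start < 0 or end > genome.length(contig):
            return False
        for s, e in placed[contig]:
            if start < e and s < end:
                return False
        placed[contig].append((start, end))
        records.append((contig, start, end))
        return True

    if n_prom:
        tss_pool = rng.permutation(len(genes))
        k = 0
        for gi in tss_pool:
            if k >= n_prom:
                break
            g = genes[gi]
            w = int(widths[len(records)])
            if try_place(g.contig, g.tss - w // 2, w):
                k += 1
    attempts = 0
    while len(records) < n_peaks and attempts < 50 * n_peaks:
        attempts += 1
        ci = rng.choice(len(contigs), p=lengths / lengths.sum())
        contig = contigs[ci]
        w = int(widths[len(records)])
        start = int(rng.integers(0, max(1, genome.length(contig) - w)))
        try_place(contig, start, w)
    if len(records) < n_peaks:
        raise RuntimeError("could not place all truth peaks without overlap")

    w_arr = np.array([e - s for _, s, e in records], dtype=float)
    weights = w_arr / w_arr.sum()
    # significance grows with emission weight, with noise; keeps q ranking
    # informative but imperfect, as real peak callers are
    neglog_q = np.maximum(
        0.0, 20 * weights / weights.max() + rng.normal(0, 1.0, n_peaks)
    )
    peaks = tuple(
        Peak(c, s, e, neglog10_q=float(q), score=float(10 * q), name=f"truth_{i + 1}")
        for i, ((c, s, e), q) in enumerate(zip(records, neglog_q))
    )
    return TruthPeakSet(peaks=peaks, weights=weights, frip=frip)


def _uniform_positions(
    n: int, genome: GenomeModel, rng: np.random.Generator, carrier: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """(contig index, position) for n reads uniform on the (non-)carrier genome."""
    names = (
        sorted(genome.carrier_contigs) if carrier else genome.signal_contigs
    )
    lengths = np.array([genome.length(c) for c in names], dtype=np.int64)
    ci = rng.choice(len(names), size=n, p=lengths / lengths.sum())
    pos = (rng.random(n) * lengths[ci]).astype(np.int64)
    return ci, pos


class _BackgroundSampler:
    """Uniform sampler over the non-carrier genome minus the truth peaks.

    Background reads avoid peak space so the realised in-peak read fraction
    converges to the configured f for any peak set, making the generative
    FRiP exact rather than approximate.
    """

    def __init__(self, genome: GenomeModel, truth: TruthPeakSet):
        peak_ivs: dict[str, list[tuple[int, int]]] = {}
        for p in truth.peaks:
            peak_ivs.setdefault(p.contig, []).append((p.start, p.end))
        self.contigs: list[str] = []
        self.intervals: list[tuple[int, int]] = []
        for c in genome.signal_contigs:
            free = subtract_intervals(
                [(0, genome.length(c))], peak_ivs.get(c, [])
            )
            for iv in free:
                self.contigs.append(c)
                self.intervals.append(iv)
        widths = np.array([e - s for s, e in self.intervals], dtype=np.int64)
        self.cum = np.concatenate([[0], np.cumsum(widths)])
        if self.cum[-1] == 0:
            raise ValueError("truth peaks cover the whole genome")

    def draw(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        offs = (rng.random(n) * self.cum[-1]).astype(np.int64)
        idx = np.searchsorted(self.cum, offs, side="right") - 1
        starts = np.array([s for s, _ in self.intervals], dtype=np.int64)
        pos = starts[idx] + (offs - self.cum[idx])
        contigs = np.array(self.contigs, dtype=object)[idx]
        return contigs, pos


def simulate_reads(
    truth: TruthPeakSet,
    n_reads: int,
    carrier_fraction: float,
    genome: GenomeModel,
    seed: int = 0,
) -> list[ReadRecord]:
    """Draw reads from the carrier/peak/background mixture.

    Each read independently: with probability ``carrier_fraction`` it is
    placed uniformly on the carrier contig; otherwise with probability
    ``truth.frip`` inside a truth peak (peak chosen by emission weight,
    position uniform within the peak), else uniformly on the non-carrier
    genome outside the peaks, so the realised in-peak fraction matches the
    configured FRiP.  Strands are uniform.
    """
    if not 0.0 <= carrier_fraction < 1.0:
        raise ValueError("carrier_fraction must be in [0, 1)")
    if truth.frip > 0 and not truth.peaks:
        raise ValueError("cannot draw in-peak reads from an empty truth set")
    if carrier_fraction > 0 and not genome.carrier_contigs:
        raise ValueError("carrier_fraction > 0 but genome has no carrier contig")
    rng = np.random.default_rng(seed)
    u = rng.random(n_reads)
    is_carrier = u < carrier_fraction
    is_peak = (~is_carrier) & (rng.random(n_reads) < truth.frip)
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")

    contig_of = np.empty(n_reads, dtype=object)
    pos = np.empty(n_reads, dtype=np.int64)

    n_car = int(is_carrier.sum())
    if n_car:
        names = sorted(genome.carrier_contigs)
        ci, p = _uniform_positions(n_car, genome, rng, carrier=True)
        contig_of[is_carrier] = np.array(names, dtype=object)[ci]
        pos[is_carrier] = p
    n_pk = int(is_peak.sum())
    if n_pk:
        pk_idx = rng.choice(len(truth.peaks), size=n_pk, p=truth.weights)
        starts = np.array([p.start for p in truth.peaks], dtype=np.int64)
        widths = np.array([p.width for p in truth.peaks], dtype=np.int64)
        offs = (rng.random(n_pk) * widths[pk_idx]).astype(np.int64)
        contig_of[is_peak] = np.array(
            [p.contig for p in truth.peaks], dtype=object
        )[pk_idx]
        pos[is_peak] = starts[pk_idx] + offs
    is_bg = ~(is_carrier | is_peak)
    n_bg = int(is_bg.sum())
    if n_bg:
        c, p = _BackgroundSampler(genome, truth).draw(n_bg, rng)
        contig_of[is_bg] = c
        pos[is_bg] = p

    return [
        ReadRecord(
            contig_of[i],
            int(pos[i]),
            strands[i],
            is_carrier=bool(is_carrier[i]),
        )
        for i in range(n_reads)
    ]


def simulate_single_cells(
    truth: TruthPeakSet,
    cfg: ScSimConfig,
    genome: GenomeModel,
    seed: int = 0,
) -> tuple[list[ReadRecord], dict[str, CellTruth]]:
    """Barcoded reads for ``cfg.n_cells`` plate-indexed cells, plus bookkeeping.

    Cell i captures each truth peak independently with probability
    ``cfg.capture_rate``; its in-peak reads are drawn only from the captured
    subset (weights renormalised).  Background reads are uniform over the
    non-peak genome, so each cell's realised in-peak fraction is Binomial
    with rate ``truth.frip``.  The returned :class:`CellTruth` records the
    captured peak indices and the realised in-peak read count for oracle
    use.
    """
    rng = np.random.default_rng(seed)
    background = _BackgroundSampler(genome, truth)
    mu_log = np.log(cfg.mean_reads_per_cell) - cfg.sigma_log**2 / 2.0
    n_per_cell = np.maximum(
        1, np.round(rng.lognormal(mu_log, cfg.sigma_log, cfg.n_cells))
    ).astype(int)

    starts = np.array([p.start for p in truth.peaks], dtype=np.int64)
    widths = np.array([p.width for p in truth.peaks], dtype=np.int64)
    contig_arr = np.array([p.contig for p in truth.peaks], dtype=object)

    all_reads: list[ReadRecord] = []
    cell_truth: dict[str, CellTruth] = {}
    for i in range(cfg.n_cells):
        barcode = cfg.barcode(i)
        n = int(n_per_cell[i])
        captured = np.flatnonzero(rng.random(len(truth.peaks)) < cfg.capture_rate)
        p_in = truth.frip if len(captured) else 0.0
        in_peak = rng.random(n) < p_in
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        contig_of = np.empty(n, dtype=object)
        pos = np.empty(n, dtype=np.int64)
        n_pk = int(in_peak.sum())
        if n_pk:
            w = truth.weights[captured]
            pk = captured[rng.choice(len(captured), size=n_pk, p=w / w.sum())]
            offs = (rng.random(n_pk) * widths[pk]).astype(np.int64)
            contig_of[in_peak] = contig_arr[pk]
            pos[in_peak] = starts[pk] + offs
        n_bg = n - n_pk
        if n_bg:
            c, p = background.draw(n_bg, rng)
            contig_of[~in_peak] = c
            pos[~in_peak] = p
        for j in range(n):
            all_reads.append(
                ReadRecord(contig_of[j], int(pos[j]), strands[j], barcode=barcode)
            )
        cell_truth[barcode] = CellTruth(
            barcode=barcode,
            n_reads=n,
            captured_peaks=tuple(int(k) for k in captured),
            n_in_peak=n_pk,
        )
    return all_reads, cell_truth


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, dispersion) with Var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_dmr_counts(
    cfg: DmrSimConfig,
    genes: list[GeneModel],
    genome: GenomeModel,
    seed: int = 0,
) -> tuple[list[Peak], pd.DataFrame, pd.DataFrame]:
    """Peaks, a peaks x samples count matrix, and per-peak truth labels.

    Peaks are placed across promoter / exonic / intronic / intergenic space
    (roughly uniformly over eligible locations of each class under the
    promoter > exonic > intronic priority).  Counts are NB with the
    configured mean and dispersion; planted peaks have their condition-2
    mean multiplied by ``2**(+/- cfg.lfc)``.
    """
    from epibench.benchmark import make_promoters

    rng = np.random.default_rng(seed)
    candidates = _class_candidates(genes, genome, make_promoters)
    classes = ("promoter", "exonic", "intronic", "intergenic")
    usable = {
        cls: [(c, s, e) for c, s, e in candidates[cls] if e - s >= cfg.peak_width]
        for cls in classes
    }
    avail = [cls for cls in classes if usable[cls]]
    if not avail:
        raise ValueError("annotation leaves no room for any peak class")

    peaks: list[Peak] = []
    intended: list[str] = []
    taken: dict[str, list[tuple[int, int]]] = {}

    def place_in(cls: str) -> bool:
        for _ in range(200):
            c, s, e = usable[cls][int(rng.integers(0, len(usable[cls])))]
            start = int(rng.integers(s, e - cfg.peak_width + 1))
            end = start + cfg.peak_width
            if all(
                not (start < te and ts < end) for ts, te in taken.get(c, [])
            ):
                taken.setdefault(c, []).append((start, end))
                peaks.append(
                    Peak(
                        c,
                        start,
                        end,
                        neglog10_q=3.0,
                        name=f"peak_{len(peaks) + 1:05d}",
                    )
                )
                intended.append(cls)
                return True
        return False

    rotation = list(avail)
    i = 0
    while len(peaks) < cfg.n_peaks:
        cls = rotation[i % len(rotation)]
        if not place_in(cls):
            # class space exhausted: drop it from the rotation
            rotation.remove(cls)
            if not rotation:
                raise RuntimeError(
                    f"genome too small for {cfg.n_peaks} peaks of "
                    f"{cfg.peak_width} bp"
                )
            continue
        i += 1

    n = len(peaks)
    n_de = int(round(cfg.effect_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    direction = np.array(["null"] * n, dtype=object)
    lfc_true = np.zeros(n)
    if n_de:
        up = rng.random(n_de) < cfg.hyper_fraction
        direction[de_idx[up]] = "hyper"
        direction[de_idx[~up]] = "hypo"
        lfc_true[de_idx[up]] = cfg.lfc
        lfc_true[de_idx[~up]] = -cfg.lfc

    mu1 = np.full(n, cfg.baseline_mean)
    mu2 = mu1 * np.power(2.0, lfc_true)
    cols = {}
    for r in range(cfg.n_replicates):
        cols[f"cond1_rep{r + 1}"] = _nb_draw(rng, mu1, cfg.dispersion)
    for r in range(cfg.n_replicates):
        cols[f"cond2_rep{r + 1}"] = _nb_draw(rng, mu2, cfg.dispersion)
    index = [p.name for p in peaks]
    counts = pd.DataFrame(cols, index=index)
    truth = pd.DataFrame(
        {
            "direction": direction,
            "true_lfc": lfc_true,
            "intended_class": intended,
        },
        index=index,
    )
    return peaks, counts, truth


def _class_candidates(genes, genome, make_promoters):
    """Per-class lists of (contig, start, end) where a peak of that class fits.

    Mirrors the annotation priority: exonic space excludes promoters,
    intronic excludes promoters and exons, intergenic excludes everything.
    """
    by_contig: dict[str, dict[str, list[tuple[int, int]]]] = {
        c: {"prom": [], "exon": [], "span": []} for c in genome.signal_contigs
    }
    for pr in make_promoters(genes, genome=genome):
        by_contig[pr.contig]["prom"].append((pr.start, pr.end))
    for g in genes:
        by_contig[g.contig]["span"].append(g.span)
        by_contig[g.contig]["exon"].extend(g.exons)
    out = {"promoter": [], "exonic": [], "intronic": [], "intergenic": []}
    for contig in genome.signal_contigs:
        d = by_contig[contig]
        prom = merge_intervals(d["prom"])
        exon = merge_intervals(d["exon"])
        span = merge_intervals(d["span"])
        genic_or_prom = merge_intervals(prom + span)
        whole = [(0, genome.length(contig))]
        for s, e in prom:
            out["promoter"].append((contig, s, e))
        for s, e in subtract_intervals(exon, prom):
            out["exonic"].append((contig, s, e))
        for s, e in subtract_intervals(subtract_intervals(span, exon), prom):
            out["intronic"].append((contig, s, e))
        for s, e in subtract_intervals(whole, genic_or_prom):
            out["intergenic"].append((contig, s, e))
    return out
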