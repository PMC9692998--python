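# Methods

This note documents the statistical procedures implemented in `epibench`,
the assumptions behind the synthetic-data generators, and the numerical
conventions chosen where the field's practice leaves room.

## Coordinates, reads and carrier accounting

All intervals are 0-based, half-open (BED-native); SAM positions are
converted on input.  A read is reduced to the single base at its 5′ end
(`reference_start` for forward, `reference_end − 1` for reverse
alignments): every metric in the package is a ratio of read counts, for
which point membership is sufficient, so fragment extension and smoothing
are deliberately out of scope.  Duplicates are reads at the same contig,
position and orientation; the first occurrence in input order is kept,
which makes deduplication deterministic and idempotent.  Whether
single-cell libraries are deduplicated per cell or pooled is exposed as the
`per_barcode` flag rather than fixed, since either convention is found in
practice; the pipeline deduplicates per cell.

Carrier DNA (the 48,502-bp phage lambda genome appended to the alignment
reference) is recognised purely by contig name.  Carrier reads count toward
the contamination percentage and are excluded from every signal metric
(FRiP, binned tracks, TSS profiles, peak counts).

## QC statistics

**FRiP** is the fraction of non-carrier deduplicated reads whose start lies
inside the union of the peak set.  Peaks are merged before counting, so
nested or overlapping peaks cannot double-count a read, and
`frip(reads, merge(peaks)) == frip(reads, peaks)` holds by construction.

**Replicate correlation** is the Pearson *r* of raw read counts in
non-overlapping bins across all non-carrier contigs — 4 kb by default, 10
kb for coarse methylome comparisons.  Zero bins are retained and counts are
not log-transformed; with most of the genome empty, *r* is dominated by the
shared peak structure, which is what the statistic is meant to capture.
Constant tracks are an error rather than a NaN.

**TSS profiles** divide ±`flank` (3 kb) around each TSS into `binsize`
(200 bp) bins oriented 5′→3′ (minus-strand windows are reversed, so
mirroring every gene's strand reverses the profile exactly), count read
starts per bin, divide by the library's total mapped reads, and average
over genes.  Windows clipped at contig edges keep their genes in the
average with zeros in the out-of-contig bins; dropping those genes would
bias the profile toward long contigs.

## Promoter gold standard and ROC

Promoters span [TSS − 2000, TSS + 500) on the plus strand and the strand
mirror on the minus strand (both 2,500 bp, containing the TSS base), clipped
to the contig.  Promoters overlapping ≥1 bp of a reference (bulk/ENCODE)
peak are the gold-standard positives; all other promoters are the
negatives.

The benchmark unit is the promoter, not the raw peak: true/false positive
*rates* need a bounded negative class, and only the promoter universe
provides one.  Each promoter is scored by the best −log10 *q* of any
overlapping test peak (−∞ if none; a peak with a missing *q*-value scores 0,
i.e. ranks last among called peaks).  Sweeping the cutoff over the unique
scores from strict to loose yields TPR/FPR points, anchored at (0,0) and
(1,1); AUC is the trapezoidal integral, which equals the Mann–Whitney
statistic P(score⁺ > score⁻) + ½·P(tie) — a property the test suite checks
exactly.  The sweep filters one fixed peak set post hoc rather than
re-running a peak caller per cutoff.  The operating cutoff maximises
Youden's *J* = TPR − FPR, ties resolving to the stricter cutoff; reported
on the *q* scale as 10^(−cutoff).

Coverage is the fraction of positive promoters overlapped by ≥1 test peak.
Precision's denominator is the test peaks that overlap *any* promoter (the
`all_peaks_denominator` flag switches to all test peaks): a promoter-level
precision should not penalise distal peaks that the promoter universe
cannot adjudicate.

## Single-cell evaluation

Cells are addressed by the Cartesian product of T5 and T7 Tn5 barcodes
(8 × 12 = 96 by default); matching is exact, with an off-by-default
Hamming-1 rescue, and non-matching reads land in an `undetermined` bin so
demultiplexing always partitions the input.  Per cell, sensitivity is the
fraction of reference peaks recovered by ≥1 read ("recovered" has no
minimum-read threshold) and precision the fraction of the cell's reads
inside reference peaks.  Cells are ranked independently per metric for the
top-5% summary (top ⌈0.05·n⌉ cells).  The matched-depth random control
draws uniform positions; its expected precision is the merged-peak fraction
of the genome, and its expected sensitivity has the closed occupancy form
mean over peaks of 1 − (1 − wᵢ/G)ⁿ.  Pseudobulk pooling concatenates
per-cell deduplicated reads — same-position reads from different cells are
distinct molecules and are kept.

## DMR calling

Counts are read-start memberships per peak per sample.  Peaks with a total
of more than 10 counts across samples are retained — the threshold is
strict (a total of exactly 10 is dropped), applied to the total by default
with a per-sample variant available.  Size factors are plain
median-of-ratios over peaks with all-positive counts.

The test is a per-peak negative-binomial Wald test, written for the
two-condition, few-replicate regime:

- **Dispersion.**  Method-of-moments on normalised counts with pooled
  within-condition variance, floored at 1e−8.  Because a 2+2 design gives
  hopelessly noisy per-peak estimates, they are shrunk toward a fitted
  trend α(μ) = a₀ + a₁/μ by empirical-Bayes weighting in log space: the
  sampling variance of a log dispersion estimate is approximated by
  trigamma(df/2) (df = samples − conditions), the prior variance by the
  excess spread of the log residuals (floored at 0.25), and the posterior
  weight on the trend follows from the usual normal–normal form.  With one
  replicate per condition, dispersion is estimated across conditions
  (conservative, since it absorbs the condition effect) and a warning is
  issued.
- **Effect and test.**  log2FC = log2((m₂ + ½)/(m₁ + ½)) on normalised
  condition means; the 0.5 pseudocount keeps zero-count conditions finite
  and shrinks extreme ratios slightly.  The Wald variance comes from the
  delta method with Var(K/s) = μ/s + αμ²; p-values are two-sided normal,
  FDR is Benjamini–Hochberg.  Swapping condition labels negates every
  log2FC exactly and preserves p-values (the reference condition is the
  lexicographically smaller label).
- **Thresholds.**  hyper: log2FC ≥ +1 and FDR < 0.001; hypo: log2FC ≤ −1
  and FDR < 0.001; the magnitude bound is inclusive, the FDR bound strict.

This is a self-contained pipeline with its own documented conventions —
it is validated against this package's oracle definitions and
cross-checked for sign and approximate effect size against an independent
NB-GLM implementation in the test suite, but numerical equivalence with
any external differential-binding tool is not claimed.

Genomic classification follows the conventional priority hierarchy
promoter > exonic > intronic > intergenic, testing the DMR interval against
promoter unions, exon unions, gene-spans-minus-exons, and the remainder.
Assignment of intergenic DMRs to genes is not attempted.

## Synthetic-data generators

The generators emulate the statistical structure the analyses assume, not
sequences: no FASTQ, error model or mappability.  All are bit-reproducible
for a fixed seed, with one RNG stream per top-level call and derived
offsets for sub-streams.

- **Truth peaks** have log-normal widths (median 1 kb, resembling H3K4me3
  promoter peaks) and emission weights proportional to width; a
  configurable fraction is centred on TSSs.  Their −log10 *q* scores grow
  with emission weight plus noise, so *q*-ranking is informative but
  imperfect, as real callers are.
- **Bulk reads** mix three components: carrier (uniform on lambda, rate
  *c*), in-peak (rate *f*, peak by emission weight, position uniform in
  peak), and background.  Background positions are uniform on the
  non-carrier genome *excluding* peak space, so the realised in-peak
  fraction is exactly Binomial(*f*) regardless of how much of the genome
  the peaks cover — making the generative FRiP an exact target rather than
  an approximation that only holds for sparse peak sets.
- **Single cells** (96 per plate) capture each truth peak independently
  with probability 0.3 — a free parameter standing in for per-cell capture
  efficiency, not an estimate from data — and receive log-normal read
  counts with arithmetic mean 6,500 (σ_log = 0.5), the per-cell unique-read
  scale such assays achieve.  In-peak reads come only from the captured
  subset; the generator records each cell's captured peaks and realised
  in-peak count for oracle use.
- **DMR counts** are NB(μ = 100, α = 0.05) with 2 replicates per condition
  and 2,000 peaks by default; 10% carry a planted log2FC of ±2.  Peaks are
  placed across the four genomic classes (cycling through whichever classes
  still have room), which lets classification be validated against intended
  truth.

What passing tests on this data do **not** show: robustness to mappability
artifacts, GC bias, copy-number variation, fragment-length effects, barcode
sequencing errors, or peak-caller idiosyncrasies — none of which the
generators model.

## Problem sizes and tolerances

Simulation-based checks run at 10⁵ reads for rate recovery (binomial 3·SE
tolerances), 96 cells for plate evaluation, and five seeds of the
2,000-peak DMR scenario for sensitivity/FDR — sizes at which the sampling
bands are tight enough to be meaningful while the whole suite stays fast.
Exact-equivalence checks (AUC vs Mann–Whitney, interval index vs brute
force) use hundreds of random instances at up to 500 promoters / 2,000
intervals.  Floating-point equality is asserted at 1e−12 where the
quantities are algebraically identical, and statistical checks never assert
tighter than 3 standard errors of the relevant estimator.
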