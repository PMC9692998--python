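# epibench

Quality control, gold-standard benchmarking and differential-methylation
analysis for **carrier-assisted low-input ChIP-seq and MeDIP-seq** data.

Low-input chromatin profiling protocols spike exogenous carrier material
(phage lambda DNA, modified histone peptides) into the library preparation
to prevent sample loss when starting from tens of cells — or single cells
indexed by combinatorial Tn5 barcodes.  Judging whether such an experiment
worked, and comparing it against bulk references, comes down to a small set
of standard statistics.  `epibench` implements that analysis layer as a
tested, reusable library over aligned read positions (SAM or BED), peak
calls (narrowPeak/broadPeak) and gene annotations:

- **Library QC** — duplication rate (reads at the same position and
  orientation collapse to one), carrier contamination (% of reads on the
  lambda contig), FRiP (fraction of reads in peaks), and genome-wide
  replicate correlation: Pearson *r* between read counts in 4-kb bins
  (10-kb bins for coarse methylome comparisons).
- **TSS profiles** — average read density in 200-bp bins over ±3 kb around
  transcription start sites, oriented 5′→3′ and normalised per mapped read.
- **Gold-standard benchmarking** — promoters ([TSS − 2000, TSS + 500)) that
  overlap a bulk/ENCODE reference peak are the positives, the rest
  negatives; a test peak set yields promoter-level coverage (sensitivity)
  and precision, plus a ROC curve over −log10 *q* cutoffs with trapezoidal
  AUC and a Youden-*J* operating point.
- **Single-cell evaluation** — exact T5×T7 barcode demultiplexing, per-cell
  sensitivity (fraction of reference peaks recovered by ≥1 read) and
  precision (fraction of reads inside reference peaks), top-5% summaries, a
  matched-depth uniform-random control, and pooled pseudobulk.
- **DMR calling** — peak × sample count matrices, a strict >10 total-count
  filter, median-of-ratios normalisation, a negative-binomial Wald test on
  log2 fold changes with empirical-Bayes dispersion shrinkage,
  Benjamini–Hochberg FDR, thresholds |log2FC| ≥ 1 and FDR < 0.001, and
  promoter / exonic / intronic / intergenic classification.
- **Synthetic data** — generators for genomes, annotations, truth peaks,
  bulk reads, 96-cell plates and two-condition NB count matrices with
  planted effects, so every stage can be validated against known truth
  without downloading any dataset.

## Worked example

```python
from epibench import synthetic_data as sd, qc_metrics as qc, benchmark as bm

genome = sd.simulate_genome(n_contigs=2, contig_length=1_000_000, seed=0)
genes = sd.simulate_annotation(genome, 300, seed=1)
truth = sd.simulate_truth_peaks(genome, n_peaks=200, frip=0.25, seed=2,
                                genes=genes, at_promoters=0.5)
reads = sd.simulate_reads(truth, 100_000, carrier_fraction=0.005,
                          genome=genome, seed=3)

report = qc.qc_report(reads, list(truth.peaks))
print(f"unique reads      {report.n_unique}")
print(f"duplication rate  {report.duplication_rate:.3f}")
print(f"carrier fraction  {report.carrier_fraction:.3f}%")
print(f"FRiP              {report.frip:.3f}")

gold = bm.build_gold_standard(list(truth.peaks), genes, genome=genome)
coverage, precision = bm.coverage_precision(list(truth.peaks), gold)
roc = bm.roc_curve(list(truth.peaks), gold)
print(f"promoter coverage {coverage:.3f}, precision {precision:.3f}, AUC {roc.auc:.3f}")
```

prints

```
unique reads      98554
duplication rate  0.014
carrier fraction  0.557%
FRiP              0.244
promoter coverage 1.000, precision 1.000, AUC 1.000
```

100,000 simulated reads with a 0.5% carrier spike and a generative in-peak
fraction of 0.25 recover those rates within sampling error (the 1.4%
"duplication" is positional collision, not PCR); benchmarking the truth
peaks against a gold standard derived from themselves gives perfect
coverage, precision and AUC, as it must.

## Command line

Four pipeline modes, driven by a flat `key = value` config file or `--set`
overrides, each writing TSV/JSON bundles plus a reproducibility manifest:

```sh
epibench simulate  --out sim --seed 11 --set n_reads=100000
epibench chip-eval --out chip --set reads=sim/bulk_rep1.bed,sim/bulk_rep2.bed \
    --set test_peaks=sim/truth_peaks.narrowPeak \
    --set reference_peaks=sim/truth_peaks.narrowPeak \
    --set genes=sim/genes.gtf --set genome=sim/genome.chrom.sizes
epibench sc-eval   ...   # per-cell metrics, top-5% table, random control
epibench medip-dmr ...   # DMR table, class summary, 10-kb correlation matrix
```

Re-running a mode with the same config and seed reproduces every output
byte for byte.

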