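"""Peak counting, NB differential testing and genomic classification."""

import numpy as np
import pandas as pd
import pytest

from epibench import dmr_analysis as dm
from epibench import genome_core as gc
from epibench import synthetic_data as sd

LABELS = ["cond1", "cond1", "cond2", "cond2"]


def _reads(contig, positions):
    return [gc.ReadRecord(contig, p, "+") for p in positions]


class TestCountReadsInPeaks:
    def test_empty_and_concentrated(self):
        peaks = [gc.Peak("chr1", 0, 100, name="a"), gc.Peak("chr1", 200, 300, name="b")]
        mat = dm.count_reads_in_peaks(peaks, {"s1": [], "s2": _reads("chr1", [10, 20, 250])})
        assert mat["s1"].tolist() == [0, 0]
        assert mat["s2"].tolist() == [2, 1]

    def test_matches_brute_force_membership(self):
        rng = np.random.default_rng(1)
        peaks = [
            gc.Peak("chr1", int(s), int(s + w), name=f"p{i}")
            for i, (s, w) in enumerate(
                zip(rng.integers(0, 90_000, 40), rng.integers(50, 2000, 40))
            )
        ]
        reads = _reads("chr1", rng.integers(0, 100_000, 2000))
        mat = dm.count_reads_in_peaks(peaks, {"s": reads})
        brute = [
            sum(1 for r in reads if p.start <= r.start < p.end) for p in peaks
        ]
        assert mat["s"].tolist() == brute


class TestFilterMinCount:
    def test_more_than_ten_is_strict(self):
        mat = pd.DataFrame({"a": [5, 5, 0], "b": [5, 6, 0]}, index=["x", "y", "z"])
        kept = dm.filter_min_count(mat)  # totals 10, 11, 0
        assert kept.index.tolist() == ["y"]

    def test_min_total_zero_keeps_nonzero_rows(self):
        mat = pd.DataFrame({"a": [1, 0], "b": [0, 0]})
        assert len(dm.filter_min_count(mat, min_total=0)) == 1

    def test_per_sample_mode(self):
        mat = pd.DataFrame({"a": [11, 11], "b": [11, 10]})
        assert len(dm.filter_min_count(mat, per_sample=True)) == 1


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        mat = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert dm.size_factors(mat).tolist() == pytest.approx([1.0, 1.0])

    def test_doubled_sample_factor_ratio_two(self):
        mat = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = dm.size_factors(mat)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_matches_direct_median_of_ratios(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.poisson(50, (100, 4)), columns=list("abcd"))
        f = dm.size_factors(mat)
        counts = mat.to_numpy(float)
        rows = counts[(counts > 0).all(axis=1)]
        geo = np.exp(np.log(rows).mean(axis=1))
        brute = [np.median(rows[:, j] / geo) for j in range(4)]
        assert f.tolist() == pytest.approx(brute)

    def test_requires_an_all_positive_row(self):
        mat = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="positive"):
            dm.size_factors(mat)


class TestBhAdjust:
    def test_step_up_formula(self):
        # m * p / rank, then cumulative min from the largest p
        fdr = dm.bh_adjust(np.array([0.001, 0.02, 0.9]))
        assert fdr.tolist() == pytest.approx([0.003, 0.03, 0.9])

    def test_monotone_in_pvalues(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        fdr = dm.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-15).all()


class TestNbDifferential:
    def test_exact_fourfold_gives_lfc_two(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(100, 300)
        base = np.maximum(base, 1)
        mat = pd.DataFrame(
            {
                "a1": base,
                "a2": base,
                "b1": 4 * base,
                "b2": 4 * base,
            }
        )
        unit = pd.Series(1.0, index=mat.columns)
        res = dm.nb_differential(mat, LABELS, factors=unit)
        assert np.abs(res["log2fc"] - 2.0).max() < 0.05  # pseudocount shrinks slightly

    def test_label_swap_negates_lfc_and_keeps_p(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.poisson(80, (200, 4)), columns=list("abcd"))
        mat += 1
        fwd = dm.nb_differential(mat, LABELS)
        rev = dm.nb_differential(mat, ["cond2", "cond2", "cond1", "cond1"])
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_single_condition_rejected(self):
        mat = pd.DataFrame({"a": [5], "b": [6]})
        with pytest.raises(ValueError, match="two conditions"):
            dm.nb_differential(mat, ["c1", "c1"])

    def test_one_vs_one_warns_and_runs(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.poisson(50, (100, 2)) + 1, columns=["a", "b"])
        with pytest.warns(UserWarning, match="single replicate"):
            res = dm.nb_differential(mat, ["c1", "c2"])
        assert ((res["pvalue"] >= 0) & (res["pvalue"] <= 1)).all()

    def test_null_simulation_controls_false_positives(self, dmr_setup):
        genes, genome = dmr_setup
        cfg = sd.DmrSimConfig(n_peaks=800, effect_fraction=0.0)
        _, counts, _ = sd.simulate_dmr_counts(cfg, genes, genome, seed=7)
        res = dm.classify_dmrs(dm.nb_differential(dm.filter_min_count(counts), LABELS))
        assert (res["direction"] != "null").sum() <= 4  # ~ Binom(800, 0.001) upper band

    def test_agrees_with_reference_nb_glm_on_direction(self, dmr_setup):
        """Cross-check against an independent NB GLM fit (pydeseq2) on a small
        planted-effect matrix: strong planted peaks should agree in sign and
        roughly in effect size, though the two dispersion/shrinkage schemes
        differ by design."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        genes, genome = dmr_setup
        cfg = sd.DmrSimConfig(n_peaks=200, effect_fraction=0.2)
        _, counts, truth = sd.simulate_dmr_counts(cfg, genes, genome, seed=8)
        kept = dm.filter_min_count(counts)
        ours = dm.nb_differential(kept, LABELS)

        meta = pd.DataFrame({"condition": LABELS}, index=kept.columns)
        dds = DeseqDataSet(
            counts=kept.T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        stats = DeseqStats(
            dds, contrast=["condition", "cond2", "cond1"], quiet=True
        )
        stats.summary()
        ref = stats.results_df

        planted = truth.loc[kept.index, "direction"] != "null"
        same_sign = np.sign(ours.loc[planted, "log2fc"]) == np.sign(
            ref.loc[planted.index[planted], "log2FoldChange"]
        )
        assert same_sign.all()
        diff = (
            ours.loc[planted, "log2fc"]
            - ref.loc[planted.index[planted], "log2FoldChange"]
        )
        assert np.abs(diff).median() < 0.25


@pytest.fixture(scope="module")
def dmr_setup():
    genome = sd.simulate_genome(n_contigs=2, contig_length=2_000_000, seed=0)
    genes = sd.simulate_annotation(genome, 150, seed=1)
    return genes, genome


class TestClassifyDmrs:
    def _results(self, lfc, fdr):
        return pd.DataFrame({"log2fc": lfc, "fdr": fdr})

    def test_printed_threshold_boundaries(self):
        res = dm.classify_dmrs(
            self._results(
                [-1.2, 0.8, 1.0, -1.0, 2.0, 1.5],
                [1e-4, 1e-5, 1e-4, 1e-4, 0.001, 0.01],
            )
        )
        # |lfc| >= 1 inclusive; fdr < 0.001 strictly
        assert res["direction"].tolist() == [
            "hypo",   # -1.2 at 1e-4
            "null",   # |0.8| < 1 despite tiny fdr
            "hyper",  # exactly 1.0 is inclusive
            "hypo",   # exactly -1.0 is inclusive
            "null",   # fdr exactly 0.001 is excluded
            "null",   # fdr above threshold
        ]

    def test_partition_counts(self):
        rng = np.random.default_rng(9)
        res = dm.classify_dmrs(
            self._results(rng.normal(0, 2, 500), rng.random(500) * 0.01)
        )
        counts = res["direction"].value_counts()
        assert counts.sum() == 500


class TestAnnotateGenomicClass:
    def _genes(self):
        # + strand gene: span [10_000, 20_000), exons at both ends, intron between
        return [
            gc.GeneModel(
                "g1", "chr1", "+", 10_000, 20_000,
                ((10_000, 11_000), (19_000, 20_000)),
            )
        ]

    def test_priority_promoter_beats_exon(self):
        # overlaps promoter [8000, 10500) and exon 1
        peak = gc.Peak("chr1", 10_400, 10_600)
        assert dm.annotate_genomic_class([peak], self._genes()) == ["promoter"]

    def test_intron_only(self):
        peak = gc.Peak("chr1", 15_000, 15_200)
        assert dm.annotate_genomic_class([peak], self._genes()) == ["intronic"]

    def test_exonic(self):
        peak = gc.Peak("chr1", 19_100, 19_200)
        assert dm.annotate_genomic_class([peak], self._genes()) == ["exonic"]

    def test_gene_free_contig_intergenic(self):
        peak = gc.Peak("chr9", 100, 200)
        assert dm.annotate_genomic_class([peak], self._genes()) == ["intergenic"]

    def test_matches_brute_force_enumeration(self, dmr_setup):
        from epibench.benchmark import make_promoters

        genes, genome = dmr_setup
        rng = np.random.default_rng(10)
        peaks = [
            gc.Peak("chr1", int(s), int(s) + 300)
            for s in rng.integers(0, 1_999_000, 300)
        ]
        got = dm.annotate_genomic_class(peaks, genes, genome)
        proms = [
            (p.start, p.end)
            for p in make_promoters(genes, genome=genome)
            if p.contig == "chr1"
        ]
        chr1_genes = [g for g in genes if g.contig == "chr1"]
        for peak, cls in zip(peaks, got):
            in_prom = any(s < peak.end and peak.start < e for s, e in proms)
            in_exon = any(
                s < peak.end and peak.start < e
                for g in chr1_genes
                for s, e in g.exons
            )
            in_intron = any(
                s < peak.end and peak.start < e
                for g in chr1_genes
                for s, e in zip(
                    [e for _, e in g.exons[:-1]], [s for s, _ in g.exons[1:]]
                )
            )
            expect = (
                "promoter"
                if in_prom
                else "exonic"
                if in_exon
                else "intronic"
                if in_intron
                else "intergenic"
            )
            assert cls == expect

    def test_summary_counts_non_null_only(self):
        res = pd.DataFrame(
            {
                "direction": ["hyper", "hypo", "null", "hypo"],
                "genomic_class": ["promoter", "promoter", "exonic", "intronic"],
            }
        )
        tab = dm.class_summary(res)
        assert tab["n_dmrs"].sum() == 3
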