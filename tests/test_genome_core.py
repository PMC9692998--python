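"""Data model, file I/O and interval primitives."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epibench import genome_core as gc


@pytest.fixture
def tiny_genome():
    return gc.GenomeModel(
        [("chr1", 10_000), ("chr2", 5_000), ("lambda", gc.LAMBDA_LENGTH)],
        carrier_contigs=("lambda",),
    )


class TestGenomeModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="duplicate"):
            gc.GenomeModel([("chr1", 10), ("chr1", 20)])
        with pytest.raises(ValueError, match="length"):
            gc.GenomeModel([("chr1", 0)])
        with pytest.raises(ValueError, match="carrier"):
            gc.GenomeModel([("chr1", 10)], carrier_contigs=("lambda",))

    def test_signal_vs_carrier_partition(self, tiny_genome):
        assert tiny_genome.signal_contigs == ["chr1", "chr2"]
        assert tiny_genome.is_carrier("lambda")
        assert tiny_genome.total_length() == 15_000
        assert tiny_genome.total_length(include_carrier=True) == 15_000 + gc.LAMBDA_LENGTH

    def test_chrom_sizes_roundtrip(self, tiny_genome, tmp_path):
        p = tmp_path / "g.chrom.sizes"
        gc.write_chrom_sizes(tiny_genome, p)
        assert gc.read_chrom_sizes(p) == tiny_genome


class TestReadIO:
    def test_bed6_field_mapping(self, tiny_genome, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t100\t150\t.\t0\t+\nlambda\t5\t6\tAAACCC\t0\t-\n")
        reads = gc.read_reads(p, tiny_genome)
        assert reads[0] == gc.ReadRecord("chr1", 100, "+")
        assert reads[1].is_carrier and reads[1].barcode == "AAACCC"
        assert reads[1].strand == "-"

    def test_bed6_errors_name_line(self, tiny_genome, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\t.\t0\t+\nchrX\t1\t2\t.\t0\t+\n")
        with pytest.raises(gc.FormatError, match="2: unknown contig 'chrX'"):
            gc.read_reads(p, tiny_genome)
        p.write_text("chr1\t1\t2\n")
        with pytest.raises(gc.FormatError, match="6 columns"):
            gc.read_reads(p, tiny_genome)

    def test_sam_strand_and_filtering(self, tiny_genome, tmp_path):
        sam = tmp_path / "r.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            f"@SQ\tSN:chr1\tLN:10000\n@SQ\tSN:lambda\tLN:{gc.LAMBDA_LENGTH}\n"
            "fwd\t0\tchr1\t101\t30\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"
            "rev\t16\tchr1\t201\t30\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"
            "unmapped\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*\n"
            "secondary\t256\tchr1\t301\t30\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"
            "car\t0\tlambda\t11\t30\t10M\t*\t0\t0\tAAAAAAAAAA\t*\tCB:Z:ACGT\n"
        )
        reads = gc.read_reads(sam, tiny_genome)
        assert len(reads) == 3  # unmapped and secondary dropped
        assert reads[0] == gc.ReadRecord("chr1", 100, "+")  # POS converted to 0-based
        # 5' end of the reverse read: POS 201 (1-based) + 10M -> last base 209
        assert reads[1].strand == "-" and reads[1].start == 209
        assert reads[2].is_carrier and reads[2].barcode == "ACGT"

    def test_read_write_roundtrip(self, tiny_genome, tmp_path):
        reads = [
            gc.ReadRecord("chr1", 5, "+", barcode="AC"),
            gc.ReadRecord("lambda", 9, "-", is_carrier=True),
        ]
        p = tmp_path / "rt.bed"
        gc.write_reads(reads, p)
        assert gc.read_reads(p, tiny_genome) == reads


class TestPeakIO:
    def test_narrowpeak_q_convention(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text(
            "chr1\t10\t50\tpk1\t100\t.\t5.0\t4.0\t2.0\t20\n"
            "chr1\t60\t90\tpk2\t50\t.\t1.0\t-1\t-1\t-1\n"
        )
        peaks = gc.read_peaks(p)
        assert peaks[0].neglog10_q == 2.0  # i.e. q = 0.01
        assert peaks[1].neglog10_q is None  # -1 sentinel means missing
        assert peaks[1].q_rank_score == 0.0  # missing q ranks last

    def test_bed3_has_no_q(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t10\t50\n")
        (peak,) = gc.read_peaks(p, format="bed3")
        assert peak.neglog10_q is None

    @pytest.mark.parametrize("fmt", ["narrowPeak", "broadPeak", "bed3"])
    def test_roundtrip_identity(self, fmt, tmp_path):
        peaks = [
            gc.Peak("chr1", 10, 50, neglog10_q=2.5, score=7.0, name="a"),
            gc.Peak("chr2", 0, 9, neglog10_q=None, score=0.0, name="b"),
        ]
        p = tmp_path / f"x.{fmt}"
        gc.write_peaks(peaks, p, format=fmt)
        back = gc.read_peaks(p, format=fmt)
        for orig, rt in zip(peaks, back):
            assert (rt.contig, rt.start, rt.end) == (orig.contig, orig.start, orig.end)
            if fmt != "bed3":
                assert rt.neglog10_q == orig.neglog10_q
                assert rt.score == orig.score

    def test_invalid_interval_rejected(self, tmp_path):
        p = tmp_path / "bad.narrowPeak"
        p.write_text("chr1\t50\t50\tx\t0\t.\t0\t-1\t1.0\t-1\n")
        with pytest.raises(gc.FormatError, match="start >= end"):
            gc.read_peaks(p)
        with pytest.raises(ValueError):
            gc.Peak("chr1", 5, 5)


class TestGeneIO:
    def test_gtf_roundtrip_and_tss(self, tmp_path):
        genes = [
            gc.GeneModel("g1", "chr1", "+", 100, 1000, ((100, 300), (600, 1000))),
            gc.GeneModel("g2", "chr1", "-", 2000, 3000, ((2000, 3000),)),
        ]
        p = tmp_path / "g.gtf"
        gc.write_genes(genes, p)
        back = gc.read_genes(p)
        assert back == genes
        assert back[0].tss == 100
        assert back[1].tss == 2999  # minus strand: last base of the span

    def test_gene_invariants(self):
        with pytest.raises(ValueError, match="no exons"):
            gc.GeneModel("g", "chr1", "+", 0, 10, ())
        with pytest.raises(ValueError, match="overlap"):
            gc.GeneModel("g", "chr1", "+", 0, 10, ((0, 5), (4, 10)))
        with pytest.raises(ValueError, match="outside span"):
            gc.GeneModel("g", "chr1", "+", 0, 10, ((0, 12),))


class TestDedup:
    def test_same_location_and_orientation_removed(self):
        r = gc.ReadRecord("chr1", 100, "+")
        assert gc.dedup_reads([r, r]) == [r]

    def test_orientation_distinguishes(self):
        reads = [gc.ReadRecord("chr1", 100, "+"), gc.ReadRecord("chr1", 100, "-")]
        assert gc.dedup_reads(reads) == reads

    def test_per_barcode_key(self):
        reads = [
            gc.ReadRecord("chr1", 100, "+", barcode="A"),
            gc.ReadRecord("chr1", 100, "+", barcode="B"),
        ]
        assert len(gc.dedup_reads(reads, per_barcode=True)) == 2
        assert len(gc.dedup_reads(reads, per_barcode=False)) == 1

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(0, 50),
                st.sampled_from("+-"),
                st.sampled_from([None, "A", "B"]),
            ),
            max_size=60,
        ),
        st.booleans(),
    )
    def test_matches_brute_force_grouping_and_is_idempotent(self, recs, per_bc):
        reads = [gc.ReadRecord(c, s, o, barcode=b) for c, s, o, b in recs]
        out = gc.dedup_reads(reads, per_barcode=per_bc)
        # brute force: first read of each key group, in input order
        expected = []
        for r in reads:
            if not any(
                r.dedup_key(per_bc) == q.dedup_key(per_bc) for q in expected
            ):
                expected.append(r)
        assert out == expected
        assert gc.dedup_reads(out, per_barcode=per_bc) == out


class TestIntervals:
    def test_half_open_adjacency(self):
        assert not gc.overlaps((0, 10), (10, 20))
        assert gc.overlaps((0, 10), (9, 20))

    @given(
        st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)), max_size=80),
        st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)), max_size=80),
    )
    def test_count_overlapping_equals_all_pairs(self, qs, ss):
        queries = [(s, s + w) for s, w in qs]
        subjects = [(s, s + w) for s, w in ss]
        got = gc.count_overlapping(queries, subjects)
        brute = [
            sum(1 for sub in subjects if gc.overlaps(q, sub)) for q in queries
        ]
        assert got.tolist() == brute

    @given(st.lists(st.tuples(st.integers(0, 200), st.integers(1, 40)), max_size=40))
    def test_merge_covers_exactly_the_union(self, raw):
        ivs = [(s, s + w) for s, w in raw]
        merged = gc.merge_intervals(ivs)
        union = set()
        for s, e in ivs:
            union.update(range(s, e))
        covered = set()
        for s, e in merged:
            assert s < e
            covered.update(range(s, e))
        assert covered == union
        # disjoint, sorted, non-adjacent
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            assert e1 < s2

    @given(
        st.lists(st.tuples(st.integers(0, 150), st.integers(1, 30)), max_size=30),
        st.lists(st.tuples(st.integers(0, 150), st.integers(1, 30)), max_size=30),
    )
    def test_subtract_is_set_difference(self, ra, rb):
        a = [(s, s + w) for s, w in ra]
        b = [(s, s + w) for s, w in rb]
        got = set()
        for s, e in gc.subtract_intervals(a, b):
            got.update(range(s, e))
        want = {x for s, e in a for x in range(s, e)} - {
            x for s, e in b for x in range(s, e)
        }
        assert got == want

    def test_points_in_intervals_handles_nesting(self):
        ivs = [(10, 50), (20, 30), (60, 70)]
        pts = np.array([5, 10, 25, 49, 50, 65, 70])
        mask = gc.points_in_intervals(pts, ivs)
        assert mask.tolist() == [False, True, True, True, False, True, False]


class TestBinCounts:
    def test_floor_division_assignment(self, tiny_genome):
        track = gc.bin_counts([gc.ReadRecord("chr1", 4000, "+")], tiny_genome, 4000)
        assert track.counts["chr1"][1] == 1
        assert track.total == 1

    def test_total_conserved_and_carrier_excluded(self, tiny_genome):
        rng = np.random.default_rng(0)
        reads = [
            gc.ReadRecord("chr1", int(p), "+") for p in rng.integers(0, 10_000, 500)
        ] + [gc.ReadRecord("lambda", 5, "+", is_carrier=True)]
        for binsize in (1, 7, 4000, 10_000, 1_000_000):
            track = gc.bin_counts(reads, tiny_genome, binsize)
            assert track.total == 500
            assert "lambda" not in track.counts

    def test_last_bin_may_be_short(self, tiny_genome):
        track = gc.bin_counts([], tiny_genome, 4000)
        # chr2 is 5,000 bp -> 2 bins (4,000 + 1,000)
        assert len(track.counts["chr2"]) == 2
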