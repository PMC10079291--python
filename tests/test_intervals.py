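import numpy as np
import pytest
from scipy import stats as sps

from crmkit.genome import GenomeLayout
from crmkit.intervals import (
    Peak,
    PeakSet,
    PeakParseError,
    annotate_features,
    merge_union,
    nearest_gene,
    overlap_any,
    partition_by_marks,
    random_regions,
    read_peaks,
    venn_two,
    write_peaks,
)

from _oracles import (
    brute_annotate,
    brute_merge,
    brute_nearest,
    brute_overlap_any,
    brute_partition,
    overlap_matrix,
)
from conftest import random_genes, random_peakset


class TestReadWrite:
    def test_narrowpeak_fields(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text("chr1\t100\t200\tp1\t0\t.\t5.0\t4.0\t3.0\t50\n")
        ps = read_peaks(f, "narrowPeak")
        p = ps[0]
        assert (p.start, p.end, p.summit_offset, p.score) == (100, 200, 50, 5.0)
        assert p.summit == 150

    def test_missing_summit_is_midpoint(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text("chr1\t100\t201\tp1\t0\t.\t5.0\t-1\t-1\t-1\n")
        p = read_peaks(f, "narrowPeak")[0]
        assert p.summit_offset is None
        assert p.summit == 150  # floor of midpoint

    def test_empty_interval_rejected(self, tmp_path):
        f = tmp_path / "bad.bed"
        f.write_text("chr1\t100\t100\n")
        with pytest.raises(PeakParseError, match="empty interval"):
            read_peaks(f, "BED3")

    def test_malformed_line_names_lineno(self, tmp_path):
        f = tmp_path / "bad.bed"
        f.write_text("chr1\t1\t10\nchr1\toops\t20\n")
        with pytest.raises(PeakParseError, match=":2"):
            read_peaks(f, "BED3")

    def test_interval_beyond_chromosome_rejected(self, tmp_path, layout):
        f = tmp_path / "far.bed"
        f.write_text("chr2\t59000\t61000\n")
        with pytest.raises(Exception, match="exceeds"):
            read_peaks(f, "BED3", layout)

    def test_roundtrip_identity(self, tmp_path, layout):
        rng = np.random.default_rng(0)
        ps = random_peakset(rng, layout, 1000, scores=True)
        f = tmp_path / "rt.narrowPeak"
        write_peaks(ps, f, "narrowPeak")
        back = read_peaks(f, "narrowPeak")
        assert [(p.chromosome, p.start, p.end, p.id, p.score, p.summit_offset) for p in ps] == [
            (p.chromosome, p.start, p.end, p.id, p.score, p.summit_offset) for p in back
        ]


class TestOverlap:
    def test_one_bp_overlap(self, layout):
        q = PeakSet([Peak("chr1", 10, 20)], layout=layout)
        s = PeakSet([Peak("chr1", 19, 30)], layout=layout)
        assert overlap_any(q, s)[0]

    def test_half_open_adjacency(self, layout):
        q = PeakSet([Peak("chr1", 10, 20)], layout=layout)
        s = PeakSet([Peak("chr1", 20, 30)], layout=layout)
        assert not overlap_any(q, s)[0]

    def test_matches_all_pairs_oracle(self, layout):
        rng = np.random.default_rng(1)
        for _ in range(5):
            q = random_peakset(rng, layout, 500)
            s = random_peakset(rng, layout, 500)
            np.testing.assert_array_equal(overlap_any(q, s), brute_overlap_any(q, s))

    def test_symmetry(self, layout):
        rng = np.random.default_rng(2)
        a = random_peakset(rng, layout, 200)
        b = random_peakset(rng, layout, 200)
        m = overlap_matrix(a, b)
        np.testing.assert_array_equal(overlap_any(a, b), m.any(axis=1))
        np.testing.assert_array_equal(overlap_any(b, a), m.T.any(axis=1))


class TestPartition:
    def test_definition_cases(self, layout):
        crm = PeakSet([Peak("chr1", 100, 200), Peak("chr1", 900, 1000)], layout=layout)
        ac = PeakSet([Peak("chr1", 150, 160)], layout=layout)
        me3 = PeakSet([Peak("chr1", 190, 260)], layout=layout)
        labels = partition_by_marks(crm, ac, me3)
        assert list(labels) == ["I", "IV"]

    def test_is_partition_and_matches_oracle(self, layout):
        rng = np.random.default_rng(3)
        for _ in range(5):
            crm = random_peakset(rng, layout, 300)
            ac = random_peakset(rng, layout, 150)
            me3 = random_peakset(rng, layout, 150)
            labels = partition_by_marks(crm, ac, me3)
            np.testing.assert_array_equal(labels, brute_partition(crm, ac, me3))
            counts = {c: int((labels == c).sum()) for c in "I II III IV".split()}
            assert sum(counts.values()) == len(crm)


class TestVenn:
    def test_identical_sets_all_shared(self, layout):
        a = PeakSet([Peak("chr1", 10, 50), Peak("chr2", 5, 9)], layout=layout)
        la, lb = venn_two(a, a)
        assert set(la) == {"shared"} and set(lb) == {"shared"}

    def test_disjoint_sets(self, layout):
        a = PeakSet([Peak("chr1", 10, 50)], layout=layout)
        b = PeakSet([Peak("chr1", 60, 90)], layout=layout)
        la, lb = venn_two(a, b)
        assert list(la) == ["a_only"] and list(lb) == ["b_only"]

    def test_matches_oracle(self, layout):
        rng = np.random.default_rng(4)
        a = random_peakset(rng, layout, 400)
        b = random_peakset(rng, layout, 400)
        la, lb = venn_two(a, b)
        np.testing.assert_array_equal(
            la, np.where(brute_overlap_any(a, b), "shared", "a_only")
        )
        np.testing.assert_array_equal(
            lb, np.where(brute_overlap_any(b, a), "shared", "b_only")
        )


class TestMergeUnion:
    def test_simple_merge_and_passthrough(self, layout):
        a = PeakSet([Peak("chr1", 10, 20), Peak("chr1", 15, 25)], layout=layout)
        merged = merge_union([a])
        assert [(p.start, p.end) for p in merged] == [(10, 25)]
        disjoint = PeakSet([Peak("chr1", 10, 20), Peak("chr1", 30, 40)], layout=layout)
        assert [(p.start, p.end) for p in merge_union([disjoint])] == [(10, 20), (30, 40)]

    def test_bookended_intervals_merge(self, layout):
        a = PeakSet([Peak("chr1", 10, 20), Peak("chr1", 20, 30)], layout=layout)
        assert [(p.start, p.end) for p in merge_union([a])] == [(10, 30)]

    def test_summit_from_highest_score(self, layout):
        a = PeakSet(
            [Peak("chr1", 10, 20, "lo", 1.0, 2), Peak("chr1", 15, 40, "hi", 9.0, 10)],
            layout=layout,
        )
        m = merge_union([a])[0]
        assert m.summit == 25  # 15 + 10, from the higher-score peak
        assert m.score == 9.0

    def test_matches_sweepline_oracle_and_idempotent(self, layout):
        rng = np.random.default_rng(5)
        sets = [random_peakset(rng, layout, 300) for _ in range(3)]
        merged = merge_union(sets)
        expect = brute_merge(sets)
        got = {}
        for p in merged:
            got.setdefault(p.chromosome, []).append((p.start, p.end))
        assert got == expect
        again = merge_union([merged])
        assert [(p.chromosome, p.start, p.end) for p in again] == [
            (p.chromosome, p.start, p.end) for p in merged
        ]
        # merged intervals pairwise disjoint
        for ivs in got.values():
            assert all(e1 < s2 for (_, e1), (s2, _) in zip(ivs, ivs[1:]))


class TestNearestGene:
    def test_containment_and_cutoff(self, layout):
        genes = random_genes(np.random.default_rng(6), layout, 1)
        g = genes[0]
        inside = PeakSet([Peak(g.chromosome, g.start, g.start + 2, summit_offset=0)])
        assert nearest_gene(inside, genes) == [g.gene_id]
        far_start = g.end - 1 + 12_000
        far = PeakSet([Peak(g.chromosome, far_start, far_start + 2, summit_offset=0)])
        assert nearest_gene(far, genes) == [None]

    def test_matches_bruteforce(self, layout):
        rng = np.random.default_rng(7)
        peaks = random_peakset(rng, layout, 1000)
        genes = random_genes(rng, layout, 200)
        assert nearest_gene(peaks, genes, 10_000) == brute_nearest(peaks, genes, 10_000)

    def test_assigned_distance_within_cutoff(self, layout):
        rng = np.random.default_rng(8)
        peaks = random_peakset(rng, layout, 300)
        genes = random_genes(rng, layout, 50)
        from _oracles import point_gene_distance

        by_id = {g.gene_id: g for g in genes}
        for p, gid in zip(peaks, nearest_gene(peaks, genes, 5000)):
            if gid is not None:
                assert point_gene_distance(p.summit, by_id[gid]) <= 5000


class TestAnnotateFeatures:
    def test_promoter_window_plus_strand(self, layout):
        genes = random_genes(np.random.default_rng(9), layout, 0)
        from crmkit.genome import GeneModel

        g = GeneModel("g", "chr1", "+", 50_000, 55_000, ((50_000, 55_000),))
        peaks = PeakSet([Peak("chr1", 49_400, 49_600, summit_offset=100)])  # TSS - 500
        assert annotate_features(peaks, [g]) == ["promoter"]

    def test_no_genes_is_intergenic(self, layout):
        peaks = PeakSet([Peak("chr2", 100, 200)])
        genes = random_genes(np.random.default_rng(10), layout, 5)
        genes = [g for g in genes if g.chromosome != "chr2"]
        assert annotate_features(peaks, genes) == ["intergenic"]

    def test_matches_exhaustive_oracle(self, layout):
        rng = np.random.default_rng(11)
        peaks = random_peakset(rng, layout, 400)
        genes = random_genes(rng, layout, 80)
        assert annotate_features(peaks, genes) == brute_annotate(peaks, genes)


class TestRandomRegions:
    def test_empty_and_determinism(self, layout):
        assert len(random_regions(layout, [], 1)) == 0
        a = random_regions(layout, [100] * 50, 42)
        b = random_regions(layout, [100] * 50, 42)
        assert [(p.chromosome, p.start, p.end) for p in a] == [
            (p.chromosome, p.start, p.end) for p in b
        ]

    def test_lengths_and_bounds(self, layout):
        lengths = list(np.random.default_rng(12).integers(10, 2000, 500))
        regions = random_regions(layout, lengths, 3)
        assert [p.length for p in regions] == [int(x) for x in lengths]
        for p in regions:
            assert 0 <= p.start and p.end <= layout[p.chromosome]

    def test_placement_proportional_to_length(self, layout):
        regions = random_regions(layout, [50] * 10_000, 99)
        counts = np.array(
            [sum(p.chromosome == c for p in regions) for c in layout.chromosomes]
        )
        expected = np.array([layout[c] - 49 for c in layout.chromosomes], dtype=float)
        expected = expected / expected.sum() * 10_000
        _, p = sps.chisquare(counts, expected)
        assert p > 0.01
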