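import numpy as np
import pytest

from crmkit.genome import GeneModel, GenomeLayout
from crmkit.intervals import Peak, PeakSet
from crmkit.signal import (
    binned_coverage,
    matrix_at_summits,
    metagene_profile,
    pearson_at_regions,
    quantify_regions,
    read_bedgraph,
    top_fraction,
    write_bedgraph,
)

from conftest import random_peakset


@pytest.fixture(scope="module")
def small_layout():
    return GenomeLayout({"chrA": 10_000, "chrB": 7_531})


def tiling_fragments(layout, frag=100):
    """Fragments tiling every chromosome exactly once (1× coverage)."""
    peaks = []
    for c in layout.chromosomes:
        for s in range(0, layout[c] - frag + 1, frag):
            peaks.append(Peak(c, s, s + frag))
        if layout[c] % frag:
            peaks.append(Peak(c, layout[c] - (layout[c] % frag), layout[c]))
    return PeakSet(peaks, "tiling", layout)


class TestBinnedCoverage:
    def test_uniform_coverage_rpgc_is_one(self, small_layout):
        frags = tiling_fragments(small_layout)
        track = binned_coverage(frags, small_layout, 50, "RPGC")
        for c in small_layout.chromosomes:
            np.testing.assert_allclose(track.values[c], 1.0, rtol=1e-9)

    def test_bpm_sums_to_million(self, small_layout):
        rng = np.random.default_rng(0)
        frags = random_peakset(rng, small_layout, 500, max_len=200)
        track = binned_coverage(frags, small_layout, 50, "BPM")
        total = sum(v.sum() for v in track.values.values())
        np.testing.assert_allclose(total, 1e6, rtol=1e-9)

    def test_bpm_scale_invariance_under_duplication(self, small_layout):
        rng = np.random.default_rng(1)
        frags = random_peakset(rng, small_layout, 300, max_len=200)
        doubled = PeakSet(list(frags) + list(frags), "dup", small_layout)
        a = binned_coverage(frags, small_layout, 50, "BPM")
        b = binned_coverage(doubled, small_layout, 50, "BPM")
        for c in small_layout.chromosomes:
            np.testing.assert_allclose(a.values[c], b.values[c], rtol=1e-9)

    def test_zero_signal_normalization_errors(self, small_layout):
        empty = PeakSet([], layout=small_layout)
        with pytest.raises(ValueError, match="zero total signal"):
            binned_coverage(empty, small_layout, 50, "BPM")


class TestMatrixAtSummits:
    def test_default_shape_is_100_columns(self, small_layout):
        frags = tiling_fragments(small_layout)
        track = binned_coverage(frags, small_layout, 50)
        peaks = PeakSet([Peak("chrA", 4000, 4400, "p", summit_offset=200)])
        m = matrix_at_summits(track, peaks)
        assert m.values.shape == (1, 100)

    def test_constant_track_gives_constant_matrix(self, small_layout):
        frags = tiling_fragments(small_layout)
        track = binned_coverage(frags, small_layout, 50)
        peaks = PeakSet([Peak("chrA", 4000, 4400, "p", summit_offset=200)])
        m = matrix_at_summits(track, peaks)
        np.testing.assert_allclose(m.values, 1.0)

    def test_point_mass_peaks_in_central_bin(self, small_layout):
        frags = PeakSet([Peak("chrA", 5000, 5020)], layout=small_layout)
        track = binned_coverage(frags, small_layout, 10)
        peaks = PeakSet([Peak("chrA", 4800, 5200, "p", summit_offset=200)])  # summit 5000
        m = matrix_at_summits(track, peaks, window=1000, bin=50)
        assert m.values[0].argmax() == 10  # column covering [5000, 5050)

    def test_out_of_chromosome_zero_filled(self, small_layout):
        frags = tiling_fragments(small_layout)
        track = binned_coverage(frags, small_layout, 50)
        peaks = PeakSet([Peak("chrA", 0, 100, "edge", summit_offset=0)])
        m = matrix_at_summits(track, peaks, window=1000, bin=50)
        assert (m.values[0][:10] == 0).all()  # bins left of position 0
        np.testing.assert_allclose(m.values[0][10:], 1.0)


class TestMetagene:
    def test_flat_on_constant_track(self, small_layout):
        track = binned_coverage(tiling_fragments(small_layout), small_layout, 50)
        genes = [GeneModel("g1", "chrA", "+", 3000, 5000, ((3000, 5000),))]
        prof = metagene_profile(track, genes, flank=1000)
        np.testing.assert_allclose(prof, 1.0)

    def test_strand_mirror_symmetry(self, small_layout):
        rng = np.random.default_rng(2)
        frags = random_peakset(rng, small_layout, 400, max_len=150)
        track = binned_coverage(frags, small_layout, 50)
        plus = [GeneModel("gp", "chrA", "+", 3000, 5000, ((3000, 5000),))]
        minus = [GeneModel("gm", "chrA", "-", 3000, 5000, ((3000, 5000),))]
        p1 = metagene_profile(track, plus, flank=1000)
        p2 = metagene_profile(track, minus, flank=1000)
        # reversing a - strand gene of even length recovers the + strand view
        np.testing.assert_allclose(p1, p2[::-1], atol=1e-9)

    def test_body_scaling_equivariance(self):
        # two genes, lengths L and 2L, carrying proportionally stretched
        # identical signal, must produce identical body segments
        layout = GenomeLayout({"c": 50_000})
        frags = []
        for rep, (start, L) in enumerate([(10_000, 1000), (30_000, 2000)]):
            scale = L // 1000
            for i in range(0, 1000, 100):  # signal blocks every 100 bp units
                depth = (i // 100) % 3 + 1
                for _ in range(depth):
                    frags.append(Peak("c", start + i * scale, start + (i + 100) * scale))
        track = binned_coverage(PeakSet(frags, layout=layout), layout, 1)
        g1 = [GeneModel("a", "c", "+", 10_000, 11_000, ((10_000, 11_000),))]
        g2 = [GeneModel("b", "c", "+", 30_000, 32_000, ((30_000, 32_000),))]
        b1 = metagene_profile(track, g1, flank=1000)[20:120]
        b2 = metagene_profile(track, g2, flank=1000)[20:120]
        np.testing.assert_allclose(b1, b2, rtol=1e-9)


class TestQuantify:
    def test_constant_track_mean(self, small_layout):
        track = binned_coverage(tiling_fragments(small_layout), small_layout, 50)
        regions = PeakSet([Peak("chrA", 123, 4567), Peak("chrB", 0, 7531)])
        np.testing.assert_allclose(quantify_regions(track, regions, "mean"), 1.0)

    def test_sum_additivity(self, small_layout):
        rng = np.random.default_rng(3)
        frags = random_peakset(rng, small_layout, 300, max_len=200)
        track = binned_coverage(frags, small_layout, 50)
        whole = PeakSet([Peak("chrA", 1000, 3000)])
        halves = PeakSet([Peak("chrA", 1000, 2000), Peak("chrA", 2000, 3000)])
        np.testing.assert_allclose(
            quantify_regions(track, whole, "sum")[0],
            quantify_regions(track, halves, "sum").sum(),
            rtol=1e-9,
        )

    def test_matches_per_bp_bruteforce(self, small_layout):
        rng = np.random.default_rng(4)
        frags = random_peakset(rng, small_layout, 200, max_len=300)
        track = binned_coverage(frags, small_layout, 50)
        regions = random_peakset(rng, small_layout, 50, max_len=700)
        got = quantify_regions(track, regions, "mean")
        for i, r in enumerate(regions):
            per_bp = np.array(
                [track.values[r.chromosome][pos // 50] for pos in range(r.start, r.end)]
            )
            np.testing.assert_allclose(got[i], per_bp.mean(), rtol=1e-9)


class TestTopFraction:
    def test_full_set_and_top_three(self, small_layout):
        peaks = PeakSet(
            [Peak("chrA", 10 * i, 10 * i + 5, f"p{i}", float(i + 1)) for i in range(10)]
        )
        assert len(top_fraction(peaks, 1.0)) == 10
        top = top_fraction(peaks, 0.30)
        assert sorted(p.id for p in top) == ["p7", "p8", "p9"]

    def test_all_ties_returns_full_set(self, small_layout):
        peaks = PeakSet([Peak("chrA", 10 * i, 10 * i + 5, f"p{i}", 7.0) for i in range(10)])
        assert len(top_fraction(peaks, 0.30)) == 10

    def test_missing_scores_error(self):
        peaks = PeakSet([Peak("chrA", 0, 10, "p0")])
        with pytest.raises(ValueError, match="no score"):
            top_fraction(peaks, 0.5)


class TestPearson:
    def test_self_and_anti_correlation(self, small_layout):
        rng = np.random.default_rng(5)
        frags = random_peakset(rng, small_layout, 400, max_len=150)
        track = binned_coverage(frags, small_layout, 50)
        regions = random_peakset(rng, small_layout, 40, max_len=500)
        assert pearson_at_regions(track, track, regions) == pytest.approx(1.0)
        flipped = track.scaled(-1.0, "raw")
        for c in flipped.values:
            flipped.values[c] = flipped.values[c] + 5.0
        assert pearson_at_regions(track, flipped, regions) == pytest.approx(-1.0)

    def test_matches_direct_formula(self, small_layout):
        rng = np.random.default_rng(6)
        t1 = binned_coverage(random_peakset(rng, small_layout, 300, max_len=150), small_layout, 50)
        t2 = binned_coverage(random_peakset(rng, small_layout, 300, max_len=150), small_layout, 50)
        regions = random_peakset(rng, small_layout, 60, max_len=400)
        x = quantify_regions(t1, regions)
        y = quantify_regions(t2, regions)
        r_direct = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert pearson_at_regions(t1, t2, regions) == pytest.approx(r_direct)


class TestBedgraphRoundtrip:
    def test_roundtrip_preserves_bins(self, small_layout, tmp_path):
        rng = np.random.default_rng(7)
        frags = random_peakset(rng, small_layout, 200, max_len=200)
        track = binned_coverage(frags, small_layout, 50)
        f = tmp_path / "t.bedGraph"
        write_bedgraph(track, f)
        back = read_bedgraph(f, small_layout, 50)
        for c in small_layout.chromosomes:
            np.testing.assert_allclose(back.values[c], track.values[c], rtol=1e-5)
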