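import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribd.core import (
    build_window_grid,
    call_windows,
    compute_pipeline,
    invert_ribd,
    population_fraction,
    ribd_scores,
    window_coverage,
)
from ribd.io import GenomeLayout, IbdSegment, PopulationManifest

from conftest import random_instance
from oracle import brute_force_pipeline


@pytest.fixture
def manifest():
    return PopulationManifest(
        (("S1", "source1"), ("S2", "source1"), ("T1", "source2"),
         ("A1", "admixed"), ("A2", "admixed"))
    )


def seg(sample_a, hap_a, sample_b, hap_b, start, end, chrom="chr1", lod=9.0):
    return IbdSegment(sample_a, hap_a, sample_b, hap_b, chrom, start, end, lod)


class TestWindowGrid:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (25_000, [(0, 10_000), (10_000, 20_000), (20_000, 25_000)]),
            (10_000, [(0, 10_000)]),
            (9_999, [(0, 9_999)]),
        ],
    )
    def test_tiling_examples(self, length, expected):
        grid = build_window_grid(GenomeLayout((("chr1", length),)), 10_000)
        got = [(int(s), int(e)) for s, e in zip(*grid.bounds("chr1"))]
        assert got == expected

    def test_rejects_nonpositive_window(self):
        with pytest.raises(ValueError):
            build_window_grid(GenomeLayout((("chr1", 100),)), 0)

    @settings(max_examples=100, deadline=None)
    @given(length=st.integers(1, 500_000), w=st.integers(1, 50_000))
    def test_windows_tile_chromosome_exactly(self, length, w):
        grid = build_window_grid(GenomeLayout((("c", length),)), w)
        s, e = grid.bounds("c")
        assert s[0] == 0 and e[-1] == length
        assert (e > s).all() and (e - s <= w).all()
        assert (s[1:] == e[:-1]).all()  # disjoint, no gaps

    def test_sliding_step_overlaps(self):
        grid = build_window_grid(GenomeLayout((("c", 30_000),)), 10_000, step=5_000)
        s, _ = grid.bounds("c")
        assert list(s) == [0, 5_000, 10_000, 15_000, 20_000, 25_000]


class TestWindowCoverage:
    @pytest.mark.parametrize(
        "seg_iv,win,expected",
        [((1_000, 5_000), (0, 10_000), 0.4),
         ((0, 10_000), (0, 10_000), 1.0),
         ((20_000, 30_000), (0, 10_000), 0.0)],
    )
    def test_examples(self, seg_iv, win, expected):
        assert window_coverage(*seg_iv, *win) == expected


class TestCallWindows:
    def grid(self, length=10_000):
        return build_window_grid(GenomeLayout((("chr1", length),)), 10_000)

    def test_single_full_segment_calls_only_that_haplotype(self, manifest):
        calls = call_windows(
            [seg("A1", 1, "S1", 1, 0, 10_000)], self.grid(), manifest, "source1"
        )
        m = calls.calls["chr1"]
        assert m[calls.units.index(("A1", 1)), 0]
        assert not m[calls.units.index(("A1", 2)), 0]
        assert not m[calls.units.index(("A2", 1)), 0]

    def test_union_of_overlapping_tracts_counted_once(self, manifest):
        """Two partners' tracts [0,3000)+[2000,6000) merge to 6000/10000 covered."""
        segments = [seg("A1", 1, "S1", 1, 0, 3_000), seg("A1", 1, "S2", 2, 2_000, 6_000)]
        called = call_windows(segments, self.grid(), manifest, "source1", min_cov=0.5)
        assert called.calls["chr1"][called.units.index(("A1", 1)), 0]
        not_called = call_windows(segments, self.grid(), manifest, "source1", min_cov=0.7)
        assert not not_called.calls["chr1"][not_called.units.index(("A1", 1)), 0]

    def test_individual_unit_requires_one_haplotype_to_pass(self, manifest):
        # each haplotype covers 40%: pooled coverage is 80% but neither passes alone
        segments = [seg("A1", 1, "S1", 1, 0, 4_000), seg("A1", 2, "S1", 1, 4_000, 8_000)]
        calls = call_windows(segments, self.grid(), manifest, "source1", unit="individual")
        assert not calls.calls["chr1"][calls.units.index("A1"), 0]
        # one haplotype covering 60% is enough
        calls2 = call_windows(
            [seg("A1", 2, "S1", 1, 0, 6_000)], self.grid(), manifest, "source1",
            unit="individual",
        )
        assert calls2.calls["chr1"][calls2.units.index("A1"), 0]

    def test_pairwise_unit_keeps_partners_separate(self, manifest):
        # two partners each covering 30%: no pair passes min_cov=0.5
        segments = [seg("A1", 1, "S1", 1, 0, 3_000), seg("A1", 1, "S2", 1, 3_000, 6_000)]
        calls = call_windows(segments, self.grid(), manifest, "source1", unit="pairwise")
        assert calls.counts("chr1")[0] == 0
        assert calls.n_units == 2 * 2 * 2 * 2  # 2 admixed x 2 haps x 2 source1 x 2 haps


class TestFractionsAndScores:
    def test_population_fraction_counts_called_units(self, manifest):
        grid = build_window_grid(GenomeLayout((("chr1", 10_000),)), 10_000)
        segments = [
            seg("A1", 1, "S1", 1, 0, 10_000),
            seg("A1", 2, "S1", 1, 0, 10_000),
            seg("A2", 1, "S1", 2, 0, 10_000),
        ]
        calls = call_windows(segments, grid, manifest, "source1")
        frac = population_fraction(calls, manifest)
        assert frac["chr1"][0] == 0.75  # 3 of 4 admixed haplotypes

    def test_no_calls_gives_zero_everywhere(self, manifest):
        grid = build_window_grid(GenomeLayout((("chr1", 30_000),)), 10_000)
        calls = call_windows([], grid, manifest, "source1")
        assert (population_fraction(calls, manifest)["chr1"] == 0).all()

    @pytest.mark.parametrize(
        "f1,f2,mode,expected",
        [
            (0.75, 0.25, "normalized", (0.75, 0.25, 0.5)),
            (0.5, 0.5, "normalized", (0.5, 0.5, 0.0)),
            (0.3, 0.2, "normalized", (0.6, 0.4, 0.2)),
            (0.3, 0.2, "raw", (0.3, 0.2, 0.1)),
            (0.0, 0.0, "normalized", (0.0, 0.0, 0.0)),
        ],
    )
    def test_ribd_scores(self, f1, f2, mode, expected):
        g1, g2, r = ribd_scores(np.array([f1]), np.array([f2]), mode)
        assert (g1[0], g2[0], r[0]) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "ribd,expected", [(0.5, (0.75, 0.25)), (0.0, (0.5, 0.5)), (1.0, (1.0, 0.0))]
    )
    def test_invert_ribd_under_sum_to_one(self, ribd, expected):
        assert invert_ribd(ribd) == pytest.approx(expected)

    def test_invert_ribd_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            invert_ribd(1.5)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(-1.0, 1.0, allow_nan=False))
    def test_invert_is_right_inverse_of_the_score(self, r):
        s1, s2 = invert_ribd(r)
        assert 0.0 <= s1 <= 1.0 and 0.0 <= s2 <= 1.0
        assert s1 + s2 == pytest.approx(1.0)
        assert s1 - s2 == pytest.approx(r)


class TestPipeline:
    def test_empty_segments_give_zero_scores(self, manifest):
        layout = GenomeLayout((("chr1", 30_000),))
        records = compute_pipeline([], layout, manifest)
        assert len(records) == 3
        assert all(r.ribd == 0.0 and r.zero_evidence for r in records)

    def test_saturated_source1_sharing_gives_plus_one(self, manifest):
        layout = GenomeLayout((("chr1", 30_000),))
        segments = [
            IbdSegment(A, h, "S1", 1, "chr1", 0, 30_000, 9.0)
            for A in ("A1", "A2")
            for h in (1, 2)
        ]
        records = compute_pipeline(segments, layout, manifest)
        assert all(r.ribd == 1.0 for r in records)

    @pytest.mark.parametrize("unit", ["haplotype", "individual", "pairwise"])
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_per_base_brute_force_exactly(self, seed, unit):
        layout, manifest, segments = random_instance(seed)
        for mode in ("raw", "normalized"):
            got = compute_pipeline(
                segments, layout, manifest, window_size=100, unit=unit, mode=mode
            )
            expected = brute_force_pipeline(
                segments, layout, manifest, window_size=100, unit=unit, mode=mode
            )
            assert got == expected

    @pytest.mark.parametrize("seed", [5, 6])
    def test_antisymmetry_under_source_swap(self, seed):
        layout, manifest, segments = random_instance(seed)
        fwd = compute_pipeline(segments, layout, manifest, window_size=100)
        rev = compute_pipeline(segments, layout, manifest.swap_sources(), window_size=100)
        for a, b in zip(fwd, rev):
            assert a.ribd == -b.ribd
            assert (a.n_ibd_s1, a.n_ibd_s2) == (b.n_ibd_s2, b.n_ibd_s1)
            assert (a.ibd_s1, a.ibd_s2) == (b.ibd_s2, b.ibd_s1)

    def test_scores_bounded(self):
        layout, manifest, segments = random_instance(9, n_segments=120)
        for mode in ("raw", "normalized"):
            for rec in compute_pipeline(segments, layout, manifest, window_size=100, mode=mode):
                assert -1.0 <= rec.ribd <= 1.0
                assert 0.0 <= rec.ibd_s1 <= 1.0 and 0.0 <= rec.ibd_s2 <= 1.0

    def test_adding_source1_segment_never_decreases_raw_ribd(self):
        layout, manifest, segments = random_instance(13, n_segments=40)
        base = compute_pipeline(segments, layout, manifest, window_size=100, mode="raw")
        extra = IbdSegment("A_0", 1, "S1_0", 1, "c1", 200, 1_400, 9.0)
        more = compute_pipeline(
            segments + [extra], layout, manifest, window_size=100, mode="raw"
        )
        assert all(m.ribd >= b.ribd for b, m in zip(base, more))

    def test_no_cross_chromosome_leakage(self):
        layout, manifest, segments = random_instance(17, chrom_lens=(2_000, 1_500))
        joint = compute_pipeline(segments, layout, manifest, window_size=100)
        for chrom, length in layout.chromosomes:
            solo_layout = GenomeLayout(((chrom, length),))
            solo_segs = [s for s in segments if s.chrom == chrom]
            solo = compute_pipeline(solo_segs, solo_layout, manifest, window_size=100)
            assert [r for r in joint if r.chrom == chrom] == solo
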