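import numpy as np
import pytest

from fracseq import (
    IntronProfile,
    aggregate_profiles,
    bin_intron,
    profile_slope,
    rank_fractions_by_slope,
)
from fracseq.annotation import GenomicInterval, IntronRecord
from fracseq.coverage import CoverageTrack
from fracseq.profiles import IntronTooShort, SlopeStat


def _intron(start, end, strand="+"):
    return IntronRecord(
        interval=GenomicInterval("chr1", start, end, strand),
        parent_gene="g",
        five_prime_offset=0,
    )


def _track(depth, strand="+"):
    return CoverageTrack("chr1", strand, np.asarray(depth, dtype=float), 1_000_000)


class TestBinIntron:
    def test_constant_depth(self):
        depth = np.zeros(1200)
        depth[100:1100] = 4.0
        prof = bin_intron(_intron(100, 1100), _track(depth))
        assert prof.bins.shape == (100,)
        assert prof.left_flank.shape == (50,) and prof.right_flank.shape == (50,)
        np.testing.assert_allclose(prof.bins, 4.0)

    def test_bin_means_match_brute_force(self):
        L = 1037  # not divisible by 100: exercises the floor bin edges
        depth = np.zeros(L + 200, dtype=float)
        depth[100 : 100 + L] = np.arange(L, 0, -1)
        prof = bin_intron(_intron(100, 100 + L), _track(depth))
        seg = depth[100 : 100 + L]
        expected = []
        for b in range(100):
            lo, hi = (b * L) // 100, ((b + 1) * L) // 100
            expected.append(seg[lo:hi].mean())
        np.testing.assert_allclose(prof.bins, expected)
        assert all(a > b for a, b in zip(prof.bins, prof.bins[1:]))

    def test_minus_strand_is_reverse_of_plus(self):
        rng = np.random.default_rng(0)
        depth = rng.integers(0, 10, size=1300).astype(float)
        plus = bin_intron(_intron(100, 1200, "+"), _track(depth, "+"))
        minus = bin_intron(_intron(100, 1200, "-"), _track(depth, "-"))
        np.testing.assert_allclose(minus.bins, plus.bins[::-1])
        np.testing.assert_allclose(minus.left_flank, plus.right_flank[::-1])
        np.testing.assert_allclose(minus.right_flank, plus.left_flank[::-1])

    def test_too_short_intron_raises(self):
        with pytest.raises(IntronTooShort):
            bin_intron(_intron(100, 150), _track(np.zeros(400)))

    def test_flank_outside_reference_raises(self):
        with pytest.raises(ValueError, match="flank"):
            bin_intron(_intron(10, 400), _track(np.zeros(500)))


class TestAggregateProfiles:
    def _profile(self, value, size_class="S"):
        return IntronProfile(
            bins=np.full(100, float(value)),
            left_flank=np.full(50, float(value)),
            right_flank=np.full(50, float(value)),
            n_introns=1,
            size_class=size_class,
        )

    def test_identical_profiles_average_to_themselves(self):
        agg = aggregate_profiles([self._profile(2), self._profile(2)])
        np.testing.assert_allclose(agg.bins, 2.0)
        assert agg.n_introns == 2

    def test_elementwise_mean(self):
        agg = aggregate_profiles([self._profile(2), self._profile(4)])
        np.testing.assert_allclose(agg.bins, 3.0)

    def test_class_filter_and_empty_selection(self):
        profiles = [self._profile(1, "S"), self._profile(5, "XL")]
        agg = aggregate_profiles(profiles, class_filter="XL")
        np.testing.assert_allclose(agg.bins, 5.0)
        with pytest.raises(ValueError):
            aggregate_profiles(profiles, class_filter="M")

    def test_normalized_aggregation_equalizes_intron_weight(self):
        agg = aggregate_profiles([self._profile(1), self._profile(9)], normalize=True)
        np.testing.assert_allclose(agg.bins, 1.0)
        assert agg.units == "raw_depth_normalized"


class TestProfileSlope:
    def _profile_from_bins(self, bins):
        return IntronProfile(
            bins=np.asarray(bins, dtype=float),
            left_flank=np.zeros(50),
            right_flank=np.zeros(50),
            n_introns=1,
            size_class="S",
        )

    def test_constant_profile_slope_zero(self):
        stat = profile_slope(self._profile_from_bins(np.full(100, 3.0)))
        assert stat.slope == pytest.approx(0.0, abs=1e-12)
        assert not stat.zero_coverage

    def test_linear_profile_matches_closed_form_ols(self):
        y = np.linspace(2.0, 1.0, 100)
        x = (np.arange(100) + 0.5) / 100
        beta = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        expected = beta / y.mean()  # -> about -0.667 relative change per intron
        stat = profile_slope(self._profile_from_bins(y))
        assert stat.slope == pytest.approx(expected)
        assert expected == pytest.approx(-0.6734, abs=1e-3)
        assert stat.r_squared == pytest.approx(1.0)

    def test_zero_coverage_flagged(self):
        stat = profile_slope(self._profile_from_bins(np.zeros(100)))
        assert stat.zero_coverage and stat.slope == 0.0


class TestRankFractions:
    def test_steepest_first(self):
        slopes = [
            ("total", SlopeStat(-0.3, 1, 1)),
            ("cyto", SlopeStat(0.0, 1, 1)),
            ("nuclear", SlopeStat(-0.5, 1, 1)),
            ("polyA", SlopeStat(-0.2, 1, 1)),
        ]
        assert rank_fractions_by_slope(slopes) == ["nuclear", "total", "polyA", "cyto"]

    def test_ties_keep_input_order(self):
        slopes = [("a", SlopeStat(-0.1, 1, 1)), ("b", SlopeStat(-0.1, 1, 1))]
        assert rank_fractions_by_slope(slopes) == ["a", "b"]
        assert rank_fractions_by_slope(slopes[::-1]) == ["b", "a"]

    def test_requires_two_fractions(self):
        with pytest.raises(ValueError):
            rank_fractions_by_slope([("only", SlopeStat(0, 1, 1))])


class TestFractionRankingOnSimulations:
    def test_raw_slope_orders_fractions_by_nascent_content(self, default_genome):
        from fracseq import (
            GenomeCoverage,
            SimulationConfig,
            collect_introns,
            profile_size_classes,
            rank_fractions_by_slope,
            simulate_reads,
        )

        _, genes, ref_lengths = default_genome
        introns = collect_introns(genes)
        slopes = []
        # nascent proportions 0.9 / 0.5 / 0.3 / 0.0
        for label, m in (("nuc", 0.1), ("tot", 0.5), ("pa", 0.7), ("cyto", 1.0)):
            cfg = SimulationConfig(n_reads=100_000, mature_fraction=m, seed=23)
            reads, _ = simulate_reads(cfg, genes)
            cov = GenomeCoverage.from_reads(reads, ref_lengths)
            slopes.append((label, profile_size_classes(introns, cov)["XL"][1]))
        assert rank_fractions_by_slope(slopes, use_raw=True) == ["nuc", "tot", "pa", "cyto"]


class TestOrientationInvariance:
    def test_minus_strand_equals_mirrored_plus_construction(self):
        rng = np.random.default_rng(1)
        depth = rng.integers(0, 8, size=2000).astype(float)
        minus_prof = bin_intron(_intron(300, 1700, "-"), _track(depth, "-"))
        mirrored = depth[::-1]
        n = depth.size
        plus_prof = bin_intron(
            _intron(n - 1700, n - 300, "+"), _track(mirrored, "+")
        )
        np.testing.assert_allclose(minus_prof.bins, plus_prof.bins)
        np.testing.assert_allclose(minus_prof.left_flank, plus_prof.left_flank)
        np.testing.assert_allclose(minus_prof.right_flank, plus_prof.right_flank)
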