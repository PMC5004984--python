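"""Signal extraction, rank-sum comparison and threshold-sweep curves."""

import numpy as np
import pytest
from scipy import stats

from hoxloci.core import GenomicInterval, SignalTrack, ValidationError
from hoxloci.signal import (
    compare_signal,
    median_signal_over_regions,
    multi_siteset_ranking,
    signal_at_points,
    threshold_sweep,
)


def _random_track(rng, chrom="c", length=10_000, max_step=60):
    """Random step track with gaps."""
    steps = []
    pos = 0
    while pos < length - 1:
        width = int(rng.integers(5, max_step))
        if rng.random() < 0.7:
            steps.append((chrom, pos, min(pos + width, length), float(rng.normal())))
        pos += width
    return SignalTrack(steps)


class TestSignalAtPoints:
    def test_step_value_and_gap(self):
        track = SignalTrack([("c", 0, 10, 1.5)])
        vals = signal_at_points(track, [("c", 5), ("c", 15)])
        assert vals[0] == 1.5 and np.isnan(vals[1])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        track = _random_track(rng)
        steps = list(track)
        positions = [("c", int(p)) for p in rng.integers(0, 10_000, 200)]
        got = signal_at_points(track, positions)
        for (chrom, pos), value in zip(positions, got):
            covering = [v for c, s, e, v in steps if c == chrom and s <= pos < e]
            if covering:
                assert value == covering[0]
            else:
                assert np.isnan(value)


class TestMedianOverRegions:
    def test_uniform_track(self):
        track = SignalTrack([("c", 0, 1000, 2.5)])
        (m,) = median_signal_over_regions(track, [GenomicInterval("c", 100, 900)])
        assert m == 2.5

    def test_even_base_count_averages_central_pair(self):
        track = SignalTrack([("c", 0, 50, 1.0), ("c", 50, 100, 3.0)])
        (m,) = median_signal_over_regions(track, [GenomicInterval("c", 0, 100)])
        assert m == 2.0

    def test_exclusion_removes_bases(self):
        track = SignalTrack([("c", 0, 50, 1.0), ("c", 50, 100, 3.0)])
        (m,) = median_signal_over_regions(
            track, [GenomicInterval("c", 0, 100)], exclude=[GenomicInterval("c", 40, 100)]
        )
        assert m == 1.0

    def test_fully_excluded_region_is_missing(self):
        track = SignalTrack([("c", 0, 100, 1.0)])
        (m,) = median_signal_over_regions(
            track, [GenomicInterval("c", 10, 20)], exclude=[GenomicInterval("c", 0, 50)]
        )
        assert np.isnan(m)

    @pytest.mark.parametrize("seed", [2, 3])
    def test_matches_per_base_expansion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        track = _random_track(rng)
        steps = list(track)
        regions = []
        for _ in range(40):
            s = int(rng.integers(0, 9_800))
            regions.append(GenomicInterval("c", s, s + int(rng.integers(20, 200))))
        got = median_signal_over_regions(track, regions)
        per_base = np.full(10_000, np.nan)
        for _, s, e, v in steps:
            per_base[s:e] = v
        for region, value in zip(regions, got):
            bases = per_base[region.start : region.end]
            bases = bases[~np.isnan(bases)]
            if bases.size == 0:
                assert np.isnan(value)
            else:
                assert value == pytest.approx(np.median(bases))


class TestCompareSignal:
    def test_identical_samples_p_half(self):
        x = np.linspace(-1, 1, 101)
        cmp = compare_signal(x, x.copy())
        assert 0.4 <= cmp.wilcoxon_p <= 0.6

    def test_large_shift_reaches_extreme_p(self):
        rng = np.random.default_rng(0)
        bg = rng.normal(0, 1, 100)
        cmp = compare_signal(bg + 100.0, bg)
        assert cmp.wilcoxon_p < 1e-20

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_shift_power(self, seed):
        """A one-sigma shift at n=500 per group is detected at p < 1e-20."""
        rng = np.random.default_rng(seed)
        fg = rng.normal(1.0, 1.0, 500)
        bg = rng.normal(0.0, 1.0, 500)
        assert compare_signal(fg, bg).wilcoxon_p < 1e-20

    def test_missing_values_excluded_and_counted(self):
        fg = [1.0, 2.0, np.nan]
        bg = [0.0, np.nan, np.nan]
        cmp = compare_signal(fg, bg)
        assert (cmp.n_fg, cmp.n_bg) == (2, 1)
        assert (cmp.n_missing_fg, cmp.n_missing_bg) == (1, 2)

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            compare_signal([np.nan], [1.0])

    def test_permutation_null_p_uniform(self):
        """Rank-sum p on permuted labels of one pooled sample is uniform
        (KS test not rejected at alpha = 0.01)."""
        rng = np.random.default_rng(7)
        pooled = rng.normal(0, 1, 60)
        ps = []
        for _ in range(1000):
            perm = rng.permutation(pooled)
            ps.append(compare_signal(perm[:30], perm[30:]).wilcoxon_p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_rejection_rate_under_null(self):
        """One-sided test at alpha = 0.05 rejects ~5% of permuted nulls."""
        rng = np.random.default_rng(8)
        pooled = rng.normal(0, 1, 60)
        rej = 0
        reps = 1000
        for _ in range(reps):
            perm = rng.permutation(pooled)
            rej += compare_signal(perm[:30], perm[30:]).wilcoxon_p < 0.05
        band = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) <= band + 0.005  # discreteness allowance


class TestThresholdSweep:
    def test_all_equal_values(self):
        curve = threshold_sweep({"s": [2.0, 2.0, 2.0]}, [1.0, 2.0, 3.0])
        assert list(curve.fractions["s"]) == [1.0, 0.0, 0.0]

    def test_manual_four_value_fixture(self):
        curve = threshold_sweep({"s": [0.0, 1.0, 2.0, 3.0]}, [0.5, 1.5, 2.5])
        assert list(curve.fractions["s"]) == [0.75, 0.5, 0.25]

    def test_missing_counts_in_denominator(self):
        curve = threshold_sweep({"s": [1.0, np.nan, np.nan, np.nan]}, [0.5])
        assert curve.fractions["s"][0] == 0.25

    def test_curves_monotone_nonincreasing(self, small_dataset):
        ds = small_dataset
        vals = signal_at_points(ds.track, [(p.chrom, p.summit) for p in ds.peaks])
        curve = threshold_sweep({"peaks": vals}, np.arange(-3, 3, 0.25))
        f = curve.fractions["peaks"]
        assert np.all(np.diff(f) <= 0)
        assert np.all((f >= 0) & (f <= 1))

    def test_shifted_set_dominates(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 400)
        curve = threshold_sweep(
            {"hi": base + 1.0, "lo": base}, np.arange(-2, 2, 0.2)
        )
        assert np.all(curve.fractions["hi"] >= curve.fractions["lo"])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            threshold_sweep({"s": [1.0]}, [])


class TestRanking:
    def test_dominated_curve_ranks_lower(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 300)
        curve = threshold_sweep(
            {"a": base + 1.0, "b": base}, np.arange(-2, 2, 0.2)
        )
        ranking = multi_siteset_ranking(curve)
        assert [name for name, _ in ranking] == ["a", "b"]

    def test_identical_curves_tie_broken_by_name(self):
        vals = [0.0, 1.0, 2.0]
        curve = threshold_sweep({"zeta": vals, "alpha": vals}, [0.5, 1.5])
        ranking = multi_siteset_ranking(curve)
        assert [name for name, _ in ranking] == ["alpha", "zeta"]

    def test_planted_order_recovered(self):
        rng = np.random.default_rng(3)
        curve = threshold_sweep(
            {
                "high": rng.normal(2.0, 1.0, 300),
                "mid": rng.normal(1.0, 1.0, 300),
                "low": rng.normal(0.0, 1.0, 300),
            },
            np.arange(-2, 4, 0.2),
        )
        assert [n for n, _ in multi_siteset_ranking(curve)] == ["high", "mid", "low"]
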