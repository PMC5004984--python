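"""Tile-activity enrichment, hypergeometric tails and stratifications."""

import math

import numpy as np
import pytest

from hoxloci.core import GenomicInterval, Peak, Tile, ValidationError, overlap_bp, summit_windows
from hoxloci.tiles import (
    EnrichmentResult,
    activity_enrichment,
    cobinding_partition,
    compare_counts,
    compare_two_subsets,
    hot_stratified_enrichment,
    hypergeometric_upper_tail,
    stage_stratified_enrichment,
    tiles_overlapping_summits,
)


def hypergeom_oracle(k, n, K, N):
    """Exact rational enumeration of the upper tail via binomial coefficients."""
    denom = math.comb(N, n)
    total = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
    )
    return total / denom


def _tile(tid, chrom, start, end, active=True, stages=None):
    return Tile(tid, GenomicInterval(chrom, start, end), active, stages)


def _peak(chrom, summit, score=6.0, name="p"):
    return Peak(GenomicInterval(chrom, summit - 50, summit + 50), summit, score, name)


class TestHypergeometricTail:
    def test_exhaustive_enumeration_small_N(self):
        for N in range(1, 26):
            for n in range(0, N + 1):
                for K in range(0, N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        p = hypergeometric_upper_tail(k, n, K, N)
                        oracle = hypergeom_oracle(k, n, K, N)
                        assert p == pytest.approx(oracle, rel=1e-6), (k, n, K, N)

    def test_random_instances_up_to_N_200(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            N = int(rng.integers(26, 201))
            n = int(rng.integers(0, N + 1))
            K = int(rng.integers(0, N + 1))
            lo = max(0, n + K - N)
            k = int(rng.integers(lo, min(n, K) + 1))
            assert hypergeometric_upper_tail(k, n, K, N) == pytest.approx(
                hypergeom_oracle(k, n, K, N), rel=1e-6
            )

    def test_k_zero_is_one(self):
        assert hypergeometric_upper_tail(0, 10, 50, 100) == 1.0

    def test_all_draws_successes(self):
        assert hypergeometric_upper_tail(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_monotone_nonincreasing_in_k(self):
        ps = [hypergeometric_upper_tail(k, 40, 60, 120) for k in range(0, 41)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_upper_tail(5, 4, 10, 20)
        with pytest.raises(ValidationError):
            hypergeometric_upper_tail(0, 15, 10, 20)  # k below feasible minimum


class TestTilesOverlappingSummits:
    def test_summit_inside_tile_flank_zero(self):
        tiles = [_tile("t1", "c", 100, 300)]
        assert tiles_overlapping_summits(tiles, [_peak("c", 200)], 0) == tiles

    def test_flank_window_reaches_tile(self):
        tiles = [_tile("t1", "c", 1000, 1300)]
        peak = _peak("c", 800)  # summit 200 bp left of the tile start
        assert tiles_overlapping_summits(tiles, [peak], 250) == tiles
        assert tiles_overlapping_summits(tiles, [peak], 100) == []

    @pytest.mark.parametrize("flank", [0, 100, 250])
    def test_matches_all_pairs_oracle(self, flank, small_dataset):
        tiles = small_dataset.tiles[:150]
        peaks = small_dataset.peaks[:80]
        got = {t.id for t in tiles_overlapping_summits(tiles, peaks, flank)}
        windows = summit_windows(peaks, flank)
        expected = {
            t.id
            for t in tiles
            if any(overlap_bp(t.interval, w) > 0 for w in windows)
        }
        assert got == expected


class TestActivityEnrichment:
    def test_study_scale_counts(self):
        """192 of 248 bound tiles active vs 3557 of 7705 overall: 77.4% vs
        46.2%, a 1.7-fold increase."""
        r = EnrichmentResult(192, 248, 3557, 7705)
        s = r.summary()
        assert s["fraction_pct"] == 77.4
        assert s["baseline_pct"] == 46.2
        assert s["fold"] == 1.7
        assert 0.8e-24 < r.p < 3.4e-24  # within 2x of the expected order

    def test_subset_equals_universe(self):
        tiles = [_tile(f"t{i}", "c", i * 100, i * 100 + 50, active=i % 2 == 0)
                 for i in range(10)]
        r = activity_enrichment(tiles, tiles)
        assert r.fold == 1.0
        assert 0.4 <= r.p <= 1.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValidationError):
            activity_enrichment([], [_tile("t", "c", 0, 10)])

    def test_synthetic_recovers_conditional_activity(self, default_dataset):
        ds = default_dataset
        bound = [t for t, b in zip(ds.tiles, ds.tile_bound) if b]
        r = activity_enrichment(bound, ds.tiles)
        p1 = ds.scenario.p_active_bound
        se = math.sqrt(p1 * (1 - p1) / len(bound))
        assert abs(r.fraction - p1) <= 3 * se


class TestStageStratification:
    def test_all_stages_equal_overall(self):
        # single stage: flags coincide with active_any by construction
        tiles = [
            _tile(f"t{i}", "c", i * 100, i * 100 + 50, active=i < 6, stages=(i < 6,))
            for i in range(10)
        ]
        subset = tiles[:4]
        results, mean_fold = stage_stratified_enrichment(subset, tiles)
        overall = activity_enrichment(subset, tiles)
        assert len(results) == 1
        assert results[0].fraction == overall.fraction
        assert mean_fold == pytest.approx(overall.fold)

    def test_planted_per_stage_folds_average(self):
        """Stage folds of 2 and 3 in a constructed universe average to 2.5."""
        tiles = []
        for i in range(100):
            s1 = i < 20          # baseline 20%
            s2 = i < 10          # baseline 10%
            tiles.append(_tile(f"u{i}", "c", i * 100, i * 100 + 50,
                               active=s1 or s2, stages=(s1, s2)))
        # subset of 10 tiles: stage1 active 4 (40% = 2x), stage2 active 3 (30% = 3x)
        subset = tiles[:3] + tiles[10:11] + tiles[20:26]
        results, mean_fold = stage_stratified_enrichment(subset, tiles)
        assert results[0].fold == pytest.approx(2.0)
        assert results[1].fold == pytest.approx(3.0)
        assert mean_fold == pytest.approx(2.5)

    def test_empty_stage_fold_zero_p_one(self):
        tiles = [
            _tile(f"t{i}", "c", i * 100, i * 100 + 50, active=False, stages=(False,))
            for i in range(10)
        ]
        results, mean_fold = stage_stratified_enrichment(tiles[:3], tiles)
        assert results[0].fold == 0.0
        assert results[0].p == 1.0

    def test_missing_stage_columns_rejected(self):
        tiles = [_tile("t1", "c", 0, 50, active=True, stages=None)]
        with pytest.raises(ValidationError):
            stage_stratified_enrichment(tiles, tiles)


class TestHotStratification:
    def test_hand_built_eight_tile_fixture(self):
        # bound tiles overlap a peak summit; HOT tiles overlap [10_000, 10_500)
        hot = [GenomicInterval("c", 10_000, 10_500)]
        peaks = [_peak("c", 150), _peak("c", 10_150, name="q")]
        tiles = [
            _tile("b_h", "c", 10_100, 10_200, active=True),    # bound + HOT
            _tile("b_h2", "c", 10_050, 10_250, active=False),  # bound + HOT
            _tile("b_n", "c", 100, 200, active=True),          # bound, non-HOT
            _tile("b_n2", "c", 120, 220, active=True),         # bound, non-HOT
            _tile("u_h", "c", 10_300, 10_400, active=True),    # unbound + HOT
            _tile("u_n", "c", 5000, 5100, active=False),
            _tile("u_n2", "c", 6000, 6100, active=True),
            _tile("u_n3", "c", 7000, 7100, active=False),
        ]
        strat = hot_stratified_enrichment(tiles, peaks, hot)
        assert strat.cells[(True, True)] == (1, 2)
        assert strat.cells[(True, False)] == (2, 2)
        assert strat.cells[(False, True)] == (1, 1)
        assert strat.cells[(False, False)] == (1, 3)
        assert strat.non_hot.fraction == pytest.approx(1.0)
        assert strat.non_hot.baseline == pytest.approx(3 / 5)

    def test_no_hot_regions_collapses_to_plain_enrichment(self):
        peaks = [_peak("c", 150)]
        tiles = [
            _tile("a", "c", 100, 200, active=True),
            _tile("b", "c", 5000, 5100, active=False),
            _tile("d", "c", 6000, 6100, active=True),
        ]
        strat = hot_stratified_enrichment(tiles, peaks, [])
        plain = activity_enrichment(tiles_overlapping_summits(tiles, peaks, 0), tiles)
        assert strat.hot is None
        assert (strat.non_hot.k, strat.non_hot.n, strat.non_hot.K, strat.non_hot.N) == (
            plain.k, plain.n, plain.K, plain.N,
        )

    def test_partition_cells_sum_to_universe(self, small_dataset):
        ds = small_dataset
        strat = hot_stratified_enrichment(ds.tiles, ds.peaks, ds.hot)
        assert sum(n for _, n in strat.cells.values()) == len(ds.tiles)


class TestCompareSubsets:
    def test_locus_vs_outside_worked_example(self):
        """64/78 (82%) vs 177/264 (67%) differ with hypergeometric p 0.0066."""
        c = compare_counts(64, 78, 177, 264)
        assert round(100 * c.fraction_a) == 82
        assert round(100 * c.fraction_b) == 67
        assert c.p == pytest.approx(0.0066, abs=5e-4)

    def test_cobound_vs_pho_only_worked_example(self):
        c = compare_counts(31, 40, 40, 72)
        assert round(100 * c.fraction_a, 1) == 77.5
        assert round(100 * c.fraction_b, 1) == 55.6

    def test_identical_composition_not_significant(self):
        c = compare_counts(20, 40, 20, 40)
        assert 0.4 <= c.p <= 1.0

    def test_overlapping_subsets_rejected(self):
        t = _tile("x", "c", 0, 50)
        with pytest.raises(ValidationError):
            compare_two_subsets([t], [t])


class TestCobindingPartition:
    def test_no_peaks_gives_empty_cobound_class(self):
        tiles = [_tile("a", "c", 100, 200)]
        pho = [GenomicInterval("c", 150, 160)]
        part = cobinding_partition(tiles, pho, [])
        assert part.pho_and_ubx == []
        assert part.pho_only == tiles

    def test_partition_is_exhaustive_and_disjoint(self, small_dataset):
        ds = small_dataset
        part = cobinding_partition(ds.tiles, ds.pho, ds.peaks, flank=250)
        ids = [t.id for t in part.pho_only + part.pho_and_ubx + part.other]
        assert sorted(ids) == sorted(t.id for t in ds.tiles)

    def test_study_scale_fraction(self):
        """71 of 112 Pho-bound tiles active = 63.4%."""
        tiles = [
            _tile(f"t{i}", "c", 1000 * i, 1000 * i + 100, active=i < 71)
            for i in range(112)
        ]
        pho = [GenomicInterval("c", 1000 * i, 1000 * i + 100) for i in range(112)]
        part = cobinding_partition(tiles, pho, [])
        fr = part.activity_fractions()
        assert round(100 * fr["pho_bound"], 1) == 63.4


class TestCalibration:
    def test_type_one_error_rate_under_null(self):
        """With activity independent of binding, the hypergeometric test
        rejects at its achievable size (discrete null, alpha = 0.05)."""
        N, K, n = 200, 90, 40
        from scipy import stats

        # achievable size of the discrete test at nominal alpha = 0.05
        ks = np.arange(max(0, n + K - N), min(n, K) + 1)
        pvals = np.array([hypergeometric_upper_tail(int(k), n, K, N) for k in ks])
        pmf = stats.hypergeom.pmf(ks, N, K, n)
        size = float(pmf[pvals <= 0.05].sum())
        rng = np.random.default_rng(42)
        reps = 2000
        draws = stats.hypergeom.rvs(N, K, n, size=reps, random_state=rng)
        rej = np.mean([
            hypergeometric_upper_tail(int(k), n, K, N) <= 0.05 for k in draws
        ])
        band = 2.576 * math.sqrt(size * (1 - size) / reps)
        assert abs(rej - size) <= band
        assert 0.01 < size <= 0.05  # the discrete size is near, never above, 5%
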