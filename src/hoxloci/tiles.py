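"""Enrichment of enhancer activity among peak-bound reporter tiles.

The universe is a genome-scale set of reporter-assayed tiles, each flagged
active or inactive (overall and optionally per developmental stage).  A
tile is "bound" when it overlaps a peak summit window: with flank 0 the
summit base must fall inside the tile (the rule used for plain bound-tile
enrichment); with flank 250 a +/- 250 bp window around the summit must
share >= 1 bp with the tile (the rule used for co-binding analyses).

All significance is hypergeometric: drawing ``n`` tiles from a universe of
``N`` containing ``K`` active ones, the upper-tail probability of seeing at
least the observed ``k`` active tiles.  The upper tail is P(X >= k), the
standard enrichment convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .core import (
    Genome,
    IntervalSet,
    Peak,
    Tile,
    ValidationError,
    summit_windows,
)


def hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValidationError(f"infeasible hypergeometric counts k={k} n={n} K={K} N={N}")
    if k < max(0, n + K - N):
        raise ValidationError(f"k={k} below the minimum feasible overlap {max(0, n + K - N)}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentResult:
    """(k, n, K, N) contingency summary with fraction, fold and upper-tail p."""

    k: int  # active in subset
    n: int  # subset size
    K: int  # active in universe
    N: int  # universe size

    def __post_init__(self):
        if not (0 <= self.k <= self.n <= self.N and self.k <= self.K <= self.N):
            raise ValidationError(
                f"infeasible counts k={self.k} n={self.n} K={self.K} N={self.N}"
            )

    @property
    def fraction(self) -> float:
        return self.k / self.n if self.n else 0.0

    @property
    def baseline(self) -> float:
        return self.K / self.N

    @property
    def fold(self) -> float:
        if self.K == 0:
            return 0.0
        return self.fraction / self.baseline

    @property
    def p(self) -> float:
        if self.n == 0:
            return 1.0
        return hypergeometric_upper_tail(self.k, self.n, self.K, self.N)

    def summary(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "K": self.K,
            "N": self.N,
            "fraction_pct": round(100 * self.fraction, 1),
            "baseline_pct": round(100 * self.baseline, 1),
            "fold": round(self.fold, 1),
            "p": self.p,
        }


def tiles_overlapping_summits(
    tiles: Sequence[Tile],
    peaks: Sequence[Peak],
    flank: int = 0,
    genome: Genome | None = None,
) -> list[Tile]:
    """Tiles sharing >= 1 bp with any [summit-flank, summit+flank+1) window."""
    windows = IntervalSet(summit_windows(peaks, flank, genome))
    return [t for t in tiles if windows.overlaps(t.interval)]


def activity_enrichment(subset: Sequence[Tile], universe: Sequence[Tile]) -> EnrichmentResult:
    """Overall-activity enrichment of a tile subset against its universe."""
    if not subset:
        raise ValidationError("activity_enrichment requires a non-empty subset")
    _require_subset(subset, universe)
    return EnrichmentResult(
        k=sum(t.active_any for t in subset),
        n=len(subset),
        K=sum(t.active_any for t in universe),
        N=len(universe),
    )


def stage_stratified_enrichment(
    subset: Sequence[Tile], universe: Sequence[Tile]
) -> tuple[list[EnrichmentResult], float]:
    """Per-stage enrichment plus the mean per-stage fold."""
    if not subset:
        raise ValidationError("stage_stratified_enrichment requires a non-empty subset")
    _require_subset(subset, universe)
    n_stages = {len(t.stage_activity) for t in universe if t.stage_activity is not None}
    if len(n_stages) != 1 or any(t.stage_activity is None for t in universe):
        raise ValidationError("stage_activity missing or of unequal length across tiles")
    (k_stages,) = n_stages
    results = []
    for s in range(k_stages):
        results.append(
            EnrichmentResult(
                k=sum(t.stage_activity[s] for t in subset),
                n=len(subset),
                K=sum(t.stage_activity[s] for t in universe),
                N=len(universe),
            )
        )
    mean_fold = sum(r.fold for r in results) / k_stages
    return results, mean_fold


@dataclass(frozen=True)
class HotStratification:
    """Activity enrichment of bound tiles inside each HOT stratum.

    ``cells`` maps (bound, hot) to (n_active, n_total); ``hot`` and
    ``non_hot`` compare bound tiles of a stratum against all tiles of that
    stratum (the matching non-bound-inclusive universe), mirroring the
    bound-vs-all comparison of the unstratified analysis.
    """

    cells: dict[tuple[bool, bool], tuple[int, int]]
    hot: EnrichmentResult | None
    non_hot: EnrichmentResult | None


def hot_stratified_enrichment(
    tiles: Sequence[Tile],
    peaks: Sequence[Peak],
    hot_regions,
    flank: int = 0,
    genome: Genome | None = None,
) -> HotStratification:
    bound = set(t.id for t in tiles_overlapping_summits(tiles, peaks, flank, genome))
    hot = IntervalSet(hot_regions)
    cells: dict[tuple[bool, bool], list[Tile]] = {
        (b, h): [] for b in (True, False) for h in (True, False)
    }
    for t in tiles:
        cells[(t.id in bound, hot.overlaps(t.interval))].append(t)
    counts = {
        key: (sum(t.active_any for t in ts), len(ts)) for key, ts in cells.items()
    }
    results = {}
    for h in (True, False):
        stratum = cells[(True, h)] + cells[(False, h)]
        in_cell = cells[(True, h)]
        if in_cell and stratum:
            results[h] = EnrichmentResult(
                k=sum(t.active_any for t in in_cell),
                n=len(in_cell),
                K=sum(t.active_any for t in stratum),
                N=len(stratum),
            )
        else:
            results[h] = None
    return HotStratification(counts, results[True], results[False])


@dataclass(frozen=True)
class SubsetComparison:
    k_a: int
    n_a: int
    k_b: int
    n_b: int

    @property
    def fraction_a(self) -> float:
        return self.k_a / self.n_a

    @property
    def fraction_b(self) -> float:
        return self.k_b / self.n_b

    @property
    def p(self) -> float:
        """Upper-tail hypergeometric p that subset A is the more active one.

        A union B is the population, all actives are the successes, A is the
        drawn sample and k_a the observed overlap.
        """
        return hypergeometric_upper_tail(
            self.k_a, self.n_a, self.k_a + self.k_b, self.n_a + self.n_b
        )


def compare_two_subsets(
    subset_a: Sequence[Tile], subset_b: Sequence[Tile]
) -> SubsetComparison:
    """Compare activity fractions of two disjoint tile subsets."""
    ids_a = {t.id for t in subset_a}
    if ids_a & {t.id for t in subset_b}:
        raise ValidationError("subsets must be disjoint")
    if not subset_a or not subset_b:
        raise ValidationError("both subsets must be non-empty")
    return SubsetComparison(
        k_a=sum(t.active_any for t in subset_a),
        n_a=len(subset_a),
        k_b=sum(t.active_any for t in subset_b),
        n_b=len(subset_b),
    )


def compare_counts(k_a: int, n_a: int, k_b: int, n_b: int) -> SubsetComparison:
    """Two-subset comparison from pre-tabulated counts."""
    return SubsetComparison(k_a, n_a, k_b, n_b)


@dataclass(frozen=True)
class CobindingPartition:
    """Tiles split by Pho binding and Pho+peak co-binding."""

    pho_only: list[Tile]
    pho_and_ubx: list[Tile]
    other: list[Tile]

    def activity_fractions(self) -> dict[str, float]:
        def frac(ts):
            return sum(t.active_any for t in ts) / len(ts) if ts else float("nan")

        pho_bound = self.pho_only + self.pho_and_ubx
        return {
            "pho_bound": frac(pho_bound),
            "pho_only": frac(self.pho_only),
            "pho_and_ubx": frac(self.pho_and_ubx),
            "other": frac(self.other),
        }


def cobinding_partition(
    tiles: Sequence[Tile],
    pho_regions,
    ubx_peaks: Sequence[Peak],
    flank: int = 250,
    genome: Genome | None = None,
) -> CobindingPartition:
    """Partition tiles into Pho-only, Pho+peak co-bound, and the rest.

    Pho binding is >= 1 bp overlap with a Pho region; co-binding adds
    overlap with a peak summit +/- flank window (default 250 bp).
    """
    pho = IntervalSet(pho_regions)
    windows = IntervalSet(summit_windows(ubx_peaks, flank, genome)) if ubx_peaks else None
    pho_only, pho_and_ubx, other = [], [], []
    for t in tiles:
        if pho.overlaps(t.interval):
            if windows is not None and windows.overlaps(t.interval):
                pho_and_ubx.append(t)
            else:
                pho_only.append(t)
        else:
            other.append(t)
    return CobindingPartition(pho_only, pho_and_ubx, other)


def _require_subset(subset: Iterable[Tile], universe: Iterable[Tile]) -> None:
    missing = {t.id for t in subset} - {t.id for t in universe}
    if missing:
        raise ValidationError(f"subset tiles not in universe: {sorted(missing)[:5]}")
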