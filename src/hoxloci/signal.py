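"""External ChIP signal at peak summits vs control regions.

Signal is read from stepwise-constant log2(ChIP/input) tracks either at
single summit positions or as a base-weighted median over (optionally
HOT-masked) regions.  Foreground/background comparisons use the one-sided
Wilcoxon rank-sum test (tie-corrected normal approximation, enrichment
direction foreground > background); threshold-sweep curves report, per site
set, the fraction of sites whose signal exceeds each cut-off, with missing
signal counted in the denominator so curves of differently sized site sets
stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import GenomicInterval, IntervalSet, SignalTrack, ValidationError


def signal_at_points(
    track: SignalTrack, positions: Sequence[tuple[str, int]]
) -> np.ndarray:
    """Track value at each (chrom, pos); NaN where no step covers the base."""
    out = np.empty(len(positions), dtype=float)
    by_chrom: dict[str, list[int]] = {}
    for i, (chrom, _pos) in enumerate(positions):
        by_chrom.setdefault(chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        pos = np.array([positions[i][1] for i in idxs], dtype=np.int64)
        out[np.array(idxs)] = track.values_at(chrom, pos)
    return out


def _weighted_median(widths: np.ndarray, values: np.ndarray) -> float:
    """Median of the per-base expansion: each value repeated width times.

    For an even total base count the median is the mean of the two central
    base values.
    """
    order = np.argsort(values, kind="stable")
    w = widths[order].astype(np.int64)
    v = values[order]
    total = int(w.sum())
    cum = np.cumsum(w)
    if total % 2 == 1:
        return float(v[np.searchsorted(cum, total // 2, side="right")])
    lo = float(v[np.searchsorted(cum, total // 2 - 1, side="right")])
    hi = float(v[np.searchsorted(cum, total // 2, side="right")])
    return (lo + hi) / 2.0


def median_signal_over_regions(
    track: SignalTrack,
    regions: Sequence[GenomicInterval],
    exclude=None,
) -> np.ndarray:
    """Base-weighted median step value per region, after masking ``exclude``.

    Bases inside ``exclude`` (e.g. HOT regions) and bases not covered by any
    step contribute nothing; a region with no remaining covered base yields
    NaN.
    """
    mask = IntervalSet(exclude) if exclude else None
    out = np.empty(len(regions), dtype=float)
    for i, region in enumerate(regions):
        pieces = (
            mask.subtract(region) if mask is not None else [(region.start, region.end)]
        )
        widths, values = [], []
        starts, ends, vals = track.steps(region.chrom)
        for ps, pe in pieces:
            lo = int(np.searchsorted(ends, ps, side="right"))
            hi = int(np.searchsorted(starts, pe, side="left"))
            for j in range(lo, hi):
                ov = min(int(ends[j]), pe) - max(int(starts[j]), ps)
                if ov > 0:
                    widths.append(ov)
                    values.append(vals[j])
        if not widths:
            out[i] = np.nan
        else:
            out[i] = _weighted_median(np.asarray(widths), np.asarray(values))
    return out


@dataclass(frozen=True)
class SignalComparison:
    median_fg: float
    median_bg: float
    wilcoxon_p: float
    n_fg: int
    n_bg: int
    n_missing_fg: int
    n_missing_bg: int


def compare_signal(fg_values, bg_values) -> SignalComparison:
    """One-sided rank-sum comparison (foreground > background).

    NaN (missing) values are dropped before testing and their counts
    reported; the asymptotic normal approximation with tie correction is
    used, appropriate at the sample sizes of genome-scale site sets.
    """
    fg = np.asarray(fg_values, dtype=float)
    bg = np.asarray(bg_values, dtype=float)
    n_missing_fg = int(np.isnan(fg).sum())
    n_missing_bg = int(np.isnan(bg).sum())
    fg = fg[~np.isnan(fg)]
    bg = bg[~np.isnan(bg)]
    if fg.size == 0 or bg.size == 0:
        raise ValidationError("compare_signal: a sample is empty after NaN removal")
    res = stats.mannwhitneyu(fg, bg, alternative="greater", method="asymptotic")
    return SignalComparison(
        float(np.median(fg)),
        float(np.median(bg)),
        float(res.pvalue),
        fg.size,
        bg.size,
        n_missing_fg,
        n_missing_bg,
    )


@dataclass(frozen=True)
class OverlapCurve:
    """Per-site-set fraction of sites with signal above each threshold."""

    grid: np.ndarray
    fractions: dict[str, np.ndarray]

    def area(self, name: str) -> float:
        return float(np.trapezoid(self.fractions[name], self.grid))


def threshold_sweep(values_by_siteset: dict[str, Sequence[float]], grid) -> OverlapCurve:
    """Fraction of sites strictly above each threshold, per site set.

    Missing (NaN) values count as "not above" but stay in the denominator,
    so fractions are comparable across site sets of different sizes.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("threshold grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("threshold grid must be strictly increasing")
    if not values_by_siteset:
        raise ValidationError("need >= 1 site set")
    fractions = {}
    for name, values in values_by_siteset.items():
        v = np.asarray(values, dtype=float)
        v = v[:, None]
        above = np.nansum(v > grid[None, :], axis=0)
        fractions[name] = above / len(values)
    return OverlapCurve(grid, fractions)


def multi_siteset_ranking(curve: OverlapCurve) -> list[tuple[str, float]]:
    """Site sets ordered by descending area under their overlap curve.

    Ties are broken lexicographically by name for determinism.
    """
    areas = [(name, curve.area(name)) for name in curve.fractions]
    return sorted(areas, key=lambda t: (-t[1], t[0]))
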