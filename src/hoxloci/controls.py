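"""Matched negative-control regions.

Controls are fixed-width regions whose genomic-category distribution (the
same summit-point classifier used for peaks) matches the peak set's: target
per-category counts come from largest-remainder rounding of n x the peak
fractions, and region midpoints are sampled uniformly within each
category's genomic territory, rejecting candidates that overlap any peak
interval or a previously accepted control.  Sampling is deterministic given
the seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import CATEGORIES, GeneAnnotation, _CODE, summit_categories
from .core import GenomicInterval, IntervalSet, Peak, ValidationError


@dataclass(frozen=True)
class ControlSet:
    regions: list[GenomicInterval]
    categories: list[str]  # midpoint category per region, aligned with regions
    target_counts: dict[str, int]
    seed: int
    width: int

    @property
    def achieved_counts(self) -> dict[str, int]:
        return {c: self.categories.count(c) for c in CATEGORIES}


def largest_remainder_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Integer quotas summing exactly to n, each within 1 of n x fraction."""
    raw = {c: n * f for c, f in fractions.items()}
    floors = {c: int(np.floor(v)) for c, v in raw.items()}
    shortfall = n - sum(floors.values())
    remainders = sorted(
        fractions, key=lambda c: (raw[c] - floors[c], c), reverse=True
    )
    for c in remainders[:shortfall]:
        floors[c] += 1
    return floors


def sample_matched_controls(
    peaks: Sequence[Peak],
    annotation: GeneAnnotation,
    n: int,
    width: int | None = None,
    seed: int = 0,
    promoter_upstream: int = 500,
    promoter_downstream: int = 100,
    max_tries: int = 10_000,
) -> ControlSet:
    """Sample n control regions category-matched to the peak summits."""
    if n <= 0:
        raise ValidationError(f"n must be > 0, got {n}")
    peaks = list(peaks)
    if not peaks:
        raise ValidationError("need >= 1 peak to match against")
    if width is None:
        width = int(np.median([p.interval.length for p in peaks]))
    cats = summit_categories(peaks, annotation, promoter_upstream, promoter_downstream)
    fractions = {c: cats.count(c) / len(cats) for c in CATEGORIES}
    targets = largest_remainder_counts(fractions, n)

    cmap = annotation.category_map(promoter_upstream, promoter_downstream)
    chrom_names = list(cmap)
    peak_set = IntervalSet(p.interval for p in peaks)
    rng = np.random.default_rng(seed)

    # accepted controls per chromosome, kept sorted by start for overlap checks
    accepted: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def collides(chrom: str, start: int, end: int) -> bool:
        ivs = accepted[chrom]
        i = bisect.bisect_left(ivs, (end, end))
        return i > 0 and ivs[i - 1][1] > start

    regions: list[GenomicInterval] = []
    region_cats: list[str] = []
    for cat in CATEGORIES:
        quota = targets[cat]
        if quota == 0:
            continue
        code = _CODE[cat]
        territory = {
            c: np.flatnonzero(cmap[c] == code) if code else np.flatnonzero(cmap[c] == 0)
            for c in chrom_names
        }
        sizes = np.array([territory[c].size for c in chrom_names], dtype=float)
        if sizes.sum() == 0:
            raise ValidationError(f"no genomic territory for category {cat!r}")
        probs = sizes / sizes.sum()
        placed = 0
        while placed < quota:
            for _ in range(max_tries):
                chrom = chrom_names[rng.choice(len(chrom_names), p=probs)]
                mid = int(territory[chrom][rng.integers(territory[chrom].size)])
                start = mid - width // 2
                end = start + width
                if start < 0 or end > len(cmap[chrom]):
                    continue
                if peak_set.overlaps(GenomicInterval(chrom, start, end)):
                    continue
                if collides(chrom, start, end):
                    continue
                bisect.insort(accepted[chrom], (start, end))
                regions.append(GenomicInterval(chrom, start, end))
                region_cats.append(cat)
                placed += 1
                break
            else:
                raise ValidationError(
                    f"could not place control {placed + 1}/{quota} for category "
                    f"{cat!r} within {max_tries} tries (territory too small?)"
                )
    return ControlSet(regions, region_cats, targets, seed, width)


def matching_report(
    controls: ControlSet, peaks: Sequence[Peak], annotation: GeneAnnotation,
    promoter_upstream: int = 500, promoter_downstream: int = 100,
) -> tuple[pd.DataFrame, float]:
    """Per-category fraction table and the max |control - peak| deviation."""
    peak_cats = summit_categories(
        list(peaks), annotation, promoter_upstream, promoter_downstream
    )
    n_p, n_c = len(peak_cats), len(controls.regions)
    rows = []
    for cat in CATEGORIES:
        pf = peak_cats.count(cat) / n_p if n_p else 0.0
        cf = controls.categories.count(cat) / n_c if n_c else 0.0
        rows.append({"category": cat, "peak_fraction": pf, "control_fraction": cf,
                     "abs_deviation": abs(pf - cf)})
    df = pd.DataFrame(rows).set_index("category")
    return df, float(df["abs_deviation"].max())
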