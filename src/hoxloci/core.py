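"""Core genomic data model and interval algebra.

All coordinates inside the package are 0-based half-open ([start, end));
1-based inclusive records (peak-caller TSV, GFF) are converted at the I/O
boundary and nowhere else.  Strand is carried but ignored by all overlap
logic except motif scanning, since ChIP peaks are unstranded.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

#: Sentinel returned by signal queries that fall outside any covered step.
MISSING = float("nan")


class ParseError(ValueError):
    """A malformed record in an input file; carries path and line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class ValidationError(ValueError):
    """Semantically invalid data (e.g. coordinates off the chromosome)."""


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome name/length table (the coordinate frame).

    Chromosome order is preserved from the source ``chrom.sizes`` file and
    used for all sorted outputs.
    """

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in genome")
        for name, length in self.chroms:
            if length <= 0:
                raise ValidationError(f"chromosome {name} has length {length} <= 0")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "Genome":
        return cls(tuple(sizes.items()))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in dict(self.chroms)

    def __len__(self) -> int:
        return len(self.chroms)

    def length(self, chrom: str) -> int:
        try:
            return dict(self.chroms)[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chroms)

    def chrom_order(self, chrom: str) -> int:
        return self.names.index(chrom)

    def validate_interval(self, iv: "GenomicInterval") -> None:
        if iv.chrom not in self:
            raise ValidationError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.length(iv.chrom):
            raise ValidationError(
                f"interval {iv} exceeds {iv.chrom} length {self.length(iv.chrom)}"
            )


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __repr__(self):
        return f"{self.chrom}:[{self.start},{self.end})"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared base pairs between two intervals (0 on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal disjoint cover of the union, sorted by (chrom, start).

    Book-ended intervals ([0,100) and [100,200)) merge: union semantics, as
    needed when contiguously tiling windows are collapsed into loci.
    """
    by_key = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_key:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


class IntervalSet:
    """Merged, binary-searchable set of intervals for overlap membership.

    Built once, queried many times; the merged representation makes every
    overlap query O(log n) because disjoint sorted intervals have sorted
    end coordinates as well.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for iv in merge_intervals(intervals):
            self._starts.setdefault(iv.chrom, []).append(iv.start)
            self._ends.setdefault(iv.chrom, []).append(iv.end)

    def __bool__(self) -> bool:
        return bool(self._starts)

    def intervals(self) -> Iterator[GenomicInterval]:
        for chrom in self._starts:
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                yield GenomicInterval(chrom, s, e)

    @property
    def total_bp(self) -> int:
        return sum(
            e - s
            for chrom in self._starts
            for s, e in zip(self._starts[chrom], self._ends[chrom])
        )

    def overlaps(self, iv: GenomicInterval) -> bool:
        """True iff >= 1 bp is shared with any member interval."""
        starts = self._starts.get(iv.chrom)
        if not starts:
            return False
        i = bisect.bisect_left(starts, iv.end)  # last member starting before iv.end
        return i > 0 and self._ends[iv.chrom][i - 1] > iv.start

    def contains_point(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos)
        return i > 0 and self._ends[chrom][i - 1] > pos

    def overlap_bp(self, iv: GenomicInterval) -> int:
        starts = self._starts.get(iv.chrom)
        if not starts:
            return 0
        ends = self._ends[iv.chrom]
        lo = bisect.bisect_right(ends, iv.start)
        hi = bisect.bisect_left(starts, iv.end)
        return sum(
            min(ends[i], iv.end) - max(starts[i], iv.start) for i in range(lo, hi)
        )

    def intersect(self, iv: GenomicInterval) -> list[tuple[int, int]]:
        """(start, end) pieces of ``iv`` covered by the set."""
        starts = self._starts.get(iv.chrom)
        if not starts:
            return []
        ends = self._ends[iv.chrom]
        lo = bisect.bisect_right(ends, iv.start)
        hi = bisect.bisect_left(starts, iv.end)
        return [
            (max(starts[i], iv.start), min(ends[i], iv.end)) for i in range(lo, hi)
        ]

    def subtract(self, iv: GenomicInterval) -> list[tuple[int, int]]:
        """(start, end) pieces of ``iv`` NOT covered by the set."""
        pieces = []
        cursor = iv.start
        for s, e in self.intersect(iv):
            if s > cursor:
                pieces.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < iv.end:
            pieces.append((cursor, iv.end))
        return pieces


@dataclass(frozen=True)
class Peak:
    """A scored ChIP-enriched interval with a single-base summit.

    The summit is the absolute 0-based position of maximal enrichment and is
    the anchor for every downstream point-based operation; the score is the
    peak caller's unitless significance score (thresholds 3 and 5 in the
    default configuration).
    """

    interval: GenomicInterval
    summit: int
    score: float
    name: str = ""

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside interval {self.interval} "
                f"for peak {self.name!r}"
            )
        if self.score <= 0:
            raise ValidationError(f"peak {self.name!r} has score {self.score} <= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def filter_by_score(peaks: Sequence[Peak], threshold: float) -> list[Peak]:
    """Peaks with score >= threshold (inclusive boundary), stable order."""
    if threshold <= 0:
        raise ValidationError(f"score threshold must be > 0, got {threshold}")
    return [p for p in peaks if p.score >= threshold]


def summit_windows(
    peaks: Iterable[Peak], flank: int, genome: Genome | None = None
) -> list[GenomicInterval]:
    """Window [summit - flank, summit + flank + 1) per peak, clipped to the
    chromosome when a genome is supplied.  flank=0 is the single summit base."""
    if flank < 0:
        raise ValidationError(f"flank must be >= 0, got {flank}")
    out = []
    for p in peaks:
        start = max(0, p.summit - flank)
        end = p.summit + flank + 1
        if genome is not None:
            end = min(end, genome.length(p.chrom))
        out.append(GenomicInterval(p.chrom, start, end))
    return out


@dataclass(frozen=True)
class Tile:
    """An enhancer-candidate fragment tested in a reporter assay.

    ``active_any`` flags reporter activity at any developmental stage;
    ``stage_activity`` optionally records activity per stage interval, in
    which case the overall flag must equal their OR.
    """

    id: str
    interval: GenomicInterval
    active_any: bool
    stage_activity: tuple[bool, ...] | None = None

    def __post_init__(self):
        if self.stage_activity is not None and self.active_any != any(
            self.stage_activity
        ):
            raise ValidationError(
                f"tile {self.id}: active_any inconsistent with stage flags"
            )


class SignalTrack:
    """Stepwise-constant per-chromosome signal (e.g. log2 ChIP/input).

    Steps are sorted and non-overlapping per chromosome; queries outside any
    covered step return NaN (the declared missing-value sentinel).
    """

    def __init__(self, steps: Iterable[tuple[str, int, int, float]]):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in steps:
            if not np.isfinite(value):
                raise ValidationError(f"non-finite value {value} at {chrom}:{start}")
            if start < 0 or start >= end:
                raise ValidationError(f"invalid step {chrom}:[{start},{end})")
            per_chrom.setdefault(chrom, []).append((start, end, value))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, triples in per_chrom.items():
            triples.sort()
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"overlapping steps on {chrom}")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = np.array([t[2] for t in triples], dtype=float)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._starts)

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, values) arrays for one chromosome (possibly empty)."""
        empty = np.array([], dtype=np.int64)
        return (
            self._starts.get(chrom, empty),
            self._ends.get(chrom, empty),
            self._values.get(chrom, np.array([], dtype=float)),
        )

    def __iter__(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self._starts:
            for s, e, v in zip(
                self._starts[chrom], self._ends[chrom], self._values[chrom]
            ):
                yield chrom, int(s), int(e), float(v)

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Step value covering each position; NaN where uncovered."""
        positions = np.asarray(positions, dtype=np.int64)
        starts, ends, values = self.steps(chrom)
        out = np.full(positions.shape, MISSING, dtype=float)
        if starts.size == 0:
            return out
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        covered = np.zeros_like(ok)
        covered[ok] = ends[idx[ok]] > positions[ok]
        out[covered] = values[idx[covered]]
        return out


@dataclass
class AnalysisConfig:
    """Pipeline-wide thresholds and sizes.

    Defaults follow the study configuration: score thresholds 3 (all peaks)
    and 5 (strong peaks), 100-kb scan windows, >= 25 peaks per window to call
    a highly targeted locus, summit +/- 250 bp co-binding windows, and 1425
    matched control regions.
    """

    score_low: float = 3.0
    score_high: float = 5.0
    window_size: int = 100_000
    cluster_min: int = 25
    summit_flank: int = 250
    n_controls: int = 1425
    promoter_upstream: int = 500
    promoter_downstream: int = 100
    random_seed: int = 0

    def __post_init__(self):
        for name in (
            "score_low",
            "score_high",
            "window_size",
            "cluster_min",
            "n_controls",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.summit_flank < 0:
            raise ValidationError("summit_flank must be >= 0")
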