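"""Peak-set quality control: mock-based FDR and replicate track correlation.

The empirical false-discovery rate of a ChIP peak set is estimated from a
mock immunoprecipitation (untagged strain): FDR = peaks called in the mock
sample / peaks called in the ChIP sample x 100%, with both counts taken at
the same score threshold.  The ratio is used as printed, without
pseudocounts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Genome, Peak, SignalTrack, ValidationError, filter_by_score


@dataclass(frozen=True)
class FdrReport:
    threshold: float
    n_chip: int
    n_mock: int
    fdr_percent: float | None  # None when n_chip == 0 (undefined, no division)
    status: str = "ok"


def mock_fdr(
    chip_peaks: Sequence[Peak], mock_peaks: Sequence[Peak], threshold: float
) -> FdrReport:
    """Mock/ChIP peak-count ratio at a score threshold, as a percentage."""
    n_chip = len(filter_by_score(chip_peaks, threshold))
    n_mock = len(filter_by_score(mock_peaks, threshold))
    if n_chip == 0:
        return FdrReport(threshold, 0, n_mock, None, status="undefined: no ChIP peaks")
    return FdrReport(threshold, n_chip, n_mock, 100.0 * n_mock / n_chip)


class UndefinedCorrelationError(ValidationError):
    """Raised when a binned signal vector has zero variance."""


def _binned_means(track: SignalTrack, genome: Genome, bin_size: int) -> np.ndarray:
    """Coverage-weighted mean signal per fixed genomic bin; gaps count as 0.

    Read-coverage semantics: a base not covered by any step contributes 0 to
    its bin, so sparse tracks are comparable genome-wide.
    """
    chunks = []
    for chrom, length in genome.chroms:
        n_bins = -(-length // bin_size)
        acc = np.zeros(n_bins, dtype=float)
        starts, ends, values = track.steps(chrom)
        for s, e, v in zip(starts, ends, values):
            e = min(int(e), length)
            s = int(s)
            if s >= e:
                continue
            b0, b1 = s // bin_size, (e - 1) // bin_size
            if b0 == b1:
                acc[b0] += v * (e - s)
            else:
                acc[b0] += v * ((b0 + 1) * bin_size - s)
                acc[b1] += v * (e - b1 * bin_size)
                if b1 - b0 > 1:
                    acc[b0 + 1 : b1] += v * bin_size
        # last bin may be shorter than bin_size
        widths = np.full(n_bins, bin_size, dtype=float)
        widths[-1] = length - (n_bins - 1) * bin_size
        chunks.append(acc / widths)
    return np.concatenate(chunks)


def binned_track_correlation(
    track_a: SignalTrack, track_b: SignalTrack, genome: Genome, bin_size: int = 1000
) -> float:
    """Pearson correlation of the two tracks' binned genome-wide signal."""
    if bin_size <= 0:
        raise ValidationError(f"bin_size must be > 0, got {bin_size}")
    a = _binned_means(track_a, genome, bin_size)
    b = _binned_means(track_b, genome, bin_size)
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError("zero variance in a binned signal vector")
    return float(np.corrcoef(a, b)[0, 1])
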