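"""IUPAC motif scanning and fold enrichment between region sets.

Occurrences of a degenerate (IUPAC) motif are counted on both strands of
the forward sequence: a hit at offset i means either the motif itself or
its reverse complement matches the forward strand at i.  Overlapping
occurrences count individually; a palindromic match at the same offset is
counted once.  ``N`` bases in the sequence never match.

Enrichment between a foreground and a background region set is the ratio
of per-bp hit densities, with an upper-tail binomial p-value for the
foreground count given its scanned length and the background rate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .core import GenomicInterval, ValidationError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement_iupac(motif: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(motif))


def _compile(motif: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all found; character classes
    # list concrete bases only, so sequence 'N' never matches
    body = "".join(f"[{IUPAC[c]}]" for c in motif)
    return re.compile(f"(?=(?:{body}))")


def scan_iupac(sequence: str, motif: str) -> list[int]:
    """0-based forward-strand offsets of both-strand motif hits, sorted.

    Identical offsets from a palindromic forward/reverse match are
    deduplicated.
    """
    if not motif:
        raise ValidationError("motif is empty")
    bad = set(motif.upper()) - set(IUPAC)
    if bad:
        raise ValidationError(f"non-IUPAC characters in motif: {sorted(bad)}")
    motif = motif.upper()
    seq = sequence.upper()
    hits = {m.start() for m in _compile(motif).finditer(seq)}
    rc = reverse_complement_iupac(motif)
    if rc != motif:
        hits |= {m.start() for m in _compile(rc).finditer(seq)}
    return sorted(hits)


@dataclass(frozen=True)
class MotifEnrichmentResult:
    motif: str
    fg_hits: int
    fg_bp: int
    bg_hits: int
    bg_bp: int
    fold: float | None  # None when the background rate is 0 (undefined ratio)
    p: float

    @property
    def fg_rate(self) -> float:
        return self.fg_hits / self.fg_bp

    @property
    def bg_rate(self) -> float:
        return self.bg_hits / self.bg_bp


def count_hits_in_regions(
    regions: Sequence[GenomicInterval], genome_seq: dict[str, str], motif: str
) -> tuple[int, int]:
    """(total hits, total scanned bp) over a region set."""
    hits = 0
    bp = 0
    for iv in regions:
        if iv.chrom not in genome_seq:
            raise ValidationError(f"no sequence for chromosome {iv.chrom!r}")
        seq = genome_seq[iv.chrom]
        if iv.end > len(seq):
            raise ValidationError(f"region {iv} exceeds sequence length {len(seq)}")
        hits += len(scan_iupac(seq[iv.start : iv.end], motif))
        bp += iv.length
    return hits, bp


def motif_fold_enrichment(
    fg_regions: Sequence[GenomicInterval],
    bg_regions: Sequence[GenomicInterval],
    genome_seq: dict[str, str],
    motif: str,
) -> MotifEnrichmentResult:
    """Density-ratio fold enrichment of the motif in foreground vs background.

    p is the upper-tail binomial probability of >= fg_hits in fg_bp
    positions at the background per-bp rate.  With zero background hits the
    fold is undefined (None) and p is computed against the pseudocount rate
    (bg_hits + 1) / bg_bp.
    """
    if not fg_regions or not bg_regions:
        raise ValidationError("both region sets must be non-empty")
    fg_hits, fg_bp = count_hits_in_regions(fg_regions, genome_seq, motif)
    bg_hits, bg_bp = count_hits_in_regions(bg_regions, genome_seq, motif)
    bg_rate = bg_hits / bg_bp
    if bg_hits == 0:
        fold = None
        rate = (bg_hits + 1) / bg_bp
    else:
        fold = (fg_hits / fg_bp) / bg_rate
        rate = bg_rate
    p = 1.0 if fg_hits == 0 else float(stats.binom.sf(fg_hits - 1, fg_bp, min(rate, 1.0)))
    return MotifEnrichmentResult(motif.upper(), fg_hits, fg_bp, bg_hits, bg_bp, fold, p)
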