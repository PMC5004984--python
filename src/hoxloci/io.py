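"""Readers and writers for the plain-text formats the pipeline touches.

Every reader converts to the internal 0-based half-open convention at the
boundary; every writer emits tab-separated, newline-terminated records in the
same dialect it reads, so a write/read round-trip is the identity.

Dialects
--------
peak_tsv
    ``chrom  start  end  name  summit  score`` with 1-based inclusive
    coordinates and a 1-based absolute summit (peak-caller style output).
bed6plus
    BED6 (0-based half-open, score in column 5, strand in column 6) plus a
    7th column giving the summit as a 0-based offset from the interval start.

The tile activity table is a headered TSV with columns ``id, chrom, start,
end, active_any`` (0-based half-open) and optional ``stage_*`` columns of
0/1 flags ordered by developmental stage.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    Genome,
    GenomicInterval,
    ParseError,
    Peak,
    SignalTrack,
    Tile,
    ValidationError,
)

PEAK_DIALECTS = ("peak_tsv", "bed6plus")


def _check_chrom(genome: Genome | None, chrom: str, path, lineno: int) -> None:
    if genome is not None and chrom not in genome:
        raise ValidationError(
            f"{path}:{lineno}: chromosome {chrom!r} absent from genome "
            f"(known: {', '.join(genome.names)})"
        )


def _data_lines(path):
    """Yield (lineno, fields) skipping blanks, comments and track lines."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_chrom_sizes(path) -> Genome:
    """Two-column TSV of chromosome name and length."""
    chroms = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, "expected 2 columns (chrom, length)")
        try:
            chroms.append((fields[0], int(fields[1])))
        except ValueError:
            raise ParseError(path, lineno, f"bad length {fields[1]!r}") from None
    return Genome(tuple(chroms))


def write_chrom_sizes(path, genome: Genome) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chroms:
            fh.write(f"{name}\t{length}\n")


def read_peak_table(path, dialect: str = "peak_tsv", genome: Genome | None = None) -> list[Peak]:
    """Parse a peak table into internal coordinates, preserving file order."""
    if dialect not in PEAK_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {PEAK_DIALECTS}")
    peaks = []
    for lineno, fields in _data_lines(path):
        # tolerate a single header row (non-numeric start column)
        if lineno == 1 and not _is_int(fields[1] if len(fields) > 1 else ""):
            continue
        try:
            if dialect == "peak_tsv":
                if len(fields) < 6:
                    raise ParseError(path, lineno, "expected 6 columns")
                chrom, start1, end1, name, summit1, score = fields[:6]
                iv = GenomicInterval(chrom, int(start1) - 1, int(end1))
                summit = int(summit1) - 1
            else:
                if len(fields) < 7:
                    raise ParseError(path, lineno, "expected 7 columns")
                chrom, start0, end0, name, score, strand, offset = fields[:7]
                iv = GenomicInterval(chrom, int(start0), int(end0), strand)
                summit = iv.start + int(offset)
            _check_chrom(genome, chrom, path, lineno)
            peak = Peak(iv, summit, float(score), name)
        except (ValueError, TypeError) as exc:
            if isinstance(exc, (ParseError, ValidationError)):
                raise
            raise ParseError(path, lineno, f"malformed peak row: {exc}") from None
        if genome is not None:
            genome.validate_interval(iv)
        peaks.append(peak)
    return peaks


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def write_peak_table(path, peaks: Sequence[Peak], dialect: str = "peak_tsv") -> None:
    if dialect not in PEAK_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            if dialect == "peak_tsv":
                fh.write(
                    f"{iv.chrom}\t{iv.start + 1}\t{iv.end}\t{p.name}"
                    f"\t{p.summit + 1}\t{p.score:g}\n"
                )
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score:g}"
                    f"\t{iv.strand}\t{p.summit - iv.start}\n"
                )


def read_bed(path, genome: Genome | None = None) -> list[GenomicInterval]:
    """BED3+ intervals (strand taken from column 6 when present)."""
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, "expected >= 3 BED columns")
        try:
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
        except (ValueError, ValidationError) as exc:
            raise ParseError(path, lineno, f"malformed BED row: {exc}") from None
        _check_chrom(genome, iv.chrom, path, lineno)
        if genome is not None:
            genome.validate_interval(iv)
        out.append(iv)
    return out


def write_bed(path, intervals: Iterable[GenomicInterval], names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bedgraph(path, genome: Genome | None = None) -> SignalTrack:
    steps = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(path, lineno, "expected 4 bedGraph columns")
        try:
            steps.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError as exc:
            raise ParseError(path, lineno, f"malformed bedGraph row: {exc}") from None
        _check_chrom(genome, fields[0], path, lineno)
    return SignalTrack(steps)


def write_bedgraph(path, track: SignalTrack) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_tile_table(path, genome: Genome | None = None) -> list[Tile]:
    """Headered TSV of enhancer tiles with activity flags (see module docs)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    required = {"id", "chrom", "start", "end", "active_any"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"tile table missing columns: {sorted(missing)}")
    stage_cols = [c for c in df.columns if c.startswith("stage_")]
    tiles = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        _check_chrom(genome, row.chrom, path, i)
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        if genome is not None:
            genome.validate_interval(iv)
        stages = (
            tuple(bool(getattr(row, c)) for c in stage_cols) if stage_cols else None
        )
        tiles.append(Tile(str(row.id), iv, bool(row.active_any), stages))
    return tiles


def write_tile_table(path, tiles: Sequence[Tile]) -> None:
    n_stages = 0
    for t in tiles:
        if t.stage_activity is not None:
            n_stages = max(n_stages, len(t.stage_activity))
    stage_cols = [f"stage_{i + 1}" for i in range(n_stages)]
    with open(path, "w") as fh:
        fh.write("\t".join(["id", "chrom", "start", "end", "active_any"] + stage_cols) + "\n")
        for t in tiles:
            row = [t.id, t.interval.chrom, str(t.interval.start), str(t.interval.end),
                   str(int(t.active_any))]
            flags = t.stage_activity or ()
            row += [str(int(f)) for f in flags] + [""] * (n_stages - len(flags))
            fh.write("\t".join(row) + "\n")


def read_fasta(path) -> dict[str, str]:
    """Uppercased sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str], width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gene_annotation(path, genome: Genome):
    """GFF3/GTF gene models -> GeneAnnotation (see :mod:`hoxloci.annotation`)."""
    from .annotation import GeneAnnotation

    return GeneAnnotation.from_gff(path, genome)
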