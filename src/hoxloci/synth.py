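"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates, at a desk-scale genome, the features every
downstream stage relies on: a scored peak set whose strong fraction and
clustering mirror the study configuration (a two-component score mixture
with ~28% of peaks at score >= 5, plus a dozen densely clustered loci of 30
peaks each), a reporter-tile universe whose activity probability is
elevated at bound tiles (0.774 vs 0.45, pooling to roughly the 46% overall
activity rate), a small mock peak set sized to a planted FDR, HOT and
Pho-bound interval sets, a stepwise Gaussian signal track with a planted
log2 shift at a fraction of peak summits, and i.i.d. ACGT sequence with a
motif planted at a controlled background rate and fold elevation in summit
windows.

Everything is drawn from a single seeded generator in a fixed order, so a
scenario + seed determines every output byte; the ground truth of all
planted labels is recorded and written alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .annotation import Gene, GeneAnnotation, Transcript
from .core import Genome, GenomicInterval, Peak, SignalTrack, Tile, ValidationError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_chrom_sizes() -> dict[str, int]:
    return {
        "chr2L": 6_000_000,
        "chr2R": 6_000_000,
        "chr3L": 5_000_000,
        "chr3R": 5_000_000,
    }


@dataclass
class SynthScenario:
    """All knobs of the generator; defaults are the standard study-like
    conditions used throughout the test-suite and validation runs."""

    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    # gene models: one fixed-structure gene every `gene_pitch` bp
    gene_pitch: int = 25_000
    gene_length: int = 10_000
    gene_offset: int = 5_000
    # peaks
    n_background_peaks: int = 550
    peak_width: int = 200
    score_low: float = 3.0
    score_high: float = 5.0
    strong_fraction: float = 0.28  # P(score >= score_high), as in the study's 1479/5282
    # clustered loci
    n_clusters: int = 12
    peaks_per_cluster: int = 30
    cluster_span: int = 60_000
    cluster_min_separation: int = 300_000
    # mock ChIP
    fdr_target: float = 0.001  # planted mock/ChIP peak-count ratio (0.1%)
    # reporter tiles
    n_tiles: int = 2000
    tile_width: int = 2_000
    p_active_bound: float = 0.774
    p_active_unbound: float = 0.45
    n_stages: int = 3
    p_active_hot: float | None = None  # optional HOT-dominated activity override
    # HOT and Pho interval sets
    n_hot: int = 60
    hot_width: int = 2_000
    n_pho: int = 150
    pho_width: int = 500
    pho_peak_fraction: float = 0.4  # fraction of Pho regions centred on peak summits
    # signal track
    signal_step: int = 100
    signal_bg_mean: float = 0.0
    signal_bg_sd: float = 1.0
    signal_shift: float = 1.0
    signal_shift_fraction: float = 0.5
    signal_shift_halfwidth: int = 500
    # sequence / motif
    motif: str = "GCCATT"
    motif_bg_rate: float = 0.002  # target per-bp both-strand hit density outside peaks
    motif_fg_fold: float = 2.3
    motif_fg_flank: int = 250
    seed: int = 0

    def __post_init__(self):
        for name in ("p_active_bound", "p_active_unbound", "strong_fraction",
                     "signal_shift_fraction", "pho_peak_fraction", "fdr_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")

    def small(self) -> "SynthScenario":
        """A scaled-down copy for fast unit tests (same structure)."""
        return replace(
            self,
            chrom_sizes={"chrA": 1_000_000, "chrB": 800_000},
            n_background_peaks=60,
            n_clusters=2,
            cluster_min_separation=150_000,
            n_tiles=300,
            n_hot=10,
            n_pho=30,
            signal_step=200,
        )


@dataclass
class SyntheticDataset:
    scenario: SynthScenario
    genome: Genome
    genes: list[Gene]
    peaks: list[Peak]
    mock_peaks: list[Peak]
    cluster_spans: list[GenomicInterval]
    cluster_id: list[int]  # per peak; -1 = background
    signal_shifted: list[bool]  # per peak
    tiles: list[Tile]
    tile_bound: list[bool]
    hot: list[GenomicInterval]
    pho: list[GenomicInterval]
    track: SignalTrack
    sequences: dict[str, str]

    def annotation(self) -> GeneAnnotation:
        return GeneAnnotation(self.genes, self.genome)

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {"entity": "peak", "id": p.name, "label": "cluster_id", "value": cid}
            for p, cid in zip(self.peaks, self.cluster_id)
        ]
        rows += [
            {"entity": "peak", "id": p.name, "label": "signal_shifted", "value": int(s)}
            for p, s in zip(self.peaks, self.signal_shifted)
        ]
        rows += [
            {"entity": "tile", "id": t.id, "label": "bound", "value": int(b)}
            for t, b in zip(self.tiles, self.tile_bound)
        ]
        sc = self.scenario
        for key, val in (
            ("n_peaks", len(self.peaks)),
            ("n_mock_peaks", len(self.mock_peaks)),
            ("fdr_target", sc.fdr_target),
            ("p_active_bound", sc.p_active_bound),
            ("p_active_unbound", sc.p_active_unbound),
            ("motif_bg_rate", sc.motif_bg_rate),
            ("motif_fg_fold", sc.motif_fg_fold),
            ("seed", sc.seed),
        ):
            rows.append({"entity": "scenario", "id": "-", "label": key, "value": val})
        return pd.DataFrame(rows, columns=["entity", "id", "label", "value"])

    def gff_text(self) -> str:
        lines = ["##gff-version 3"]
        for g in self.genes:
            c, strand = g.span.chrom, g.span.strand
            lines.append(
                f"{c}\tsynth\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t{strand}\t.\tID={g.id}"
            )
            for t in g.transcripts:
                lines.append(
                    f"{c}\tsynth\tmRNA\t{t.span.start + 1}\t{t.span.end}\t.\t{strand}\t.\t"
                    f"ID={t.id};Parent={g.id}"
                )
                for ex in t.exons:
                    lines.append(
                        f"{c}\tsynth\texon\t{ex.start + 1}\t{ex.end}\t.\t{strand}\t.\tParent={t.id}"
                    )
                for cd in t.cds:
                    lines.append(
                        f"{c}\tsynth\tCDS\t{cd.start + 1}\t{cd.end}\t.\t{strand}\t0\tParent={t.id}"
                    )
        return "\n".join(lines) + "\n"

    def write(self, outdir) -> dict[str, Path]:
        """Write the full dataset as plain-text files; returns path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {name: outdir / fname for name, fname in (
            ("chrom_sizes", "chrom.sizes"),
            ("genes", "genes.gff"),
            ("peaks", "peaks.tsv"),
            ("mock_peaks", "mock_peaks.tsv"),
            ("tiles", "tiles.tsv"),
            ("hot", "hot.bed"),
            ("pho", "pho.bed"),
            ("signal", "signal.bedgraph"),
            ("genome", "genome.fa"),
            ("truth", "truth.tsv"),
        )}
        hio.write_chrom_sizes(paths["chrom_sizes"], self.genome)
        paths["genes"].write_text(self.gff_text())
        hio.write_peak_table(paths["peaks"], self.peaks)
        hio.write_peak_table(paths["mock_peaks"], self.mock_peaks)
        hio.write_tile_table(paths["tiles"], self.tiles)
        hio.write_bed(paths["hot"], self.hot, [f"hot_{i+1}" for i in range(len(self.hot))])
        hio.write_bed(paths["pho"], self.pho, [f"pho_{i+1}" for i in range(len(self.pho))])
        hio.write_bedgraph(paths["signal"], self.track)
        hio.write_fasta(paths["genome"], self.sequences)
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths


def expected_random_match_rate(motif: str) -> float:
    """Expected both-strand per-bp hit density of a motif in i.i.d. uniform
    ACGT sequence."""
    from .motifs import IUPAC, reverse_complement_iupac

    per_strand = math.prod(len(IUPAC[c]) for c in motif.upper()) * 0.25 ** len(motif)
    if reverse_complement_iupac(motif.upper()) == motif.upper():
        return per_strand
    return 2.0 * per_strand


def _weighted_chrom(rng, genome: Genome) -> str:
    weights = np.array([l for _, l in genome.chroms], dtype=float)
    return genome.names[rng.choice(len(weights), p=weights / weights.sum())]


def _make_genes(scenario: SynthScenario, genome: Genome) -> list[Gene]:
    """Fixed-structure genes laid down on a regular pitch, alternating strand.

    Relative structure (length 10 kb at defaults): exons [0,800), [3000,5000),
    [8000,10000); CDS from 400 to 9500 within exons, leaving a 400 bp 5'UTR
    and a 500 bp 3'UTR on the plus strand (mirrored on minus).
    """
    L = scenario.gene_length
    rel_exons = [(0, L * 8 // 100), (L * 30 // 100, L // 2), (L * 80 // 100, L)]
    cds_lo, cds_hi = L * 4 // 100, L * 95 // 100
    genes = []
    k = 0
    for chrom, length in genome.chroms:
        g0 = scenario.gene_offset
        while g0 + L <= length:
            strand = "+" if k % 2 == 0 else "-"
            exons = tuple(
                GenomicInterval(chrom, g0 + a, g0 + b, strand) for a, b in rel_exons
            )
            cds = []
            for ex in exons:
                s, e = max(ex.start, g0 + cds_lo), min(ex.end, g0 + cds_hi)
                if s < e:
                    cds.append(GenomicInterval(chrom, s, e, strand))
            span = GenomicInterval(chrom, g0, g0 + L, strand)
            tid = f"gene{k + 1}.t1"
            genes.append(
                Gene(f"gene{k + 1}", span, (Transcript(tid, span, exons, tuple(cds)),))
            )
            k += 1
            g0 += scenario.gene_pitch
    return genes


def _place_clusters(rng, scenario: SynthScenario, genome: Genome) -> list[GenomicInterval]:
    span = scenario.cluster_span
    margin = 50_000
    for _, length in genome.chroms:
        if span + 2 * margin > length:
            raise ValidationError(
                f"cluster span {span} does not fit any chromosome with margins"
            )
    spans: list[GenomicInterval] = []
    tries = 0
    while len(spans) < scenario.n_clusters:
        tries += 1
        if tries > 10_000:
            raise ValidationError("could not pack clusters; genome too small")
        chrom = _weighted_chrom(rng, genome)
        length = genome.length(chrom)
        start = int(rng.integers(margin, length - span - margin))
        cand = GenomicInterval(chrom, start, start + span)
        if all(
            s.chrom != chrom
            or abs(s.start - cand.start) >= span + scenario.cluster_min_separation
            for s in spans
        ):
            spans.append(cand)
    return spans


def _draw_scores(rng, scenario: SynthScenario, n: int) -> np.ndarray:
    """Shifted-exponential scores >= score_low with the configured strong
    fraction above score_high."""
    scale = (scenario.score_high - scenario.score_low) / -math.log(
        scenario.strong_fraction
    )
    return scenario.score_low + rng.exponential(scale, size=n)


def _make_peaks(
    rng, scenario: SynthScenario, genome: Genome, cluster_spans
) -> tuple[list[Peak], list[int]]:
    w = scenario.peak_width
    half = w // 2
    entries = []  # (chrom, summit, cluster_id)
    for _ in range(scenario.n_background_peaks):
        chrom = _weighted_chrom(rng, genome)
        summit = int(rng.integers(half, genome.length(chrom) - half))
        entries.append((chrom, summit, -1))
    for ci, span in enumerate(cluster_spans):
        for _ in range(scenario.peaks_per_cluster):
            summit = int(rng.integers(span.start, span.end))
            entries.append((span.chrom, summit, ci))
    scores = _draw_scores(rng, scenario, len(entries))
    order = {name: i for i, name in enumerate(genome.names)}
    idx = sorted(range(len(entries)), key=lambda i: (order[entries[i][0]], entries[i][1]))
    peaks, cluster_id = [], []
    for rank, i in enumerate(idx):
        chrom, summit, cid = entries[i]
        start = max(0, summit - half)
        end = min(genome.length(chrom), summit + w - half)
        peaks.append(
            Peak(GenomicInterval(chrom, start, end), summit, float(round(scores[i], 3)),
                 f"p{rank + 1:05d}")
        )
        cluster_id.append(cid)
    return peaks, cluster_id


def _make_mock_peaks(rng, scenario: SynthScenario, genome: Genome, n_chip: int) -> list[Peak]:
    n_mock = int(round(scenario.fdr_target * n_chip))
    w, half = scenario.peak_width, scenario.peak_width // 2
    scores = _draw_scores(rng, scenario, n_mock)
    peaks = []
    for i in range(n_mock):
        chrom = _weighted_chrom(rng, genome)
        summit = int(rng.integers(half, genome.length(chrom) - half))
        peaks.append(
            Peak(
                GenomicInterval(chrom, summit - half, summit + w - half),
                summit,
                float(round(scores[i], 3)),
                f"m{i + 1:04d}",
            )
        )
    return peaks


def _stage_prob(p_any: float, n_stages: int) -> float:
    """Per-stage Bernoulli probability whose OR over stages equals p_any."""
    return 1.0 - (1.0 - p_any) ** (1.0 / n_stages)


def _make_tiles(
    rng, scenario: SynthScenario, genome: Genome, peaks, hot
) -> tuple[list[Tile], list[bool]]:
    from .core import IntervalSet

    # allocate tiles per chromosome proportionally, laid on a regular pitch
    lengths = np.array([l for _, l in genome.chroms], dtype=float)
    alloc = np.floor(scenario.n_tiles * lengths / lengths.sum()).astype(int)
    for i in np.argsort(-(scenario.n_tiles * lengths / lengths.sum() - alloc)):
        if alloc.sum() >= scenario.n_tiles:
            break
        alloc[i] += 1
    summits: dict[str, np.ndarray] = {}
    for p in peaks:
        summits.setdefault(p.chrom, [])
    for p in peaks:
        summits[p.chrom].append(p.summit)
    summits = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in summits.items()}
    hot_set = IntervalSet(hot)
    tiles, bound_flags = [], []
    k = 0
    for (chrom, length), n_c in zip(genome.chroms, alloc):
        if n_c == 0:
            continue
        pitch = length // n_c
        for j in range(n_c):
            start = j * pitch + max(0, (pitch - scenario.tile_width) // 2)
            end = min(start + scenario.tile_width, length)
            iv = GenomicInterval(chrom, start, end)
            ss = summits.get(chrom, np.array([], dtype=np.int64))
            bound = bool(
                np.searchsorted(ss, end) - np.searchsorted(ss, start) > 0
            )
            if scenario.p_active_hot is not None and hot_set.overlaps(iv):
                p_any = scenario.p_active_hot
            else:
                p_any = scenario.p_active_bound if bound else scenario.p_active_unbound
            s = _stage_prob(p_any, scenario.n_stages)
            stages = tuple(bool(rng.random() < s) for _ in range(scenario.n_stages))
            k += 1
            tiles.append(Tile(f"VT{k:05d}", iv, any(stages), stages))
            bound_flags.append(bound)
    return tiles, bound_flags


def _make_regions(rng, genome: Genome, n: int, width: int) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        chrom = _weighted_chrom(rng, genome)
        start = int(rng.integers(0, genome.length(chrom) - width))
        out.append(GenomicInterval(chrom, start, start + width))
    return out


def _make_pho(rng, scenario: SynthScenario, genome: Genome, peaks) -> list[GenomicInterval]:
    n_on_peaks = int(round(scenario.pho_peak_fraction * scenario.n_pho))
    n_on_peaks = min(n_on_peaks, len(peaks))
    chosen = rng.choice(len(peaks), size=n_on_peaks, replace=False)
    half = scenario.pho_width // 2
    out = []
    for i in chosen:
        p = peaks[int(i)]
        start = max(0, p.summit - half)
        end = min(genome.length(p.chrom), start + scenario.pho_width)
        out.append(GenomicInterval(p.chrom, start, end))
    out.extend(_make_regions(rng, genome, scenario.n_pho - n_on_peaks, scenario.pho_width))
    return out


def _make_signal(
    rng, scenario: SynthScenario, genome: Genome, peaks
) -> tuple[SignalTrack, list[bool]]:
    step = scenario.signal_step
    values: dict[str, np.ndarray] = {}
    for chrom, length in genome.chroms:
        n_steps = -(-length // step)
        values[chrom] = rng.normal(
            scenario.signal_bg_mean, scenario.signal_bg_sd, n_steps
        )
    n_shift = int(round(scenario.signal_shift_fraction * len(peaks)))
    shifted_idx = set(
        int(i) for i in rng.choice(len(peaks), size=n_shift, replace=False)
    )
    hw = scenario.signal_shift_halfwidth
    shifted = []
    for i, p in enumerate(peaks):
        is_shifted = i in shifted_idx
        shifted.append(is_shifted)
        if is_shifted:
            lo = max(0, p.summit - hw) // step
            hi = min(genome.length(p.chrom), p.summit + hw + 1) // step + 1
            values[p.chrom][lo : min(hi, len(values[p.chrom]))] += scenario.signal_shift
    steps = []
    for chrom, length in genome.chroms:
        v = values[chrom]
        for j in range(len(v)):
            steps.append((chrom, j * step, min((j + 1) * step, length), float(round(v[j], 4))))
    return SignalTrack(steps), shifted


def _make_sequences(
    rng, scenario: SynthScenario, genome: Genome, peaks
) -> dict[str, str]:
    motif = scenario.motif.upper()
    from .core import merge_intervals
    from .motifs import IUPAC

    m_len = len(motif)
    p_nat = expected_random_match_rate(motif)
    bg_plant = max(0.0, scenario.motif_bg_rate - p_nat)
    fg_extra = max(0.0, (scenario.motif_fg_fold - 1.0) * scenario.motif_bg_rate)
    degenerate = any(len(IUPAC[c]) > 1 for c in motif)
    fixed_word = np.frombuffer(motif.encode(), dtype=np.uint8)

    def concrete() -> np.ndarray:
        if not degenerate:
            return fixed_word
        return np.array(
            [ord(IUPAC[c][rng.integers(len(IUPAC[c]))]) for c in motif], dtype=np.uint8
        )

    # overlapping summit windows are merged so the planting rate (and hence
    # the realized foreground density) is uniform across the foreground bp
    fg_windows = merge_intervals(
        GenomicInterval(
            p.chrom,
            max(0, p.summit - scenario.motif_fg_flank),
            min(genome.length(p.chrom), p.summit + scenario.motif_fg_flank + 1),
        )
        for p in peaks
    )
    fg_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in fg_windows:
        fg_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    seqs: dict[str, str] = {}
    for chrom, length in genome.chroms:
        arr = _BASES[rng.integers(0, 4, size=length)].copy()
        n_bg = rng.poisson(bg_plant * length)
        for pos in rng.integers(0, length - m_len, size=n_bg):
            arr[pos : pos + m_len] = concrete()
        for lo, hi in fg_by_chrom.get(chrom, []):
            span = hi - lo
            if span <= m_len:
                continue
            n_fg = rng.poisson(fg_extra * span)
            for off in rng.integers(0, span - m_len, size=n_fg):
                arr[lo + off : lo + off + m_len] = concrete()
        seqs[chrom] = arr.tobytes().decode("ascii")
    return seqs


def generate(scenario: SynthScenario) -> SyntheticDataset:
    """Draw a full dataset from the scenario; deterministic under its seed."""
    rng = np.random.default_rng(scenario.seed)
    genome = Genome.from_dict(scenario.chrom_sizes)
    genes = _make_genes(scenario, genome)
    cluster_spans = _place_clusters(rng, scenario, genome)
    peaks, cluster_id = _make_peaks(rng, scenario, genome, cluster_spans)
    mock_peaks = _make_mock_peaks(rng, scenario, genome, len(peaks))
    hot = _make_regions(rng, genome, scenario.n_hot, scenario.hot_width)
    tiles, tile_bound = _make_tiles(rng, scenario, genome, peaks, hot)
    pho = _make_pho(rng, scenario, genome, peaks)
    track, signal_shifted = _make_signal(rng, scenario, genome, peaks)
    sequences = _make_sequences(rng, scenario, genome, peaks)
    return SyntheticDataset(
        scenario=scenario,
        genome=genome,
        genes=genes,
        peaks=peaks,
        mock_peaks=mock_peaks,
        cluster_spans=cluster_spans,
        cluster_id=cluster_id,
        signal_shifted=signal_shifted,
        tiles=tiles,
        tile_bound=tile_bound,
        hot=hot,
        pho=pho,
        track=track,
        sequences=sequences,
    )


def replicate_tracks(
    genome: Genome,
    step: int = 1000,
    shared_sd: float = 1.0,
    noise_sd: float = 0.4,
    seed: int = 0,
) -> tuple[SignalTrack, SignalTrack]:
    """Two replicate-like tracks = shared signal + independent noise.

    The expected Pearson correlation of their binned values is
    shared_sd^2 / (shared_sd^2 + noise_sd^2) (0.862 at the defaults),
    emulating the concordance of two good ChIP replicates.
    """
    rng = np.random.default_rng(seed)
    steps_a, steps_b = [], []
    for chrom, length in genome.chroms:
        n = -(-length // step)
        shared = rng.normal(0.0, shared_sd, n)
        a = shared + rng.normal(0.0, noise_sd, n)
        b = shared + rng.normal(0.0, noise_sd, n)
        for j in range(n):
            s, e = j * step, min((j + 1) * step, length)
            steps_a.append((chrom, s, e, float(a[j])))
            steps_b.append((chrom, s, e, float(b[j])))
    return SignalTrack(steps_a), SignalTrack(steps_b)
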