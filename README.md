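# hoxloci

Downstream analysis of Hox transcription-factor ChIP-seq peak sets, built
around the biology of Ultrabithorax (Ubx) binding in the *Drosophila*
embryo: Hox factors bind thousands of genomic sites, their strongest
binding concentrates into dense clusters at developmental gene loci, and
their bound regions are enriched for active enhancers and for Polycomb
response elements.  `hoxloci` takes called peaks (not reads) and provides
the statistics to make each of those statements quantitative:

* **Peak QC** — empirical false-discovery rate from a mock
  immunoprecipitation, `FDR = 100% · n_mock / n_chip` at a common score
  threshold, and Pearson concordance of replicate coverage tracks over
  genomic bins.
* **Genomic annotation** — each peak summit is assigned one category
  (promoter, 5′UTR, coding exon, intron, 3′UTR, intergenic) under a fixed
  precedence, and the peak distribution is compared with the genome's
  per-base composition under the identical rule.
* **Highly targeted genomic loci (HTGLs)** — a window of width *W*
  (default 100 kb) is anchored at every peak summit; windows holding at
  least *C* summits (default 25) merge into loci scored by fold enrichment
  *n*/μ and the Poisson upper tail *P*(X ≥ *n*), μ = λ·len/*W*.
* **Enhancer-tile enrichment** — for a genome-scale set of
  reporter-assayed tiles, the activity rate of peak-bound tiles versus the
  universe, with hypergeometric upper-tail *P*(X ≥ *k*) significance and
  stage-, HOT-region- and co-binding stratifications.
* **Matched controls** — fixed-width random regions whose
  genomic-category distribution matches the peak set's (largest-remainder
  quotas, rejection sampling, seed-deterministic).
* **Signal association** — external log2(ChIP/input) tracks queried at
  summits or as base-weighted medians over regions, one-sided Wilcoxon
  rank-sum foreground-vs-control comparison, and threshold-sweep overlap
  curves with area-based ranking of site sets.
* **Motif enrichment** — both-strand IUPAC motif scanning (e.g. the Pho
  motif GCCATT) and density-ratio fold enrichment with a binomial
  upper-tail p-value.
* **Synthetic data** — a seeded generator producing a full dataset
  (peaks, mock peaks, gene models, tiles, HOT/Pho intervals, signal track,
  genome sequence) with recorded ground truth, used by the test-suite and
  available from the CLI.

## Worked example

```python
>>> from hoxloci import EnrichmentResult, poisson_enrichment
>>> EnrichmentResult(k=192, n=248, K=3557, N=7705).summary()
{'k': 192, 'n': 248, 'K': 3557, 'N': 7705, 'fraction_pct': 77.4,
 'baseline_pct': 46.2, 'fold': 1.7, 'p': 1.6646820636317755e-24}
>>> poisson_enrichment(n_observed=50, locus_length=350_000, lam=3.0)
(4.761904761904762, 1.3057622106868475e-18)
```

The first call asks: of 248 enhancer tiles overlapping a strong peak
summit, 192 were active — is that surprising when 3557 of all 7705 tiles
are active?  Answer: the bound tiles are active 77.4% of the time versus a
46.2% baseline, a 1.7-fold increase with hypergeometric p ≈ 1.7×10⁻²⁴.
The second call scores a 350-kb locus holding 50 peaks against a
background of 3 peaks per 100-kb window: 4.8-fold enriched, Poisson
p ≈ 1.3×10⁻¹⁸.

Running the whole pipeline on a synthetic dataset from the shell:

```
$ hoxloci all --out run --seed 3
metric  value
fdr_percent     0.1099
...
n_htgl_loci     12
bound_tile_active_pct   72.7
tile_baseline_active_pct        47.0
...
motif_fold      2.209
```

All 12 planted peak clusters are recovered as loci, the bound-tile
activity rate sits near the generator's 77.4% conditional probability
against a ~47% baseline, and the motif fold estimate tracks the planted
2.3× enrichment.  Every stage is also available as its own subcommand
(`simulate`, `fdr`, `trackcorr`, `annotate`, `htgl`, `tile-enrich`,
`controls`, `signal`, `sweep`, `motif`); each run writes a JSON manifest
with input digests so identical manifests imply identical outputs.

## Layout

```
src/hoxloci/
  core.py        interval algebra, Peak/Tile/SignalTrack/Genome model
  io.py          BED / bedGraph / GFF / FASTA / peak- and tile-table I/O
  peak_qc.py     mock FDR, binned track correlation
  annotation.py  summit categories and distribution summary
  htgl.py        window scan, Poisson enrichment, locus calling
  tiles.py       hypergeometric enrichment and stratifications
  controls.py    matched control sampling
  signal.py      signal extraction, rank tests, sweep curves
  motifs.py      IUPAC scanning and fold enrichment
  synth.py       synthetic-data generator with ground truth
  cli.py         `hoxloci` command-line interface
```

See `docs/methods.md` for the statistical model behind each stage and the
design decisions.
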