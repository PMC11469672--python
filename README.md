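# euseq

Analysis of nascent-transcript sequencing (EU-RNA-seq) around ionizing
radiation, and scoring of pooled CRISPR screens read out by nascent-RNA
sorting.

Shortly after DNA double-strand breaks, cells shut down a large fraction of
ongoing transcription — dominated by the ribosomal RNA genes and the highly
transcribed histone genes — while inducing many moderately expressed
protein-coding genes. Detecting a *global* shift like this is impossible
with ordinary library-size normalization, which forces every sample to the
same total. `euseq` implements the spike-in-anchored alternative and the
downstream statistics, for bench scientists and analysts working with
EU-labelled nascent RNA and ERCC spike-ins:

- **Spike-in normalization** — per-sample factors `f_s = R / E_s` from
  total ERCC reads `E_s`, so `v_{g,s} = f_s k_{g,s}` preserves genuine
  global shifts; class totals (all / rDNA / protein-coding / histone) and
  the post/pre transcription ratio.
- **Differential expression** — exact one-tail Poisson test on pooled
  normalized counts (`p = P(X ≥ b | λ = a)` in the observed direction),
  Benjamini–Hochberg FDR, DEG rule `max(FC, 1/FC) > 1.5` and `q < 0.05`;
  z-score and RPKM utilities.
- **Expression strata** — expression ranking, top-k DEG extraction,
  gene-length comparisons (Mann–Whitney U) between activated and repressed
  genes, fold-change-versus-expression tables.
- **Metagene profiles** — scaled gene-body coverage (100 body bins, ±3 kb
  flanks in 50-bp windows) and a 5'-vs-3' depletion index
  `I = log2(r5/r3)` separating initiation-like from elongation-like
  loss.
- **CRISPR screen scoring** — exact guide counting from FASTQ, the
  normalization `n = r/T × 10⁶ + 1`, `CRISPR score = log2(n_high/n_unsorted)`,
  per-guide Poisson enrichment tests with FDR, and gene-level hit calls
  (≥ 1 guide with `q ≤ 0.01` and `FC ≥ 1.5`, plus a stricter ≥ 2-guide
  "robust" flag).
- **Synthetic data** — generators for count matrices, coverage pairs and
  screens with known ground truth, so every stage is validated by parameter
  recovery without external data.

The statistical stages are scikit-learn-style estimators
(`ErccNormalizer`, `PoissonDETester`, `GuideEnrichmentScorer`) with plain
functions as thin wrappers; see `docs/methods.md` for the models,
assumptions and known caveats (including the calibration behaviour of the
fixed-rate Poisson test at moderate counts).

## Worked example

Simulate a nascent experiment with a known global shutdown and run the full
workflow (normalize → DE → strata):

```sh
euseq --out-dir run1 --seed 7 run --workflow nascent --simulate
```

```json
{
  "estimated_global_ratio": 0.47217316097870504,
  "n_degs": 865,
  "n_down": 265,
  "n_tested": 2063,
  "n_up": 600,
  "true_global_ratio": 0.47172681226309326
}
```

The simulation's true post/pre transcription ratio (0.4717 — a ~53% global
shutdown, driven by rDNA and histone repression) is recovered by the
spike-anchored estimate to three decimals; 600 genes are called up and 265
down, matching the generator's structure of many moderate inductions plus
repression of the most expressed genes. All stage tables (normalized
matrix, scale factors, class totals, DE results, rankings, per-stratum
log2FC) land in `run1/` with a JSON manifest of parameters and output
checksums.

The screen workflow behaves the same way:

```sh
euseq --out-dir run2 --seed 7 run --workflow screen --simulate
```

```json
{
  "n_guides": 10000,
  "n_hit_genes": 26,
  "precision": 0.7692307692307693,
  "sensitivity": 1.0
}
```

All 20 planted hit genes are recovered (sensitivity 1.0); the lenient
printed one-guide hit rule admits a handful of false positives (precision
0.77 here) — the `robust` column in `run2/gene_hits.tsv` flags the
essentially false-positive-free ≥ 2-guide calls.

Individual stages are available as subcommands operating on TSV/BED/
bedGraph/FASTQ files — `simulate-nascent`, `simulate-screen`, `normalize`,
`de`, `strata`, `metagene`, `screen-count`, `screen-score` — and everything
is importable as a library:

```python
from euseq import (NascentSimConfig, simulate_nascent_counts,
                   ErccNormalizer, PoissonDETester)

cm, truth = simulate_nascent_counts(NascentSimConfig(seed=7))
norm = ErccNormalizer().fit(cm).transform(cm)
de = PoissonDETester().fit(norm)
print(de.n_up_, de.n_down_)
```

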