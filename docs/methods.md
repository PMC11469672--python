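# Methods

`euseq` analyses nascent-RNA sequencing (EU-RNA-seq) of cells before and
shortly after ionizing radiation (IR), plus a pooled CRISPR screen read out
by nascent-RNA flow sorting. This note describes the models, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Spike-in-anchored normalization

IR causes a *global* drop in transcription. Any normalization that equalizes
per-sample totals (CPM, TMM, median-of-ratios under their usual assumptions)
removes exactly that signal. Because an equal mass of ERCC spike-in RNA is
added per fixed number of cells, spike-in reads provide an absolute anchor:

    f_s = R / E_s,        v_{g,s} = f_s · k_{g,s}

where `E_s` is sample *s*'s total spike-in reads, `R` a common reference,
and `k_{g,s}` the raw count. `R` defaults to the arithmetic mean of the
`E_s`, which keeps normalized values on the raw-count scale; since `R`
multiplies every sample equally, between-sample ratios — the quantities of
interest — do not depend on it. A sample with zero spike-in reads is an
error, not a silent drop. Spike-in rows (class `spikein`, or the `ERCC-`
gene-id prefix as a fallback) are excluded from every downstream gene-level
analysis.

The package's validation shows why the anchor matters: on simulated uniform
shutdowns with true post/pre ratio r ∈ {0.3, 0.5, 0.8} at 5×10⁶ reads per
sample, spike-anchored class totals recover r to within ±0.03, while a naive
total-count estimate sits at 1.0 regardless of r.

## One-tail Poisson differential expression

Replicates are summed per condition after normalization (sums of Poisson
variables stay Poisson, so the exact test remains coherent); unequal
replicate counts are rebalanced by `n_pre/n_post`. For each gene the pooled
pre-IR value `a` is treated as a fixed rate and the pooled post-IR value `b`
(rounded half-even) is scored in the tail matching the observed direction:

    p = P(X ≥ round(b))   if b > a,   X ~ Poisson(max(a, 0.5))
    p = P(X ≤ round(b))   if b < a;   p = 1 if b = a

Tails are exact (regularized incomplete gamma), never normal
approximations. Benjamini–Hochberg adjustment runs over tested genes
(pooled `a+b ≥ min_pooled`, default 10 — too few reads to support a
1.5-fold call below that). A gene is differentially expressed when
`q < 0.05` and `max(FC, 1/FC) > 1.5`, with
`FC = (b + 0.5)/(a + 0.5)`; the pseudocount (0.5) guards zeros and also
floors the Poisson rate. The two-sided application of the fold-change gate
means one rule produces both the up and the down calls.

**Calibration caveat (important).** Treating `a` as a *fixed* rate ignores
its own sampling noise; with equal replicate numbers the nominal z-score is
inflated by about √2. For genes whose pooled counts lie roughly between 30
and 600, a null 1.5-fold fluctuation can reach a nominal p small enough to
survive BH, so the DEG list carries a small excess of false calls
concentrated at moderate counts: on a 5,000-gene null at 5×10⁶ reads with a
log-normal (sd = 1) expression spread, the pipeline calls ~10–25 false DEGs
per run. The effect vanishes when counts are large (≳10⁷ reads, or a narrow
expression spread) and shrinks with more pooled replicates. The test suite
measures and documents both the raw-p inflation and the null DEG count
rather than pretending the test is calibrated; users who need strict FDR
control at moderate depth should treat marginal calls (q near the
threshold, pooled counts < ~600) with caution.

On spiked data the rule is powerful: 300 genes at FC 2 and 200 at FC 0.5
among 5,000 are recovered with sensitivity ≈ 0.99 and false-discovery
proportion ≈ 0.02–0.05.

Row z-scores (for heatmaps) use the sample standard deviation (n−1);
constant rows are dropped with a warning. RPKM divides spike-normalized
counts by transcript length in kb; the length is taken as given in the
annotation (the package does not reconstruct transcripts from exons).

## Expression strata and gene length

Genes are ranked by mean normalized expression over all samples (or by
pre-IR RPKM), descending, with ties broken by gene id so top-k sets are
reproducible. Length comparisons between activated / repressed /
non-changed classes use the two-sided Mann–Whitney U test — chosen for
distribution-freeness since gene lengths are heavy-tailed — exact when both
groups have ≤ 12 members and no ties, normal approximation with continuity
correction otherwise; pairs with a class of fewer than 3 genes are reported
as not computable. Per-stratum summaries report the mean log2 fold change
and its one-sample t statistic against zero.

## Metagene profiles and the depletion index

Each gene body is rescaled to 100 bins (fractional-base weighting at bin
boundaries, so mass is conserved for any gene length), flanked by 3 kb of
fixed 50-bp windows on each side; minus-strand genes are reversed so bin 0
is always 5'. Genes shorter than 500 bp, or on chromosomes absent from the
coverage, are excluded with a warning. Averaging across genes is
*unweighted* so deeply covered genes do not dominate the profile shape, and
the per-sample spike scale factor multiplies the profile so pre/post are on
a common absolute scale.

The depletion index compares where along the body the post-IR signal was
lost:

    r5 = mean(post_b / pre_b) over the 5' half of body bins
    r3 = same over the 3' half
    I  = log2(r5 / r3)

The central 10% of body bins is excluded to avoid boundary/ramp effects.
`|I| < 0.3` is "initiation-like" (the whole body dropped uniformly —
transcription failed to start), `I ≥ 0.3` is "elongation-like (3' loss)"
(polymerases cleared the 5' end but did not reach the 3' end), `I ≤ −0.3`
flags the unusual converse. The index is invariant to any common scaling
of both profiles. Flanks are not used by the index: flanking signal mixes
neighbouring transcription units and divergent transcription.

## CRISPR screen scoring

Guides are counted by exact sequence match (no mismatches), either anchored
at a fixed read offset or by scanning every position with per-length k-mer
indexes; a read matching more than one distinct guide is counted as
ambiguous and discarded, and matched + unmatched + ambiguous equals reads
seen, exactly. Normalized abundance, fold change and CRISPR score follow
the screen's defining formulas:

    n = r / T × 10⁶ + 1,    FC = n_high / n_unsorted,    score = log2(FC)

The enrichment test uses *raw* counts (the +1-normalized values are
non-integral): an upper-tail Poisson of the EU-high count against the
depth-matched expectation `λ = max(r_unsorted · T_high/T_unsorted, 0.5)`,
with BH adjustment across all guides. A gene is a hit when at least one of
its guides has `q ≤ 0.01` and `FC ≥ 1.5`; because a single-guide rule is
lenient, a stricter `robust` flag (≥ 2 passing guides) is reported
alongside. The unsorted bin plays the role of "initial" abundance and the
EU-high bin "final".

The same fixed-rate caveat as in the DE test applies: at the reduced
simulation scale (2,000 genes × 5 guides, 2×10⁶ reads per bin, 20 hit
genes with 3 of 5 guides enriched 4-fold) sensitivity is ~1.0 and precision
~0.75–0.85 under the one-guide rule; the robust flag removes essentially
all false hits at a small sensitivity cost.

## Synthetic data: what it emulates, and what it does not

`simulate_nascent_counts` draws a gene × sample matrix whose expected count
is `depth · jitter_s · a_g · m_g(condition)`. The structure mirrors the
biology the analysis must cope with: three rDNA meta-genes carrying 70% of
non-spike reads before IR (18S/28S/5.8S stand-ins; the true share is
configurable since nascent pools are rDNA-dominated to a degree that varies
by protocol), a small histone class drawn ~e² above the protein-coding
log-normal baseline (histones are among the most highly transcribed genes),
92 spike-in species whose true abundance is identical in every sample, and
a per-sample depth jitter (uniform 0.7–1.3) that makes spike anchoring
non-trivial. IR acts multiplicatively: rDNA and histones ×0.3, 30% of
protein-coding genes ×2 (drawn from the middle of the expression
distribution) and 10% ×0.5 (the most expressed genes) — more genes up than
down, with repression concentrated at the top, the qualitative structure of
the transcriptional response this pipeline targets. Noise is Poisson by
default (matching the downstream test); a gamma-Poisson (negative binomial)
mode exists to stress-test calibration. One seed per call; sub-streams are
spawned deterministically, so identical configs give bit-identical tables.

The generator does **not** emulate: mapping ambiguity of real rDNA repeats
(handled upstream by rDNA-first alignment in practice), read-level
artifacts (adapters, duplicates), cell-cycle structure of the nascent
signal, or correlated biological replicate variation beyond the chosen
noise law. Passing recovery tests therefore demonstrate that the
*computation* is correct under its stated model, not that the model captures
every property of real libraries — in particular the Poisson assumption is
optimistic for biological replicates, which is exactly the regime the
calibration caveat above quantifies.

`simulate_coverage` writes flat-body per-base coverage (bedGraph-backed)
for a pre/post pair with the post profile depleted uniformly (initiation
mode) or over the 3' half with a linear ramp across the middle 10%
(elongation mode), with independent multiplicative log-normal noise per
50-bp bin. `simulate_screen` draws log-normal guide abundances and
multinomial sequencing of both bins, enriching the chosen hit guides by a
known factor in the EU-high bin; `screen_reads` can expand any count vector
into synthetic FASTQ to exercise the counting path end to end.

## Numerical and design choices

- Exact Poisson tails via `scipy.stats.poisson.sf/cdf` (incomplete gamma);
  verified against direct pmf summation to 1e-12 for λ ≤ 100, k ≤ 400.
- Benjamini–Hochberg implemented as the step-up `min_{j≥i} p_(j)·m/j`,
  clipped to 1, order-preserving; cross-checked against statsmodels.
- Observed pooled values are rounded half-even before the exact test.
- Ranking ties break lexically by gene id; all tables round-trip through
  TSV with `#` provenance headers; intervals are 0-based half-open
  throughout.
- Genes present in counts but missing from the annotation default to class
  `protein_coding` with a warning and are excluded from length-based
  analyses.
- Simulation sizes in the test-suite and in `scripts/acceptance.py` (5,000
  genes for DE properties, 200 genes for metagene sets, 2,000 × 5 guides
  for the screen) were chosen as the smallest scales at which the measured
  properties are stable from seed to seed.

## Limitations

- The DE and screen tests inherit the fixed-rate Poisson construction,
  with the anti-conservatism at moderate counts quantified above.
- Normalization assumes spike-in totals are unbiased per sample; no
  dose-response regression over the ERCC concentration ladder is
  performed.
- Coverage interchange is bedGraph only (no BAM/bigwig); guide matching is
  exact-only, with no mismatch tolerance.
- Transcript length is a single per-gene number supplied by the
  annotation; isoform structure is ignored.
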