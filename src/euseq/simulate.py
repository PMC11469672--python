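"""Synthetic data with known ground truth for every pipeline stage.

Three generators mirror the statistical structure the analysis assumes:

``simulate_nascent_counts``
    A nascent-transcript (EU-labelled) count matrix.  The read pool is
    dominated by ribosomal RNA (three rDNA meta-genes standing in for
    18S/28S/5.8S), contains a highly expressed histone class, a log-normal
    protein-coding background, and 92 spike-in species whose true abundance
    is identical in every sample (equal cell numbers, equal spike mass).
    Irradiation acts as per-gene multiplicative effects: strong repression
    of rDNA and histones, up-regulation of a fraction of moderately
    expressed protein-coding genes.  Per-sample sequencing depth is jittered
    so that spike-in anchoring is non-trivial.

``simulate_coverage``
    Per-base gene-body coverage for a pre/post pair, with the post profile
    depleted either uniformly ("initiation" mode: transcription fails to
    start, the whole body drops) or only over the 3' half ("elongation"
    mode: polymerases clear the 5' end but do not reach the 3' end).

``simulate_screen``
    A pooled CRISPR screen: log-normal baseline guide abundances, multinomial
    sequencing of an unsorted bin and an EU-high bin in which the guides of
    hit genes are enriched by a known factor.

Each generator takes one seed; sub-streams are spawned deterministically, so
identical configuration implies bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneAnnotation, GuideLibrary
from .errors import ParameterError
from .io import BedGraphCoverage
from .screen import ScreenCounts

__all__ = [
    "NascentSimConfig",
    "NascentTruth",
    "simulate_nascent_counts",
    "CoverageSim",
    "simulate_coverage",
    "ScreenSimConfig",
    "ScreenTruth",
    "simulate_screen",
    "screen_reads",
]

#: Approximate mature rRNA lengths (bp) for the three rDNA meta-genes.
_RDNA_LENGTHS = {"rDNA_18S": 1870, "rDNA_28S": 4730, "rDNA_5.8S": 157}


@dataclass
class NascentSimConfig:
    """Generative parameters for the nascent count matrix.

    Defaults describe the study conditions: ~70% of non-spike reads from
    rDNA before irradiation, strong repression of rDNA and histones after,
    more genes up than down among protein-coding genes, two replicates per
    condition at 5e6 reads.
    """

    n_genes: int = 2000
    n_histone: int = 60
    rdna_units: int = 3
    rdna_read_fraction: float = 0.7
    n_spikeins: int = 92
    spike_read_fraction: float = 0.05
    depth_per_sample: float = 5e6
    n_reps: int = 2
    effect_rdna: float = 0.3
    effect_histone: float = 0.3
    frac_up: float = 0.30
    frac_down: float = 0.10
    fc_up: float = 2.0
    fc_down: float = 0.5
    expr_logmean: float = 3.0
    expr_logsd: float = 1.0
    length_range_bp: tuple = (500, 100_000)
    noise: str = "poisson"
    nb_dispersion: float = 0.05
    #: assign down-effects to the most expressed protein-coding genes and
    #: up-effects to the middle of the expression distribution (the observed
    #: structure of the response); False assigns both at random
    stratified_effects: bool = True
    #: log-mean shift making histones among the most highly transcribed genes
    histone_logmean_shift: float = 2.0
    #: per-sample depth multiplier range (set to (1, 1) for equal depths)
    depth_jitter: tuple = (0.7, 1.3)
    seed: int = 0

    def validate(self) -> None:
        for name in ("rdna_read_fraction", "spike_read_fraction", "frac_up", "frac_down"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_up + self.frac_down > 1:
            raise ParameterError("frac_up + frac_down must be <= 1")
        if self.depth_per_sample <= 0:
            raise ParameterError("depth_per_sample must be > 0")
        for name in ("effect_rdna", "effect_histone", "fc_up", "fc_down"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.noise not in ("poisson", "nb"):
            raise ParameterError(f"noise must be 'poisson' or 'nb', got {self.noise!r}")
        if min(self.n_genes, self.rdna_units, self.n_spikeins, self.n_reps) < 1:
            raise ParameterError("n_genes, rdna_units, n_spikeins, n_reps must be >= 1")


@dataclass
class NascentTruth:
    """Ground truth for a simulated nascent count matrix."""

    table: pd.DataFrame  # index gene_id; columns: class, length_bp, baseline, multiplier
    global_ratio: float  # abundance-weighted mean multiplier over non-spike genes
    depth_multipliers: pd.Series  # per-sample depth jitter

    def __post_init__(self) -> None:
        w = self.table.loc[self.table["class"] != "spikein"]
        expect = float(np.average(w["multiplier"], weights=w["baseline"]))
        if not math.isclose(expect, self.global_ratio, rel_tol=1e-12, abs_tol=1e-12):
            raise ParameterError("global ratio inconsistent with per-gene truth")


def _gene_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def simulate_nascent_counts(config: NascentSimConfig) -> tuple[CountMatrix, NascentTruth]:
    """Draw a raw count matrix plus its ground truth.

    Expected count for gene g in sample s is
    ``depth_per_sample * jitter_s * a_g * m_g(condition_s)`` where the
    baseline abundances a_g sum to one over all genes (spike-ins included)
    before irradiation, and m_g = 1 for every gene pre-IR and for spike-ins
    always.  Counts are Poisson (default) or gamma-Poisson (negative
    binomial) around that expectation.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_depth, rng_noise = (np.random.default_rng(c) for c in ss.spawn(3))

    # --- gene table -------------------------------------------------------
    rdna_ids = list(_RDNA_LENGTHS)[: config.rdna_units]
    rdna_ids += _gene_ids("rDNA_extra", max(0, config.rdna_units - len(_RDNA_LENGTHS)))
    hist_ids = _gene_ids("hist", config.n_histone)
    pc_ids = _gene_ids("gene", config.n_genes)
    spike_ids = [f"ERCC-{i:05d}" for i in range(1, config.n_spikeins + 1)]
    classes = (
        ["rDNA"] * len(rdna_ids)
        + ["histone"] * len(hist_ids)
        + ["protein_coding"] * len(pc_ids)
        + ["spikein"] * len(spike_ids)
    )
    lo, hi = config.length_range_bp
    lengths = np.concatenate(
        [
            [_RDNA_LENGTHS.get(g, 5000) for g in rdna_ids],
            rng_struct.integers(lo, hi + 1, size=len(hist_ids)),
            rng_struct.integers(lo, hi + 1, size=len(pc_ids)),
            rng_struct.integers(250, 2001, size=len(spike_ids)),
        ]
    )

    # --- baseline abundances ---------------------------------------------
    pc_base = rng_struct.lognormal(config.expr_logmean, config.expr_logsd, size=len(pc_ids))
    hist_base = rng_struct.lognormal(
        config.expr_logmean + config.histone_logmean_shift,
        config.expr_logsd / 2,
        size=len(hist_ids),
    )
    other_total = pc_base.sum() + hist_base.sum()
    f = config.rdna_read_fraction
    rdna_total = f / (1 - f) * other_total if f < 1 else other_total * 1e6
    rdna_base = np.full(len(rdna_ids), rdna_total / len(rdna_ids))
    nonspike_total = other_total + rdna_base.sum()
    s = config.spike_read_fraction
    spike_rel = rng_struct.lognormal(0.0, 1.0, size=len(spike_ids))
    spike_base = spike_rel / spike_rel.sum() * (s / (1 - s) * nonspike_total if s < 1 else 0)
    baseline = np.concatenate([rdna_base, hist_base, pc_base, spike_base])
    baseline = baseline / baseline.sum()  # pre-IR expected share of one read

    # --- irradiation effects ---------------------------------------------
    mult = np.ones(baseline.size)
    mult[: len(rdna_ids)] = config.effect_rdna
    mult[len(rdna_ids) : len(rdna_ids) + len(hist_ids)] = config.effect_histone
    n_down = int(round(config.frac_down * len(pc_ids)))
    n_up = int(round(config.frac_up * len(pc_ids)))
    pc_slice = slice(len(rdna_ids) + len(hist_ids), len(rdna_ids) + len(hist_ids) + len(pc_ids))
    pc_mult = np.ones(len(pc_ids))
    if config.stratified_effects:
        order = np.argsort(-pc_base, kind="mergesort")  # descending expression
        down_idx = order[:n_down]
        remaining = order[n_down:]
        start = max(0, (len(remaining) - n_up) // 2)
        up_idx = remaining[start : start + n_up]
    else:
        pick = rng_struct.choice(len(pc_ids), size=n_down + n_up, replace=False)
        down_idx, up_idx = pick[:n_down], pick[n_down:]
    pc_mult[down_idx] = config.fc_down
    pc_mult[up_idx] = config.fc_up
    mult[pc_slice] = pc_mult

    gene_ids = rdna_ids + hist_ids + pc_ids + spike_ids
    truth_tbl = pd.DataFrame(
        {
            "class": classes,
            "length_bp": lengths.astype(np.int64),
            "baseline": baseline,
            "multiplier": mult,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    nonspike = truth_tbl["class"] != "spikein"
    global_ratio = float(
        np.average(truth_tbl.loc[nonspike, "multiplier"], weights=truth_tbl.loc[nonspike, "baseline"])
    )

    # --- samples ----------------------------------------------------------
    sample_ids, conditions, reps = [], [], []
    for cond in ("pre_IR", "post_IR"):
        for r in range(1, config.n_reps + 1):
            sample_ids.append(f"{cond}_rep{r}")
            conditions.append(cond)
            reps.append(r)
    jit_lo, jit_hi = config.depth_jitter
    jitter = rng_depth.uniform(jit_lo, jit_hi, size=len(sample_ids))
    design = pd.DataFrame(
        {"condition": conditions, "replicate": reps},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    counts = np.empty((len(gene_ids), len(sample_ids)), dtype=np.int64)
    for j, cond in enumerate(conditions):
        # spike-ins keep m = 1 by construction (their multiplier is 1)
        m = mult if cond == "post_IR" else np.ones_like(mult)
        lam = config.depth_per_sample * jitter[j] * baseline * m
        if config.noise == "poisson":
            counts[:, j] = rng_noise.poisson(lam)
        else:
            shape = 1.0 / config.nb_dispersion
            lam_g = rng_noise.gamma(shape, lam / shape)
            counts[:, j] = rng_noise.poisson(lam_g)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=truth_tbl.index, columns=sample_ids),
        gene_meta=truth_tbl[["class", "length_bp"]].copy(),
        design=design,
    )
    truth = NascentTruth(
        table=truth_tbl,
        global_ratio=global_ratio,
        depth_multipliers=pd.Series(jitter, index=sample_ids),
    )
    return cm, truth


def nascent_annotation(truth: NascentTruth) -> GeneAnnotation:
    """Annotation table derived from simulation truth (no genomic intervals)."""
    tbl = truth.table[["class", "length_bp"]].copy()
    for col in ("chrom", "start", "end", "strand"):
        tbl[col] = np.nan
    return GeneAnnotation(tbl)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageSim:
    """Pre/post coverage pair with the gene models and truth labels."""

    pre: BedGraphCoverage
    post: BedGraphCoverage
    genes: pd.DataFrame  # BED6-style: chrom, start, end, name, score, strand
    mode: str
    depletion: float


def simulate_coverage(
    n_genes: int,
    mode: str,
    depletion: float,
    bin_noise_sd: float,
    seed: int,
    gene_length_range: tuple = (2000, 6000),
    mean_depth: float = 20.0,
    depth_logsd: float = 0.5,
    bin_bp: int = 50,
    gap_bp: int = 7000,
) -> CoverageSim:
    """Simulate flat gene-body coverage depleted after irradiation.

    Pre-IR, each gene has a flat expected depth (log-normal across genes).
    Post-IR the expected depth is multiplied by ``1 - depletion`` — over the
    whole body in ``"initiation"`` mode, or only over the 3' half (with a
    linear ramp across the middle 10% of the body) in ``"elongation"`` mode.
    Multiplicative log-normal noise with sd ``bin_noise_sd`` is applied
    independently per 50-bp bin and condition.  Genes alternate strands and
    are separated by ``gap_bp`` of zero coverage.
    """
    if not 0 < depletion < 1:
        raise ParameterError(f"depletion must lie in (0, 1), got {depletion}")
    if mode not in ("initiation", "elongation"):
        raise ParameterError(f"mode must be 'initiation' or 'elongation', got {mode!r}")
    if bin_noise_sd < 0:
        raise ParameterError("bin_noise_sd must be >= 0")
    ss = np.random.SeedSequence(seed)
    rng_struct, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))

    lo, hi = gene_length_range
    lengths = rng_struct.integers(lo, hi + 1, size=n_genes)
    depths = rng_struct.lognormal(np.log(mean_depth), depth_logsd, size=n_genes)
    rows_pre, rows_post, bed = [], [], []
    pos = gap_bp
    chrom = "chrSim"
    for i in range(n_genes):
        L = int(lengths[i])
        strand = "+" if i % 2 == 0 else "-"
        start, end = pos, pos + L
        bed.append((chrom, start, end, f"cg{i + 1:05d}", 0, strand))
        edges = np.arange(start, end, bin_bp)
        edges = np.append(edges, end)
        mids = (edges[:-1] + edges[1:]) / 2.0
        frac = (mids - start) / L  # 5'->3' fraction for + strand
        if strand == "-":
            frac = 1.0 - frac
        if mode == "initiation":
            factor = np.full(frac.size, 1.0 - depletion)
        else:
            factor = np.interp(frac, [0.45, 0.55], [1.0, 1.0 - depletion])
        n_bins = frac.size
        noise_pre = (
            rng_noise.lognormal(0.0, bin_noise_sd, n_bins) if bin_noise_sd > 0 else np.ones(n_bins)
        )
        noise_post = (
            rng_noise.lognormal(0.0, bin_noise_sd, n_bins) if bin_noise_sd > 0 else np.ones(n_bins)
        )
        pre_vals = depths[i] * noise_pre
        post_vals = depths[i] * factor * noise_post
        for k in range(n_bins):
            rows_pre.append((chrom, int(edges[k]), int(edges[k + 1]), pre_vals[k]))
            rows_post.append((chrom, int(edges[k]), int(edges[k + 1]), post_vals[k]))
        pos = end + gap_bp
    cols = ["chrom", "start", "end", "value"]
    return CoverageSim(
        pre=BedGraphCoverage(pd.DataFrame(rows_pre, columns=cols)),
        post=BedGraphCoverage(pd.DataFrame(rows_post, columns=cols)),
        genes=pd.DataFrame(bed, columns=["chrom", "start", "end", "name", "score", "strand"]),
        mode=mode,
        depletion=depletion,
    )


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Generative parameters for the pooled screen (reduced-scale analogue of
    a genome-wide library of ~90k guides over ~18k genes)."""

    n_genes: int = 2000
    guides_per_gene: int = 5
    n_hits: int = 20
    guides_enriched_per_hit: int = 3
    enrichment_factor: float = 4.0
    depth_unsorted: int = 2_000_000
    depth_high: int = 2_000_000
    abundance_logsd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.guides_enriched_per_hit > self.guides_per_gene:
            raise ParameterError("guides_enriched_per_hit must be <= guides_per_gene")
        if self.enrichment_factor <= 1:
            raise ParameterError("enrichment_factor must be > 1")
        if min(self.depth_unsorted, self.depth_high) <= 0:
            raise ParameterError("depths must be > 0")
        if self.n_hits > self.n_genes:
            raise ParameterError("n_hits must be <= n_genes")


@dataclass
class ScreenTruth:
    """Ground truth for a simulated screen."""

    hit_genes: list
    guide_enrichment: pd.Series  # guide_id -> true enrichment factor
    library: GuideLibrary
    baseline: pd.Series  # guide_id -> relative abundance

    def __post_init__(self) -> None:
        if len(set(self.hit_genes)) != len(self.hit_genes):
            raise ParameterError("duplicate hit genes in truth")


def _random_guide_sequences(n: int, rng, length: int = 20) -> list[str]:
    seqs: set[str] = set()
    alphabet = np.array(list("ACGT"))
    while len(seqs) < n:
        block = rng.integers(0, 4, size=(n - len(seqs) + 8, length))
        for row in block:
            seqs.add("".join(alphabet[row]))
            if len(seqs) == n:
                break
    out = sorted(seqs)
    rng.shuffle(out)
    return out


def simulate_screen(config: ScreenSimConfig) -> tuple[ScreenCounts, ScreenTruth]:
    """Draw guide counts for the unsorted and EU-high bins plus ground truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_count = (np.random.default_rng(c) for c in ss.spawn(2))

    genes = _gene_ids("sg", config.n_genes)
    records = []
    for g in genes:
        for k in range(1, config.guides_per_gene + 1):
            records.append((g, f"{g}_g{k}"))
    n_guides = len(records)
    seqs = _random_guide_sequences(n_guides, rng_struct)
    lib = GuideLibrary(
        pd.DataFrame(records, columns=["gene_id", "guide_id"]).assign(sequence=seqs)
    )

    baseline = rng_struct.lognormal(0.0, config.abundance_logsd, size=n_guides)
    baseline = baseline / baseline.sum()
    hit_genes = sorted(rng_struct.choice(genes, size=config.n_hits, replace=False))
    enrich = np.ones(n_guides)
    gene_arr = lib.table["gene_id"].to_numpy()
    for g in hit_genes:
        idx = np.flatnonzero(gene_arr == g)
        chosen = rng_struct.choice(idx, size=config.guides_enriched_per_hit, replace=False)
        enrich[chosen] = config.enrichment_factor

    p_unsorted = baseline
    p_high = baseline * enrich
    p_high = p_high / p_high.sum()
    r_u = rng_count.multinomial(int(config.depth_unsorted), p_unsorted)
    r_h = rng_count.multinomial(int(config.depth_high), p_high)

    table = lib.table.copy()
    table["count_unsorted"] = r_u
    table["count_high"] = r_h
    diag = pd.DataFrame(
        {
            "bin": ["unsorted", "high"],
            "n_reads_seen": [int(r_u.sum()), int(r_h.sum())],
            "n_matched": [int(r_u.sum()), int(r_h.sum())],
            "n_unmatched": [0, 0],
            "n_ambiguous": [0, 0],
        }
    )
    counts = ScreenCounts(table=table, diagnostics=diag)
    guide_index = pd.Index(lib.table["guide_id"], name="guide_id")
    truth = ScreenTruth(
        hit_genes=list(hit_genes),
        guide_enrichment=pd.Series(enrich, index=guide_index),
        library=lib,
        baseline=pd.Series(baseline, index=guide_index),
    )
    return counts, truth


def screen_reads(per_guide_counts: pd.Series, lib: GuideLibrary, seed: int = 0,
                 read_length: int = 50, guide_offset: int = 10):
    """Expand per-guide counts into synthetic sequencing reads.

    Each read embeds the guide's exact sequence at ``guide_offset`` inside
    random flanking sequence; useful for exercising the FASTQ counting path.
    Yields (read_id, sequence, qualities) tuples.
    """
    rng = np.random.default_rng(seed)
    alphabet = "ACGT"
    seq_of = dict(zip(lib.table["guide_id"], lib.table["sequence"]))
    i = 0
    for gid, n in per_guide_counts.items():
        guide = seq_of[gid]
        for _ in range(int(n)):
            i += 1
            left = "".join(rng.choice(list(alphabet), size=guide_offset))
            right_len = max(0, read_length - guide_offset - len(guide))
            right = "".join(rng.choice(list(alphabet), size=right_len))
            seq = left + guide + right
            yield f"read{i}", seq, "I" * len(seq)
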