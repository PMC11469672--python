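"""End-to-end workflows: nascent-transcript DE and the CRISPR screen.

Each workflow reads (or simulates) its inputs, runs the stages in order,
writes every stage's table under ``out_dir``, and finishes with a JSON run
manifest recording inputs, parameters, seed, package version, per-stage
summary counts, and a sha256 checksum of every written file — a manifest
plus the inputs fully determines the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as eio
from .containers import GeneAnnotation
from .diffexpr import PoissonDETester
from .errors import EuseqError, AnalysisError
from .metagene import ProfileLayout, average_profile, initiation_elongation_index
from .normalization import ErccNormalizer, class_totals
from .screen import GuideEnrichmentScorer, combine_bins, count_guides, read_screen_counts, write_screen_counts
from .simulate import (
    NascentSimConfig,
    ScreenSimConfig,
    nascent_annotation,
    simulate_nascent_counts,
    simulate_screen,
)
from .strata import decile_log2fc, fc_vs_expression, length_by_class, rank_genes, top_k_strata

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_nascent_workflow", "run_screen_workflow"]


@dataclass
class RunConfig:
    """Workflow configuration; round-trips through YAML unchanged."""

    workflow: str = "nascent"
    out_dir: str = "euseq_out"
    seed: int = 0
    simulate: bool = False
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def stage_params(self, stage: str) -> dict:
        return dict(self.params.get(stage, {}))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    """Context attaching the stage name to any error raised inside it."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, Exception):
            raise AnalysisError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def _finish_manifest(config: RunConfig, out: Path, outputs: list[Path], stats: dict) -> Path:
    from . import __version__

    manifest = {
        "workflow": config.workflow,
        "version": __version__,
        "seed": config.seed,
        "inputs": config.inputs,
        "params": config.params,
        "simulate": config.simulate,
        "stats": stats,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def run_nascent_workflow(config: RunConfig) -> dict:
    """normalize -> DE -> strata (-> metagene when coverage is supplied)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stats: dict = {}

    with _Stage("input"):
        if config.simulate:
            sim_params = config.stage_params("sim")
            sim_params.setdefault("seed", config.seed)
            cm, truth = simulate_nascent_counts(NascentSimConfig(**sim_params))
            ann = nascent_annotation(truth)
            eio.write_count_table(cm, out / "counts.tsv", params={"seed": config.seed})
            eio.write_design(cm.design, out / "design.tsv")
            eio.write_tsv(truth.table, out / "truth.tsv",
                          params={"global_ratio": repr(truth.global_ratio)})
            outputs += [out / "counts.tsv", out / "design.tsv", out / "truth.tsv"]
            stats["true_global_ratio"] = truth.global_ratio
        else:
            if "counts" not in config.inputs or "design" not in config.inputs:
                raise EuseqError("inputs 'counts' and 'design' are required (or set simulate)")
            cm = eio.read_count_table(config.inputs["counts"], config.inputs["design"])
            if "annotation" in config.inputs:
                ann = eio.read_gene_models(
                    bed_path=config.inputs.get("genes_bed"),
                    table_path=config.inputs["annotation"],
                ).align_to(cm)
            else:
                ann = GeneAnnotation(cm.gene_meta.copy())
            truth = None

    with _Stage("normalize"):
        normalizer = ErccNormalizer(**config.stage_params("normalize")).fit(cm)
        norm = normalizer.transform(cm)
        eio.write_normalized_matrix(norm, out / "normalized.tsv")
        eio.write_scale_factors(normalizer.scale_factors_, out / "scale_factors.tsv")
        totals = class_totals(norm, ann)
        eio.write_tsv(totals, out / "class_totals.tsv")
        outputs += [out / "normalized.tsv", out / "scale_factors.tsv", out / "class_totals.tsv"]
        if "post_pre_ratio" in totals.columns:
            stats["estimated_global_ratio"] = float(totals.loc["total_non_spike", "post_pre_ratio"])

    with _Stage("de"):
        tester = PoissonDETester(**config.stage_params("de")).fit(norm)
        res = tester.results_
        eio.write_tsv(res.rename_axis("gene_id"), out / "de_results.tsv")
        outputs.append(out / "de_results.tsv")
        stats["n_tested"] = int(res["tested"].sum())
        stats["n_up"] = tester.n_up_
        stats["n_down"] = tester.n_down_

    with _Stage("strata"):
        sp = config.stage_params("strata")
        ranking = rank_genes(res, basis=sp.get("basis", "mean_all_samples"), norm=norm, ann=ann)
        eio.write_tsv(ranking.to_frame(), out / "ranking.tsv")
        eio.write_tsv(fc_vs_expression(res).rename_axis("gene_id"), out / "fc_vs_expression.tsv")
        eio.write_tsv(decile_log2fc(res, ranking).set_index("stratum"), out / "strata_log2fc.tsv")
        outputs += [out / "ranking.tsv", out / "fc_vs_expression.tsv", out / "strata_log2fc.tsv"]
        n_degs = int(res["deg"].sum())
        k = min(int(sp.get("k", 100)), n_degs)
        if k > 0:
            top = top_k_strata(res, ranking, norm, k=k)
            eio.write_tsv(top["zscores"].rename_axis("gene_id"), out / "topk_zscores.tsv")
            outputs.append(out / "topk_zscores.tsv")
        if ann.table["length_bp"].notna().any() and n_degs:
            lengths = length_by_class(res, ann, restrict=sp.get("restrict", "all_degs"),
                                      ranking=ranking)
            eio.write_tsv(lengths["summary"], out / "length_by_class.tsv", index=False)
            eio.write_tsv(lengths["pairwise"], out / "length_pairwise.tsv", index=False)
            outputs += [out / "length_by_class.tsv", out / "length_pairwise.tsv"]
        stats["n_degs"] = n_degs

    if {"coverage_pre", "coverage_post", "genes_bed"} <= set(config.inputs):
        with _Stage("metagene"):
            mp = config.stage_params("metagene")
            layout = ProfileLayout(**{k: v for k, v in mp.items() if k != "flat_threshold"})
            cov_pre = eio.read_bedgraph(config.inputs["coverage_pre"])
            cov_post = eio.read_bedgraph(config.inputs["coverage_post"])
            genes = eio.read_bed(config.inputs["genes_bed"])
            prof_pre = average_profile(cov_pre, genes, layout, condition="pre_IR")
            prof_post = average_profile(cov_post, genes, layout, condition="post_IR")
            idx, label = initiation_elongation_index(
                prof_pre, prof_post, flat_threshold=mp.get("flat_threshold", 0.3)
            )
            prof = prof_pre.to_frame().rename(columns={"mean_depth": "pre_IR"})
            prof["post_IR"] = prof_post.values
            eio.write_tsv(prof.set_index("bin"), out / "metagene_profile.tsv")
            outputs.append(out / "metagene_profile.tsv")
            stats["metagene_index"] = idx
            stats["metagene_class"] = label

    manifest = _finish_manifest(config, out, outputs, stats)
    return {"out_dir": out, "manifest": manifest, "stats": stats}


def run_screen_workflow(config: RunConfig) -> dict:
    """count -> normalize -> guide stats -> gene hit calls."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stats: dict = {}
    truth = None

    with _Stage("count"):
        if config.simulate:
            sim_params = config.stage_params("sim")
            sim_params.setdefault("seed", config.seed)
            counts, truth = simulate_screen(ScreenSimConfig(**sim_params))
            eio.write_guide_library(truth.library, out / "library.tsv")
            eio.write_tsv(
                pd.DataFrame({"hit_gene": truth.hit_genes}), out / "truth_hits.tsv", index=False
            )
            outputs += [out / "library.tsv", out / "truth_hits.tsv"]
        elif "screen_counts" in config.inputs:
            counts = read_screen_counts(config.inputs["screen_counts"])
        else:
            if "library" not in config.inputs:
                raise EuseqError("screen workflow needs a guide library with FASTQ inputs")
            if not {"fastq_unsorted", "fastq_high"} <= set(config.inputs):
                raise EuseqError("screen workflow needs fastq_unsorted and fastq_high inputs")
            lib = eio.read_guide_library(config.inputs["library"])
            cp = config.stage_params("count")
            bins = {}
            for bin_name in ("unsorted", "high"):
                reads = eio.iterate_fastq(config.inputs[f"fastq_{bin_name}"])
                bins[bin_name] = count_guides(
                    reads, lib, offset=cp.get("offset"), search=cp.get("search", "anchored")
                )
            counts = combine_bins(lib, bins["unsorted"], bins["high"])
        write_screen_counts(counts, out / "screen_counts.tsv", params={"seed": config.seed})
        outputs.append(out / "screen_counts.tsv")
        if counts.diagnostics is not None:
            eio.write_tsv(counts.diagnostics, out / "count_diagnostics.tsv", index=False)
            outputs.append(out / "count_diagnostics.tsv")

    with _Stage("score"):
        scorer = GuideEnrichmentScorer(**config.stage_params("score")).fit(counts)
        eio.write_tsv(scorer.guide_stats_, out / "guide_stats.tsv", index=False)
        eio.write_tsv(scorer.gene_hits_.rename_axis("gene_id"), out / "gene_hits.tsv")
        outputs += [out / "guide_stats.tsv", out / "gene_hits.tsv"]
        stats["n_guides"] = len(scorer.guide_stats_)
        stats["n_hit_genes"] = len(scorer.hit_genes_)

    if truth is not None:
        called = set(scorer.hit_genes_)
        true = set(truth.hit_genes)
        tp = len(called & true)
        stats["sensitivity"] = tp / len(true) if true else float("nan")
        stats["precision"] = tp / len(called) if called else float("nan")

    manifest = _finish_manifest(config, out, outputs, stats)
    return {"out_dir": out, "manifest": manifest, "stats": stats}
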