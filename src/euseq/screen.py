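"""Pooled CRISPR screen scoring: guide counting, normalization, per-guide
Poisson enrichment tests, CRISPR scores, and gene-level hit calls.

The screen compares guide abundances between an unsorted cell population
("initial") and the sorted EU-high bin — the 10% of cells retaining the most
nascent-RNA signal after irradiation ("final").  A gene whose guides are
enriched in the EU-high bin is implicated in transcriptional inhibition.

Per-guide quantities:

* normalized abundance  ``n = r / T * 1e6 + 1``  (reads per million, plus one)
* fold change           ``FC = n_high / n_unsorted``
* CRISPR score          ``log2(FC)``
* enrichment p-value    upper-tail Poisson of the raw EU-high count against a
  depth-matched expectation ``lam = max(r_unsorted * T_high / T_unsorted, 0.5)``
  (raw counts are used for the test because the +1-normalized values are
  non-integral; the floor avoids a zero rate for unobserved guides)

A gene is a hit when at least one of its guides has BH-adjusted p <= 0.01
and FC >= 1.5; a stricter "robust" flag requires two such guides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import GuideLibrary
from .errors import AnalysisError, FormatError, ParameterError
from .stats import bh_adjust, poisson_tail_p

__all__ = [
    "BinCounts",
    "ScreenCounts",
    "count_guides",
    "combine_bins",
    "normalize_guides",
    "guide_stats",
    "call_hit_genes",
    "GuideEnrichmentScorer",
]


@dataclass
class BinCounts:
    """Per-guide read counts for one sequencing bin, with counter diagnostics."""

    counts: pd.Series  # index guide_id
    n_reads_seen: int = 0
    n_unmatched: int = 0
    n_ambiguous: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def conserved(self) -> bool:
        """matched + unmatched + ambiguous == reads seen, exactly."""
        return self.total + self.n_unmatched + self.n_ambiguous == self.n_reads_seen


@dataclass
class ScreenCounts:
    """Guide counts for both bins plus bin totals and diagnostics."""

    table: pd.DataFrame  # columns: gene_id, guide_id, count_unsorted, count_high
    diagnostics: pd.DataFrame = field(default=None)  # per-bin counters

    def __post_init__(self) -> None:
        req = {"gene_id", "guide_id", "count_unsorted", "count_high"}
        missing = req - set(self.table.columns)
        if missing:
            raise FormatError(f"screen counts missing columns {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def total_unsorted(self) -> int:
        return int(self.table["count_unsorted"].sum())

    @property
    def total_high(self) -> int:
        return int(self.table["count_high"].sum())


def count_guides(reads, lib: GuideLibrary, offset: int | None = None,
                 search: str = "anchored") -> BinCounts:
    """Count exact guide-sequence occurrences in a read stream (one bin).

    Parameters
    ----------
    reads
        Iterable of (read_id, sequence, qualities) tuples, e.g. from
        :func:`euseq.io.iterate_fastq`.
    lib
        Validated guide library (unique sequences).
    offset
        In ``"anchored"`` mode, the fixed 0-based position of the guide in
        each read (default 0).  Ignored in ``"scan"`` mode.
    search
        ``"anchored"`` matches only at ``offset``; ``"scan"`` searches every
        position via a k-mer index keyed on guide length.

    Notes
    -----
    Matching is exact — no mismatches.  A read matching more than one
    distinct library guide is counted as ambiguous and discarded.
    """
    if len(lib) == 0:
        raise AnalysisError("empty guide library")
    if search not in ("anchored", "scan"):
        raise ParameterError(f"search must be 'anchored' or 'scan', got {search!r}")
    if offset is None:
        offset = 0
    # one index per guide length; libraries may mix 19-21 nt guides
    by_len: dict[int, dict[str, str]] = {}
    for seq, gid in zip(lib.table["sequence"], lib.table["guide_id"]):
        by_len.setdefault(len(seq), {})[seq] = gid
    counts = pd.Series(0, index=pd.Index(lib.table["guide_id"], name="guide_id"), dtype=np.int64)
    seen = unmatched = ambiguous = 0
    for _rid, seq, _qual in reads:
        seen += 1
        hits: set[str] = set()
        if search == "anchored":
            for L, index in by_len.items():
                window = seq[offset : offset + L]
                if len(window) == L and window in index:
                    hits.add(index[window])
        else:
            for L, index in by_len.items():
                for i in range(len(seq) - L + 1):
                    gid = index.get(seq[i : i + L])
                    if gid is not None:
                        hits.add(gid)
        if len(hits) == 1:
            counts[hits.pop()] += 1
        elif len(hits) > 1:
            ambiguous += 1
        else:
            unmatched += 1
    return BinCounts(counts=counts, n_reads_seen=seen,
                     n_unmatched=unmatched, n_ambiguous=ambiguous)


def combine_bins(lib: GuideLibrary, unsorted: BinCounts, high: BinCounts) -> ScreenCounts:
    """Assemble per-bin guide counts into a :class:`ScreenCounts` table."""
    tbl = lib.table[["gene_id", "guide_id"]].copy()
    tbl["count_unsorted"] = unsorted.counts.reindex(tbl["guide_id"]).to_numpy()
    tbl["count_high"] = high.counts.reindex(tbl["guide_id"]).to_numpy()
    diag = pd.DataFrame(
        {
            "bin": ["unsorted", "high"],
            "n_reads_seen": [unsorted.n_reads_seen, high.n_reads_seen],
            "n_matched": [unsorted.total, high.total],
            "n_unmatched": [unsorted.n_unmatched, high.n_unmatched],
            "n_ambiguous": [unsorted.n_ambiguous, high.n_ambiguous],
        }
    )
    return ScreenCounts(table=tbl, diagnostics=diag)


def normalize_guides(counts: ScreenCounts) -> pd.DataFrame:
    """Normalized abundance per guide and bin: ``n = r / T * 1e6 + 1``."""
    T_u, T_h = counts.total_unsorted, counts.total_high
    if T_u == 0 or T_h == 0:
        raise AnalysisError("a bin has zero total guide reads; cannot normalize")
    out = counts.table[["gene_id", "guide_id"]].copy()
    out["norm_unsorted"] = counts.table["count_unsorted"] / T_u * 1e6 + 1.0
    out["norm_high"] = counts.table["count_high"] / T_h * 1e6 + 1.0
    return out


def guide_stats(counts: ScreenCounts, lambda_floor: float = 0.5) -> pd.DataFrame:
    """Per-guide fold change, CRISPR score, enrichment p and BH q.

    FC and score come from the +1-normalized abundances exactly as defined;
    the Poisson enrichment test uses raw counts with a depth-matched rate.
    """
    norm = normalize_guides(counts)
    T_u, T_h = counts.total_unsorted, counts.total_high
    out = norm.copy()
    out["count_unsorted"] = counts.table["count_unsorted"].to_numpy()
    out["count_high"] = counts.table["count_high"].to_numpy()
    out["fc"] = out["norm_high"] / out["norm_unsorted"]
    out["crispr_score"] = np.log2(out["fc"])
    lam = np.maximum(out["count_unsorted"].to_numpy(float) * (T_h / T_u), lambda_floor)
    out["p"] = poisson_tail_p(out["count_high"].to_numpy(np.int64), lam, tail="upper")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def call_hit_genes(stats: pd.DataFrame, q_thresh: float = 0.01,
                   fc_thresh: float = 1.5) -> pd.DataFrame:
    """Gene-level hit table from per-guide statistics.

    A guide "passes" when q <= ``q_thresh`` and FC >= ``fc_thresh``; a gene
    is a hit with >= 1 passing guide and "robust" with >= 2.  Sorted by best
    q then mean CRISPR score (descending).
    """
    if len(stats) == 0:
        raise AnalysisError("no guide statistics to aggregate")
    passing = (stats["q"] <= q_thresh) & (stats["fc"] >= fc_thresh)
    grp = stats.assign(passing=passing).groupby("gene_id", sort=False)
    out = grp.agg(
        n_guides=("guide_id", "size"),
        n_passing=("passing", "sum"),
        best_q=("q", "min"),
        mean_score=("crispr_score", "mean"),
    )
    out["hit"] = out["n_passing"] >= 1
    out["robust"] = out["n_passing"] >= 2
    return out.sort_values(["best_q", "mean_score"], ascending=[True, False])


class GuideEnrichmentScorer(BaseEstimator):
    """Estimator wrapping the screen scoring stage.

    ``fit(counts)`` computes per-guide statistics and gene-level hit calls
    from a :class:`ScreenCounts`; results land in ``guide_stats_`` and
    ``gene_hits_``.

    Parameters
    ----------
    q_thresh, fc_thresh
        Hit rule: >= 1 guide with adjusted p <= q_thresh and FC >= fc_thresh.
    lambda_floor
        Lower bound on the depth-matched Poisson rate (guards zero counts).
    """

    def __init__(self, q_thresh: float = 0.01, fc_thresh: float = 1.5,
                 lambda_floor: float = 0.5):
        self.q_thresh = q_thresh
        self.fc_thresh = fc_thresh
        self.lambda_floor = lambda_floor

    def fit(self, counts: ScreenCounts, y=None):
        if self.fc_thresh <= 0 or not 0 < self.q_thresh <= 1:
            raise ParameterError("need fc_thresh > 0 and q_thresh in (0, 1]")
        self.guide_stats_ = guide_stats(counts, lambda_floor=self.lambda_floor)
        self.gene_hits_ = call_hit_genes(
            self.guide_stats_, q_thresh=self.q_thresh, fc_thresh=self.fc_thresh
        )
        self.hit_genes_ = list(self.gene_hits_.index[self.gene_hits_["hit"]])
        return self


def write_screen_counts(counts: ScreenCounts, path, params: dict | None = None) -> None:
    from .io import write_tsv

    write_tsv(counts.table, path, params=params, index=False)


def read_screen_counts(path) -> ScreenCounts:
    from .io import read_tsv

    df = read_tsv(path, dtype={"gene_id": str, "guide_id": str})
    return ScreenCounts(table=df)
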