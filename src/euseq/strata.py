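"""Expression-stratified summaries of the differential-expression result.

After irradiation the most highly transcribed genes (histones, rDNA) are
preferentially repressed while moderately expressed genes tend to be
induced.  These helpers make that structure visible: ranking genes by
expression, extracting the top-k most expressed DEGs for heatmaps,
comparing gene lengths between activated/repressed classes, and tabulating
fold change against mean expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GeneAnnotation, NormalizedMatrix
from .diffexpr import rpkm, zscore_rows
from .errors import AnalysisError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "rank_genes",
    "top_k_strata",
    "length_by_class",
    "fc_vs_expression",
    "decile_log2fc",
]


def rank_genes(de: pd.DataFrame, basis: str = "mean_all_samples",
               norm: NormalizedMatrix | None = None,
               ann: GeneAnnotation | None = None,
               pre_label: str = "pre_IR") -> pd.Series:
    """Descending expression ranks (1 = highest) over tested genes.

    ``basis="mean_all_samples"`` ranks by mean normalized expression over
    all samples; ``basis="control_rpkm"`` ranks by length-normalized
    expression in the pre-irradiation condition (requires ``norm`` and
    ``ann``).  Ties break by gene_id lexical order so rankings are
    deterministic.
    """
    tested = de.index[de["tested"]]
    if len(tested) == 0:
        raise AnalysisError("no tested genes to rank")
    if basis == "mean_all_samples":
        vals = de.loc[tested, "mean_expr"]
    elif basis == "control_rpkm":
        if norm is None or ann is None:
            raise ParameterError("control_rpkm ranking needs the normalized matrix and annotation")
        vals = rpkm(norm, ann, per_sample=False, pre_label=pre_label)[pre_label].reindex(tested)
        vals = vals.dropna()
    else:
        raise ParameterError(f"unknown ranking basis {basis!r}")
    order = sorted(vals.index, key=lambda g: (-vals[g], g))
    return pd.Series(np.arange(1, len(order) + 1), index=pd.Index(order, name="gene_id"),
                     name="rank")


def top_k_strata(de: pd.DataFrame, ranking: pd.Series, norm: NormalizedMatrix,
                 k: int = 100) -> dict:
    """The k highest-expression DEGs with their per-sample z-scores.

    Returns a dict with ``genes`` (ordered by rank), ``zscores`` (heatmap
    input), and ``directions``.
    """
    degs = de.index[de["deg"]]
    ranked_degs = ranking.reindex(degs).dropna().sort_values()
    if k > len(ranked_degs):
        raise AnalysisError(
            f"k={k} exceeds the {len(ranked_degs)} available DEGs; choose a smaller k"
        )
    top = list(ranked_degs.index[:k])
    z = zscore_rows(norm, genes=top) if top else pd.DataFrame(columns=norm.values.columns)
    return {
        "genes": top,
        "zscores": z,
        "directions": de.loc[top, "direction"] if top else pd.Series(dtype=object),
    }


def _mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p; exact null at small n without ties."""
    ties = len(np.union1d(x, y)) < len(x) + len(y)
    method = "exact" if (len(x) <= 12 and len(y) <= 12 and not ties) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def length_by_class(de: pd.DataFrame, ann: GeneAnnotation,
                    restrict: str = "all_degs", ranking: pd.Series | None = None,
                    top_n: int = 100) -> dict:
    """Gene-length summaries per DE class with pairwise rank-sum comparisons.

    Classes: ``activated`` (up DEGs), ``repressed`` (down DEGs),
    ``non_changed`` (tested non-DEGs).  ``restrict="top100"`` limits scope
    to the ``top_n`` highest-ranked tested genes (requires ``ranking``).
    Pairs where either class has fewer than 3 members are reported as not
    computable.
    """
    scope = de[de["tested"]]
    if restrict == "top100":
        if ranking is None:
            raise ParameterError("restrict='top100' needs a ranking")
        top = ranking.sort_values().index[:top_n]
        scope = scope.loc[scope.index.intersection(top)]
    elif restrict != "all_degs":
        raise ParameterError(f"unknown restrict mode {restrict!r}")

    lengths = ann.lengths(scope.index)
    scope = scope.loc[lengths.notna()]
    lengths = lengths.dropna()
    members = {
        "activated": scope.index[scope["deg"] & (scope["direction"] == "up")],
        "repressed": scope.index[scope["deg"] & (scope["direction"] == "down")],
        "non_changed": scope.index[~scope["deg"]],
    }
    summary = []
    for name, idx in members.items():
        vals = lengths.reindex(idx).dropna().to_numpy(float)
        summary.append(
            {
                "de_class": name,
                "n": len(vals),
                "median_bp": float(np.median(vals)) if len(vals) else np.nan,
                "iqr_bp": float(np.subtract(*np.percentile(vals, [75, 25]))) if len(vals) else np.nan,
            }
        )
    pairs = []
    names = list(members)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x = lengths.reindex(members[names[i]]).dropna().to_numpy(float)
            y = lengths.reindex(members[names[j]]).dropna().to_numpy(float)
            if len(x) < 3 or len(y) < 3:
                pairs.append({"class_a": names[i], "class_b": names[j],
                              "p": np.nan, "computable": False})
            else:
                pairs.append({"class_a": names[i], "class_b": names[j],
                              "p": _mwu_p(x, y), "computable": True})
    return {"summary": pd.DataFrame(summary), "pairwise": pd.DataFrame(pairs)}


def fc_vs_expression(de: pd.DataFrame) -> pd.DataFrame:
    """Per tested gene: log2 mean expression, log2 fold change, DEG flag,
    class — the MA-style view in which the highly expressed repressed genes
    (histones among them) stand out."""
    scope = de[de["tested"]]
    out = pd.DataFrame(
        {
            "log2_mean_expr": np.log2(scope["mean_expr"].clip(lower=np.nextafter(0, 1))),
            "log2_fc": np.log2(scope["fc"]),
            "deg": scope["deg"],
            "direction": scope["direction"],
            "class": scope["class"] if "class" in scope.columns else "protein_coding",
        },
        index=scope.index,
    )
    out["histone_callout"] = out["class"] == "histone"
    return out


def decile_log2fc(de: pd.DataFrame, ranking: pd.Series | None = None,
                  n_strata: int = 10) -> pd.DataFrame:
    """Mean log2 fold change per expression stratum (1 = most expressed).

    For each stratum reports n, mean log2FC, and the one-sample t statistic
    of log2FC against zero — the summary behind "highly expressed genes go
    down, moderately expressed genes go up".
    """
    if ranking is None:
        ranking = rank_genes(de)
    ranked = ranking.sort_values()
    strata_idx = np.array_split(np.arange(len(ranked)), n_strata)
    rows = []
    lfc = np.log2(de["fc"])
    for i, idx in enumerate(strata_idx, start=1):
        genes = ranked.index[idx]
        x = lfc.reindex(genes).dropna().to_numpy(float)
        t = sps.ttest_1samp(x, 0.0).statistic if len(x) > 2 else np.nan
        rows.append({"stratum": i, "n": len(x), "mean_log2fc": float(np.mean(x)),
                     "t_vs_zero": float(t)})
    return pd.DataFrame(rows)
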