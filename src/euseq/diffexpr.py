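"""One-tail Poisson differential expression on spike-normalized nascent counts.

Replicates are pooled (summed) per condition — sums of Poisson counts stay
Poisson, so the exact one-tail test remains coherent.  For each gene the
pooled pre-irradiation value ``a`` is treated as a fixed rate and the pooled
post-irradiation value ``b`` (rounded half-even to an integer) is scored
against Poisson(a) in the tail matching the observed direction.  A gene is
called differentially expressed when the Benjamini-Hochberg q-value is below
``fdr_thresh`` and the fold change exceeds ``fc_thresh`` in either direction
(``max(FC, 1/FC) > fc_thresh``).

The fixed-rate construction ignores the sampling noise of ``a`` and is
therefore anti-conservative for small rates when taken as a calibrated
p-value; combined with the fold-change gate and FDR adjustment the DEG call
is conservative in practice (see the test suite's calibration checks).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import GeneAnnotation, NormalizedMatrix
from .errors import AnalysisError, AnnotationError, DesignError, ParameterError
from .stats import bh_adjust, poisson_tail_p, round_half_even

logger = logging.getLogger(__name__)

__all__ = [
    "pool_condition",
    "call_degs",
    "PoissonDETester",
    "zscore_rows",
    "rpkm",
]


def pool_condition(norm: NormalizedMatrix, pre_label: str = "pre_IR",
                   post_label: str = "post_IR") -> pd.DataFrame:
    """Sum normalized values over replicates per condition.

    Returns a DataFrame with columns ``a`` (pooled pre) and ``b`` (pooled
    post).  With unequal replicate counts the post pool is rescaled by
    n_pre / n_post so the two pools stay comparable.
    """
    pre = norm.samples_for(pre_label)
    post = norm.samples_for(post_label)
    if not pre or not post:
        missing = pre_label if not pre else post_label
        raise DesignError(f"condition {missing!r} has no samples")
    a = norm.values[pre].sum(axis=1)
    b = norm.values[post].sum(axis=1)
    if len(pre) != len(post):
        scale = len(pre) / len(post)
        logger.info(
            "unequal replicate counts (%d pre vs %d post); rescaling post pool by %.4g",
            len(pre), len(post), scale,
        )
        b = b * scale
    return pd.DataFrame({"a": a, "b": b})


def call_degs(pooled: pd.DataFrame, min_pooled: float = 10.0, fc_thresh: float = 1.5,
              fdr_thresh: float = 0.05, pseudocount: float = 0.5,
              mean_expr: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene fold change, one-tail Poisson p, BH q, and DEG calls.

    Parameters
    ----------
    pooled
        DataFrame with pooled condition values ``a`` (pre) and ``b`` (post).
    min_pooled
        Genes with a + b below this are not tested (too few reads to call a
        1.5-fold change); they appear with ``tested=False``.
    fc_thresh, fdr_thresh
        DEG rule: max(FC, 1/FC) > fc_thresh and q < fdr_thresh.
    pseudocount
        Added to both pools for the fold change, and floors the Poisson rate.
    mean_expr
        Optional per-gene mean expression carried into the result.
    """
    if fc_thresh <= 0 or pseudocount < 0 or not 0 < fdr_thresh <= 1:
        raise ParameterError("invalid DEG thresholds")
    a = pooled["a"].to_numpy(float)
    b = pooled["b"].to_numpy(float)
    tested = (a + b) >= min_pooled
    if not tested.any():
        raise AnalysisError("no genes pass the min_pooled testing filter")
    fc = (b + pseudocount) / (a + pseudocount)
    direction = np.where(b > a, "up", np.where(b < a, "down", "none"))

    p = np.ones(a.size)
    k = round_half_even(b)
    lam = np.maximum(a, pseudocount)
    up = tested & (b > a)
    down = tested & (b < a)
    if up.any():
        p[up] = poisson_tail_p(k[up], lam[up], tail="upper")
    if down.any():
        p[down] = poisson_tail_p(k[down], lam[down], tail="lower")

    q = np.full(a.size, np.nan)
    q[tested] = bh_adjust(p[tested])
    deg = tested & (q < fdr_thresh) & (np.maximum(fc, 1.0 / fc) > fc_thresh)

    out = pd.DataFrame(
        {
            "a": a,
            "b": b,
            "fc": fc,
            "direction": direction,
            "p": np.where(tested, p, np.nan),
            "q": q,
            "deg": deg,
            "tested": tested,
        },
        index=pooled.index,
    )
    out["mean_expr"] = mean_expr.reindex(out.index) if mean_expr is not None else (a + b) / 2.0
    return out


class PoissonDETester(BaseEstimator):
    """Estimator running the pooled one-tail Poisson DE test on a
    :class:`~euseq.containers.NormalizedMatrix`.

    Parameters mirror :func:`call_degs`; spike-in rows are excluded before
    testing.  After ``fit`` the per-gene table is in ``results_`` and the
    up/down DEG counts in ``n_up_`` / ``n_down_``.
    """

    def __init__(self, min_pooled: float = 10.0, fc_thresh: float = 1.5,
                 fdr_thresh: float = 0.05, pseudocount: float = 0.5,
                 pre_label: str = "pre_IR", post_label: str = "post_IR"):
        self.min_pooled = min_pooled
        self.fc_thresh = fc_thresh
        self.fdr_thresh = fdr_thresh
        self.pseudocount = pseudocount
        self.pre_label = pre_label
        self.post_label = post_label

    def fit(self, X: NormalizedMatrix, y=None):
        values = X.nonspike()
        sub = NormalizedMatrix(
            values=values,
            gene_meta=X.gene_meta.loc[values.index],
            design=X.design,
            scale_factors=X.scale_factors,
        )
        pooled = pool_condition(sub, self.pre_label, self.post_label)
        mean_expr = values.mean(axis=1)
        res = call_degs(
            pooled,
            min_pooled=self.min_pooled,
            fc_thresh=self.fc_thresh,
            fdr_thresh=self.fdr_thresh,
            pseudocount=self.pseudocount,
            mean_expr=mean_expr,
        )
        res.insert(0, "class", X.gene_meta.loc[res.index, "class"])
        self.results_ = res
        deg = res[res["deg"]]
        self.n_up_ = int((deg["direction"] == "up").sum())
        self.n_down_ = int((deg["direction"] == "down").sum())
        logger.info("DEG calls: %d up, %d down of %d tested",
                    self.n_up_, self.n_down_, int(res["tested"].sum()))
        return self


def zscore_rows(values, genes=None) -> pd.DataFrame:
    """Row-wise expression z-scores across samples.

    z_{g,s} = (v_{g,s} - mean_s) / sd_s with the sample standard deviation
    (n - 1 denominator).  Rows with zero sd are dropped with a warning.
    """
    if isinstance(values, NormalizedMatrix):
        values = values.values
    if genes is not None:
        values = values.loc[[g for g in genes if g in values.index]]
    if values.shape[1] < 2:
        raise AnalysisError("z-scores need at least 2 samples")
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("dropping %d constant rows from z-score matrix", int((~keep).sum()))
    v = values.loc[keep]
    return v.sub(mu[keep], axis=0).div(sd[keep], axis=0)


def rpkm(norm: NormalizedMatrix, ann: GeneAnnotation, per_sample: bool = True,
         pre_label: str = "pre_IR", post_label: str = "post_IR") -> pd.DataFrame:
    """Reads per kilobase: spike-normalized values divided by gene length/1000.

    With ``per_sample=False`` the values are condition means.  Genes whose
    annotated length is missing are dropped with a warning; a non-positive
    length raises :class:`AnnotationError`.
    """
    values = norm.nonspike()
    lengths = ann.lengths(values.index)
    if (lengths.dropna() <= 0).any():
        bad = lengths[lengths <= 0].index[0]
        raise AnnotationError(f"gene {bad!r} has non-positive length")
    keep = lengths.notna()
    if (~keep).any():
        logger.warning("dropping %d genes without annotated length from RPKM", int((~keep).sum()))
    values = values.loc[keep]
    kb = lengths[keep] / 1000.0
    if not per_sample:
        cond = {
            pre_label: values[ [s for s in values.columns if s in norm.samples_for(pre_label)] ].mean(axis=1),
            post_label: values[ [s for s in values.columns if s in norm.samples_for(post_label)] ].mean(axis=1),
        }
        values = pd.DataFrame(cond)
    return values.div(kb, axis=0)
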