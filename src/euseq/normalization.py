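"""ERCC spike-in anchored normalization.

When a perturbation changes *total* transcription (here, a global shutdown
after irradiation), per-sample library-size normalization erases exactly the
signal of interest: dividing by total reads forces every sample to the same
scale.  Because the same mass of ERCC spike-in RNA is added per fixed number
of cells, the spike-in reads instead provide an absolute anchor: each
sample's counts are rescaled so its total spike-in reads equal a common
reference, and genuine global shifts survive.

Scale factors: f_s = R / E_s, where E_s is sample s's total spike-in reads
and R is the reference (mean of the E_s by default; the choice of R only
sets the overall scale, never the between-sample ratios).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CountMatrix, GeneAnnotation, NormalizedMatrix, ScaleFactors
from .errors import DesignError, NormalizationError, ParameterError

logger = logging.getLogger(__name__)

__all__ = ["ErccNormalizer", "ercc_scale_factors", "normalize", "class_totals"]


class ErccNormalizer(BaseEstimator, TransformerMixin):
    """Transformer computing and applying ERCC spike-in scale factors.

    Parameters
    ----------
    reference_mode
        ``"mean"`` (default) sets the reference R to the arithmetic mean of
        the per-sample spike totals, keeping normalized values on the raw
        count scale; ``"first_sample"`` uses the first sample's total.

    Attributes
    ----------
    scale_factors_ : ScaleFactors
        Per-sample spike totals E_s and factors f_s = R / E_s.
    """

    def __init__(self, reference_mode: str = "mean"):
        self.reference_mode = reference_mode

    def fit(self, X: CountMatrix, y=None):
        if self.reference_mode not in ("mean", "first_sample"):
            raise ParameterError(
                f"reference_mode must be 'mean' or 'first_sample', got {self.reference_mode!r}"
            )
        spike = X.counts.loc[X.spikein_mask]
        totals = spike.sum(axis=0).astype(float)
        zero = totals.index[totals <= 0]
        if len(zero):
            raise NormalizationError(
                f"sample {zero[0]!r} has zero spike-in reads; cannot anchor normalization"
            )
        ref = float(totals.mean()) if self.reference_mode == "mean" else float(totals.iloc[0])
        self.scale_factors_ = ScaleFactors(ercc_totals=totals, reference=ref)
        self.samples_ = list(X.sample_ids)
        return self

    def transform(self, X: CountMatrix) -> NormalizedMatrix:
        sf = self.scale_factors_
        if list(X.sample_ids) != self.samples_:
            raise DesignError("count matrix samples do not match the fitted scale factors")
        values = X.counts.astype(float) * sf.factors
        return NormalizedMatrix(
            values=values,
            gene_meta=X.gene_meta.copy(),
            design=X.design.copy(),
            scale_factors=sf,
        )


def ercc_scale_factors(counts: CountMatrix, reference_mode: str = "mean") -> ScaleFactors:
    """Per-sample ERCC totals and factors f_s = R / E_s."""
    return ErccNormalizer(reference_mode=reference_mode).fit(counts).scale_factors_


def normalize(counts: CountMatrix, factors: ScaleFactors | None = None,
              reference_mode: str = "mean") -> NormalizedMatrix:
    """Apply spike-in scale factors: v_{g,s} = f_s * k_{g,s}."""
    est = ErccNormalizer(reference_mode=reference_mode)
    if factors is None:
        est.fit(counts)
    else:
        est.scale_factors_ = factors
        est.samples_ = list(factors.factors.index)
    return est.transform(counts)


def class_totals(norm: NormalizedMatrix, ann: GeneAnnotation | None = None,
                 pre_label: str = "pre_IR", post_label: str = "post_IR") -> pd.DataFrame:
    """Per-sample normalized totals for the headline gene classes.

    Rows: ``total_non_spike``, ``rDNA``, ``protein_coding``, ``histone``.
    Columns: one per sample, then per-condition means and the post/pre
    ratio of the condition means — the global-transcription readout.
    """
    classes = (
        ann.classes(norm.values.index) if ann is not None else norm.gene_meta["class"]
    )
    spike = norm.spikein_mask
    groups = {
        "total_non_spike": ~spike,
        "rDNA": (classes == "rDNA") & ~spike,
        "protein_coding": (classes == "protein_coding") & ~spike,
        "histone": (classes == "histone") & ~spike,
    }
    rows = {}
    for name, mask in groups.items():
        if not mask.any():
            logger.warning("class %s has no genes; total reported as 0", name)
        rows[name] = norm.values.loc[np.asarray(mask)].sum(axis=0)
    out = pd.DataFrame(rows).T
    pre_samples = norm.samples_for(pre_label)
    post_samples = norm.samples_for(post_label)
    if pre_samples and post_samples:
        out["mean_pre"] = out[pre_samples].mean(axis=1)
        out["mean_post"] = out[post_samples].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out["post_pre_ratio"] = out["mean_post"] / out["mean_pre"]
    out.index.name = "gene_class"
    return out
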