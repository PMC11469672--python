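"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`CountMatrix`: a gene x sample table of raw
read counts together with per-gene metadata (class, transcript length) and
a per-sample design (condition, replicate).  Spike-in (ERCC) rows live in
the same matrix and are identified by ``class == "spikein"`` or by the
``ERCC-`` gene-id prefix; they anchor cross-sample normalization and are
excluded from every gene-level analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

logger = logging.getLogger(__name__)

#: Fixed gene-class vocabulary.
GENE_CLASSES = ("rDNA", "histone", "protein_coding", "spikein")

#: Gene-id prefix that marks a spike-in row when the class column is absent/blank.
SPIKEIN_PREFIX = "ERCC-"


def _check_unique(values, what: str) -> None:
    dup = pd.Index(values)[pd.Index(values).duplicated()]
    if len(dup):
        raise FormatError(f"duplicate {what}: {sorted(set(dup))[:5]}")


@dataclass
class CountMatrix:
    """Raw gene x sample counts with gene metadata and sample design.

    Parameters
    ----------
    counts
        Integer counts, index = gene_id, columns = sample_id.
    gene_meta
        Indexed by gene_id with columns ``class`` (one of
        :data:`GENE_CLASSES`) and ``length_bp``.
    design
        Indexed by sample_id with columns ``condition`` and ``replicate``.
    """

    counts: pd.DataFrame
    gene_meta: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_unique(self.counts.index, "gene_ids")
        _check_unique(self.counts.columns, "sample_ids")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac = arr[arr != np.floor(arr)] if np.issubdtype(arr.dtype, np.floating) else None
            if frac is not None and len(frac):
                raise FormatError(f"non-integer count value {frac.flat[0]!r}")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {self.counts.index[g]!r}, sample {self.counts.columns[s]!r}"
            )
        if not self.gene_meta.index.equals(self.counts.index):
            self.gene_meta = self.gene_meta.reindex(self.counts.index)
        bad = set(self.gene_meta["class"].dropna()) - set(GENE_CLASSES)
        if bad:
            raise FormatError(f"unknown gene class(es): {sorted(bad)}")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise DesignError(f"samples without a condition mapping: {sorted(missing)}")
        self.design = self.design.loc[list(self.counts.columns)]
        if not self.spikein_mask.any():
            raise FormatError("no spike-in rows (class 'spikein' or gene_id prefix 'ERCC-') found")

    @property
    def spikein_mask(self) -> pd.Series:
        """Boolean per-gene mask; class column wins, ``ERCC-`` prefix is the fallback."""
        cls = self.gene_meta["class"]
        by_class = cls == "spikein"
        by_prefix = cls.isna() & self.counts.index.str.startswith(SPIKEIN_PREFIX)
        return by_class | by_prefix

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def samples_for(self, condition: str) -> list[str]:
        sel = self.design.index[self.design["condition"] == condition]
        return list(sel)

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.design["condition"]:
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class GeneAnnotation:
    """Per-gene class, transcript length and genomic interval (0-based half-open)."""

    table: pd.DataFrame  # index gene_id; columns: class, length_bp, chrom, start, end, strand

    REQUIRED = ("class", "length_bp", "chrom", "start", "end", "strand")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                self.table[col] = np.nan
        _check_unique(self.table.index, "annotation gene_ids")
        iv = self.table.dropna(subset=["start", "end"])
        bad = iv[iv["end"] <= iv["start"]]
        if len(bad):
            raise FormatError(f"interval with end <= start for gene {bad.index[0]!r}")
        strands = set(self.table["strand"].dropna()) - {"+", "-"}
        if strands:
            raise FormatError(f"invalid strand value(s): {sorted(strands)}")

    def lengths(self, gene_ids) -> pd.Series:
        return self.table["length_bp"].reindex(gene_ids)

    def classes(self, gene_ids) -> pd.Series:
        return self.table["class"].reindex(gene_ids)

    def align_to(self, counts: CountMatrix) -> "GeneAnnotation":
        """Reindex to the genes of a count matrix.

        Genes present in the counts but absent here are retained with class
        ``protein_coding`` and no length (they are later excluded from
        length-based analyses); a warning is logged.
        """
        missing = [g for g in counts.gene_ids if g not in self.table.index]
        tbl = self.table.reindex(counts.gene_ids)
        if missing:
            logger.warning(
                "%d genes in counts missing from annotation; defaulting class to protein_coding",
                len(missing),
            )
            tbl.loc[missing, "class"] = "protein_coding"
        return GeneAnnotation(tbl)


@dataclass
class GuideLibrary:
    """CRISPR guide library: (gene_id, guide_id, 19-21 nt ACGT sequence)."""

    table: pd.DataFrame  # columns: gene_id, guide_id, sequence

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t["guide_id"], "guide_ids")
        _check_unique(t["sequence"], "guide sequences")
        seqs = t["sequence"].astype(str)
        ok = seqs.str.fullmatch(r"[ACGT]{19,21}")
        if not ok.all():
            bad = t.loc[~ok, "guide_id"].iloc[0]
            raise FormatError(f"guide {bad!r} has an invalid sequence (need 19-21 nt uppercase ACGT)")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.table["gene_id"]))


@dataclass
class ScaleFactors:
    """Per-sample ERCC totals and multiplicative scale factors f_s = R / E_s."""

    ercc_totals: pd.Series  # E_s, indexed by sample
    reference: float  # R
    factors: pd.Series = field(default=None)  # f_s

    def __post_init__(self) -> None:
        if self.factors is None:
            self.factors = self.reference / self.ercc_totals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ercc_total": self.ercc_totals, "scale_factor": self.factors}
        ).rename_axis("sample_id")


@dataclass
class NormalizedMatrix:
    """ERCC-normalized values v_{g,s} = f_s * k_{g,s}; shares metadata with its source."""

    values: pd.DataFrame
    gene_meta: pd.DataFrame
    design: pd.DataFrame
    scale_factors: ScaleFactors

    @property
    def spikein_mask(self) -> pd.Series:
        cls = self.gene_meta["class"]
        return (cls == "spikein") | (
            cls.isna() & self.values.index.str.startswith(SPIKEIN_PREFIX)
        )

    def nonspike(self) -> pd.DataFrame:
        return self.values.loc[~self.spikein_mask]

    def samples_for(self, condition: str) -> list[str]:
        return list(self.design.index[self.design["condition"] == condition])
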