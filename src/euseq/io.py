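"""Readers and writers for the formats the pipeline touches.

Conventions
-----------
* All tables are TSV; writers prepend ``#``-prefixed comment lines carrying
  provenance (package version, parameters) which readers skip.
* All interval arithmetic is 0-based half-open; BED round-trips unchanged.
* Spike-in rows are identified by the ``class`` column when present,
  otherwise by the ``ERCC-`` gene-id prefix.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneAnnotation, GuideLibrary, NormalizedMatrix, ScaleFactors
from .errors import FormatError

logger = logging.getLogger(__name__)

_META_COLS = ("gene_id", "class", "length_bp")


def _provenance_lines(params: dict | None) -> list[str]:
    from . import __version__

    lines = [f"# euseq {__version__}"]
    for k, v in (params or {}).items():
        lines.append(f"# {k}={v}")
    return lines


def write_tsv(df: pd.DataFrame, path, params: dict | None = None, index: bool = True) -> None:
    """Write a TSV with ``#`` provenance comment lines before the header."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _provenance_lines(params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_design(path) -> pd.DataFrame:
    """Read a sample design TSV (columns: sample_id, condition, replicate)."""
    df = read_tsv(path)
    for col in ("sample_id", "condition"):
        if col not in df.columns:
            raise FormatError(f"design table missing required column {col!r}")
    if "replicate" not in df.columns:
        df["replicate"] = df.groupby("condition").cumcount() + 1
    return df.set_index("sample_id")


def read_count_table(path, design) -> CountMatrix:
    """Read a gene x sample count TSV into a validated :class:`CountMatrix`.

    The table carries gene metadata columns (``gene_id``, optionally
    ``class`` and ``length_bp``) followed by one column per sample.
    ``design`` is a design DataFrame or a path to a design TSV mapping
    sample -> condition.
    """
    if not isinstance(design, pd.DataFrame):
        design = read_design(design)
    df = read_tsv(path, dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing 'gene_id' column")
    sample_cols = [c for c in df.columns if c not in _META_COLS]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns found")
    counts = df[sample_cols].copy()
    for col in sample_cols:
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any():
            row = df.loc[vals.isna(), "gene_id"].iloc[0]
            raise FormatError(f"{path}: non-numeric count at gene {row!r}, sample {col!r}")
        if (vals != np.floor(vals)).any():
            bad = df.loc[vals != np.floor(vals)].iloc[0]
            raise FormatError(
                f"{path}: non-integer count {vals[vals != np.floor(vals)].iloc[0]!r} "
                f"at gene {bad['gene_id']!r}, sample {col!r}"
            )
        counts[col] = vals.astype(np.int64)
    counts.index = pd.Index(df["gene_id"], name="gene_id")
    meta = pd.DataFrame(index=counts.index)
    meta["class"] = pd.Series(
        df["class"].values if "class" in df.columns else np.nan,
        index=counts.index, dtype=object,
    )
    meta["class"] = meta["class"].replace("", np.nan)
    # prefix fallback: make the class explicit so downstream grouping is uniform
    fallback = meta["class"].isna() & counts.index.str.startswith("ERCC-")
    meta.loc[fallback, "class"] = "spikein"
    meta["length_bp"] = (
        pd.to_numeric(df["length_bp"], errors="coerce").values if "length_bp" in df.columns else np.nan
    )
    return CountMatrix(counts=counts, gene_meta=meta, design=design)


def write_count_table(cm: CountMatrix, path, params: dict | None = None) -> None:
    out = cm.gene_meta.copy()
    out = out[["class", "length_bp"]]
    out = pd.concat([out, cm.counts], axis=1)
    write_tsv(out.rename_axis("gene_id"), path, params=params)


def write_design(design: pd.DataFrame, path) -> None:
    write_tsv(design.rename_axis("sample_id"), path)


def write_normalized_matrix(nm: NormalizedMatrix, path, params: dict | None = None) -> None:
    out = nm.gene_meta[["class", "length_bp"]].copy()
    out = pd.concat([out, nm.values], axis=1)
    write_tsv(out.rename_axis("gene_id"), path, params=params)


def read_normalized_matrix(path, design, scale_factors: ScaleFactors | None = None) -> NormalizedMatrix:
    """Read a normalized-matrix TSV written by :func:`write_normalized_matrix`."""
    if not isinstance(design, pd.DataFrame):
        design = read_design(design)
    df = read_tsv(path, dtype={"gene_id": str}).set_index("gene_id")
    sample_cols = [c for c in df.columns if c not in ("class", "length_bp")]
    meta = df[["class", "length_bp"]].copy() if "class" in df.columns else pd.DataFrame(index=df.index)
    values = df[sample_cols].astype(float)
    return NormalizedMatrix(values=values, gene_meta=meta, design=design.loc[sample_cols],
                            scale_factors=scale_factors)


def write_scale_factors(sf: ScaleFactors, path) -> None:
    write_tsv(sf.to_frame(), path, params={"reference": repr(sf.reference)})


def read_scale_factors(path) -> ScaleFactors:
    df = read_tsv(path).set_index("sample_id")
    ref = float((df["ercc_total"] * df["scale_factor"]).iloc[0])
    return ScaleFactors(ercc_totals=df["ercc_total"], reference=ref, factors=df["scale_factor"])


# ---------------------------------------------------------------------------
# gene models (BED6 + tabular annotation)
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED6 file into a DataFrame (0-based half-open, unchanged)."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{i}: BED6 requires 6 columns (strand missing?)")
            chrom, start, end, name, score, strand = parts[:6]
            start, end = int(start), int(end)
            if end <= start:
                raise FormatError(f"{path}:{i}: interval end {end} <= start {start}")
            if strand not in "+-":
                raise FormatError(f"{path}:{i}: invalid strand {strand!r}")
            rows.append((chrom, start, end, name, score, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gene_models(bed_path=None, table_path=None) -> GeneAnnotation:
    """Merge BED6 intervals with a tabular annotation.

    For genes present in both sources the interval comes from the BED and
    class/length from the table.  Either source alone is accepted.
    """
    if bed_path is None and table_path is None:
        raise FormatError("read_gene_models needs a BED and/or a table path")
    frames = {}
    if bed_path is not None:
        bed = read_bed(bed_path).set_index("name")
        frames["bed"] = bed
    if table_path is not None:
        tbl = read_tsv(table_path, dtype={"gene_id": str}).set_index("gene_id")
        frames["table"] = tbl
    genes = pd.Index([])
    for f in frames.values():
        genes = genes.union(f.index, sort=False)
    out = pd.DataFrame(index=genes)
    out.index.name = "gene_id"
    if "table" in frames:
        tbl = frames["table"]
        for col in ("class", "length_bp", "chrom", "start", "end", "strand"):
            if col in tbl.columns:
                out[col] = tbl[col].reindex(genes)
    if "bed" in frames:
        bed = frames["bed"]
        for col in ("chrom", "start", "end", "strand"):
            if col not in out.columns:
                out[col] = pd.Series(index=out.index, dtype=object)
        # BED interval wins where present
        have = genes.intersection(bed.index)
        out.loc[have, ["chrom", "start", "end", "strand"]] = bed.loc[
            have, ["chrom", "start", "end", "strand"]
        ].values
    if "length_bp" not in out.columns:
        out["length_bp"] = np.nan
    # fall back to interval span when the table gives no length
    if {"start", "end"} <= set(out.columns):
        span = pd.to_numeric(out["end"], errors="coerce") - pd.to_numeric(out["start"], errors="coerce")
        out["length_bp"] = pd.to_numeric(out["length_bp"], errors="coerce").fillna(span)
    return GeneAnnotation(out)


def write_gene_annotation(ann: GeneAnnotation, path) -> None:
    write_tsv(ann.table.rename_axis("gene_id"), path)


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------

class BedGraphCoverage:
    """Queryable per-base depth backed by non-overlapping bedGraph intervals."""

    def __init__(self, intervals: pd.DataFrame):
        # intervals: chrom, start, end, value
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in intervals.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(np.int64)
            ends = grp["end"].to_numpy(np.int64)
            if (starts[1:] < ends[:-1]).any():
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise FormatError(
                    f"overlapping bedGraph intervals on {chrom}: "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            self._chroms[chrom] = (starts, ends, grp["value"].to_numpy(float))

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    def depth(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depth over [start, end); 0 where uncovered or chrom unknown."""
        n = end - start
        out = np.zeros(n, float)
        if chrom not in self._chroms or n <= 0:
            return out
        starts, ends, values = self._chroms[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            a, b = max(s, start), min(e, end)
            if b > a:
                out[a - start : b - start] = v
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, (starts, ends, values) in self._chroms.items():
            rows.append(
                pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": values})
            )
        return pd.concat(rows, ignore_index=True)


def read_bedgraph(path) -> BedGraphCoverage:
    """Read a 4-column bedGraph (0-based half-open, non-overlapping per chrom)."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{i}: bedGraph requires 4 columns")
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    return BedGraphCoverage(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))


def write_bedgraph(cov: BedGraphCoverage, path) -> None:
    cov.to_frame().to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def iterate_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, qualities) from a FASTQ or FASTQ.gz file.

    Sequences are uppercased.  Truncated or malformed records raise
    :class:`FormatError` with the record index.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            idx += 1
            if not qual:
                raise FormatError(f"{path}: truncated FASTQ record #{idx}")
            header, seq, plus, qual = (s.rstrip("\n") for s in (header, seq, plus, qual))
            if not header.startswith("@") or not plus.startswith("+"):
                raise FormatError(f"{path}: malformed FASTQ record #{idx}")
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}: record #{idx}: sequence length {len(seq)} != quality length {len(qual)}"
                )
            yield header[1:].split()[0], seq.upper(), qual


def write_fastq(records, path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# guide libraries and screen count tables
# ---------------------------------------------------------------------------

def read_guide_library(path) -> GuideLibrary:
    df = read_tsv(path, dtype=str)
    for col in ("gene_id", "guide_id", "sequence"):
        if col not in df.columns:
            raise FormatError(f"{path}: guide library missing column {col!r}")
    return GuideLibrary(df[["gene_id", "guide_id", "sequence"]])


def write_guide_library(lib: GuideLibrary, path) -> None:
    write_tsv(lib.table, path, index=False)
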