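"""Readers and writers for the on-disk formats the pipeline touches.

Interchange formats are plain text throughout:

* dense per-chromosome contact matrices, tab-delimited, with header
  row/column labelled ``chrom:start-end`` (the classic dense dump used for
  250 kb compartment analysis);
* bedGraph for compartment eigenvector tracks;
* BED6 for gene annotations;
* GMT for gene sets;
* TSV (genes x samples) for expression counts.

Numeric serialization is fixed at 6 significant digits so that write->read
round trips are bit-stable and testable.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContactMatrix, CompartmentTrack
from .errors import AlignmentError, FormatError, IntegrityError
from .genome import BinIndex, GeneAnnotation, GeneSetCollection

__all__ = [
    "read_dense_matrix",
    "write_dense_matrix",
    "read_bedgraph_track",
    "write_bedgraph_track",
    "read_bed_genes",
    "write_bed_genes",
    "read_gmt",
    "write_gmt",
    "read_expression_tsv",
    "write_expression_tsv",
]

_FMT = "{:.6g}"  # canonical 6-significant-digit serialization


def _fmt(x: float) -> str:
    return _FMT.format(float(x))


# ---------------------------------------------------------------------------
# dense contact matrices
# ---------------------------------------------------------------------------

def read_dense_matrix(path: str | Path, expected_bin_size: int | None = None) -> ContactMatrix:
    """Read a dense tab-delimited contact matrix with ``chrom:start-end`` headers.

    The body must be square, numeric and non-negative. Asymmetries up to a
    relative 1e-6 of the larger entry are averaged away; anything larger is
    an integrity error naming the worst cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(
            f"{path}: matrix body is {df.shape[0]}x{df.shape[1]}, not square"
        )
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column headers disagree")
    bins = [BinIndex.from_label(str(lbl), i) for i, lbl in enumerate(df.columns)]
    _validate_bin_grid(bins, expected_bin_size, str(path))
    try:
        counts = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix body") from exc
    if np.isnan(counts).any():
        raise FormatError(f"{path}: matrix body contains missing values")
    if (counts < 0).any():
        raise ValueError(f"{path}: matrix has negative entries")
    asym = np.abs(counts - counts.T)
    tol = 1e-6 * np.maximum(np.maximum(np.abs(counts), np.abs(counts.T)), 1e-12)
    if (asym > tol).any():
        i, j = np.unravel_index(np.argmax(asym - tol), asym.shape)
        raise IntegrityError(
            f"{path}: asymmetry at ({bins[i].label}, {bins[j].label}): "
            f"{counts[i, j]!r} vs {counts[j, i]!r}"
        )
    counts = (counts + counts.T) / 2.0
    return ContactMatrix(counts, bins)


def _validate_bin_grid(bins: list[BinIndex], bin_size: int | None, where: str) -> None:
    for prev, cur in zip(bins, bins[1:]):
        if cur.chromosome == prev.chromosome and cur.start != prev.end:
            raise FormatError(f"{where}: bins {prev.label} and {cur.label} are not contiguous")
    if bin_size is not None:
        for b in bins[:-1]:
            nxt = bins[b.ordinal + 1]
            if nxt.chromosome == b.chromosome and b.end - b.start != bin_size:
                raise FormatError(
                    f"{where}: bin {b.label} is not {bin_size} bp wide"
                )


def write_dense_matrix(matrix: ContactMatrix, path: str | Path) -> None:
    labels = [b.label for b in matrix.bins]
    with open(path, "w") as fh:
        fh.write("\t".join([""] + labels) + "\n")
        for lbl, row in zip(labels, matrix.counts):
            fh.write(lbl + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# bedGraph compartment tracks
# ---------------------------------------------------------------------------

def read_bedgraph_track(path: str | Path, bins: list[BinIndex]) -> CompartmentTrack:
    """Read a 4-column bedGraph whose intervals align exactly to ``bins``.

    Bins absent from the file become NaN; intervals that match no bin raise
    an alignment error, repeated intervals a format error.
    """
    index = {(b.chromosome, b.start, b.end): b.ordinal for b in bins}
    values = np.full(len(bins), np.nan)
    seen: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, start_s, end_s, val_s = fields
            try:
                key = (chrom, int(start_s), int(end_s))
                value = float(val_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable fields") from exc
            if key not in index:
                raise AlignmentError(
                    f"{path}:{lineno}: interval {chrom}:{key[1]}-{key[2]} matches no bin"
                )
            ordinal = index[key]
            if ordinal in seen:
                raise FormatError(f"{path}:{lineno}: bin {chrom}:{key[1]}-{key[2]} repeated")
            seen.add(ordinal)
            values[ordinal] = value
    return CompartmentTrack(values, list(bins))


def write_bedgraph_track(track: CompartmentTrack, path: str | Path) -> None:
    """Write defined bins as 4-column bedGraph (NaN bins are omitted)."""
    with open(path, "w") as fh:
        for b, v in zip(track.bins, track.values):
            if not math.isnan(v):
                fh.write(f"{b.chromosome}\t{b.start}\t{b.end}\t{_fmt(v)}\n")


# ---------------------------------------------------------------------------
# BED6 gene annotations
# ---------------------------------------------------------------------------

def read_bed_genes(path: str | Path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                genes.append(
                    GeneAnnotation(name, name, chrom, int(start_s), int(end_s), strand)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_bed_genes(genes: list[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file (set name, description, members)."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            try:
                collection.add(name, members)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = ".") -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description] + members) + "\n")


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV of expression counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty expression table")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicated gene identifier {dup!r}")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise FormatError(f"{path}: non-numeric expression values")
    return df


def write_expression_tsv(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", float_format="%.6g")
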