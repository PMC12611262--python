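"""Genomic coordinate primitives: bins, gene annotations, gene sets.

All coordinates are 0-based half-open in memory; dialect conversions (if a
format requires them) happen inside parsers and serializers only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

__all__ = [
    "BinIndex",
    "GeneAnnotation",
    "GeneSetCollection",
    "make_bins",
    "gene_density",
]


@dataclass(frozen=True)
class BinIndex:
    """One fixed-width genomic bin.

    ``end - start`` equals the configured bin size except possibly for the
    last bin of a chromosome; ordinals are consecutive within a chromosome.
    """

    chromosome: str
    start: int
    end: int
    ordinal: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid bin interval {self.chromosome}:{self.start}-{self.end}"
            )

    @property
    def label(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"

    @classmethod
    def from_label(cls, label: str, ordinal: int) -> "BinIndex":
        try:
            chrom, span = label.rsplit(":", 1)
            start_s, end_s = span.split("-", 1)
            return cls(chrom, int(start_s), int(end_s), ordinal)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"cannot parse bin header {label!r}") from exc


def make_bins(
    chromosome: str,
    n_bins: int,
    bin_size: int,
    chromosome_length: int | None = None,
    ordinal_offset: int = 0,
) -> list[BinIndex]:
    """Build a consecutive bin grid for one chromosome.

    If ``chromosome_length`` is given, the last bin is truncated to it.
    """
    if n_bins < 1 or bin_size < 1:
        raise ValueError("n_bins and bin_size must be positive")
    bins = []
    for i in range(n_bins):
        start = i * bin_size
        end = (i + 1) * bin_size
        if chromosome_length is not None:
            end = min(end, chromosome_length)
        bins.append(BinIndex(chromosome, start, end, ordinal_offset + i))
    return bins


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval in BED convention (0-based half-open)."""

    gene_id: str
    gene_name: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. epithelial / mesenchymal signatures).

    Sets are non-empty and contain no duplicate symbols; member order is
    preserved as read.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)

    def add(self, name: str, members: list[str]) -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene set name {name!r}")
        if not members:
            raise FormatError(f"gene set {name!r} is empty")
        seen = set()
        for m in members:
            if m in seen:
                raise FormatError(f"gene set {name!r}: duplicate member {m!r}")
            seen.add(m)
        self.sets[name] = list(members)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def overlaps(gene: GeneAnnotation, bin_: BinIndex) -> bool:
    """Half-open interval overlap on the same chromosome, strand-agnostic."""
    return (
        gene.chromosome == bin_.chromosome
        and gene.start < bin_.end
        and bin_.start < gene.end
    )


def gene_density(bins: list[BinIndex], genes: list[GeneAnnotation]) -> np.ndarray:
    """Number of genes overlapping each bin (half-open overlap).

    Standard orientation covariate for compartment tracks: gene-dense regions
    are expected to be euchromatic (A).
    """
    density = np.zeros(len(bins), dtype=float)
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for i, b in enumerate(bins):
        for g in by_chrom.get(b.chromosome, ()):
            if g.start < b.end and b.start < g.end:
                density[i] += 1
    return density
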