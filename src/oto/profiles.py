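"""Multi-cell-type profiling: clustering, PCA, top-loading bins, overlaps.

A *profile* is an entities x features matrix — cell types x bins for
compartment eigenvector values, or cell types x genes for expression. The
operations here reproduce the standard unsupervised characterization of
such panels: Pearson-similarity Ward clustering (d = 1 - r), mean-centered
PCA with a deterministic sign convention, extraction of the top-k positive
and negative loading features, mapping of bins to overlapping genes, and
set-overlap fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import CompartmentTrack
from .errors import DegenerateInputError, UsageError
from .genome import BinIndex, GeneAnnotation

__all__ = [
    "ProfileMatrix",
    "LoadingSelection",
    "PCAResult",
    "assemble_profile",
    "expression_profile",
    "pearson_distance",
    "ward_cluster",
    "profile_pca",
    "top_loading_bins",
    "bins_to_genes",
    "overlap_fraction",
]


@dataclass
class ProfileMatrix:
    """Entities x features matrix with no missing values."""

    values: np.ndarray
    entity_names: list[str]
    feature_ids: list
    feature_kind: str  # "bin" | "gene"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_names), len(self.feature_ids)):
            raise UsageError("profile shape does not match entity/feature labels")
        if np.isnan(self.values).any():
            raise UsageError("profile contains NaN values")


@dataclass
class LoadingSelection:
    """Top-k positive and top-k negative loading features of one component."""

    positive_features: list
    negative_features: list
    component: int
    k: int


@dataclass
class PCAResult:
    scores: np.ndarray  # entities x components
    loadings: np.ndarray  # features x components
    explained_variance_ratio: np.ndarray


def assemble_profile(tracks: dict[str, CompartmentTrack]) -> ProfileMatrix:
    """Stack per-cell-type compartment tracks into a profile.

    Any bin that is NaN in at least one cell type is dropped (count is
    recorded); tracks must share one bin grid.
    """
    names = list(tracks)
    if not names:
        raise UsageError("no tracks to assemble")
    first = tracks[names[0]]
    for name in names[1:]:
        t = tracks[name]
        if len(t.bins) != len(first.bins) or any(
            a.label != b.label for a, b in zip(t.bins, first.bins)
        ):
            raise UsageError(f"track {name!r} is on a different bin grid")
    if len(names) < 3:
        warnings.warn("fewer than 3 cell types; clustering/PCA downstream will fail")
    stacked = np.vstack([tracks[n].values for n in names])
    keep = ~np.isnan(stacked).any(axis=0)
    return ProfileMatrix(
        stacked[:, keep],
        names,
        [b.ordinal for b, k in zip(first.bins, keep) if k],
        "bin",
        n_dropped=int((~keep).sum()),
    )


def expression_profile(expression, log_transform: bool = True) -> ProfileMatrix:
    """Samples x genes profile from a genes x samples count table.

    Counts are log2(count+1)-transformed and zero-variance genes dropped,
    the standard preprocessing ahead of expression PCA.
    """
    values = expression.to_numpy(dtype=float).T
    if log_transform:
        values = np.log2(values + 1.0)
    keep = values.std(axis=0) > 0
    return ProfileMatrix(
        values[:, keep],
        list(expression.columns),
        [g for g, k in zip(expression.index, keep) if k],
        "gene",
        n_dropped=int((~keep).sum()),
    )


def pearson_distance(profile: ProfileMatrix) -> np.ndarray:
    """Pairwise distance d(i,j) = 1 - Pearson r(i,j) between entities."""
    values = profile.values
    stds = values.std(axis=1)
    for i, s in enumerate(stds):
        if s == 0:
            raise DegenerateInputError(
                f"entity {profile.entity_names[i]!r} has zero variance"
            )
    dist = 1.0 - np.corrcoef(values)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def ward_cluster(distance: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Ward-linkage agglomerative clustering on a precomputed distance matrix.

    Returns the SciPy linkage matrix and the dendrogram leaf order.
    """
    distance = np.asarray(distance, dtype=float)
    if np.isnan(distance).any():
        raise DegenerateInputError("distance matrix contains NaN")
    condensed = squareform(distance, checks=False)
    linkage = hierarchy.linkage(condensed, method="ward")
    leaves = hierarchy.leaves_list(linkage)
    return linkage, [int(i) for i in leaves]


def profile_pca(profile: ProfileMatrix, n_components: int = 2) -> PCAResult:
    """Feature-wise mean-centered PCA (no variance scaling).

    Component signs are fixed so each loading vector's largest-magnitude
    element is positive, making results reproducible across platforms.
    """
    n_entities, n_features = profile.values.shape
    if n_entities < 3:
        raise UsageError("PCA needs at least 3 entities")
    max_components = min(n_entities - 1, n_features)
    if n_components > max_components:
        warnings.warn(
            f"n_components clipped from {n_components} to {max_components}"
        )
        n_components = max_components
    centered = profile.values - profile.values.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total_var = (s**2).sum()
    scores = (u * s)[:, :n_components]
    loadings = vt.T[:, :n_components]
    for c in range(n_components):
        peak = np.argmax(np.abs(loadings[:, c]))
        if loadings[peak, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return PCAResult(scores, loadings, evr)


def top_loading_bins(
    pca: PCAResult, profile: ProfileMatrix, component: int = 0, k: int = 100
) -> LoadingSelection:
    """The k most-positive and k most-negative loading features.

    Each list is sorted by |loading| descending; ties break by feature
    ordinal. If fewer than k strictly positive (or negative) loadings
    exist, all available are returned with a warning.
    """
    if component >= pca.loadings.shape[1]:
        raise UsageError(f"component {component} was not computed")
    loading = pca.loadings[:, component]
    idx = np.arange(loading.size)
    desc = np.lexsort((idx, -loading))  # loading descending, ties by ordinal
    asc = np.lexsort((idx, loading))  # loading ascending, ties by ordinal
    positive = [i for i in desc if loading[i] > 0][:k]
    negative = [i for i in asc if loading[i] < 0][:k]
    if len(positive) < k or len(negative) < k:
        warnings.warn(
            f"only {len(positive)} positive / {len(negative)} negative loadings"
        )
    return LoadingSelection(
        [profile.feature_ids[i] for i in positive],
        [profile.feature_ids[i] for i in negative],
        component,
        k,
    )


def bins_to_genes(
    selection: list[int], annotation: list[GeneAnnotation], bins: list[BinIndex]
) -> list[str]:
    """Genes overlapping any selected bin (half-open, strand-agnostic).

    ``selection`` holds bin ordinals into ``bins``; the result is
    deduplicated and sorted.
    """
    by_ordinal = {b.ordinal: b for b in bins}
    chosen = [by_ordinal[i] for i in selection]
    found = set()
    for g in annotation:
        for b in chosen:
            if g.chromosome == b.chromosome and g.start < b.end and b.start < g.end:
                found.add(g.gene_id)
                break
    return sorted(found)


def overlap_fraction(reference, query) -> float:
    """|reference ∩ query| / |reference|."""
    reference = set(reference)
    if not reference:
        raise UsageError("empty reference set")
    return len(reference & set(query)) / len(reference)
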