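"""Epithelial/mesenchymal scoring of expression profiles.

Two complementary per-sample scores over curated epithelial (E) and
mesenchymal (M) signature gene sets:

* a single-sample enrichment statistic — a Kolmogorov-Smirnov-style random
  walk down the sample's expression ranking that rises by 1/n at signature
  genes and falls by 1/(N-n) elsewhere, scored as the signed
  maximum-magnitude deviation (range [-1, 1]). Being a rank statistic it is
  invariant under monotone transforms of expression.
* non-negative PCA (nnPCA) — for each signature submatrix, axes with
  non-negative gene loadings that maximize projection variance, found by
  projected power iteration with Hotelling deflation; the per-sample score
  is the projection on the first axis.

Both express the EMT position of a sample; the combined axis is M - E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, UsageError
from .genome import GeneSetCollection

__all__ = [
    "EMTScores",
    "NonNegativeAxes",
    "enrichment_score",
    "score_panel",
    "nnpca_axes",
    "nnpca_scores",
]


@dataclass
class EMTScores:
    """Per-sample epithelial and mesenchymal scores (samples indexed)."""

    table: pd.DataFrame  # columns: E_score, M_score, combined (M - E)
    method: str  # "enrichment" | "nnpca"


@dataclass
class NonNegativeAxes:
    """Non-negative loading axes and per-sample projections."""

    loadings: np.ndarray  # genes x axes, all >= 0, unit columns
    projections: np.ndarray  # samples x axes
    gene_ids: list[str]
    cosines: np.ndarray  # pairwise |cosine| between axes (recorded, not enforced)
    n_iterations: list[int]


def enrichment_score(expression_sample: pd.Series, gene_set: list[str]) -> float:
    """Signed KS-walk enrichment of ``gene_set`` in one expression vector.

    Genes are ranked by expression descending (ties broken by gene
    identifier, ascending — deterministic across platforms); the running
    sum gains 1/n at set genes and loses 1/(N-n) elsewhere, and the value
    at the maximum-magnitude deviation is returned.
    """
    values = expression_sample
    present = [g for g in gene_set if g in values.index]
    if not present:
        raise DegenerateInputError("no gene-set member present among expressed genes")
    n, big_n = len(set(present)), len(values)
    if n >= big_n:
        raise UsageError("gene set covers the whole expression vector")
    order = sorted(values.index, key=lambda g: (-values[g], g))
    in_set = np.array([g in set(present) for g in order])
    steps = np.where(in_set, 1.0 / n, -1.0 / (big_n - n))
    walk = np.cumsum(steps)
    peak = int(np.argmax(np.abs(walk)))
    return float(walk[peak])


def score_panel(expression: pd.DataFrame, sets: GeneSetCollection) -> EMTScores:
    """Enrichment E and M scores per sample of a genes x samples table."""
    for name in ("E", "M"):
        if name not in sets:
            raise UsageError(f"gene set collection lacks set {name!r}")
    rows = {}
    for sample in expression.columns:
        col = expression[sample]
        e = enrichment_score(col, sets["E"])
        m = enrichment_score(col, sets["M"])
        rows[sample] = {"E_score": e, "M_score": m, "combined": m - e}
    return EMTScores(pd.DataFrame(rows).T, method="enrichment")


def _leading_pc(x: np.ndarray) -> np.ndarray:
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    v = vt[0]
    peak = np.argmax(np.abs(v))
    if v[peak] < 0:
        v = -v
    return v


def nnpca_axes(
    expression: pd.DataFrame,
    gene_set: list[str],
    n_axes: int = 1,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> NonNegativeAxes:
    """Sequential non-negative PCA on the gene-set submatrix.

    The submatrix is log2(count+1)-transformed and gene-centered; each axis
    maximizes projection variance subject to loadings >= 0 and unit norm,
    via projected power iteration on the covariance (multiply, clip
    negatives to zero, renormalize), initialized deterministically from the
    clipped leading standard principal axis. Later axes are computed after
    Hotelling deflation of the data; cross-axis cosines are recorded.
    """
    if n_axes < 1:
        raise UsageError("n_axes must be >= 1")
    present = [g for g in gene_set if g in expression.index]
    if not present:
        raise DegenerateInputError("no gene-set member present in expression table")
    x = np.log2(expression.loc[present].to_numpy(dtype=float).T + 1.0)
    x = x - x.mean(axis=0, keepdims=True)  # samples x genes, gene-centered

    axes, projections, iters = [], [], []
    residual = x.copy()
    for _ in range(n_axes):
        cov = residual.T @ residual / max(1, residual.shape[0] - 1)
        v0 = _leading_pc(residual)
        # a mixed-sign principal axis clips into two candidate cones; run the
        # iteration from both and keep the higher-variance solution
        starts = [s for s in (np.clip(v0, 0.0, None), np.clip(-v0, 0.0, None)) if s.any()]
        if not starts:
            raise DegenerateInputError("nnPCA axis collapsed to zero; use fewer axes")
        best_w, best_var, it = None, -np.inf, 0
        for start in starts:
            w = start / np.linalg.norm(start)
            used = 0
            for used in range(1, max_iter + 1):
                w_new = np.clip(cov @ w, 0.0, None)
                norm = np.linalg.norm(w_new)
                if norm == 0:
                    raise DegenerateInputError(
                        "nnPCA axis collapsed to zero; use fewer axes"
                    )
                w_new /= norm
                if np.linalg.norm(w_new - w) < tol:
                    w = w_new
                    break
                w = w_new
            var = float(w @ cov @ w)
            if var > best_var:
                best_w, best_var, it = w, var, used
        w = best_w
        axes.append(w)
        # scores live on the data the axis was fit to (the deflated residual),
        # the usual convention for sequential deflation schemes; for the first
        # axis this is the original gene-centered matrix
        projections.append(residual @ w)
        iters.append(it)
        residual = residual - np.outer(residual @ w, w)

    loadings = np.column_stack(axes)
    gram = np.abs(loadings.T @ loadings)
    np.fill_diagonal(gram, 1.0)
    return NonNegativeAxes(
        loadings=loadings,
        projections=np.column_stack(projections),
        gene_ids=present,
        cosines=gram,
        n_iterations=iters,
    )


def nnpca_scores(expression: pd.DataFrame, sets: GeneSetCollection) -> EMTScores:
    """nnPCA E and M scores: projection on the first non-negative axis of
    each signature submatrix (gene-centered within this panel)."""
    for name in ("E", "M"):
        if name not in sets:
            raise UsageError(f"gene set collection lacks set {name!r}")
    e_axes = nnpca_axes(expression, sets["E"], n_axes=1)
    m_axes = nnpca_axes(expression, sets["M"], n_axes=1)
    table = pd.DataFrame(
        {
            "E_score": e_axes.projections[:, 0],
            "M_score": m_axes.projections[:, 0],
        },
        index=expression.columns,
    )
    table["combined"] = table["M_score"] - table["E_score"]
    return EMTScores(table, method="nnpca")
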