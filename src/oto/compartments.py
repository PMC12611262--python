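"""From a raw binned contact matrix to oriented A/B compartment calls.

The chain is the standard eigenvector method for 250 kb compartment
analysis: iterative-correction (ICE) balancing, scaling of each chromosome
to a fixed total, observed/expected distance normalization, the leading
eigenvector of the Pearson correlation matrix of the O/E map, a global
sign orientation against a covariate (gene density by convention), and
finally discrete calls: positive values are A (euchromatic), negative B
(heterochromatic).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import eigh
from scipy.stats import pearsonr

from .containers import ContactMatrix, CompartmentTrack, StateTrack
from .errors import (
    ConvergenceWarning,
    DegenerateInputError,
    OrientationWarning,
    UsageError,
)

__all__ = [
    "ice_normalize",
    "scale_chromosome",
    "observed_over_expected",
    "compartment_eigenvector",
    "select_compartment_component",
    "orient_track",
    "call_states",
]

#: bins whose raw marginal falls below this fraction of the median marginal
#: are masked before balancing (sparsity filter)
SPARSITY_FRACTION = 0.1


def ice_normalize(
    matrix: ContactMatrix, tol: float = 1e-6, max_iter: int = 200
) -> tuple[ContactMatrix, np.ndarray]:
    """Iterative-correction (ICE) balancing of a symmetric contact matrix.

    Symmetric Sinkhorn-style iteration: the matrix is repeatedly divided by
    the outer product of its unmasked marginals normalized to mean one,
    until the coefficient of variation of the unmasked row sums drops below
    ``tol`` (or ``max_iter`` is reached, in which case the result is flagged
    unconverged via a warning and ``converged=False``). The total count over
    unmasked bins is preserved by a final global rescale. Returns the
    balanced matrix and the accumulated per-bin bias (1 on masked bins).
    """
    counts = matrix.counts.copy()
    mask = matrix.mask.copy()

    # sparsity filter: drop bins with unusually low coverage
    marginals = counts.sum(axis=0)
    live = ~mask
    if live.sum() < 2:
        raise DegenerateInputError("fewer than 2 unmasked bins")
    median = np.median(marginals[live])
    mask |= marginals < SPARSITY_FRACTION * median
    live = ~mask
    if live.sum() < 2:
        raise DegenerateInputError("sparsity filter masked all bins")

    sub = counts[np.ix_(live, live)]
    original_total = sub.sum()
    bias = np.ones(live.sum())
    converged = False
    for _ in range(max_iter):
        s = sub.sum(axis=0)
        mean = s.mean()
        if mean == 0:
            raise DegenerateInputError("all-zero matrix after masking")
        cv = s.std() / mean
        if cv < tol:
            converged = True
            break
        step = s / mean
        sub /= np.outer(step, step)
        bias *= step
    else:
        s = sub.sum(axis=0)
        converged = s.std() / s.mean() < tol
    if not converged:
        warnings.warn(
            f"ICE did not reach row-sum CV < {tol} in {max_iter} iterations",
            ConvergenceWarning,
        )
    if sub.sum() > 0:
        sub *= original_total / sub.sum()

    out = np.zeros_like(counts)
    out[np.ix_(live, live)] = sub
    full_bias = np.ones(matrix.n_bins)
    full_bias[live] = bias
    balanced = ContactMatrix(
        out, list(matrix.bins), mask=mask, balanced=True, converged=converged
    )
    return balanced, full_bias


def scale_chromosome(matrix: ContactMatrix, target_total: float = 1e6) -> ContactMatrix:
    """Scale all entries so the unmasked upper-triangle total (including the
    diagonal) equals ``target_total`` — the per-chromosome '1M' convention."""
    live = matrix.unmasked
    sub = matrix.counts[np.ix_(live, live)]
    total = np.triu(sub).sum()
    if total <= 0:
        raise DegenerateInputError("cannot scale a matrix with zero total")
    return matrix.with_counts(matrix.counts * (target_total / total))


def observed_over_expected(matrix: ContactMatrix) -> np.ndarray:
    """Divide each entry by the mean contact at its genomic distance.

    The expected value at distance d is the mean over unmasked pairs on the
    |i-j| = d diagonal. Masked rows/columns are NaN; distances at which no
    unmasked contact was observed anywhere (zero mean) give the neutral
    value 1.0 so the downstream correlation is defined.
    """
    live = matrix.unmasked
    sub = matrix.counts[np.ix_(live, live)]
    n = sub.shape[0]
    oe_sub = np.full_like(sub, np.nan)
    for d in range(n):
        i = np.arange(n - d)
        diag = sub[i, i + d]
        mean = diag.mean()
        scaled = diag / mean if mean > 0 else np.ones_like(diag)
        oe_sub[i, i + d] = scaled
        oe_sub[i + d, i] = scaled
    oe = np.full_like(matrix.counts, np.nan)
    oe[np.ix_(live, live)] = oe_sub
    return oe


def compartment_eigenvector(
    matrix: ContactMatrix, component: int = 0
) -> CompartmentTrack:
    """Eigenvector of the Pearson-correlation matrix of the O/E map.

    The O/E columns (over unmasked bins) are correlated against each other;
    PCA is then performed on the correlation matrix (column-centered), and
    the requested eigenvector (0 = leading, the default compartment axis)
    is returned as a unit-norm per-bin track with NaN on masked bins.
    Orientation (global sign) is deferred to :func:`orient_track`.
    """
    live = matrix.unmasked
    if live.size < 10:
        raise DegenerateInputError("need at least 10 unmasked bins")
    oe = observed_over_expected(matrix)[np.ix_(live, live)]
    stds = oe.std(axis=0)
    degenerate = np.flatnonzero(stds == 0)
    if degenerate.size:
        labels = [matrix.bins[live[i]].label for i in degenerate[:5]]
        raise DegenerateInputError(
            f"constant O/E columns at bins {labels} (and "
            f"{max(0, degenerate.size - 5)} more)"
        )
    corr = np.corrcoef(oe, rowvar=False)
    centered = corr - corr.mean(axis=0, keepdims=True)
    cov = centered.T @ centered
    n = cov.shape[0]
    if not 0 <= component < n:
        raise UsageError(f"component {component} out of range for {n} bins")
    k = n - 1 - component
    _, vec = eigh(cov, subset_by_index=[k, k])
    vec = vec[:, 0]
    vec /= np.linalg.norm(vec)
    values = np.full(matrix.n_bins, np.nan)
    values[live] = vec
    return CompartmentTrack(values, list(matrix.bins), oriented=False)


def select_compartment_component(
    matrix: ContactMatrix, covariate: np.ndarray, n_candidates: int = 3
) -> tuple[CompartmentTrack, int]:
    """Among the first ``n_candidates`` eigenvectors, pick the one most
    correlated (in magnitude) with the orientation covariate.

    Chromosome arms or other large-scale features occasionally displace the
    compartment signal from the leading component; this helper exists for
    those cases. The default pipeline uses the leading component directly.
    """
    covariate = np.asarray(covariate, dtype=float)
    best, best_r, best_c = None, -1.0, 0
    for c in range(n_candidates):
        track = compartment_eigenvector(matrix, component=c)
        ok = track.defined & ~np.isnan(covariate)
        if np.std(track.values[ok]) == 0 or np.std(covariate[ok]) == 0:
            continue
        r = abs(float(pearsonr(track.values[ok], covariate[ok])[0]))
        if r > best_r:
            best, best_r, best_c = track, r, c
    if best is None:
        raise DegenerateInputError("no candidate component could be correlated")
    return best, best_c


def orient_track(track: CompartmentTrack, covariate: np.ndarray) -> CompartmentTrack:
    """Fix the eigenvector's global sign against an A-correlated covariate.

    Flips the whole track if its Pearson correlation with the covariate is
    negative, so that positive values mean A. A correlation of magnitude
    below 0.1 is flagged as ambiguous orientation (warning).
    """
    covariate = np.asarray(covariate, dtype=float)
    if covariate.shape != track.values.shape:
        raise UsageError("covariate length does not match track")
    ok = track.defined & ~np.isnan(covariate)
    if ok.sum() < 10:
        raise DegenerateInputError("covariate defined on fewer than 10 unmasked bins")
    if np.std(track.values[ok]) == 0 or np.std(covariate[ok]) == 0:
        raise DegenerateInputError("constant track or covariate; cannot orient")
    r = float(pearsonr(track.values[ok], covariate[ok])[0])
    if abs(r) < 0.1:
        warnings.warn(
            f"orientation is ambiguous (|r| = {abs(r):.3f} < 0.1)", OrientationWarning
        )
    sign = -1.0 if r < 0 else 1.0
    return CompartmentTrack(
        track.values * sign, list(track.bins), oriented=True, orientation_r=abs(r)
    )


def call_states(track: CompartmentTrack) -> StateTrack:
    """Discrete A/B calls from an oriented track: sign decides, 0/NaN -> NA."""
    if not track.oriented:
        raise UsageError("call_states requires an oriented track")
    states = np.full(len(track.bins), "NA", dtype="<U2")
    states[np.nan_to_num(track.values) > 0] = "A"
    states[np.nan_to_num(track.values) < 0] = "B"
    return StateTrack(states, list(track.bins))
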