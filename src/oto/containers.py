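"""In-memory containers for contact matrices and compartment tracks."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import IntegrityError, UsageError
from .genome import BinIndex

__all__ = ["ContactMatrix", "CompartmentTrack", "StateTrack"]

#: relative symmetry tolerance for contact matrices
SYMMETRY_RTOL = 1e-6

STATE_A = "A"
STATE_B = "B"
STATE_NA = "NA"


@dataclass
class ContactMatrix:
    """A symmetric, non-negative, per-chromosome binned contact matrix.

    ``mask[i] is True`` means bin *i* is excluded from analysis (typically
    unmappable / zero-coverage); masked bins are retained in the matrix so
    that bin coordinates stay genome-wide.
    """

    counts: np.ndarray
    bins: list[BinIndex]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    balanced: bool = False
    converged: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise IntegrityError("contact matrix must be square")
        if len(self.bins) != self.counts.shape[0]:
            raise IntegrityError(
                f"{len(self.bins)} bins for a {self.counts.shape[0]}-row matrix"
            )
        if np.any(self.counts < 0):
            raise ValueError("contact matrix has negative entries")
        scale = max(np.abs(self.counts).max(), 1.0)
        if np.abs(self.counts - self.counts.T).max() > SYMMETRY_RTOL * scale:
            raise IntegrityError("contact matrix is not symmetric")
        if self.mask is None:
            self.mask = ~self.counts.any(axis=0)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.counts.shape[0],):
            raise IntegrityError("mask length does not match matrix")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def unmasked(self) -> np.ndarray:
        return np.flatnonzero(~self.mask)

    def with_counts(self, counts: np.ndarray, **kwargs) -> "ContactMatrix":
        return replace(self, counts=counts, **kwargs)


@dataclass
class CompartmentTrack:
    """Signed per-bin eigenvector values; NaN marks masked bins.

    Positive values are A (euchromatic), negative B (heterochromatic) once
    the track has been oriented against a covariate.
    """

    values: np.ndarray
    bins: list[BinIndex]
    oriented: bool = False
    orientation_r: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.bins),):
            raise IntegrityError("track length does not match bins")
        if self.oriented and self.orientation_r is not None and self.orientation_r < 0:
            raise IntegrityError("oriented track must record a non-negative correlation")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class StateTrack:
    """Discrete per-bin compartment calls: 'A', 'B' or 'NA'."""

    states: np.ndarray
    bins: list[BinIndex]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="<U2")
        if self.states.shape != (len(self.bins),):
            raise IntegrityError("state track length does not match bins")
        bad = set(np.unique(self.states)) - {STATE_A, STATE_B, STATE_NA}
        if bad:
            raise ValueError(f"invalid compartment states: {sorted(bad)}")

    @classmethod
    def from_signs(cls, signs: np.ndarray, bins: list[BinIndex]) -> "StateTrack":
        """Build from a +1/-1 integer vector (ground-truth representation)."""
        signs = np.asarray(signs)
        states = np.where(signs > 0, STATE_A, np.where(signs < 0, STATE_B, STATE_NA))
        return cls(states.astype("<U2"), bins)

    def signs(self) -> np.ndarray:
        """+1 for A, -1 for B, 0 for NA."""
        return np.where(
            self.states == STATE_A, 1, np.where(self.states == STATE_B, -1, 0)
        )


def require_same_bins(a, b) -> None:
    if len(a.bins) != len(b.bins) or any(
        x.label != y.label for x, y in zip(a.bins, b.bins)
    ):
        raise UsageError("operands are defined on different bin grids")
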