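"""Organ-permissive compartment-switch classification and its bias correction.

For one organ system, each bin's compartment state in cancer is compared
with the matched normal epithelium, giving a *pair state* — AA, AB, BA or
BB (normal letter first). Cross-comparing the primary-organ pair state with
a secondary organ's pair state yields 16 categories ``XY_ZW``. Two of them
are *organ-permissive*: AB_BB and BA_AA — the primary-organ cancer switches
toward the compartment state that the secondary organ holds in both its
normal and cancerous cells.

Because different secondary organs have different baseline switching rates,
cross-organ comparisons use an adjustment built from the secondary organ's
compartment stability probabilities: p(TA|NA) is the probability that a bin
in compartment A in the secondary organ's normal cells is still A in its
localized cancer (p(TB|NB) analogously; minima across cell lines). The
category percentages are then multiplied by (1 - p): (1 - p(TA|NA)) scales
the BA_AA percentage and (1 - p(TB|NB)) the AB_BB percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .containers import StateTrack, require_same_bins
from .errors import DegenerateInputError, UsageError
from .genome import BinIndex

__all__ = [
    "PAIR_LABELS",
    "CROSS_LABELS",
    "PERMISSIVE_LABELS",
    "PairStateTrack",
    "CrossStateTrack",
    "StabilityProbabilities",
    "PermissiveSummary",
    "pair_states",
    "consensus_pair_states",
    "cross_states",
    "permissive_summary",
    "stability_probabilities",
    "adjusted_permissive",
    "compare_target_organs",
]

PAIR_LABELS = ("AA", "AB", "BA", "BB")
CROSS_LABELS = tuple(f"{p}_{s}" for p, s in product(PAIR_LABELS, PAIR_LABELS))
#: the organ-permissive categories: cancer switches toward the secondary
#: organ's (stable) compartment state
PERMISSIVE_LABELS = frozenset({"AB_BB", "BA_AA"})
#: categories shared between the two organs' cancers (same-direction switches)
CANCER_SHARED_LABELS = frozenset({"AB_AB", "BA_BA"})

_NA = "NA"


@dataclass
class PairStateTrack:
    """Per-bin normal-vs-cancer label: AA/AB/BA/BB, or NA."""

    labels: np.ndarray
    bins: list[BinIndex]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U2")
        if self.labels.shape != (len(self.bins),):
            raise UsageError("pair-state track length does not match bins")


@dataclass
class CrossStateTrack:
    """Per-bin primary_secondary cross label (16 categories), or NA."""

    labels: np.ndarray
    bins: list[BinIndex]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U5")
        if self.labels.shape != (len(self.bins),):
            raise UsageError("cross-state track length does not match bins")


@dataclass
class StabilityProbabilities:
    """Secondary-organ compartment stability, minima over cancer cell lines."""

    p_TA_given_NA: float
    p_TB_given_NB: float
    per_line: pd.DataFrame  # columns: p_TA_given_NA, p_TB_given_NB
    n_NA_bins: int
    n_NB_bins: int


@dataclass
class PermissiveSummary:
    """Counts and fractions over the 16 cross categories, plus adjustments."""

    category_counts: dict[str, int]
    n_informative_bins: int
    permissive_fraction: float
    percent_of_informative: dict[str, float]
    permissive_fraction_all_bins: float
    adjusted_BA_AA_percent: float | None = None
    adjusted_AB_BB_percent: float | None = None
    probabilities: StabilityProbabilities | None = None
    permissive_labels: frozenset = field(default=PERMISSIVE_LABELS)


def pair_states(normal: StateTrack, cancer: StateTrack) -> PairStateTrack:
    """Concatenate normal and cancer per-bin states; NA propagates."""
    require_same_bins(normal, cancer)
    n, c = normal.states, cancer.states
    ok = (n != _NA) & (c != _NA)
    labels = np.full(len(normal.bins), _NA, dtype="<U2")
    labels[ok] = np.char.add(n[ok], c[ok])
    return PairStateTrack(labels, list(normal.bins))


def consensus_pair_states(normal: StateTrack, cancers: list[StateTrack]) -> PairStateTrack:
    """Pair state shared by *every* cancer line of a group, else NA.

    With a single cancer track this reduces to :func:`pair_states`.
    """
    if not cancers:
        raise UsageError("need at least one cancer track")
    tracks = [pair_states(normal, c) for c in cancers]
    labels = tracks[0].labels.copy()
    for t in tracks[1:]:
        labels = np.where(labels == t.labels, labels, _NA).astype("<U2")
    return PairStateTrack(labels, list(normal.bins))


def cross_states(primary: PairStateTrack, secondary: PairStateTrack) -> CrossStateTrack:
    """Cross label ``XY_ZW`` from primary and secondary pair states."""
    require_same_bins(primary, secondary)
    p, s = primary.labels, secondary.labels
    ok = (p != _NA) & (s != _NA)
    labels = np.full(len(primary.bins), _NA, dtype="<U5")
    labels[ok] = np.char.add(np.char.add(p[ok], "_"), s[ok])
    return CrossStateTrack(labels, list(primary.bins))


def permissive_summary(
    cross: CrossStateTrack, permissive_labels: frozenset = PERMISSIVE_LABELS
) -> PermissiveSummary:
    """Tabulate the 16 categories and the permissive fraction.

    ``permissive_fraction`` is the share of permissive bins among bins whose
    *primary* pair state shows a compartment change (AB or BA) — the
    fraction of primary-organ compartment alterations that are also
    secondary-organ permissive. The all-informative-bins variant and the
    per-category percentages (x100, per informative bin; the input of the
    cross-organ adjustment) are reported alongside.
    """
    labels = cross.labels
    counts = {lbl: int((labels == lbl).sum()) for lbl in CROSS_LABELS}
    n_informative = int(sum(counts.values()))
    changed = sum(
        count for lbl, count in counts.items() if lbl[:2] in ("AB", "BA")
    )
    permissive = sum(counts[lbl] for lbl in permissive_labels)
    if changed == 0:
        raise DegenerateInputError(
            "no informative bins with a primary-organ compartment change"
        )
    percent = {
        lbl: 100.0 * count / n_informative for lbl, count in counts.items()
    }
    return PermissiveSummary(
        category_counts=counts,
        n_informative_bins=n_informative,
        permissive_fraction=permissive / changed,
        percent_of_informative=percent,
        permissive_fraction_all_bins=permissive / n_informative,
        permissive_labels=permissive_labels,
    )


def stability_probabilities(
    secondary_normal: StateTrack, secondary_cancers: list[StateTrack]
) -> StabilityProbabilities:
    """p(TA|NA) and p(TB|NB) per secondary cancer line, and their minima."""
    if not secondary_cancers:
        raise UsageError("need at least one secondary cancer track")
    rows = {}
    n_na = n_nb = 0
    for i, cancer in enumerate(secondary_cancers):
        require_same_bins(secondary_normal, cancer)
        n, c = secondary_normal.states, cancer.states
        ok = (n != _NA) & (c != _NA)
        in_a = ok & (n == "A")
        in_b = ok & (n == "B")
        if in_a.sum() == 0:
            raise DegenerateInputError("no normal-A bins: p(TA|NA) undefined")
        if in_b.sum() == 0:
            raise DegenerateInputError("no normal-B bins: p(TB|NB) undefined")
        rows[f"line_{i + 1}"] = {
            "p_TA_given_NA": float((c[in_a] == "A").sum() / in_a.sum()),
            "p_TB_given_NB": float((c[in_b] == "B").sum() / in_b.sum()),
        }
        n_na, n_nb = int(in_a.sum()), int(in_b.sum())
    per_line = pd.DataFrame(rows).T
    return StabilityProbabilities(
        p_TA_given_NA=float(per_line["p_TA_given_NA"].min()),
        p_TB_given_NB=float(per_line["p_TB_given_NB"].min()),
        per_line=per_line,
        n_NA_bins=n_na,
        n_NB_bins=n_nb,
    )


def adjusted_permissive(
    summary: PermissiveSummary,
    probs: StabilityProbabilities,
    weight_by_p: bool = False,
) -> PermissiveSummary:
    """Apply the cross-organ bias correction to the permissive percentages.

    The stability probabilities are subtracted from one and multiplied with
    the corresponding category percentages: (1 - p(TA|NA)) x percent(BA_AA)
    and (1 - p(TB|NB)) x percent(AB_BB). ``weight_by_p`` swaps to
    p-weighting for sensitivity analysis (off by default).
    """
    wa = probs.p_TA_given_NA if weight_by_p else 1.0 - probs.p_TA_given_NA
    wb = probs.p_TB_given_NB if weight_by_p else 1.0 - probs.p_TB_given_NB
    summary.adjusted_BA_AA_percent = wa * summary.percent_of_informative["BA_AA"]
    summary.adjusted_AB_BB_percent = wb * summary.percent_of_informative["AB_BB"]
    summary.probabilities = probs
    return summary


def _common_defined(tracks: list[StateTrack]) -> np.ndarray:
    defined = tracks[0].states != _NA
    for t in tracks[1:]:
        require_same_bins(tracks[0], t)
        defined &= t.states != _NA
    return defined


def _restrict(track: StateTrack, keep: np.ndarray) -> StateTrack:
    states = track.states.copy()
    states[~keep] = _NA
    return StateTrack(states, list(track.bins))


def compare_target_organs(
    primary_normal: StateTrack,
    primary_cancers: list[StateTrack],
    organ_panels: dict[str, tuple[StateTrack, list[StateTrack]]],
) -> dict[str, PermissiveSummary]:
    """Adjusted permissive summaries for several candidate target organs.

    All organs are evaluated on the common bin set — bins with a defined
    state in every track involved — so the percentages share one
    denominator basis and are comparable across organs.
    """
    if len(organ_panels) < 2:
        raise UsageError("need at least 2 organs to compare")
    all_tracks = [primary_normal] + list(primary_cancers)
    for normal, cancers in organ_panels.values():
        all_tracks.append(normal)
        all_tracks.extend(cancers)
    common = _common_defined(all_tracks)
    if not common.any():
        raise DegenerateInputError("empty common bin set across organ panels")

    primary_pairs = consensus_pair_states(
        _restrict(primary_normal, common),
        [_restrict(c, common) for c in primary_cancers],
    )
    results = {}
    for organ, (normal, cancers) in organ_panels.items():
        sec_normal = _restrict(normal, common)
        sec_cancers = [_restrict(c, common) for c in cancers]
        secondary_pairs = consensus_pair_states(sec_normal, sec_cancers)
        cross = cross_states(primary_pairs, secondary_pairs)
        summary = permissive_summary(cross)
        probs = stability_probabilities(sec_normal, sec_cancers)
        results[organ] = adjusted_permissive(summary, probs)
    return results


def summary_table(results: dict[str, PermissiveSummary]) -> pd.DataFrame:
    """Side-by-side tabulation of per-organ adjusted summaries."""
    rows = {}
    for organ, s in results.items():
        rows[organ] = {
            "n_informative_bins": s.n_informative_bins,
            "permissive_fraction": s.permissive_fraction,
            "percent_AB_BB": s.percent_of_informative["AB_BB"],
            "percent_BA_AA": s.percent_of_informative["BA_AA"],
            "adjusted_AB_BB_percent": s.adjusted_AB_BB_percent,
            "adjusted_BA_AA_percent": s.adjusted_BA_AA_percent,
            "p_TA_given_NA": s.probabilities.p_TA_given_NA if s.probabilities else None,
            "p_TB_given_NB": s.probabilities.p_TB_given_NB if s.probabilities else None,
        }
    return pd.DataFrame(rows).T
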