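"""Classification chain vs exhaustive enumeration; adjustment arithmetic."""

import numpy as np
import pytest

from oto.containers import StateTrack
from oto.errors import DegenerateInputError, UsageError
from oto.genome import make_bins
from oto.organotropism import (
    CROSS_LABELS,
    adjusted_permissive,
    compare_target_organs,
    consensus_pair_states,
    cross_states,
    pair_states,
    permissive_summary,
    stability_probabilities,
    summary_table,
)


def track(states):
    states = list(states) if isinstance(states, str) else states
    return StateTrack(np.array(states, dtype="<U2"), make_bins("chr1", len(states), 1000))


# -- independent exhaustive oracles (pure-python, per-bin) --------------------

def oracle_pair(n, c):
    return "NA" if n == "NA" or c == "NA" else n + c


def oracle_consensus(n, cancers_at_bin):
    labels = [oracle_pair(n, c) for c in cancers_at_bin]
    return labels[0] if labels[0] != "NA" and all(l == labels[0] for l in labels) else "NA"


def oracle_cross(p, s):
    return "NA" if p == "NA" or s == "NA" else f"{p}_{s}"


class TestPairStates:
    def test_definition_of_four_cases(self):
        result = pair_states(track("AABB"), track("ABAB"))
        assert list(result.labels) == ["AA", "AB", "BA", "BB"]

    def test_na_propagates(self):
        result = pair_states(track(["A", "NA", "B"]), track(["NA", "A", "B"]))
        assert list(result.labels) == ["NA", "NA", "BB"]

    def test_matches_exhaustive_enumeration(self):
        alphabet = ["A", "B", "NA"]
        normal = [n for n in alphabet for _ in alphabet]
        cancer = alphabet * 3
        result = pair_states(track(normal), track(cancer))
        assert list(result.labels) == [oracle_pair(n, c) for n, c in zip(normal, cancer)]

    def test_mismatched_bins_is_error(self):
        a = StateTrack(np.array(["A"]), make_bins("chr1", 1, 1000))
        b = StateTrack(np.array(["A"]), make_bins("chr2", 1, 1000))
        with pytest.raises(UsageError):
            pair_states(a, b)


class TestConsensus:
    def test_agreeing_cancers_keep_label(self):
        result = consensus_pair_states(track("AA"), [track("BB"), track("BB")])
        assert list(result.labels) == ["AB", "AB"]

    def test_disagreement_becomes_na(self):
        result = consensus_pair_states(track("AA"), [track("BA"), track("AA")])
        assert list(result.labels) == ["NA", "AA"]

    def test_single_cancer_equals_pair_states(self):
        n, c = track("ABAB"), track("BBAA")
        np.testing.assert_array_equal(
            consensus_pair_states(n, [c]).labels, pair_states(n, c).labels
        )

    def test_empty_group_is_error(self):
        with pytest.raises(UsageError):
            consensus_pair_states(track("A"), [])


class TestCrossStates:
    def test_permissive_label_construction(self):
        result = cross_states(
            pair_states(track("A"), track("B")), pair_states(track("B"), track("B"))
        )
        assert list(result.labels) == ["AB_BB"]

    def test_unchanged_label(self):
        result = cross_states(
            pair_states(track("A"), track("A")), pair_states(track("A"), track("A"))
        )
        assert list(result.labels) == ["AA_AA"]

    def test_histogram_matches_exhaustive_enumeration(self, rng):
        alphabet = np.array(["A", "B", "NA"])
        for _ in range(25):
            n1, c1, n2, c2 = (rng.choice(alphabet, size=60) for _ in range(4))
            cross = cross_states(
                pair_states(track(n1), track(c1)), pair_states(track(n2), track(c2))
            )
            expected = [
                oracle_cross(oracle_pair(a, b), oracle_pair(x, y))
                for a, b, x, y in zip(n1, c1, n2, c2)
            ]
            assert list(cross.labels) == expected


class TestPermissiveSummary:
    def _summary_from_labels(self, labels):
        bins = make_bins("chr1", len(labels), 1000)
        from oto.organotropism import CrossStateTrack

        return permissive_summary(CrossStateTrack(np.array(labels, dtype="<U5"), bins))

    def test_worked_example(self):
        labels = ["AB_BB"] * 2 + ["BA_AA"] + ["AB_AB"] + ["AA_AA"] * 6
        s = self._summary_from_labels(labels)
        assert s.permissive_fraction == pytest.approx(3 / 4)
        assert s.n_informative_bins == 10
        assert sum(s.category_counts.values()) == 10

    def test_only_permissive_changes_gives_fraction_one(self):
        s = self._summary_from_labels(["AB_BB", "BA_AA", "BB_BB"])
        assert s.permissive_fraction == 1.0

    def test_cancer_shared_labels_substitution(self):
        labels = ["AB_AB"] * 3 + ["AB_BB"] + ["AA_AA"] * 4
        bins = make_bins("chr1", len(labels), 1000)
        from oto.organotropism import CrossStateTrack

        cross = CrossStateTrack(np.array(labels, dtype="<U5"), bins)
        shared = permissive_summary(cross, permissive_labels=frozenset({"AB_AB", "BA_BA"}))
        assert shared.permissive_fraction == pytest.approx(3 / 4)

    def test_no_primary_changes_is_error(self):
        with pytest.raises(DegenerateInputError):
            self._summary_from_labels(["AA_AA", "BB_BB"])

    def test_conservation_counts_plus_na(self, rng):
        alphabet = np.array(["A", "B", "NA"])
        n1, c1, n2, c2 = (rng.choice(alphabet, size=200) for _ in range(4))
        cross = cross_states(
            pair_states(track(n1), track(c1)), pair_states(track(n2), track(c2))
        )
        counts = {lbl: int((cross.labels == lbl).sum()) for lbl in CROSS_LABELS}
        na = int((cross.labels == "NA").sum())
        assert sum(counts.values()) + na == 200


class TestStabilityProbabilities:
    def test_hand_enumerated_example(self):
        probs = stability_probabilities(
            track("AABB"), [track("ABBB"), track("AABA")]
        )
        assert probs.p_TA_given_NA == pytest.approx(0.5)
        assert probs.p_TB_given_NB == pytest.approx(0.5)
        assert probs.per_line.loc["line_1", "p_TA_given_NA"] == pytest.approx(0.5)
        assert probs.per_line.loc["line_2", "p_TA_given_NA"] == pytest.approx(1.0)

    def test_identical_tumor_gives_probability_one(self):
        probs = stability_probabilities(track("ABAB"), [track("ABAB")])
        assert probs.p_TA_given_NA == 1.0
        assert probs.p_TB_given_NB == 1.0

    def test_inverted_tumor_gives_probability_zero(self):
        probs = stability_probabilities(track("ABAB"), [track("BABA")])
        assert probs.p_TA_given_NA == 0.0
        assert probs.p_TB_given_NB == 0.0

    def test_missing_compartment_is_error(self):
        with pytest.raises(DegenerateInputError):
            stability_probabilities(track("AAAA"), [track("AAAA")])


class TestAdjustment:
    def _summary(self, percent_ba_aa=10.0, percent_ab_bb=10.0):
        from oto.organotropism import PermissiveSummary

        percents = {lbl: 0.0 for lbl in CROSS_LABELS}
        percents["BA_AA"] = percent_ba_aa
        percents["AB_BB"] = percent_ab_bb
        return PermissiveSummary(
            category_counts={lbl: 0 for lbl in CROSS_LABELS},
            n_informative_bins=100,
            permissive_fraction=0.0,
            percent_of_informative=percents,
            permissive_fraction_all_bins=0.0,
        )

    def _probs(self, pa, pb):
        import pandas as pd

        from oto.organotropism import StabilityProbabilities

        return StabilityProbabilities(
            pa, pb, pd.DataFrame({"p_TA_given_NA": [pa], "p_TB_given_NB": [pb]}), 10, 10
        )

    def test_worked_example(self):
        s = adjusted_permissive(self._summary(percent_ba_aa=10.0), self._probs(0.8, 0.5))
        assert s.adjusted_BA_AA_percent == pytest.approx(2.0)

    def test_full_stability_zeroes_adjusted_percentages(self):
        s = adjusted_permissive(self._summary(), self._probs(1.0, 1.0))
        assert s.adjusted_BA_AA_percent == 0.0
        assert s.adjusted_AB_BB_percent == 0.0

    def test_zero_stability_is_identity(self):
        s = adjusted_permissive(self._summary(7.0, 3.0), self._probs(0.0, 0.0))
        assert s.adjusted_BA_AA_percent == pytest.approx(7.0)
        assert s.adjusted_AB_BB_percent == pytest.approx(3.0)

    def test_monotone_non_increasing_in_probabilities(self):
        values = []
        for p in np.linspace(0, 1, 11):
            s = adjusted_permissive(self._summary(), self._probs(p, p))
            values.append((s.adjusted_BA_AA_percent, s.adjusted_AB_BB_percent))
        ba, ab = zip(*values)
        assert all(b <= a + 1e-12 for a, b in zip(ba, ba[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(ab, ab[1:]))

    def test_adjusted_never_exceeds_unadjusted(self, rng):
        for _ in range(20):
            pa, pb = rng.random(2)
            raw_ba, raw_ab = rng.uniform(0, 20, 2)
            s = adjusted_permissive(self._summary(raw_ba, raw_ab), self._probs(pa, pb))
            assert s.adjusted_BA_AA_percent <= raw_ba
            assert s.adjusted_AB_BB_percent <= raw_ab


class TestCompareTargetOrgans:
    def _states(self, rng, n=400):
        return rng.choice(np.array(["A", "B"]), size=n)

    def _panel(self, rng, n=400):
        normal = self._states(rng, n)
        cancers = []
        for _ in range(2):
            c = normal.copy()
            flip = rng.random(n) < 0.2
            c[flip] = np.where(c[flip] == "A", "B", "A")
            cancers.append(track(list(c)))
        return track(list(normal)), cancers

    def test_identical_organ_panels_give_identical_summaries(self, rng):
        p_normal, p_cancers = self._panel(rng)
        o_normal, o_cancers = self._panel(rng)
        results = compare_target_organs(
            p_normal, p_cancers, {"x": (o_normal, o_cancers), "y": (o_normal, o_cancers)}
        )
        tab = summary_table(results)
        assert tab.loc["x"].equals(tab.loc["y"])

    def test_removing_decoy_organ_leaves_target_unchanged(self, rng):
        """Per-organ independence given a fixed common bin set: dropping a
        decoy organ whose tracks are fully defined does not change the
        target organ's summary."""
        p_normal, p_cancers = self._panel(rng)
        x = self._panel(rng)
        y = self._panel(rng)
        with_decoy = compare_target_organs(
            p_normal, p_cancers, {"x": x, "y": y, "z": y}
        )
        without = compare_target_organs(p_normal, p_cancers, {"x": x, "z": y})
        assert (
            with_decoy["x"].adjusted_BA_AA_percent
            == without["x"].adjusted_BA_AA_percent
        )
        assert with_decoy["x"].category_counts == without["x"].category_counts

    def test_fewer_than_two_organs_is_error(self, rng):
        p_normal, p_cancers = self._panel(rng)
        with pytest.raises(UsageError):
            compare_target_organs(p_normal, p_cancers, {"x": self._panel(rng)})

    def test_empty_common_bins_is_error(self):
        na = track(["NA", "NA"])
        ab = track(["A", "B"])
        with pytest.raises(DegenerateInputError):
            compare_target_organs(ab, [ab], {"x": (na, [ab]), "y": (ab, [ab])})
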