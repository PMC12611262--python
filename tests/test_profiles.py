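"""Profiling operations vs direct-formula and brute-force oracles."""

import numpy as np
import pytest
from scipy.cluster import hierarchy

from oto.containers import CompartmentTrack
from oto.errors import DegenerateInputError, UsageError
from oto.genome import GeneAnnotation, make_bins
from oto.profiles import (
    ProfileMatrix,
    assemble_profile,
    bins_to_genes,
    overlap_fraction,
    pearson_distance,
    profile_pca,
    top_loading_bins,
    ward_cluster,
)


def make_profile(values, kind="bin"):
    values = np.asarray(values, dtype=float)
    return ProfileMatrix(
        values,
        [f"ct{i}" for i in range(values.shape[0])],
        list(range(values.shape[1])),
        kind,
    )


class TestAssemble:
    def test_bin_na_in_one_cell_type_is_dropped(self):
        bins = make_bins("chr1", 4, 1000)
        tracks = {
            "a": CompartmentTrack(np.array([1.0, 2, 3, 4]), bins),
            "b": CompartmentTrack(np.array([1.0, np.nan, 3, 4]), bins),
            "c": CompartmentTrack(np.array([0.0, 1, 2, 3]), bins),
        }
        profile = assemble_profile(tracks)
        assert profile.values.shape == (3, 3)
        assert profile.n_dropped == 1
        assert profile.feature_ids == [0, 2, 3]

    def test_identical_tracks_give_rank_one_profile(self):
        bins = make_bins("chr1", 5, 1000)
        v = np.array([1.0, -1, 2, -2, 3])
        tracks = {k: CompartmentTrack(v.copy(), bins) for k in "abc"}
        profile = assemble_profile(tracks)
        assert np.linalg.matrix_rank(profile.values) == 1

    def test_cell_type_order_preserved(self):
        bins = make_bins("chr1", 3, 1000)
        tracks = {
            k: CompartmentTrack(np.array([i, i + 1.0, i + 2]), bins)
            for i, k in enumerate("xyz")
        }
        profile = assemble_profile(tracks)
        assert profile.entity_names == ["x", "y", "z"]

    def test_mismatched_bins_is_error(self):
        tracks = {
            "a": CompartmentTrack(np.zeros(3), make_bins("chr1", 3, 1000)),
            "b": CompartmentTrack(np.zeros(3), make_bins("chr2", 3, 1000)),
            "c": CompartmentTrack(np.zeros(3), make_bins("chr1", 3, 1000)),
        }
        with pytest.raises(UsageError):
            assemble_profile(tracks)


class TestPearsonDistance:
    def test_identical_rows_distance_zero(self):
        profile = make_profile([[1, 2, 3], [1, 2, 3], [3, 2, 1]])
        d = pearson_distance(profile)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_distance_two(self):
        profile = make_profile([[1, 2, 3], [3, 2, 1], [1, 3, 2]])
        d = pearson_distance(profile)
        assert d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        values = rng.normal(size=(6, 40))
        d = pearson_distance(make_profile(values))
        for i in range(6):
            for j in range(6):
                x, y = values[i], values[j]
                r = ((x - x.mean()) * (y - y.mean())).sum() / (
                    np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                )
                assert d[i, j] == pytest.approx(1 - r if i != j else 0.0, abs=1e-12)

    def test_zero_variance_entity_is_named(self):
        profile = make_profile([[1, 1, 1], [1, 2, 3], [3, 2, 1]])
        with pytest.raises(DegenerateInputError, match="ct0"):
            pearson_distance(profile)


class TestWardCluster:
    def test_identical_pair_merges_first_at_height_zero(self):
        profile = make_profile([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]])
        linkage, _ = ward_cluster(pearson_distance(profile))
        assert set(linkage[0, :2]) == {0.0, 1.0}
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_heights_non_decreasing(self, rng):
        values = rng.normal(size=(8, 30))
        linkage, _ = ward_cluster(pearson_distance(make_profile(values)))
        heights = linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_two_planted_groups_recovered(self):
        """Cutting the dendrogram at 2 recovers a planted partition."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            center_a, center_b = rng.normal(size=(2, 50))
            rows = [center_a + 0.2 * rng.normal(size=50) for _ in range(4)] + [
                center_b + 0.2 * rng.normal(size=50) for _ in range(4)
            ]
            linkage, _ = ward_cluster(pearson_distance(make_profile(rows)))
            labels = hierarchy.fcluster(linkage, 2, criterion="maxclust")
            assert len(set(labels[:4])) == 1
            assert len(set(labels[4:])) == 1
            assert labels[0] != labels[4]

    def test_nan_distance_is_error(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(DegenerateInputError):
            ward_cluster(d)


class TestPCA:
    def test_single_direction_explains_everything(self):
        base = np.array([1.0, -2.0, 3.0, 0.5])
        values = np.outer([0.0, 1.0, 2.0], base)
        pca = profile_pca(make_profile(values), n_components=2)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_is_complete(self, rng):
        values = rng.normal(size=(5, 12))
        profile = make_profile(values)
        pca = profile_pca(profile, n_components=4)
        centered = values - values.mean(axis=0)
        recon = pca.scores @ pca.loadings.T
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_matches_eigendecomposition_oracle(self, rng):
        values = rng.normal(size=(6, 15))
        pca = profile_pca(make_profile(values), n_components=3)
        centered = values - values.mean(axis=0)
        cov = centered.T @ centered
        w, v = np.linalg.eigh(cov)
        for c in range(3):
            oracle = v[:, -1 - c]
            cos = abs(oracle @ pca.loadings[:, c])
            assert cos == pytest.approx(1.0, abs=1e-10)
            var = pca.scores[:, c] @ pca.scores[:, c]
            assert var == pytest.approx(w[-1 - c], rel=1e-10)

    def test_sign_convention_largest_loading_positive(self, rng):
        values = rng.normal(size=(5, 9))
        pca = profile_pca(make_profile(values), n_components=2)
        for c in range(2):
            peak = np.argmax(np.abs(pca.loadings[:, c]))
            assert pca.loadings[peak, c] > 0

    def test_excess_components_clipped_with_warning(self, rng):
        values = rng.normal(size=(4, 6))
        with pytest.warns(UserWarning, match="clipped"):
            pca = profile_pca(make_profile(values), n_components=10)
        assert pca.scores.shape[1] == 3


class TestTopLoadings:
    def _pca_with_loadings(self, loading):
        from oto.profiles import PCAResult

        loading = np.asarray(loading, dtype=float).reshape(-1, 1)
        profile = make_profile(np.zeros((3, loading.shape[0])))
        pca = PCAResult(np.zeros((3, 1)), loading, np.array([1.0]))
        return pca, profile

    def test_single_extreme_example(self):
        pca, profile = self._pca_with_loadings([3.0, -2.0, 1.0, -4.0])
        sel = top_loading_bins(pca, profile, k=1)
        assert sel.positive_features == [0]
        assert sel.negative_features == [3]

    def test_sign_flip_swaps_selections(self):
        pca, profile = self._pca_with_loadings([3.0, -2.0, 1.0, -4.0])
        sel = top_loading_bins(pca, profile, k=1)
        pca.loadings[:, 0] *= -1
        swapped = top_loading_bins(pca, profile, k=1)
        assert swapped.positive_features == sel.negative_features
        assert swapped.negative_features == sel.positive_features

    def test_matches_brute_force_sort(self, rng):
        loading = rng.normal(size=50)
        pca, profile = self._pca_with_loadings(loading)
        k = 10
        sel = top_loading_bins(pca, profile, k=k)
        realized = pca.loadings[:, 0]  # sign convention may flip the input
        oracle_pos = sorted(
            [i for i in range(50) if realized[i] > 0], key=lambda i: -realized[i]
        )[:k]
        oracle_neg = sorted(
            [i for i in range(50) if realized[i] < 0], key=lambda i: realized[i]
        )[:k]
        assert sel.positive_features == oracle_pos
        assert sel.negative_features == oracle_neg

    def test_short_side_returns_available_with_warning(self):
        pca, profile = self._pca_with_loadings([1.0, 2.0, 3.0, -1.0])
        with pytest.warns(UserWarning):
            sel = top_loading_bins(pca, profile, k=2)
        assert len(sel.negative_features) == 1


class TestBinsToGenes:
    def test_gene_spanning_two_selected_bins_appears_once(self):
        bins = make_bins("chr1", 3, 1000)
        genes = [GeneAnnotation("g1", "g1", "chr1", 500, 1500, "+")]
        assert bins_to_genes([0, 1], genes, bins) == ["g1"]

    def test_abutting_gene_excluded_by_half_open_convention(self):
        bins = make_bins("chr1", 2, 1000)
        genes = [GeneAnnotation("g1", "g1", "chr1", 1000, 1200, "+")]
        assert bins_to_genes([0], genes, bins) == []
        assert bins_to_genes([1], genes, bins) == ["g1"]

    def test_matches_quadratic_overlap_scan(self, rng):
        bins = make_bins("chr1", 30, 1000)
        genes = []
        for i in range(60):
            start = int(rng.integers(0, 29_000))
            genes.append(
                GeneAnnotation(f"g{i}", f"g{i}", "chr1", start, start + int(rng.integers(100, 3000)), "+")
            )
        selected = sorted(rng.choice(30, size=10, replace=False).tolist())
        result = bins_to_genes(selected, genes, bins)
        oracle = sorted(
            {
                g.gene_id
                for g in genes
                for i in selected
                if g.start < bins[i].end and bins[i].start < g.end
            }
        )
        assert result == oracle


class TestOverlapFraction:
    def test_half_overlap(self):
        assert overlap_fraction(range(1, 101), range(51, 151)) == pytest.approx(0.5)

    def test_disjoint_and_subset(self):
        assert overlap_fraction({1, 2}, {3, 4}) == 0.0
        assert overlap_fraction({1, 2}, {1, 2, 3}) == 1.0

    def test_empty_reference_is_error(self):
        with pytest.raises(UsageError):
            overlap_fraction(set(), {1})
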