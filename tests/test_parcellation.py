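"""Argmax clustering, block sorting, dendrograms, label-matched accuracy.

Each operation is also checked against an exhaustive brute-force oracle
on small instances.
"""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from voxelparcel import (
    SyntheticAtlasParams,
    als_nmf,
    accuracy_vs_gene_count,
    assign_clusters,
    basis_dendrogram,
    best_label_accuracy,
    block_profiles,
    generate_atlas,
    sort_weights_by_peak,
)


class TestAssignClusters:
    def test_plain_argmax(self):
        a = assign_clusters(np.array([[0.1], [0.9]]))
        assert a.labels.tolist() == [2]
        assert not a.tie[0] and not a.empty[0]

    def test_tie_goes_to_lowest_index_and_flags(self):
        a = assign_clusters(np.array([[0.5], [0.5]]))
        assert a.labels.tolist() == [1]
        assert a.tie[0] and not a.empty[0]

    def test_all_zero_column_flagged_empty(self):
        a = assign_clusters(np.array([[0.0], [0.0]]))
        assert a.labels.tolist() == [1]
        assert a.empty[0] and not a.tie[0]

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            assign_clusters(np.array([[-0.1, 0.2]]))

    def test_against_brute_force(self):
        """Elementwise python loop oracle on random small H."""
        rng = np.random.default_rng(0)
        H = rng.uniform(size=(4, 8)).round(1)  # rounding provokes ties
        a = assign_clusters(H)
        for j in range(8):
            col = H[:, j]
            best = max(range(4), key=lambda i: (col[i], -i))
            assert a.labels[j] == best + 1
            assert a.tie[j] == (sum(c == col.max() for c in col) > 1 and col.max() > 0)
            assert a.empty[j] == (col.max() == 0)


def _valid_block_orderings(H):
    """All column orders satisfying the block rule: argmax blocks ascending,
    peaks non-increasing within a block."""
    block = H.argmax(axis=0)
    peak = H.max(axis=0)
    n = H.shape[1]
    valid = []
    for perm in itertools.permutations(range(n)):
        b = [block[j] for j in perm]
        p = [peak[j] for j in perm]
        if all(b[i] <= b[i + 1] for i in range(n - 1)) and all(
            p[i] >= p[i + 1] for i in range(n - 1) if b[i] == b[i + 1]
        ):
            valid.append(list(perm))
    return valid


class TestSortWeightsByPeak:
    def test_two_column_example(self):
        H = np.array([[1.0, 0.0], [0.0, 2.0]])
        perm, sorted_h = sort_weights_by_peak(H)
        assert perm.tolist() == [0, 1]
        assert np.array_equal(sorted_h, H)

    def test_three_column_example(self):
        """(0.9,0.1),(0.2,0.8),(0.7,0.3): block 1 holds cols 0,2 (0.9>0.7)."""
        H = np.array([[0.9, 0.2, 0.7], [0.1, 0.8, 0.3]])
        perm, sorted_h = sort_weights_by_peak(H)
        assert perm.tolist() == [0, 2, 1]
        assert _valid_block_orderings(H) == [[0, 2, 1]]  # unique valid order

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        H = rng.uniform(size=(3, 7))
        _, sorted_h = sort_weights_by_peak(H)
        perm2, resorted = sort_weights_by_peak(sorted_h)
        assert perm2.tolist() == list(range(7))
        assert np.array_equal(resorted, sorted_h)

    def test_values_unchanged(self):
        rng = np.random.default_rng(5)
        H = rng.uniform(size=(4, 6))
        perm, sorted_h = sort_weights_by_peak(H)
        assert np.array_equal(np.sort(sorted_h.ravel()), np.sort(H.ravel()))
        assert np.array_equal(sorted_h, H[:, perm])

    def test_against_exhaustive_enumeration(self):
        """Returned order is among the valid block orderings, and is the one
        preserving original order on exact ties."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            H = rng.uniform(size=(3, 6)).round(1)
            perm, _ = sort_weights_by_peak(H)
            valid = _valid_block_orderings(H)
            assert perm.tolist() in valid
            # stability: ours is the lexicographically-smallest valid order
            assert perm.tolist() == min(valid)


class TestBlockProfiles:
    def test_single_voxel_cluster_returns_its_column(self):
        H = np.array([[0.9, 0.1], [0.1, 0.9]])
        a = assign_clusters(H)
        profiles = block_profiles(H, a)
        assert np.allclose(profiles[1], H[:, 0])
        assert np.allclose(profiles[2], H[:, 1])

    def test_mean_of_two_columns(self):
        H = np.array([[1.0, 0.5], [0.0, 0.5]])
        a = assign_clusters(H)  # both columns peak on row 1 (tie goes low)
        profiles = block_profiles(H, a)
        assert np.allclose(profiles[1], [0.75, 0.25])

    def test_empty_cluster_requested(self):
        H = np.array([[1.0], [0.0]])
        a = assign_clusters(H)
        with pytest.raises(ValueError, match="no member"):
            block_profiles(H, a, clusters=[2])

    def test_block_diagonal_profiles_peak_on_own_dimension(self):
        """On a strongly block-diagonal H each mean vector peaks on itself."""
        rng = np.random.default_rng(2)
        s, per = 4, 10
        H = rng.uniform(0, 0.1, size=(s, s * per))
        for k in range(s):
            H[k, k * per : (k + 1) * per] += 1.0
        a = assign_clusters(H)
        for k, vec in block_profiles(H, a).items():
            assert vec.argmax() == k - 1


class TestBasisDendrogram:
    def test_identical_vectors_merge_at_zero(self):
        W = np.array([[1.0, 1.0], [2.0, 2.0]])
        Z, leaves, dists = basis_dendrogram(W)
        assert Z[0, 2] == 0.0

    def test_three_four_five_distance(self):
        W = np.array([[0.0, 3.0], [0.0, 4.0]])
        _, _, dists = basis_dendrogram(W)
        assert dists[0] == pytest.approx(5.0)

    def test_first_merge_joins_closest_pair_brute_force(self):
        """Columns at mutual distances ~1,1,10: first merge joins the close pair."""
        W = np.array([[0.0, 1.0, 10.0], [0.0, 0.0, 0.0]])
        Z, _, dists = basis_dendrogram(W)
        merged = {int(Z[0, 0]), int(Z[0, 1])}
        # brute-force oracle: the pair with the minimum pairwise distance
        pairs = list(itertools.combinations(range(3), 2))
        best_pair = set(pairs[int(np.argmin(dists))])
        assert merged == best_pair

    def test_needs_two_vectors(self):
        with pytest.raises(ValueError, match="at least 2"):
            basis_dendrogram(np.ones((3, 1)))


class TestBestLabelAccuracy:
    def test_relabeled_clustering_scores_one(self):
        truth = np.array([1, 1, 2, 2, 3, 3])
        pred = np.array([3, 3, 1, 1, 2, 2])  # same partition, renamed
        acc, mapping = best_label_accuracy(pred, truth)
        assert acc == 1.0
        assert mapping == {3: 1, 1: 2, 2: 3}

    def test_two_equal_classes_random_assignment_at_least_half(self):
        rng = np.random.default_rng(0)
        truth = np.repeat([1, 2], 50)
        pred = rng.integers(1, 3, size=100)
        acc, _ = best_label_accuracy(pred, truth)
        assert acc >= 0.5

    def test_invariant_under_any_relabeling_exhaustive(self):
        """Accuracy is identical for every permutation of either labeling (s<=4)."""
        rng = np.random.default_rng(6)
        truth = rng.integers(1, 5, size=12)
        pred = rng.integers(1, 5, size=12)
        base, _ = best_label_accuracy(pred, truth)
        for perm in itertools.permutations(range(1, 5)):
            relabeled = np.array([perm[p - 1] for p in pred])
            acc, _ = best_label_accuracy(relabeled, truth)
            assert acc == pytest.approx(base)

    def test_against_exhaustive_permutation_oracle(self):
        """Hungarian matching equals brute-force max over label permutations."""
        rng = np.random.default_rng(13)
        for _ in range(10):
            truth = rng.integers(1, 4, size=8)
            pred = rng.integers(1, 4, size=8)
            acc, _ = best_label_accuracy(pred, truth)
            brute = max(
                np.mean([perm[p - 1] == t for p, t in zip(pred, truth)])
                for perm in itertools.permutations(range(1, 4))
            )
            assert acc == pytest.approx(brute)


class TestPlantedRecovery:
    def test_cluster_recovery_on_default_style_atlas(self):
        """ARI >= 0.9 against planted labels on a scaled-down default atlas."""
        params = SyntheticAtlasParams(
            grid_shape=(12, 12, 4),
            n_regions=4,
            n_signature_genes_per_region=10,
            n_background_genes=60,
            noise_dispersion=1.0,
            seed=3,
        )
        atlas, truth = generate_atlas(params)
        res = als_nmf(atlas.matrix, s=4, tol=1e-6, seed=0, restarts=3)
        pred = assign_clusters(res.H).labels
        assert adjusted_rand_score(truth.voxel_domain_labels, pred) >= 0.9

    def test_accuracy_vs_gene_count_full_set_noiseless(self):
        """All genes, zero noise: every voxel classified perfectly."""
        params = SyntheticAtlasParams(
            grid_shape=(8, 4, 2),
            n_regions=2,
            n_signature_genes_per_region=5,
            n_background_genes=20,
            noise_dispersion=0.0,
            seed=0,
        )
        atlas, truth = generate_atlas(params)
        curve = accuracy_vs_gene_count(
            atlas,
            truth.voxel_domain_labels,
            gene_counts=[atlas.n_genes],
            reps=3,
            s=2,
            seed=5,
            tol=1e-9,
            restarts=3,
        )
        assert curve.mean_accuracy[0] == pytest.approx(1.0)
        assert curve.perfect_fraction[0] == pytest.approx(1.0)

    def test_accuracy_curve_validation(self):
        params = SyntheticAtlasParams(
            grid_shape=(4, 2, 2),
            n_regions=2,
            n_signature_genes_per_region=2,
            n_background_genes=4,
            seed=0,
        )
        atlas, truth = generate_atlas(params)
        with pytest.raises(ValueError, match="gene counts"):
            accuracy_vs_gene_count(
                atlas, truth.voxel_domain_labels, [999], reps=1, s=2
            )
        with pytest.raises(ValueError, match="classes"):
            accuracy_vs_gene_count(
                atlas, truth.voxel_domain_labels, [4], reps=1, s=3
            )
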