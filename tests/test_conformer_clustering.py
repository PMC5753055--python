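"""Kabsch superposition and greedy neighbour-count clustering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from strandscope.conformer_clustering import (
    BACKBONE,
    AtomSelection,
    RMSDMatrix,
    daura_cluster,
    kabsch_superpose,
    pairwise_rmsd,
)


def greedy_neighbor_clustering(matrix, cutoff):
    """Independent reference implementation on a plain distance matrix.

    Literal restatement of the procedure with python sets, used as the
    oracle for matrices small enough to inspect by hand.
    """
    n = matrix.shape[0]
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(1 for j in unassigned if matrix[i, j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = sorted(j for j in unassigned if matrix[best, j] <= cutoff)
        clusters.append((best, tuple(members)))
        unassigned -= set(members)
    return clusters


def random_rigid_rmsd(a, b, n_trials=1000, seed=0):
    """Brute-force random-rotation search: best RMSD over sampled rigid moves."""
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_trials, random_state=rng).as_matrix()
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    moved = np.einsum("rij,nj->rni", rots, bc)
    rmsds = np.sqrt(np.mean(np.sum((moved - ac) ** 2, axis=-1), axis=-1))
    return rmsds.min()


class TestKabschSuperpose:
    def test_identical_models_zero_rmsd_identity_rotation(self):
        a = np.random.default_rng(0).normal(size=(10, 3))
        rot, trans, rmsd = kabsch_superpose(a, a)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3))
        assert np.allclose(trans, 0.0, atol=1e-12)

    def test_rigidly_moved_copy_recovers_zero_rmsd(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(12, 3))
        R = Rotation.from_rotvec([0.4, 1.2, -0.5]).as_matrix()
        b = a @ R.T + np.array([3.0, -1.0, 2.0])
        rot, trans, rmsd = kabsch_superpose(a, b)
        assert rmsd <= 1e-9  # nm
        assert np.allclose(rot @ b.T + trans[:, None], a.T, atol=1e-8)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(5))
    def test_optimal_against_random_rotation_search(self, trial):
        rng = np.random.default_rng(100 + trial)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        _, _, rmsd_nm = kabsch_superpose(a, b)
        brute = random_rigid_rmsd(a, b, n_trials=1000, seed=trial) / 10.0
        assert rmsd_nm <= brute + 1e-12

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        _, _, rmsd_nm = kabsch_superpose(a, b)
        ac, bc = a - a.mean(0), b - b.mean(0)
        rot, rssd = Rotation.align_vectors(ac, bc)
        assert rmsd_nm * 10.0 == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-9)

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(5, dtype=float), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line + 1.0)

    def test_proper_rotation_even_for_reflected_input(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 3))
        b = a * np.array([1.0, 1.0, -1.0])  # mirror image
        rot, _, rmsd = kabsch_superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0)
        assert rmsd > 0  # a mirror image cannot be superposed by proper rotation


class TestPairwiseRMSD:
    def test_duplicated_models_give_zero_matrix(self, small_coordinates):
        import dataclasses

        dup = dataclasses.replace(
            small_coordinates,
            coords=np.repeat(small_coordinates.coords[:1], 5, axis=0),
            provenance=None,
        )
        mat = pairwise_rmsd(dup)
        assert np.allclose(mat.values, 0.0, atol=1e-9)

    def test_matrix_symmetric_with_zero_diagonal(self, small_coordinates):
        import dataclasses

        sub = dataclasses.replace(
            small_coordinates, coords=small_coordinates.coords[:20], provenance=None
        )
        mat = pairwise_rmsd(sub)
        assert np.array_equal(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 0.0)

    def test_entries_match_single_pair_superposition(self, small_coordinates):
        import dataclasses

        sub = dataclasses.replace(
            small_coordinates, coords=small_coordinates.coords[:12], provenance=None
        )
        mat = pairwise_rmsd(sub, BACKBONE)
        mask = BACKBONE.mask(sub)
        rng = np.random.default_rng(5)
        for _ in range(3):
            i, j = rng.choice(12, size=2, replace=False)
            _, _, rmsd = kabsch_superpose(
                sub.coords[i][mask], sub.coords[j][mask]
            )
            assert mat.values[i, j] == pytest.approx(rmsd, abs=1e-10)

    def test_selection_too_small_rejected(self, small_coordinates):
        with pytest.raises(ValueError, match="at least 3"):
            AtomSelection(atom_names=frozenset({"CM"})).mask(small_coordinates)


class TestDauraCluster:
    def test_all_neighbors_single_cluster_lowest_index_center(self):
        mat = RMSDMatrix(np.full((6, 6), 0.05) - 0.05 * np.eye(6))
        res = daura_cluster(mat, cutoff=0.2)
        assert res.n_clusters == 1
        assert res.clusters[0].center == 0
        assert res.clusters[0].members == tuple(range(6))

    def test_all_distant_gives_singletons(self):
        mat = RMSDMatrix(np.full((5, 5), 0.9) - 0.9 * np.eye(5))
        res = daura_cluster(mat, cutoff=0.2)
        assert res.n_clusters == 5
        assert all(c.size == 1 for c in res.clusters)

    def test_two_cliques_match_hand_crafted_oracle(self):
        # frames 0-2 and 3-5 form tight cliques, far from each other
        m = np.full((6, 6), 1.0)
        for group in ([0, 1, 2], [3, 4, 5]):
            for i in group:
                for j in group:
                    m[i, j] = 0.05
        np.fill_diagonal(m, 0.0)
        res = daura_cluster(RMSDMatrix(m), cutoff=0.2)
        oracle = greedy_neighbor_clustering(m, 0.2)
        assert res.n_clusters == len(oracle) == 2
        for cluster, (center, members) in zip(res.clusters, oracle):
            assert cluster.center == center
            assert cluster.members == members

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_reference_on_random_small_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 11)
        d = rng.uniform(0.0, 0.5, size=(n, n))
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        res = daura_cluster(RMSDMatrix(d), cutoff=0.2)
        oracle = greedy_neighbor_clustering(d, 0.2)
        assert [(c.center, c.members) for c in res.clusters] == oracle

    def test_partition_and_ordering_invariants(self, small_coordinates):
        import dataclasses

        sub = dataclasses.replace(
            small_coordinates, coords=small_coordinates.coords[:40], provenance=None
        )
        mat = pairwise_rmsd(sub)
        res = daura_cluster(mat, cutoff=0.15)
        all_members = sorted(m for c in res.clusters for m in c.members)
        assert all_members == list(range(40))
        sizes = [c.size for c in res.clusters]
        assert sizes == sorted(sizes, reverse=True)
        assert all(c.center in c.members for c in res.clusters)

    def test_cluster_count_non_increasing_in_cutoff(self, small_coordinates):
        import dataclasses

        sub = dataclasses.replace(
            small_coordinates, coords=small_coordinates.coords[:30], provenance=None
        )
        mat = pairwise_rmsd(sub)
        counts = [
            daura_cluster(mat, cutoff=c).n_clusters for c in (0.05, 0.1, 0.2, 0.4)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_cutoff_rejected(self):
        mat = RMSDMatrix(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            daura_cluster(mat, cutoff=0.0)
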