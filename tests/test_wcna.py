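"""Adjacency, topological overlap, tree cut, eigenprofiles, cluster merging."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import make_matrix
from polyclust import ComputationError, ConfigurationError, DataError
from polyclust.simulate import scaled_config, simulate_summary_stats
from polyclust.sumstats import harmonize_studies
from polyclust.wcna import (
    AdjacencyMatrix,
    TOMMatrix,
    cluster_eigenprofile,
    cluster_snps,
    hierarchical_clusters,
    merge_close_clusters,
    soft_adjacency,
    tom_similarity,
)


class TestSoftAdjacency:
    def test_identical_profiles_have_unit_adjacency(self):
        m = make_matrix([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        for signed in (True, False):
            a = soft_adjacency(m, power=6, signed=signed).a
            assert a[0, 1] == pytest.approx(1.0)

    def test_unsigned_folds_anticorrelated_profiles(self):
        m = make_matrix([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert soft_adjacency(m, power=6, signed=False).a[0, 1] == pytest.approx(1.0)

    def test_signed_separates_anticorrelated_profiles(self):
        m = make_matrix([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert soft_adjacency(m, power=6, signed=True).a[0, 1] == pytest.approx(0.0)

    def test_hand_computed_unsigned_value(self):
        # cor((0,1,2),(0,2,2)) = sqrt(3)/2, so a = (3/4)^3 = 27/64
        m = make_matrix([[0.0, 1.0, 2.0], [0.0, 2.0, 2.0]])
        assert soft_adjacency(m, power=6, signed=False).a[0, 1] == pytest.approx(
            27 / 64, abs=1e-12
        )

    def test_degenerate_profile_gets_zero_adjacency(self):
        m = make_matrix([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [0.0, 2.0, 1.0]])
        a = soft_adjacency(m, power=6).a
        assert a[0, 1] == 0.0 and a[0, 2] == 0.0 and a[0, 0] == 1.0

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ConfigurationError):
            soft_adjacency(make_matrix([[0.0, 1.0], [1.0, 0.0]]), power=0)


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Direct-loop evaluation of the topological overlap formula."""
    n = a.shape[0]
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            t[i, j] = (shared + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return t


class TestTOM:
    def test_two_node_network_reduces_to_adjacency(self):
        for val in (0.0, 0.3, 0.9, 1.0):
            a = np.array([[1.0, val], [val, 1.0]])
            t = tom_similarity(AdjacencyMatrix(["a", "b"], a, 6.0)).t
            assert t[0, 1] == pytest.approx(val, abs=1e-12)

    def test_complete_graph_is_all_ones(self):
        a = np.ones((5, 5))
        t = tom_similarity(AdjacencyMatrix(list("abcde"), a, 6.0)).t
        assert np.allclose(t, 1.0)

    def test_empty_graph_is_identity(self):
        a = np.eye(4)
        t = tom_similarity(AdjacencyMatrix(list("abcd"), a, 6.0)).t
        assert np.allclose(t, np.eye(4))

    @pytest.mark.parametrize("n", [3, 6, 12])
    def test_matches_direct_loop_oracle(self, n):
        rng = np.random.default_rng(n)
        c = rng.uniform(-1, 1, size=(n, n))
        a = np.abs((c + c.T) / 2) ** 3
        np.fill_diagonal(a, 1.0)
        t = tom_similarity(AdjacencyMatrix([str(i) for i in range(n)], a, 3.0)).t
        assert np.allclose(t, tom_oracle(a), atol=1e-12)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(0, 1, size=(20, 20))
        a = (c + c.T) / 2
        np.fill_diagonal(a, 1.0)
        t = tom_similarity(AdjacencyMatrix([str(i) for i in range(20)], a, 6.0)).t
        assert np.allclose(t, t.T)
        assert t.min() >= 0 and t.max() <= 1


def _block_tom(sizes, within, between):
    n = sum(sizes)
    t = np.full((n, n), between, dtype=float)
    pos = 0
    for s in sizes:
        t[pos : pos + s, pos : pos + s] = within
        pos += s
    np.fill_diagonal(t, 1.0)
    return TOMMatrix([f"s{i:03d}" for i in range(n)], t)


class TestHierarchicalClusters:
    def test_two_separated_blocks(self):
        tom = _block_tom([40, 40], within=0.9, between=0.05)
        assign = hierarchical_clusters(tom, min_size=30)
        assert assign.n_clusters == 2
        assert sorted(np.bincount(assign.labels)[1:]) == [40, 40]
        assert (assign.labels != 0).all()

    def test_small_block_below_min_size_is_unassigned(self):
        # a 20-SNP block among unconnected noise: below min_size, labelled 0
        n_noise = 40
        t = np.eye(20 + n_noise)
        t[:20, :20] = 0.9
        np.fill_diagonal(t, 1.0)
        tom = TOMMatrix([f"s{i:03d}" for i in range(20 + n_noise)], t)
        assign = hierarchical_clusters(tom, min_size=30)
        assert (assign.labels == 0).all()

    def test_labels_ordered_by_decreasing_size(self):
        tom = _block_tom([35, 60, 45], within=0.9, between=0.02)
        assign = hierarchical_clusters(tom, min_size=30)
        sizes = [np.sum(assign.labels == k) for k in (1, 2, 3)]
        assert sizes == [60, 45, 35]

    def test_too_few_snps_raises(self):
        with pytest.raises(DataError):
            hierarchical_clusters(_block_tom([10], 0.9, 0.0), min_size=30)

    def test_permutation_equivariance(self, two_block_matrix):
        assign = cluster_snps(two_block_matrix, min_size=10)
        rng = np.random.default_rng(1)
        perm = rng.permutation(two_block_matrix.n_snps)
        permuted = make_matrix(
            two_block_matrix.absz.to_numpy()[perm],
            snp_ids=[two_block_matrix.snp_ids[i] for i in perm],
        )
        assign_p = cluster_snps(permuted, min_size=10)
        ref = dict(zip(assign.snp_ids, assign.labels))
        got = dict(zip(assign_p.snp_ids, assign_p.labels))
        # same partition up to label names
        assert adjusted_rand_score(
            [ref[s] for s in assign.snp_ids], [got[s] for s in assign.snp_ids]
        ) == pytest.approx(1.0)


class TestEigenprofile:
    def test_shared_profile_gives_standardized_profile(self):
        p = np.array([4.0, 1.0, 1.0])
        m = make_matrix(np.tile(p, (5, 1)))
        v = cluster_eigenprofile(m, m.snp_ids).vector
        expected = (p - p.mean()) / p.std()
        expected /= np.linalg.norm(expected)
        assert np.allclose(np.abs(v @ expected), 1.0, atol=1e-12)
        assert v @ expected > 0  # orientation toward the mean profile

    def test_orientation_is_positive_correlation_with_mean(self):
        rng = np.random.default_rng(5)
        x = np.array([5.0, 2.0, 1.0]) + rng.normal(0, 0.3, size=(40, 3))
        m = make_matrix(x)
        v = cluster_eigenprofile(m, m.snp_ids).vector
        assert np.corrcoef(v, x.mean(axis=0))[0, 1] > 0

    def test_matches_brute_force_rotation_search(self):
        rng = np.random.default_rng(11)
        x = np.array([3.0, 1.0, 0.5]) + rng.normal(0, 0.4, size=(3, 3))
        m = make_matrix(x)
        v = cluster_eigenprofile(m, m.snp_ids).vector
        xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        best, best_val = None, -1.0
        for theta in np.linspace(0, np.pi, 721):
            for phi in np.linspace(0, 2 * np.pi, 1441):
                u = np.array(
                    [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
                )
                val = np.sum((xs @ u) ** 2)
                if val > best_val:
                    best, best_val = u, val
        assert abs(v @ best) == pytest.approx(1.0, abs=1e-3)

    def test_zero_variance_submatrix_raises(self):
        m = make_matrix(np.ones((4, 3)))
        with pytest.raises(ComputationError):
            cluster_eigenprofile(m, m.snp_ids)

    def test_fewer_than_two_members_raises(self):
        m = make_matrix([[1.0, 2.0, 3.0]])
        with pytest.raises(DataError):
            cluster_eigenprofile(m, m.snp_ids)


def _assignment(labels, matrix):
    from polyclust.wcna import ClusterAssignment

    return ClusterAssignment(snp_ids=matrix.snp_ids, labels=np.asarray(labels))


class TestMergeCloseClusters:
    @staticmethod
    def _three_cluster_matrix(cors=(0.9, 0.4, 0.4)):
        """Clusters of identical profiles whose pairwise eigenprofile
        correlations equal the requested values by construction."""
        rng = np.random.default_rng(2)
        base = np.array([1.0, 2.0, 3.0, 4.0, 2.5])
        a = (base - base.mean()) / np.linalg.norm(base - base.mean())
        r = rng.normal(size=5)
        r -= r.mean() + 0  # centred
        r -= (r @ a) * a
        r /= np.linalg.norm(r)
        s = rng.normal(size=5)
        s -= s.mean()
        s -= (s @ a) * a + (s @ r) * r
        s /= np.linalg.norm(s)
        c_ab, c_ac, c_bc = cors
        b = c_ab * a + np.sqrt(1 - c_ab**2) * r
        gamma = c_ac
        delta = (c_bc - c_ab * gamma) / np.sqrt(1 - c_ab**2)
        eps = np.sqrt(max(1 - gamma**2 - delta**2, 0.0))
        c = gamma * a + delta * r + eps * s
        rows = []
        for v in (a, b, c):
            profile = v * 2.0 + 5.0  # positive |z|-like values, same shape
            rows += [profile] * 10
        labels = [1] * 10 + [2] * 10 + [3] * 10
        return make_matrix(np.array(rows)), labels

    def test_one_merge_then_stop(self):
        m, labels = self._three_cluster_matrix((0.9, 0.4, 0.4))
        merged = merge_close_clusters(_assignment(labels, m), m, merge_dissim=0.25)
        assert merged.n_clusters == 2
        assert np.sum(merged.labels == 1) == 20  # merged pair relabelled largest

    def test_orthogonal_clusters_unchanged(self):
        m, labels = self._three_cluster_matrix((0.0, 0.0, 0.0))
        merged = merge_close_clusters(_assignment(labels, m), m, merge_dissim=0.25)
        assert merged.n_clusters == 3

    def test_high_correlation_pair_merges(self):
        m, labels = self._three_cluster_matrix((0.9, 0.0, 0.0))
        merged = merge_close_clusters(
            _assignment([l for l in labels if l != 3] + [0] * 10, m), m, merge_dissim=0.25
        )
        assert merged.n_clusters == 1

    def test_no_clusters_raises(self):
        m, _ = self._three_cluster_matrix()
        with pytest.raises(DataError):
            merge_close_clusters(_assignment([0] * 30, m), m)


class TestPlantedStructureRecovery:
    @pytest.mark.parametrize("seed", range(3))
    def test_five_group_recovery_at_reduced_scale(self, seed):
        cfg = scaled_config(1500, seed=seed)
        studies, truth = simulate_summary_stats(cfg)
        m = harmonize_studies(studies)
        assign = cluster_snps(m)
        tr = truth.loc[m.snp_ids].to_numpy()
        sel = (assign.labels != 0) & (tr != "null")
        assert adjusted_rand_score(tr[sel], assign.labels[sel]) > 0.9
        sizes = np.unique(assign.labels[assign.labels != 0], return_counts=True)[1]
        assert sizes.min() >= 30
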