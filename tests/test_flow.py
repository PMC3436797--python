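import numpy as np
import pytest
import scipy.sparse as sp

from srmcl.flow import (
    RMCLParams,
    balanced_regularizer,
    canonical_flow_matrix,
    column_argmax,
    extract_clusters,
    flow_iterations,
    inflate_with_penalty,
    is_column_stochastic,
    prune,
    regularize,
    run_rmcl,
)
from srmcl.graph import Network

from _dense_reference import dense_flow_trajectory
from conftest import build_network, random_network


def csc(arr):
    return sp.csc_array(np.asarray(arr, dtype=float))


class TestCanonicalFlowMatrix:
    def test_single_edge(self, single_edge):
        M = canonical_flow_matrix(single_edge).toarray()
        assert np.allclose(M, [[0, 1], [1, 0]])

    def test_unweighted_triangle(self, triangle):
        M = canonical_flow_matrix(triangle).toarray()
        assert np.all(np.diag(M) == 0)
        assert np.allclose(M[M > 0], 0.5)

    def test_weighted_star(self):
        net = build_network([("a", "b", 1.0), ("a", "c", 3.0)])
        M = canonical_flow_matrix(net).toarray()
        j = net.index("a")
        assert M[net.index("b"), j] == pytest.approx(0.25)
        assert M[net.index("c"), j] == pytest.approx(0.75)

    def test_isolated_node_rejected(self):
        net = Network([("a", "b")], nodes=["a", "b", "lone"])
        with pytest.raises(ValueError, match="isolated"):
            canonical_flow_matrix(net)


class TestRegularize:
    def test_identity_neutral_on_both_sides(self, triangle):
        M_G = canonical_flow_matrix(triangle)
        I = csc(np.eye(3))
        assert np.allclose(regularize(I, M_G).toarray(), M_G.toarray())
        assert np.allclose(regularize(M_G, I).toarray(), M_G.toarray())

    def test_single_edge_two_step_walk_returns(self, single_edge):
        M_G = canonical_flow_matrix(single_edge)
        assert np.allclose(regularize(M_G, M_G).toarray(), np.eye(2))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            regularize(csc(np.eye(2)), csc(np.eye(3)))


class TestBalancedRegularizer:
    def test_b_zero_returns_canonical_exactly(self, two_triangles):
        M_G = canonical_flow_matrix(two_triangles)
        out = balanced_regularizer(M_G, np.arange(1, 7, dtype=float), 0.0)
        assert (out != M_G).nnz == 0

    def test_reweighting_and_renormalization(self):
        M_G = csc([[0.5, 0.0], [0.5, 1.0]])
        out = balanced_regularizer(M_G, np.array([4.0, 1.0]), 1.0).toarray()
        assert out[:, 0] == pytest.approx([0.2, 0.8])
        assert out[:, 1] == pytest.approx([0.0, 1.0])  # single entry renormalizes

    def test_nonpositive_mass_rejected(self):
        M_G = csc(np.eye(2))
        with pytest.raises(ValueError, match="positive"):
            balanced_regularizer(M_G, np.array([1.0, 0.0]), 0.5)


class TestInflateWithPenalty:
    def test_symmetric_column_unchanged(self):
        M = csc([[0.5, 0.5], [0.5, 0.5]])
        out = inflate_with_penalty(M, r=2.0).toarray()
        assert np.allclose(out, 0.5)

    def test_classic_inflation(self):
        M = csc([[0.8, 0.2], [0.2, 0.8]])
        out = inflate_with_penalty(M, r=2.0).toarray()
        assert out[0, 0] == pytest.approx(16 / 17)
        assert out[1, 0] == pytest.approx(1 / 17)

    def test_penalized_exponent(self):
        M = csc([[0.8, 0.2], [0.2, 0.8]])
        out = inflate_with_penalty(M, r=2.0, beta=1.25, counts=np.array([1, 0]))
        top, bottom = 0.8**2.5, 0.2**2
        assert out.toarray()[0, 0] == pytest.approx(top / (top + bottom))
        assert out.toarray()[1, 0] == pytest.approx(bottom / (top + bottom))

    def test_beta_one_ignores_counts(self):
        rng = np.random.default_rng(0)
        M = sp.random_array((12, 12), density=0.4, rng=rng) + sp.eye_array(12) * 0.1
        M = sp.csc_array(M / M.sum(axis=0))
        a = inflate_with_penalty(M, 2.0, beta=1.0, counts=np.zeros(12))
        b = inflate_with_penalty(M, 2.0, beta=1.0, counts=rng.integers(0, 9, 12))
        assert abs(a - b).max() < 1e-12

    def test_underflow_falls_back_to_point_mass(self):
        M = csc([[0.5, 0.5], [0.5, 0.5]])
        # count 700 at beta=1.25 drives both exponents past float range
        out = inflate_with_penalty(M, 2.0, beta=1.25, counts=np.array([700, 700]))
        assert np.allclose(out.toarray(), [[1.0, 1.0], [0.0, 0.0]])

    def test_penalty_weakly_decreases_penalized_row(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 10))
            M = rng.uniform(0.0, 1.0, (n, n)) * (rng.random((n, n)) < 0.6)
            M[0] += 0.05  # keep columns nonempty
            M = csc(M / M.sum(axis=0))
            counts = np.zeros(n)
            base = inflate_with_penalty(M, 2.0, 1.25, counts).toarray()
            i = int(rng.integers(n))
            counts[i] = rng.integers(1, 6)
            pen = inflate_with_penalty(M, 2.0, 1.25, counts).toarray()
            assert np.all(pen[i] <= base[i] + 1e-12)


class TestPrune:
    def test_zero_threshold_is_identity(self, triangle):
        M = canonical_flow_matrix(triangle)
        assert (prune(M, 0.0) != M).nnz == 0

    def test_drop_and_renormalize(self):
        M = csc([[0.98], [0.015], [0.005]])
        out = prune(M, 1e-2).toarray().ravel()
        assert out == pytest.approx([0.98 / 0.995, 0.015 / 0.995, 0.0])

    def test_column_max_always_kept(self):
        M = csc([[1.0]])
        assert prune(M, 10.0).toarray() == pytest.approx(np.array([[1.0]]))


class TestExtractClusters:
    def test_identity_gives_singletons(self):
        clusters, attractors = extract_clusters(csc(np.eye(3)))
        assert clusters == [{0}, {1}, {2}]
        assert attractors == {0, 1, 2}

    def test_two_triangles_split_into_components(self, two_triangles):
        clusters, _ = extract_clusters_of(two_triangles)
        named = {frozenset(two_triangles.nodes[i] for i in c) for c in clusters}
        assert named == {frozenset("abc"), frozenset("xyz")}

    def test_single_edge_converges_to_one_cluster(self, single_edge):
        clusters, attractors = run_rmcl(single_edge)
        assert clusters == [{0, 1}]
        assert len(attractors) == 1

    def test_argmax_ties_break_to_lower_index(self):
        M = csc([[0.5, 0.0], [0.5, 1.0]])
        assert list(column_argmax(M)) == [0, 1]


def extract_clusters_of(net):
    return run_rmcl(net, RMCLParams())


class TestRunRMCL:
    def test_two_cliques_joined_by_edge(self, two_cliques_bridge_edge):
        net = two_cliques_bridge_edge
        clusters, _ = run_rmcl(net)
        named = {frozenset(net.nodes[i] for i in c) for c in clusters}
        assert named == {
            frozenset(["a1", "a2", "a3", "a4"]),
            frozenset(["b1", "b2", "b3", "b4"]),
        }

    def test_single_clique_is_one_cluster(self):
        nodes = [f"k{i}" for i in range(5)]
        net = build_network(
            [(nodes[i], nodes[j]) for i in range(5) for j in range(i + 1, 5)]
        )
        clusters, _ = run_rmcl(net)
        assert clusters == [set(range(5))]

    def test_output_is_partition(self):
        for seed in range(5):
            net = random_network(25, 0.2, seed)
            clusters, _ = run_rmcl(net)
            all_nodes = sorted(i for c in clusters for i in c)
            assert all_nodes == list(range(net.n))

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            run_rmcl(Network())


class TestStochasticityConservation:
    def test_every_step_on_random_graphs(self):
        """Columns sum to 1 within 1e-10 after each regularize/inflate/prune."""
        params = RMCLParams(max_inner_iters=15)
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(5, 41))
            net = random_network(n, 0.25, seed=trial, weighted=bool(trial % 2))
            M_G = canonical_flow_matrix(net)
            assert is_column_stochastic(M_G)
            counts = rng.integers(0, 4, net.n)
            for M in flow_iterations(M_G, params, beta=1.25, counts=counts):
                assert is_column_stochastic(M)


class TestDenseOracleEquivalence:
    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("b", [0.0, 0.5])
    def test_sparse_trajectory_matches_naive_dense(self, seed, b):
        """Sparse pipeline equals the naive dense recurrence to 1e-9."""
        net = random_network(50, 0.15, seed)
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 3, net.n)
        params = RMCLParams(b=b, max_inner_iters=20)
        A = net.adjacency_matrix().toarray()
        M_G = canonical_flow_matrix(net)
        sparse_traj = list(flow_iterations(M_G, params, beta=1.25, counts=counts))
        assert sparse_traj
        ref_traj = dense_flow_trajectory(
            A, params.r, b, 1.25, counts, params.prune_threshold,
            max_steps=params.max_inner_iters,
            convergence_tol=params.convergence_tol,
        )
        assert len(sparse_traj) == len(ref_traj)
        for M, ref in zip(sparse_traj, ref_traj):
            assert np.abs(M.toarray() - ref).max() <= 1e-9
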