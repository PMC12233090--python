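import numpy as np
import pytest

from scgt.hybrid_graph import (
    UNKNOWN,
    BipartiteAdjacency,
    IntraAdjacency,
    assemble_hybrid_graph,
    estimate_query_types,
    filter_inter_connections,
    intra_mnn,
    mnn_pairs,
    pca_project,
    refine_query_types,
    rpca_project,
    score_reference_cells,
)
from scgt.io_preprocess import StandardizedMatrix


def brute_force_mutual_knn(a, b, K):
    """O(n^2) oracle: mutual K-nearest-neighbor pairs between two point sets."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    knn_ab = [set(np.argsort(d[i], kind="stable")[:K]) for i in range(len(a))]
    knn_ba = [set(np.argsort(d[:, j], kind="stable")[:K]) for j in range(len(b))]
    return {
        (i, j)
        for i in range(len(a))
        for j in knn_ab[i]
        if i in knn_ba[j]
    }


def brute_force_intra_mnn(x, K):
    x = np.asarray(x, float)
    n = len(x)
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    knn = [set(np.argsort(d[i], kind="stable")[:K]) for i in range(n)]
    return {
        (min(i, j), max(i, j))
        for i in range(n)
        for j in knn[i]
        if i in knn[j]
    }


class TestProjections:
    def test_pca_identical_cells_identical_embeddings(self):
        X = np.array([[1.0, 1.0, 4.0], [2.0, 2.0, 0.0]])  # cells 0 and 1 identical
        emb = pca_project(X, 1)
        np.testing.assert_allclose(emb[0], emb[1], atol=1e-12)

    def test_pca_full_rank_preserves_distances(self):
        X = np.eye(4)  # 4 one-hot cells (genes x cells)
        emb = pca_project(X, 3)
        d_orig = np.linalg.norm(X.T[:, None] - X.T[None, :], axis=2)
        d_emb = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        np.testing.assert_allclose(d_orig, d_emb, atol=1e-10)

    def test_pca_explained_variance_matches_svd(self, rng):
        X = rng.normal(size=(100, 80))  # genes x cells
        emb = pca_project(X, 5)
        S = X.T - X.T.mean(axis=0)
        sv = np.linalg.svd(S, compute_uv=False)
        var_expected = (sv[:5] ** 2) / 80
        var_emb = emb.var(axis=0)
        np.testing.assert_allclose(var_emb, var_expected, rtol=1e-8)

    def test_rpca_identical_inputs_coincide_up_to_sign(self, rng):
        X = rng.normal(size=(20, 15))
        (rr, qr), (rq, qq) = rpca_project(X, X, 3)
        np.testing.assert_allclose(rr, qr, atol=1e-10)
        np.testing.assert_allclose(np.abs(rr), np.abs(rq), atol=1e-8)

    def test_rpca_ref_projection_equals_pca_scores(self, rng):
        Xr = rng.normal(size=(50, 40))
        Xq = rng.normal(size=(50, 30))
        (ref_in_ref, _), _ = rpca_project(Xr, Xq, 10)
        scores = pca_project(Xr, 10)
        np.testing.assert_allclose(np.abs(ref_in_ref), np.abs(scores), atol=1e-8)

    def test_rank1_data_single_component(self):
        u = np.array([[1.0], [2.0]])
        w = np.array([0.0, 1.0, 3.0])
        X = u @ w[None, :]  # rank-1, 2 genes x 3 cells
        emb = pca_project(X, 1)
        d_orig = np.linalg.norm(X.T[:, None] - X.T[None, :], axis=2)
        d_emb = np.abs(emb[:, 0][:, None] - emb[:, 0][None, :])
        np.testing.assert_allclose(d_orig, d_emb, atol=1e-10)

    def test_too_many_components_rejected(self, rng):
        X = rng.normal(size=(5, 4))
        with pytest.raises(ValueError, match="n_components"):
            pca_project(X, 10)


class TestMnnPairs:
    def test_singletons_pair(self):
        arq = mnn_pairs(np.zeros((1, 2)), np.ones((1, 2)), K=1)
        assert arq.as_set() == {(0, 0)}

    def test_geometry_excludes_far_point(self):
        a = np.array([[0.0], [100.0]])
        b = np.array([[1.0]])
        arq = mnn_pairs(a, b, K=1)
        assert arq.as_set() == {(0, 0)}  # only the near a-point is mutual

    @pytest.mark.parametrize("seed,K", [(0, 3), (1, 3), (2, 5)])
    def test_matches_brute_force(self, seed, K):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(30, 2))
        b = rng.normal(size=(30, 2))
        arq = mnn_pairs(a, b, K)
        assert arq.as_set() == brute_force_mutual_knn(a, b, K)

    def test_k_clipped_with_warning(self):
        a = np.zeros((3, 1))
        b = np.array([[0.1], [0.2]])
        with pytest.warns(UserWarning, match="clipped"):
            mnn_pairs(a, b, K=10)


class TestIntraMnn:
    def test_singleton_empty_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            adj = intra_mnn(np.zeros((1, 2)), K=1)
        assert len(adj) == 0

    def test_two_points_one_edge(self):
        adj = intra_mnn(np.array([[0.0], [1.0]]), K=1)
        assert adj.as_set() == {(0, 1)}

    @pytest.mark.parametrize("seed,K", [(0, 3), (3, 4)])
    def test_matches_brute_force(self, seed, K):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(40, 2))
        adj = intra_mnn(x, K)
        assert adj.as_set() == brute_force_intra_mnn(x, K)

    def test_no_self_loops(self, rng):
        x = rng.normal(size=(25, 3))
        adj = intra_mnn(x, 5)
        assert all(i != j for i, j in adj.pairs)


class TestScoring:
    def test_pure_neighborhood_scores_one(self):
        arr = IntraAdjacency(pairs=[(0, 1), (0, 2)], n_cells=3)
        scores = score_reference_cells(arr, ["T", "T", "T"])
        assert scores.u[0] == 1.0

    def test_isolated_cell_scores_zero(self):
        arr = IntraAdjacency(pairs=[(0, 1)], n_cells=3)
        scores = score_reference_cells(arr, ["T", "T", "B"])
        assert scores.u[2] == 0.0

    def test_half_matching_neighbors(self):
        arr = IntraAdjacency(pairs=[(0, 1), (0, 2), (0, 3), (0, 4)], n_cells=5)
        scores = score_reference_cells(arr, ["T", "T", "T", "B", "B"])
        assert scores.u[0] == 0.5


class TestEstimateQueryTypes:
    def test_single_scored_neighbor(self):
        arq = BipartiteAdjacency(pairs=[(0, 0)], n_ref=1, n_query=1)
        from scgt.hybrid_graph import ReferenceScores

        kq = estimate_query_types(arq, ["T"], ReferenceScores(u=np.array([0.8])))
        assert kq[0] == "T"

    def test_all_zero_scores_unknown(self):
        from scgt.hybrid_graph import ReferenceScores

        arq = BipartiteAdjacency(pairs=[(0, 0), (1, 0)], n_ref=2, n_query=2)
        kq = estimate_query_types(arq, ["T", "B"], ReferenceScores(u=np.zeros(2)))
        assert kq[0] == UNKNOWN
        assert kq[1] == UNKNOWN  # no neighbors at all

    def test_argmax_over_type_mass(self):
        from scgt.hybrid_graph import ReferenceScores

        arq = BipartiteAdjacency(pairs=[(0, 0), (1, 0), (2, 0)], n_ref=3, n_query=1)
        u = ReferenceScores(u=np.array([0.7, 0.6, 0.9]))
        kq = estimate_query_types(arq, ["A", "A", "B"], u)
        assert kq[0] == "A"  # 1.3 vs 0.9


class TestRefineQueryTypes:
    def test_chain_within_four_hops(self):
        aqq = IntraAdjacency(pairs=[(0, 1), (1, 2), (2, 3), (3, 4)], n_cells=5)
        kq = ["X", "T", "T", "T", "T"]
        out = refine_query_types(aqq, kq, hops=4, type_order=["T", "X"])
        assert out[0] == "T"

    def test_isolated_falls_back(self):
        aqq = IntraAdjacency(pairs=[(1, 2)], n_cells=3)
        out = refine_query_types(aqq, ["T", "A", "A"], hops=4, type_order=["A", "T"])
        assert out[0] == "T"

    def test_star_plurality(self):
        pairs = [(0, j) for j in range(1, 6)]
        aqq = IntraAdjacency(pairs=pairs, n_cells=6)
        kq = ["X", "A", "A", "A", "B", "B"]
        out = refine_query_types(aqq, kq, hops=1, type_order=["A", "B", "X"])
        assert out[0] == "A"

    def test_unknown_plurality_propagates(self):
        # a mostly-Unknown neighborhood marks the cell as reference-absent
        pairs = [(0, 1), (0, 2), (0, 3)]
        aqq = IntraAdjacency(pairs=pairs, n_cells=4)
        kq = ["B", UNKNOWN, UNKNOWN, "A"]
        out = refine_query_types(aqq, kq, hops=1, type_order=["A", "B"])
        assert out[0] == UNKNOWN

    def test_tie_between_type_and_unknown_keeps_type(self):
        pairs = [(0, 1), (0, 2)]
        aqq = IntraAdjacency(pairs=pairs, n_cells=3)
        kq = ["B", UNKNOWN, "A"]
        out = refine_query_types(aqq, kq, hops=1, type_order=["A", "B"])
        assert out[0] == "A"

    def test_hops_zero_reduces_to_estimate(self):
        aqq = IntraAdjacency(pairs=[(0, 1), (1, 2)], n_cells=3)
        kq = ["A", "B", "B"]
        out = refine_query_types(aqq, kq, hops=0, type_order=["A", "B"])
        assert list(out) == ["A", "B", "B"]


class TestFilterInterConnections:
    def test_all_agree_identity(self):
        arq = BipartiteAdjacency(pairs=[(0, 0), (1, 1)], n_ref=2, n_query=2)
        out = filter_inter_connections(arq, ["T", "B"], ["T", "B"])
        assert out.as_set() == arq.as_set()

    def test_all_disagree_empty_with_warning(self):
        arq = BipartiteAdjacency(pairs=[(0, 0), (1, 1)], n_ref=2, n_query=2)
        with pytest.warns(UserWarning, match="filtered out"):
            out = filter_inter_connections(arq, ["T", "B"], ["B", "T"])
        assert len(out) == 0

    def test_mixed_keeps_matching_subset(self):
        pairs = [(0, 0), (0, 1), (1, 2), (1, 3), (0, 4)]
        arq = BipartiteAdjacency(pairs=pairs, n_ref=2, n_query=5)
        kq_prime = ["T", "B", "B", UNKNOWN, "T"]
        out = filter_inter_connections(arq, ["T", "B"], kq_prime)
        assert out.as_set() == {(0, 0), (1, 2), (0, 4)}

    def test_monotone_shrinkage(self, rng):
        pairs = np.column_stack([rng.integers(0, 10, 50), rng.integers(0, 12, 50)])
        arq = BipartiteAdjacency(pairs=pairs, n_ref=10, n_query=12)
        labels = rng.choice(["A", "B"], size=10)
        kq_prime = rng.choice(["A", "B", UNKNOWN], size=12)
        out = filter_inter_connections(arq, labels, kq_prime)
        assert len(out) <= len(arq)
        assert out.as_set() <= arq.as_set()


class TestAssembleHybridGraph:
    def test_empty_inputs(self):
        g = assemble_hybrid_graph(
            BipartiteAdjacency(pairs=np.empty((0, 2)), n_ref=2, n_query=3),
            IntraAdjacency(pairs=np.empty((0, 2)), n_cells=2),
            IntraAdjacency(pairs=np.empty((0, 2)), n_cells=3),
        )
        assert g.n_nodes == 5 and len(g) == 0

    def test_offsets_and_provenance(self):
        g = assemble_hybrid_graph(
            BipartiteAdjacency(pairs=[(0, 0)], n_ref=2, n_query=3),
            IntraAdjacency(pairs=[(0, 1)], n_cells=2),
            IntraAdjacency(pairs=[(1, 2)], n_cells=3),
        )
        assert len(g) == 3
        by_tag = {tag: tuple(edge) for edge, tag in zip(g.edges, g.provenance)}
        assert by_tag["inter"] == (0, 2)       # query 0 offset by n_ref=2
        assert by_tag["intra_ref"] == (0, 1)
        assert by_tag["intra_query"] == (3, 4)

    def test_sparse_is_symmetric(self):
        g = assemble_hybrid_graph(
            BipartiteAdjacency(pairs=[(1, 0)], n_ref=2, n_query=2),
            IntraAdjacency(pairs=[(0, 1)], n_cells=2),
            IntraAdjacency(pairs=[(0, 1)], n_cells=2),
        )
        A = g.to_sparse().toarray()
        np.testing.assert_array_equal(A, A.T)
        assert A.sum() == 6  # 3 undirected edges
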