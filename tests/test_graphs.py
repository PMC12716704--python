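import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from magnet.config import ModelConfig
from magnet.data import LigandReceptorDB, SpatialDataset, normalize_expression
from magnet.graphs import (
    GraphError,
    build_lr_graph,
    build_similarity_graph,
    build_spatial_graph,
    conditional_similarity,
    infer_cell_grns,
    lr_pair_score,
    mean_nn_distance,
    permutation_pvalue,
    score_lr_pairs,
    select_genes_per_cell,
    spatial_kernel,
    symmetrize_similarity,
    topk_sparsify,
)


class TestSpatialKernel:
    def test_two_cells_closed_form(self):
        W = spatial_kernel(np.array([[0.0, 0.0], [3.0, 0.0]]))
        assert W[0, 1] == pytest.approx(np.exp(-0.5))
        assert W[1, 0] == pytest.approx(np.exp(-0.5))
        assert W[0, 0] == 0

    def test_coincident_cells_epsilon_guard(self):
        W = spatial_kernel(np.zeros((2, 2)))
        assert W[0, 1] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        pts = rng.random((6, 2)) * 10
        W = spatial_kernel(pts, m=1)
        d = cdist(pts, pts)
        for i in range(6):
            sigma = np.min(np.delete(d[i], i))
            for j in range(6):
                expected = 0.0 if i == j else np.exp(-d[i, j] ** 2 / (2 * sigma**2))
                assert W[i, j] == pytest.approx(expected, abs=1e-10)

    def test_single_cell_rejected(self):
        with pytest.raises(GraphError):
            spatial_kernel(np.zeros((1, 2)))


class TestTopkSparsify:
    def test_k_at_least_n_gives_complete_digraph(self, rng):
        W = rng.random((5, 5)) + 0.1
        A = topk_sparsify(W, k=10).toarray()
        assert np.array_equal(A, 1 - np.eye(5))

    def test_keeps_argmax_for_k1(self):
        W = np.array([[0, 0.9, 0.1, 0.5]] * 4, dtype=float)
        A = topk_sparsify(W, 1).toarray()
        assert A[0, 1] == 1 and A[0].sum() == 1

    def test_matches_sort_oracle_with_tie_rule(self, rng):
        W = np.round(rng.random((8, 8)), 1)  # rounding forces ties
        k = 3
        A = topk_sparsify(W, k).toarray()
        for i in range(8):
            w = W[i].copy()
            w[i] = 0
            cand = [(j, w[j]) for j in range(8) if w[j] > 0]
            cand.sort(key=lambda t: (-t[1], t[0]))
            expected = {j for j, _ in cand[:k]}
            assert set(np.flatnonzero(A[i])) == expected

    def test_rows_with_no_positive_weight_stay_empty(self):
        W = np.zeros((3, 3))
        W[0, 1] = 1.0
        A = topk_sparsify(W, 2).toarray()
        assert A.sum() == 1

    def test_structural_invariants_random(self, rng):
        A = topk_sparsify(rng.random((12, 12)), 4).toarray()
        assert np.all(np.diag(A) == 0)
        assert np.all(A.sum(axis=1) <= 4)


class TestSpatialGraph:
    def test_two_cell_dataset_mutual_edge(self):
        ds = SpatialDataset(
            expr=np.ones((2, 2)), coords=np.array([[0.0, 0], [1, 0]]),
            gene_names=["a", "b"], cell_ids=["c0", "c1"],
        )
        g = build_spatial_graph(ds, ModelConfig())
        assert np.array_equal(g.A.toarray(), [[0, 1], [1, 0]])

    def test_three_collinear_cells_neighbor_ranking(self):
        ds = SpatialDataset(
            expr=np.ones((3, 2)),
            coords=np.array([[0.0, 0], [1, 0], [3, 0]]),
            gene_names=["a", "b"], cell_ids=list("abc"),
        )
        g = build_spatial_graph(ds, ModelConfig(k_neighbors=5))
        A = g.A.toarray()
        assert A[1, 0] == 1 and A[1, 2] == 1  # middle keeps both
        # endpoint kernels rank the near neighbour strictly higher
        assert g.W[0, 1] > g.W[0, 2]
        assert g.W[2, 1] > g.W[2, 0]

    def test_default_k_is_five(self):
        assert ModelConfig().k_neighbors == 5


class TestConditionalSimilarity:
    def test_within_rho_gives_one(self):
        assert conditional_similarity(0.5, rho_i=1.0, sigma_i=2.0) == pytest.approx(1.0)

    def test_one_sigma_past_rho_gives_inv_e(self):
        p = conditional_similarity(3.0, rho_i=1.0, sigma_i=2.0, eps=0.0)
        assert p == pytest.approx(np.exp(-1))

    def test_random_instance_matches_formula(self, rng):
        d, rho, sig = rng.random(3) * 5
        p = conditional_similarity(d, rho, sig)
        assert p == pytest.approx(np.exp(-max(0, d - rho) / (sig + 1e-8)))


class TestSymmetrize:
    @pytest.mark.parametrize(
        "p,q,expected", [(1.0, 0.3, 1.0), (0.0, 0.0, 0.0), (0.5, 0.5, 0.75)]
    )
    def test_closed_forms(self, p, q, expected):
        assert symmetrize_similarity(p, q) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        p=st.floats(0, 1, allow_nan=False),
        q=st.floats(0, 1, allow_nan=False),
        q2=st.floats(0, 1, allow_nan=False),
    )
    def test_commutative_monotone_bounded(self, p, q, q2):
        a = symmetrize_similarity(p, q)
        assert a == pytest.approx(symmetrize_similarity(q, p))
        assert 0 <= a <= 1
        lo, hi = min(q, q2), max(q, q2)
        assert symmetrize_similarity(p, lo) <= symmetrize_similarity(p, hi) + 1e-12


class TestSimilarityGraph:
    def test_symmetric_weights(self, small_ds):
        ds, *_ = small_ds
        g = build_similarity_graph(ds, ModelConfig())
        assert np.allclose(g.W, g.W.T)

    def test_identical_profiles_get_similarity_one(self):
        rng = np.random.default_rng(0)
        expr = rng.random((6, 5)) * 5
        expr[3] = expr[0]  # duplicate profile
        ds = SpatialDataset(
            expr=expr, coords=rng.random((6, 2)),
            gene_names=[f"g{i}" for i in range(5)],
            cell_ids=[f"c{i}" for i in range(6)],
        )
        g = build_similarity_graph(ds, ModelConfig(k_neighbors=2))
        assert g.W[0, 3] == pytest.approx(1.0)

    def test_two_cluster_within_exceeds_between(self):
        from magnet.simulate import SimulationSpec, simulate_dataset

        spec = SimulationSpec(n_cells=10, n_genes=20, n_clusters=2, n_lr_pairs=1,
                              center_distance=4.0, seed=2)
        ds, truth = simulate_dataset(spec)
        g = build_similarity_graph(ds, ModelConfig(k_neighbors=3))
        lab = np.asarray(truth.labels)
        same = (lab[:, None] == lab[None, :]) & ~np.eye(10, dtype=bool)
        assert g.W[same].mean() > g.W[~(lab[:, None] == lab[None, :])].mean()

    def test_too_few_cells_rejected(self):
        ds = SpatialDataset(
            expr=np.ones((2, 2)), coords=np.zeros((2, 2)),
            gene_names=["a", "b"], cell_ids=["c0", "c1"],
        )
        with pytest.raises(GraphError):
            build_similarity_graph(ds, ModelConfig())


class TestLRScores:
    def make_toy(self, n=4, g=4, seed=0):
        rng = np.random.default_rng(seed)
        return SpatialDataset(
            expr=rng.random((n, g)) * 10,
            coords=rng.random((n, 2)) * 3,
            gene_names=[f"g{i}" for i in range(g)],
            cell_ids=[f"c{i}" for i in range(n)],
        )

    def test_zero_ligand_zeroes_sender_row(self):
        ds = self.make_toy()
        en = normalize_expression(ds.expr, "minmax_per_gene")
        en[2, 0] = 0.0
        S = lr_pair_score(en, ds.coords, (0, 1), sigma_global=1.0)
        assert np.all(S[2] == 0)

    def test_unit_expression_zero_distance(self):
        en = np.ones((2, 2))
        S = lr_pair_score(en, np.zeros((2, 2)), (0, 1), sigma_global=1.0)
        assert S[0, 1] == pytest.approx(1.0)

    def test_matches_triple_loop_oracle(self):
        ds = self.make_toy()
        en = normalize_expression(ds.expr, "minmax_per_gene")
        sigma = 0.7
        S = lr_pair_score(en, ds.coords, (1, 3), sigma)
        d = cdist(ds.coords, ds.coords)
        for i in range(4):
            for j in range(4):
                exp = 0.0 if i == j else en[i, 1] * en[j, 3] * np.exp(
                    -d[i, j] ** 2 / (2 * sigma**2)
                )
                assert S[i, j] == pytest.approx(exp, abs=1e-12)

    def test_pvalue_add_one_convention(self):
        ds = self.make_toy()
        en = normalize_expression(ds.expr, "minmax_per_gene")
        # huge observed beats every permutation
        p = permutation_pvalue(1e9, en, (0, 1), ds.coords, n_perm=99, rng=1)
        assert p == pytest.approx(0.01)

    def test_zero_observed_gives_p_one(self):
        ds = self.make_toy()
        en = normalize_expression(ds.expr, "minmax_per_gene")
        p = permutation_pvalue(0.0, en, (0, 1), ds.coords, n_perm=50, rng=1)
        assert p == pytest.approx(1.0)

    def test_monte_carlo_converges_to_exhaustive(self):
        """With 4 cells the receptor vector has 24 permutations; the
        Monte-Carlo p must approach the exhaustive-enumeration p."""
        ds = self.make_toy(seed=3)
        en = normalize_expression(ds.expr, "minmax_per_gene")
        sigma = mean_nn_distance(ds.coords)
        d = cdist(ds.coords, ds.coords)
        K = np.exp(-(d**2) / (2 * sigma**2))
        np.fill_diagonal(K, 0)
        lig, rec = en[:, 0], en[:, 1]
        obs = float(lig @ K @ rec)
        null = [
            float(lig @ K @ rec[list(perm)])
            for perm in itertools.permutations(range(4))
        ]
        exact = np.mean([nv >= obs - 1e-12 for nv in null])
        p_mc = permutation_pvalue(obs, en, (0, 1), ds.coords, n_perm=4000, rng=0)
        assert p_mc == pytest.approx(exact, abs=0.03)

    def test_aggregate_is_sum_of_significant_pair_scores(self, small_ds):
        ds, _, db, _ = small_ds
        table = score_lr_pairs(ds, db, alpha=0.05, n_perm=40, seed=1)
        en = normalize_expression(ds.expr, "minmax_per_gene")
        sigma = mean_nn_distance(ds.coords)
        expected = np.zeros((ds.n_cells, ds.n_cells))
        for pair, sig in zip(table.pair_indices, table.significant):
            if sig:
                expected += lr_pair_score(en, ds.coords, pair, sigma)
        assert np.allclose(table.aggregate, expected, atol=1e-12)

    def test_no_mappable_pairs_is_error(self, small_ds):
        ds, *_ = small_ds
        with pytest.raises(GraphError, match="toy"):
            build_lr_graph(ds, LigandReceptorDB(pairs=[("NOPE", "NADA")]),
                           ModelConfig())


class TestGeneSelection:
    def make_ds(self):
        rng = np.random.default_rng(1)
        expr = rng.random((3, 44))
        expr[:, 40] = 5.0  # strong non-LR genes
        expr[:, 41] = 6.0
        names = ["L1", "R1", "L2", "R2"] + [f"g{i}" for i in range(40)]
        return SpatialDataset(
            expr=expr, coords=rng.random((3, 2)),
            gene_names=names, cell_ids=["a", "b", "c"],
        )

    def test_whole_panel_when_k_equals_g(self, small_ds):
        ds, _, db, _ = small_ds
        gm = select_genes_per_cell(ds, db, ds.n_genes)
        assert all(sorted(g) == list(range(ds.n_genes)) for g in gm)

    def test_lr_pairs_first_then_top_expressed(self):
        ds = self.make_ds()
        db = LigandReceptorDB(pairs=[("L1", "R1"), ("L2", "R2")])
        gm = select_genes_per_cell(ds, db, k_genes=6)
        for i, sel in enumerate(gm):
            assert set(sel[:4]) == {0, 1, 2, 3}  # both whole pairs kept
            # remaining two slots: highest-expressed non-LR genes
            rest = [j for j in range(44) if j not in {0, 1, 2, 3}]
            rest.sort(key=lambda j: (-ds.expr[i, j], j))
            assert sel[4:] == rest[:2]

    def test_partial_pair_never_admitted(self):
        ds = self.make_ds()
        db = LigandReceptorDB(pairs=[("L1", "R1"), ("L2", "R2")])
        gm = select_genes_per_cell(ds, db, k_genes=3)
        for sel in gm:
            # one whole pair + one filler; the second pair would overflow
            assert len(sel) == 3
            assert {0, 1} <= set(sel) or {2, 3} <= set(sel)
            assert not ({0, 1} <= set(sel) and {2, 3} <= set(sel))

    def test_k_genes_exceeding_g_is_error(self, small_ds):
        ds, _, db, _ = small_ds
        with pytest.raises(GraphError):
            select_genes_per_cell(ds, db, ds.n_genes + 1)


class TestGRN:
    def test_perfectly_correlated_genes_get_edge(self):
        rng = np.random.default_rng(0)
        base = rng.random(8)
        expr = np.c_[base, base * 2, rng.random(8)] + 0.0
        ds = SpatialDataset(
            expr=expr, coords=rng.random((8, 2)),
            gene_names=["a", "b", "c"], cell_ids=[f"c{i}" for i in range(8)],
        )
        gm = [[0, 1, 2]] * 8
        gg = infer_cell_grns(ds, gm, r_min=0.99, n_neighbors=4)
        A = gg.A_g.toarray()
        assert A[0, 1] == 1  # a-b perfectly correlated within block 0

    def test_block_diagonal_contract(self, small_ds):
        ds, _, db, _ = small_ds
        gm = select_genes_per_cell(ds, db, 8)
        gg = infer_cell_grns(ds, gm, lr_db=db)
        coo = gg.A_g.tocoo()
        assert np.all(coo.row // 8 == coo.col // 8)

    def test_independent_genes_near_empty_block(self):
        """With many neighbourhood samples, |r| of independent genes stays
        below 0.6 for most pairs."""
        rng = np.random.default_rng(5)
        n, g = 40, 6
        ds = SpatialDataset(
            expr=rng.random((n, g)),
            coords=rng.random((n, 2)),
            gene_names=[f"g{i}" for i in range(g)],
            cell_ids=[f"c{i}" for i in range(n)],
        )
        gm = [list(range(g))] * n
        gg = infer_cell_grns(ds, gm, r_min=0.6, n_neighbors=30)
        density = gg.A_g.nnz / (n * g * (g - 1))
        assert density < 0.10

    def test_external_mtx_cross_block_entries_rejected(self, tmp_path):
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        rng = np.random.default_rng(0)
        ds = SpatialDataset(
            expr=rng.random((2, 4)), coords=rng.random((2, 2)),
            gene_names=list("abcd"), cell_ids=["x", "y"],
        )
        gm = [[0, 1], [2, 3]]
        bad = coo_matrix(([1.0], ([0], [3])), shape=(4, 4))  # cell0 -> cell1
        path = tmp_path / "grn.mtx"
        mmwrite(str(path), bad)
        with pytest.raises(GraphError, match="cross-cell"):
            infer_cell_grns(ds, gm, provider="external_mtx", external_path=str(path))
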