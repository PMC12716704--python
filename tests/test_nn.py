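import numpy as np
import pytest
from scipy import sparse
from scipy.special import erf

from magnet.autodiff import Parameter, Tensor
from magnet.nn import (
    attention_pool,
    cross_attention_branch,
    gated_fusion,
    gcn_encode,
    gcn_layer,
    init_branch_params,
    layer_norm,
    load_params,
    normalize_adjacency,
    save_params,
    softmax_rows,
    transformer_block,
)


def dense_gcn_oracle(A, X, W, act):
    """Brute-force dense evaluation of the renormalized propagation rule."""
    A_t = A + np.eye(len(A))
    d = A_t.sum(axis=1)
    D = np.diag(d**-0.5)
    out = D @ A_t @ D @ X @ W
    return np.maximum(out, 0) if act == "relu" else out


class TestGCN:
    def test_single_node_identity(self):
        A = sparse.csr_matrix((1, 1))
        out = gcn_layer(normalize_adjacency(A), Tensor(np.array([[2.0, 3.0]])),
                        Tensor(np.eye(2)), "linear")
        assert np.allclose(out.data, [[2.0, 3.0]])

    def test_zero_weights_give_zero(self, rng):
        A = sparse.csr_matrix(np.ones((3, 3)) - np.eye(3))
        out = gcn_layer(normalize_adjacency(A), Tensor(rng.normal(size=(3, 4))),
                        Tensor(np.zeros((4, 2))), "relu")
        assert np.all(out.data == 0)

    def test_path_graph_matches_dense_oracle(self, rng):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1
        X = rng.normal(size=(3, 5))
        W = rng.normal(size=(5, 2))
        out = gcn_layer(normalize_adjacency(A), Tensor(X), Tensor(W), "relu")
        assert np.allclose(out.data, dense_gcn_oracle(A, X, W, "relu"), atol=1e-10)

    def test_ring_graph_normalization_constant_row_sums(self):
        n = 8
        A = np.zeros((n, n))
        for i in range(n):
            A[i, (i + 1) % n] = A[(i + 1) % n, i] = 1
        P = normalize_adjacency(A).toarray()
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_encode_composes_two_layers(self, rng):
        A = (rng.random((6, 6)) > 0.5).astype(float)
        np.fill_diagonal(A, 0)
        A = np.maximum(A, A.T)
        X = rng.normal(size=(6, 7))
        W0, W1 = rng.normal(size=(7, 5)), rng.normal(size=(5, 3))
        An = normalize_adjacency(A)
        out = gcn_encode(An, Tensor(X), Tensor(W0), Tensor(W1))
        h = dense_gcn_oracle(A, X, W0, "relu")
        expected = dense_gcn_oracle(A, h, W1, "linear")
        assert np.allclose(out.data, expected, atol=1e-10)

    def test_zero_input_features_give_zero_output(self, rng):
        A = np.maximum((rng.random((4, 4)) > 0.5).astype(float), 0)
        An = normalize_adjacency(A)
        out = gcn_encode(An, Tensor(np.zeros((4, 6))),
                         Tensor(rng.normal(size=(6, 5))),
                         Tensor(rng.normal(size=(5, 3))))
        assert np.all(out.data == 0)

    def test_block_permutation_equivariance(self, rng):
        """The block-diagonal gene graph processes cells independently."""
        k, n = 3, 4
        blocks = [np.maximum((rng.random((k, k)) > 0.4), 0).astype(float)
                  for _ in range(n)]
        for b in blocks:
            np.fill_diagonal(b, 0)
        A = sparse.block_diag(blocks, format="csr")
        X = rng.normal(size=(n * k, 5))
        W0, W1 = rng.normal(size=(5, 6)), rng.normal(size=(6, 2))
        out = gcn_encode(normalize_adjacency(A), Tensor(X), Tensor(W0), Tensor(W1)).data
        perm = np.array([2, 0, 3, 1])
        Ap = sparse.block_diag([blocks[p] for p in perm], format="csr")
        node_perm = np.concatenate([np.arange(p * k, (p + 1) * k) for p in perm])
        out_p = gcn_encode(normalize_adjacency(Ap), Tensor(X[node_perm]),
                           Tensor(W0), Tensor(W1)).data
        assert np.allclose(out_p, out[node_perm], atol=1e-10)


class TestAttentionPool:
    def pool_params(self, rng, d=4, hid=3):
        return (Tensor(rng.normal(size=(d, hid))), Tensor(np.zeros((1, hid))),
                Tensor(rng.normal(size=(hid, 1))), Tensor(np.zeros((1, 1))))

    def test_k1_returns_the_lone_embedding(self, rng):
        Zg = Tensor(rng.normal(size=(3, 4)))
        out = attention_pool(Zg, 3, 1, *self.pool_params(rng))
        assert np.allclose(out.data, Zg.data)

    def test_identical_embeddings_convexity(self, rng):
        row = rng.normal(size=4)
        Zg = Tensor(np.tile(row, (6, 1)))  # 2 cells x 3 genes, all equal
        out = attention_pool(Zg, 2, 3, *self.pool_params(rng))
        assert np.allclose(out.data, np.tile(row, (2, 1)), atol=1e-12)

    def test_softmax_weights_match_hand_computation(self):
        # scorer returns logits (ln 3, 0) for the two genes of one cell
        Zg = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
        W1 = Tensor(np.eye(2))
        b1 = Tensor(np.zeros((1, 2)))
        # tanh then linear: choose W2 so logits = (ln 3, 0)
        t = np.tanh(1.0)
        W2 = Tensor(np.array([[np.log(3) / t], [0.0]]))
        b2 = Tensor(np.zeros((1, 1)))
        out, beta = attention_pool(Zg, 1, 2, W1, b1, W2, b2, return_weights=True)
        assert np.allclose(beta, [[0.75, 0.25]])
        assert np.allclose(out.data, 0.75 * Zg.data[0] + 0.25 * Zg.data[1])

    def test_output_in_convex_hull_per_coordinate(self, rng):
        Zg = Tensor(rng.normal(size=(12, 4)))
        out = attention_pool(Zg, 3, 4, *self.pool_params(rng)).data
        E = Zg.data.reshape(3, 4, 4)
        assert np.all(out <= E.max(axis=1) + 1e-12)
        assert np.all(out >= E.min(axis=1) - 1e-12)


class TestCrossAttention:
    def make_params(self, rng, d=4, heads=1):
        params = {}
        init_branch_params(rng, params, "b", d, heads)
        return params

    def test_two_cell_single_head_matches_hand_softmax(self, rng):
        d = 2
        params = {
            "b_Wq0": Tensor(np.eye(d)),
            "b_Wk0": Tensor(np.eye(d)),
            "b_Wv0": Tensor(np.eye(d)),
            "b_Wo": Tensor(np.eye(d)),
        }
        Zc = Tensor(np.array([[1.0, 0.0], [0.0, 2.0]]))
        Zg = Tensor(np.array([[1.0, 1.0], [2.0, 0.0]]))
        out, maps = cross_attention_branch(Zc, Zg, params, "b", 1,
                                           return_attention=True)
        logits = (Zc.data @ Zg.data.T) / np.sqrt(d)
        alpha = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        assert np.allclose(maps[0], alpha, atol=1e-12)
        assert np.allclose(out.data, alpha @ Zg.data, atol=1e-12)

    def test_attention_rows_sum_to_one_per_head(self, rng):
        params = self.make_params(rng, d=8, heads=2)
        Zc, Zg = Tensor(rng.normal(size=(5, 8))), Tensor(rng.normal(size=(5, 8)))
        _, maps = cross_attention_branch(Zc, Zg, params, "b", 2,
                                         return_attention=True)
        for m in maps:
            assert np.allclose(m.sum(axis=1), 1.0)

    def test_identical_gene_rows_give_constant_output(self, rng):
        params = self.make_params(rng, d=4)
        Zg = Tensor(np.tile(rng.normal(size=4), (6, 1)))
        Zc = Tensor(rng.normal(size=(6, 4)))
        out = cross_attention_branch(Zc, Zg, params, "b", 1)
        # value constancy: all query cells receive the same attended vector
        assert np.allclose(out.data - out.data[0], 0, atol=1e-12)


class TestTransformerBlock:
    def test_zero_ffn_reduces_to_layernorm_residual(self, rng):
        d = 4
        params = {}
        init_branch_params(rng, params, "b", d, 1)
        params["b_W1"] = Tensor(np.zeros((d, 4 * d)))
        params["b_W2"] = Tensor(np.zeros((4 * d, d)))
        Zc, Za = Tensor(rng.normal(size=(3, d))), Tensor(rng.normal(size=(3, d)))
        out = transformer_block(Za, Zc, params, "b")
        expected = layer_norm(Zc + Za, params["b_ln_g"], params["b_ln_b"]).data
        assert np.allclose(out.data, expected, atol=1e-12)

    def test_zero_variance_row_stays_finite(self, rng):
        d = 4
        params = {}
        init_branch_params(rng, params, "b", d, 1)
        out = transformer_block(Tensor(np.zeros((2, d))), Tensor(np.ones((2, d))),
                                params, "b")
        assert np.all(np.isfinite(out.data))

    def test_matches_step_by_step_oracle(self, rng):
        d = 8
        params = {}
        init_branch_params(rng, params, "b", d, 1)
        for key in ("b_W1", "b_W2", "b_b1", "b_b2", "b_ln_g", "b_ln_b"):
            params[key] = Tensor(rng.normal(size=params[key].data.shape))
        Zc, Za = rng.normal(size=(2, d)), rng.normal(size=(2, d))
        out = transformer_block(Tensor(Za), Tensor(Zc), params, "b").data
        x = Zc + Za
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        y = (x - mu) / np.sqrt(var + 1e-5)
        y = y * params["b_ln_g"].data + params["b_ln_b"].data
        h = y @ params["b_W1"].data + params["b_b1"].data
        g = 0.5 * h * (1 + erf(h / np.sqrt(2)))
        expected = y + (g @ params["b_W2"].data + params["b_b2"].data)
        assert np.allclose(out, expected, atol=1e-6)


class TestGatedFusion:
    def gate_params(self, rng, d=4, nb=3, hid=2):
        return {
            "gate_W1": Tensor(rng.normal(size=(nb * d, hid))),
            "gate_b1": Tensor(np.zeros((1, hid))),
            "gate_W2": Tensor(rng.normal(size=(hid, nb))),
            "gate_b2": Tensor(np.zeros((1, nb))),
        }

    def test_equal_logits_give_arithmetic_mean(self, rng):
        params = self.gate_params(rng)
        params["gate_W2"] = Tensor(np.zeros((2, 3)))  # all logits 0
        Zs = [Tensor(rng.normal(size=(4, 4))) for _ in range(3)]
        out, w = gated_fusion(Zs, params, return_weights=True)
        assert np.allclose(w, 1 / 3)
        assert np.allclose(out.data, sum(z.data for z in Zs) / 3)

    def test_identical_branches_invariant_to_gate(self, rng):
        params = self.gate_params(rng)
        Z = Tensor(rng.normal(size=(5, 4)))
        out = gated_fusion([Z, Z, Z], params)
        assert np.allclose(out.data, Z.data, atol=1e-12)

    def test_fixed_logits_softmax_arithmetic(self):
        # single cell, logits (ln 2, 0, 0) -> weights (0.5, 0.25, 0.25)
        params = {
            "gate_W1": Tensor(np.zeros((12, 2))),
            "gate_b1": Tensor(np.zeros((1, 2))),
            "gate_W2": Tensor(np.zeros((2, 3))),
            "gate_b2": Tensor(np.array([[np.log(2), 0.0, 0.0]])),
        }
        Zs = [Tensor(np.full((1, 4), v)) for v in (1.0, 2.0, 3.0)]
        out, w = gated_fusion(Zs, params, return_weights=True)
        assert np.allclose(w, [[0.5, 0.25, 0.25]])
        assert np.allclose(out.data, 0.5 * 1 + 0.25 * 2 + 0.25 * 3)

    def test_gate_weights_are_probability_simplex(self, rng):
        params = self.gate_params(rng)
        Zs = [Tensor(rng.normal(size=(6, 4))) for _ in range(3)]
        _, w = gated_fusion(Zs, params, return_weights=True)
        assert np.all(w >= 0)
        assert np.allclose(w.sum(axis=1), 1.0)


def test_softmax_rows_is_row_stochastic(rng):
    x = Tensor(rng.normal(size=(5, 7)) * 10)
    s = softmax_rows(x)
    assert np.allclose(s.data.sum(axis=1), 1.0)
    assert np.all(s.data >= 0)


def test_save_load_round_trip(tmp_path, rng):
    params = {"a": Parameter(rng.normal(size=(3, 2))),
              "b": Parameter(rng.normal(size=(1, 4)))}
    path = str(tmp_path / "params.npz")
    save_params(params, path)
    back = load_params(path)
    assert set(back) == {"a", "b"}
    assert np.array_equal(back["a"].data, params["a"].data)
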