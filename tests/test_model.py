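import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from screcon import _autodiff as ad
from screcon._autodiff import Tensor
from screcon.model import (GeneTokenModel, ModelConfig, aggregate_scales,
                           attention, attention_weights, filtered_attention,
                           gene_scores, project_qkv, residual_attention,
                           select_genes)

RNG = np.random.default_rng(0)


def leaky_oracle(x, slope=0.01):
    return np.where(x > 0, x, slope * x)


def softmax_oracle(logits):
    out = np.empty_like(logits)
    for i in range(logits.shape[0]):
        row = logits[i] - logits[i].max()
        e = np.exp(row)
        out[i] = e / e.sum()
    return out


class TestProjectQKV:
    def test_zero_weights_give_zero(self):
        X = RNG.normal(size=(3, 2))
        W = np.zeros((2, 2)); b = np.zeros(2)
        Q, K, V = project_qkv(X, W, b, W, b, W, b)
        assert (Q.value == 0).all() and (K.value == 0).all() and (V.value == 0).all()

    def test_leaky_relu_definition(self):
        X = np.array([[-1.0, 2.0]])
        I = np.eye(2); b = np.zeros(2)
        Q, _, _ = project_qkv(X, I, b, I, b, I, b, slope=0.01)
        np.testing.assert_allclose(Q.value, [[-0.01, 2.0]])

    def test_matches_affine_activation_oracle(self):
        X = RNG.normal(size=(3, 2))
        Ws = [RNG.normal(size=(2, 4)) for _ in range(3)]
        bs = [RNG.normal(size=4) for _ in range(3)]
        Q, K, V = project_qkv(X, Ws[0], bs[0], Ws[1], bs[1], Ws[2], bs[2])
        for out, W, b in zip((Q, K, V), Ws, bs):
            np.testing.assert_allclose(out.value, leaky_oracle(X @ W + b),
                                       atol=1e-6)


class TestAttention:
    def test_identical_keys_average_values(self):
        Q = RNG.normal(size=(4, 3))
        K = np.tile(RNG.normal(size=(1, 3)), (5, 1))
        V = RNG.normal(size=(5, 2))
        out = attention(Q, K, V, channels=3).value
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (4, 1)), atol=1e-8)

    def test_hand_computed_two_token_case(self):
        lam = 4
        Q = np.array([[0.0, np.log(3.0)], [0.0, 0.0]]) * np.sqrt(lam)
        K = np.eye(2)  # Q K^T / sqrt(lam) = [[0, ln 3], [0, 0]]
        out = attention(Q, K, np.eye(2), channels=lam).value
        # softmax([0, ln 3]) = (1/4, 3/4)
        np.testing.assert_allclose(out[0], [0.25, 0.75], atol=1e-10)

    def test_rows_are_convex_combinations(self):
        Q = RNG.normal(size=(6, 3)); K = RNG.normal(size=(5, 3))
        W = attention_weights(Q, K, channels=3).value
        assert (W >= 0).all()
        np.testing.assert_allclose(W.sum(axis=1), np.ones(6), atol=1e-6)

    def test_bad_channel_count(self):
        with pytest.raises(ValueError):
            attention(np.ones((2, 2)), np.ones((2, 2)), np.ones((2, 2)), 0)


class TestResidualAttention:
    def test_lambda_zero_is_plain_attention(self):
        Q, K, V = (RNG.normal(size=(4, 3)) for _ in range(3))
        X = RNG.normal(size=(4, 3))
        a = attention(Q, K, V, 3).value
        r = residual_attention(X, Q, K, V, 3, lam=0.0).value
        np.testing.assert_array_equal(a, r)

    def test_passthrough_when_values_zero(self):
        Q, K = RNG.normal(size=(4, 3)), RNG.normal(size=(4, 3))
        X = RNG.normal(size=(4, 3))
        r = residual_attention(X, Q, K, np.zeros((4, 3)), 3, lam=1.0).value
        np.testing.assert_allclose(r, X, atol=1e-12)

    def test_linearity_in_lambda(self):
        Q, K, V = (RNG.normal(size=(5, 2)) for _ in range(3))
        X = RNG.normal(size=(5, 4))
        align = (RNG.normal(size=(4, 2)), RNG.normal(size=2))
        r = residual_attention(X, Q, K, V, 2, lam=0.5, align=align).value
        oracle = (softmax_oracle(Q @ K.T / np.sqrt(2)) @ V
                  + 0.5 * (X @ align[0] + align[1]))
        np.testing.assert_allclose(r, oracle, atol=1e-6)


class TestGeneScores:
    def test_saturated_diagonal(self):
        S = softmax_oracle(np.eye(5) * 100.0)
        assert (gene_scores(S) > 0.99).all()

    def test_uniform_rows(self):
        S = np.full((8, 8), 1 / 8)
        np.testing.assert_allclose(gene_scores(S), np.full(8, 1 / 8))

    def test_matches_softmax_oracle(self):
        logits = RNG.normal(size=(5, 5))
        S = softmax_oracle(logits)
        np.testing.assert_allclose(gene_scores(S), np.diag(S), atol=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            gene_scores(np.ones((3, 4)))


class TestSelectGenes:
    def test_half_of_84_is_42(self):
        scores = RNG.normal(size=84)
        assert len(select_genes(scores, 0.5).kept_indices) == 42

    def test_floor_at_odd_count(self):
        scores = RNG.normal(size=85)
        assert len(select_genes(scores, 0.5).kept_indices) == 42

    def test_phi_one_keeps_all_in_order(self):
        res = select_genes(RNG.normal(size=10), 1.0)
        np.testing.assert_array_equal(res.kept_indices, np.arange(10))

    def test_ties_break_to_lower_index(self):
        res = select_genes(np.zeros(6), 0.5)
        np.testing.assert_array_equal(res.kept_indices, [0, 1, 2])

    def test_phi_out_of_range(self):
        for phi in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                select_genes(np.ones(4), phi)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(2, 60), st.integers(0, 2**31 - 1),
           st.floats(0.05, 1.0), st.floats(0.05, 1.0))
    def test_monotone_in_phi(self, n, seed, phi1, phi2):
        scores = np.random.default_rng(seed).normal(size=n)
        lo, hi = sorted((phi1, phi2))
        kept_lo = set(select_genes(scores, lo).kept_indices.tolist())
        kept_hi = set(select_genes(scores, hi).kept_indices.tolist())
        assert kept_lo <= kept_hi


class TestFilteredAttention:
    def _weights(self, n_feat, width):
        return {name: RNG.normal(size=(n_feat, width)) for name in "qkv"}, \
               {name: RNG.normal(size=width) for name in "qkv"}

    def test_phi_one_equals_residual_attention(self):
        X = RNG.normal(size=(5, 4))
        Ws, bs = self._weights(4, 3)
        align = (RNG.normal(size=(4, 3)), RNG.normal(size=3))
        kept = np.arange(5)
        full = filtered_attention(X, kept, Ws["q"], bs["q"], Ws["k"], bs["k"],
                                  Ws["v"], bs["v"], 3, 0.7, align).value
        Q, K, V = project_qkv(X, Ws["q"], bs["q"], Ws["k"], bs["k"],
                              Ws["v"], bs["v"])
        ref = residual_attention(X, Q, K, V, 3, lam=0.7, align=align).value
        np.testing.assert_allclose(full, ref, atol=1e-10)

    def test_cross_attention_support(self):
        """With lambda=0, outputs lie in the hull of the kept-gene values."""
        X = RNG.normal(size=(5, 4))
        Ws, bs = self._weights(4, 3)
        kept = np.array([0, 2, 4])
        align = (np.zeros((4, 3)), np.zeros(3))
        out = filtered_attention(X, kept, Ws["q"], bs["q"], Ws["k"], bs["k"],
                                 Ws["v"], bs["v"], 3, 0.0, align).value
        Vf = leaky_oracle(X[kept] @ Ws["v"] + bs["v"])
        lo, hi = Vf.min(axis=0), Vf.max(axis=0)
        assert (out >= lo - 1e-8).all() and (out <= hi + 1e-8).all()

    def test_matches_brute_force_oracle(self):
        X = RNG.normal(size=(6, 4))
        Ws, bs = self._weights(4, 2)
        align = (RNG.normal(size=(4, 2)), RNG.normal(size=2))
        kept = np.array([1, 3, 5])
        out = filtered_attention(X, kept, Ws["q"], bs["q"], Ws["k"], bs["k"],
                                 Ws["v"], bs["v"], 2, 0.9, align).value
        Q = leaky_oracle(X @ Ws["q"] + bs["q"])
        Kf = leaky_oracle(X[kept] @ Ws["k"] + bs["k"])
        Vf = leaky_oracle(X[kept] @ Ws["v"] + bs["v"])
        A = softmax_oracle(Q @ Kf.T / np.sqrt(2)) @ Vf
        R = np.zeros((6, 2))
        R[kept] = X[kept] @ align[0] + align[1]
        np.testing.assert_allclose(out, A + 0.9 * R, atol=1e-6)

    def test_out_of_range_indices(self):
        X = RNG.normal(size=(4, 3))
        Ws, bs = self._weights(3, 2)
        with pytest.raises(IndexError):
            filtered_attention(X, np.array([5]), Ws["q"], bs["q"], Ws["k"],
                               bs["k"], Ws["v"], bs["v"], 2, 1.0,
                               (np.zeros((3, 2)), np.zeros(2)))


class TestAggregateScales:
    def test_default_scale_widths_concatenate(self):
        blocks = [np.zeros((3, w)) for w in (1024, 2048, 4096)]
        assert aggregate_scales(blocks).shape == (3, 7168)

    def test_single_block_identity(self):
        b = RNG.normal(size=(4, 6))
        np.testing.assert_array_equal(aggregate_scales([b]).value, b)

    def test_concat_order(self):
        b1, b2 = RNG.normal(size=(5, 2)), RNG.normal(size=(5, 3))
        out = aggregate_scales([b1, b2]).value
        assert out.shape == (5, 5)
        np.testing.assert_array_equal(out[:, :2], b1)

    def test_token_mismatch(self):
        with pytest.raises(ValueError):
            aggregate_scales([np.zeros((3, 2)), np.zeros((4, 2))])


class TestGeneTokenModel:
    def make_model(self, **kw):
        cfg = ModelConfig(scales=kw.pop("scales", (4, 8)), decoder_hidden=8,
                          dtype="float64", **kw)
        return GeneTokenModel(n_cells=10, n_spots=7, config=cfg)

    def test_zeroed_decoder_gives_zero_prediction(self):
        model = self.make_model()
        model.params["dec_W2"].value[:] = 0
        model.params["dec_b2"].value[:] = 0
        pred = model.predict(RNG.normal(size=(10, 6)) ** 2)
        assert pred.shape == (7, 6)
        assert (pred == 0).all()

    def test_gene_permutation_equivariance(self):
        model = self.make_model(use_filtration=False)
        X = RNG.uniform(size=(10, 6))
        perm = RNG.permutation(6)
        pred = model.predict(X)
        pred_perm = model.predict(X[:, perm])
        np.testing.assert_allclose(pred_perm, pred[:, perm], atol=1e-10)

    def test_forward_matches_composed_operations(self):
        """The fused forward equals the straight-line composition of the
        independently tested building blocks."""
        cfg = ModelConfig(scales=(4, 8), decoder_hidden=8, dtype="float64",
                          filtration_phi=0.5, residual_lambda=1.0)
        model = GeneTokenModel(n_cells=10, n_spots=7, config=cfg)
        sc = RNG.uniform(size=(10, 6))
        pred = model.predict(sc)

        X = sc.T
        p = {k: v.value for k, v in model.params.items()}
        blocks = []
        for i, width in enumerate(cfg.scales):
            Q, K, V = project_qkv(X, p[f"s{i}_Wq"], p[f"s{i}_bq"],
                                  p[f"s{i}_Wk"], p[f"s{i}_bk"],
                                  p[f"s{i}_Wv"], p[f"s{i}_bv"])
            S = softmax_oracle(Q.value @ K.value.T / np.sqrt(width))
            filt = select_genes(gene_scores(S), cfg.filtration_phi)
            out = filtered_attention(
                X, filt.kept_indices, p[f"s{i}_Wq"], p[f"s{i}_bq"],
                p[f"s{i}_Wkf"], p[f"s{i}_bkf"], p[f"s{i}_Wvf"], p[f"s{i}_bvf"],
                width, cfg.residual_lambda,
                (p[f"s{i}_Walign"], p[f"s{i}_balign"]))
            blocks.append(out)
        agg = aggregate_scales(blocks).value
        H = leaky_oracle(agg @ p["dec_W1"] + p["dec_b1"])
        ref = (H @ p["dec_W2"] + p["dec_b2"]).T
        np.testing.assert_allclose(pred, ref, atol=1e-5)

    def test_attention_row_stochastic_every_scale(self):
        model = self.make_model()
        X = Tensor(RNG.uniform(size=(6, 10)))
        model.forward_tokens(X, record_states=True)
        assert len(model.last_states) == 2
        for state in model.last_states:
            np.testing.assert_allclose(state.S.sum(axis=1),
                                       np.ones(state.S.shape[0]), atol=1e-6)
            assert (state.S > 0).all() and (state.S < 1).all()

    def test_single_scale_config_equals_multiscale_off(self):
        sc = RNG.uniform(size=(10, 6))
        m_off = self.make_model(use_multiscale=False)
        cfg_single = ModelConfig(scales=(8,), decoder_hidden=8, dtype="float64")
        m_single = GeneTokenModel(10, 7, cfg_single)
        m_single.set_state({k.replace("s0_", "s0_"): v
                            for k, v in m_off.get_state().items()})
        np.testing.assert_allclose(m_off.predict(sc), m_single.predict(sc),
                                   atol=1e-12)

    def test_no_filtration_uses_full_self_attention(self):
        model = self.make_model(use_filtration=False)
        X = Tensor(RNG.uniform(size=(6, 10)))
        model.forward_tokens(X, record_states=True)
        assert model.last_filtration == []
        assert model.last_states[0].S.shape == (6, 6)

    def test_ensemble_matches_independent_replicas(self):
        cfg = ModelConfig(scales=(4, 8), decoder_hidden=8, dtype="float64")
        single = GeneTokenModel(10, 7, cfg)
        triple = GeneTokenModel(10, 7, cfg, ensemble=3)
        X = RNG.uniform(size=(3, 6, 10))
        out = triple.forward_tokens(Tensor(X)).value
        for b in range(3):
            np.testing.assert_allclose(
                out[b], single.forward_tokens(Tensor(X[b])).value, atol=1e-10)

    def test_checkpoint_round_trip(self, tmp_path):
        model = self.make_model()
        sc = RNG.uniform(size=(10, 6))
        path = tmp_path / "ckpt.npz"
        model.save(path)
        back = GeneTokenModel.load(path)
        np.testing.assert_array_equal(back.predict(sc), model.predict(sc))
        assert back.config.scales == model.config.scales

    def test_learnable_lambda_mode(self):
        model = self.make_model(learnable_lambda=True)
        assert "lam" in model.params
        assert model.predict(RNG.uniform(size=(10, 5))).shape == (7, 5)
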