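"""Forward model: shapes, attention oracle, masking, gradients, checkpoints."""

import numpy as np
import pytest

from recgobd.embedders import EmbeddingMatrix
from recgobd.metrics import bce_loss, bce_loss_grad_logits
from recgobd.network import (
    ModelConfig,
    attention_forward,
    backward_batch,
    bilstm_forward,
    category_attention,
    category_heads,
    encode_sequence,
    forward_batch,
    heads_forward,
    init_params,
    load_checkpoint,
    predict_proba,
    save_checkpoint,
)

MINI = ModelConfig(input_dim=5, n_labels=2, n_heads=2, head_dim=2,
                   rnn_hidden=2, dense_hidden=3, L=6)


@pytest.fixture()
def mini_params():
    return init_params(MINI, seed=7, dtype=np.float64)


def softmax(v):
    e = np.exp(v - v.max())
    return e / e.sum()


def attention_oracle(H, mask, params, config):
    """Naive triple-loop category attention for one sequence."""
    d, h, dk, dm = (config.n_labels, config.n_heads, config.d_k, config.d_model)
    heads = []
    for i in range(h):
        Q = np.eye(d) @ params["att_Wq"][i] + params["att_bq"][i]
        K = H @ params["att_Wk"][i] + params["att_bk"][i]
        V = H @ params["att_Wv"][i] + params["att_bv"][i]
        out = np.zeros((d, dk))
        for c in range(d):
            scores = np.array([
                Q[c] @ K[t] / np.sqrt(dk) if mask[t] else -np.inf
                for t in range(H.shape[0])
            ])
            w = softmax(scores)
            for t in range(H.shape[0]):
                if mask[t]:
                    out[c] += w[t] * V[t]
        heads.append(out)
    C = np.concatenate(heads, axis=1)
    return C @ params["att_Wo"] if config.use_output_projection else C


class TestShapes:
    def test_encoder_output_width_is_d_model(self, mini_params):
        rng = np.random.default_rng(0)
        fused = EmbeddingMatrix(rng.standard_normal((6, 5)), source="fused",
                                mask=np.array([1, 1, 1, 1, 0, 0], dtype=bool))
        H = encode_sequence(fused, mini_params, MINI)
        assert H.shape == (6, MINI.d_model)

    def test_fullsize_config_dimensions(self):
        cfg = ModelConfig(input_dim=3704)
        assert cfg.d_model == 400 and cfg.n_heads == 4 and cfg.L == 2000
        assert cfg.label_matrix.shape == (10, 10)
        assert np.array_equal(cfg.label_matrix, np.eye(10))

    def test_category_attention_output_shape(self, mini_params):
        rng = np.random.default_rng(1)
        H = rng.standard_normal((6, MINI.d_model))
        B = category_attention(H, mini_params, MINI)
        assert B.shape == (MINI.n_labels, MINI.d_model)

    def test_width_mismatch_rejected(self, mini_params):
        rng = np.random.default_rng(2)
        fused = EmbeddingMatrix(rng.standard_normal((6, 9)), source="fused")
        with pytest.raises(ValueError, match="width"):
            encode_sequence(fused, mini_params, MINI)

    def test_all_padding_rejected(self, mini_params):
        fused = EmbeddingMatrix(np.zeros((6, 5)), source="fused",
                                mask=np.zeros(6, dtype=bool))
        with pytest.raises(ValueError, match="valid region"):
            encode_sequence(fused, mini_params, MINI)

    def test_dmodel_consistency_enforced(self):
        with pytest.raises(ValueError, match="d_model"):
            ModelConfig(input_dim=10, n_heads=4, head_dim=10, rnn_hidden=30)


class TestAttention:
    def test_matches_triple_loop_oracle(self, mini_params):
        rng = np.random.default_rng(3)
        H = rng.standard_normal((6, MINI.d_model))
        mask = np.array([1, 1, 1, 1, 1, 0], dtype=bool)
        got, _ = attention_forward(H[None], mask[None], mini_params, MINI)
        want = attention_oracle(H, mask, mini_params, MINI)
        np.testing.assert_allclose(got[0], want, atol=1e-6)

    def test_softmax_rows_sum_to_one(self, mini_params):
        rng = np.random.default_rng(4)
        H = rng.standard_normal((3, 6, MINI.d_model))
        mask = np.ones((3, 6), dtype=bool)
        mask[1, 4:] = False
        _, cache = attention_forward(H, mask, mini_params, MINI)
        sums = cache["A"].sum(axis=-1)  # (B, heads, labels)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_constant_values_are_recovered(self, mini_params):
        # attention over identical value vectors returns that vector
        rng = np.random.default_rng(5)
        H = np.repeat(rng.standard_normal((1, 1, MINI.d_model)), 6, axis=1)
        mask = np.ones((1, 6), dtype=bool)
        _, cache = attention_forward(H, mask, mini_params, MINI)
        heads = np.matmul(cache["A"], cache["Vh"])
        for i in range(MINI.n_heads):
            expected = cache["Vh"][0, i, 0]
            np.testing.assert_allclose(
                heads[0, i], np.broadcast_to(expected, heads[0, i].shape), atol=1e-10
            )

    def test_padded_positions_are_inert(self, mini_params):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((2, 6, 5))
        mask = np.ones((2, 6), dtype=bool)
        mask[:, 4:] = False
        base = forward_batch(X, mask, mini_params, MINI)
        X2 = X.copy()
        X2[:, 4:, :] = rng.standard_normal((2, 2, 5)) * 50
        np.testing.assert_allclose(
            forward_batch(X2, mask, mini_params, MINI), base, atol=1e-12
        )


class TestHeads:
    def test_weight_sharing_permutes_with_categories(self, mini_params):
        rng = np.random.default_rng(7)
        B = rng.standard_normal((1, MINI.n_labels, MINI.d_model))
        logits = category_heads(B[0], mini_params)
        swapped = B[:, ::-1, :]
        np.testing.assert_allclose(
            category_heads(swapped[0], mini_params), logits[::-1], atol=1e-12
        )

    def test_zero_weights_give_constant_bias_logit(self, mini_params):
        p = dict(mini_params)
        p["head_W1"] = np.zeros_like(p["head_W1"])
        p["head_b1"] = np.zeros_like(p["head_b1"])
        p["head_b2"] = np.asarray(0.37)
        logits, _ = heads_forward(np.random.default_rng(8).standard_normal((2, 2, 4)), p)
        np.testing.assert_allclose(logits, 0.37, atol=1e-12)

    def test_toy_logits_by_hand(self):
        # 2 categories, 3 features, 2 hidden units, worked by hand
        p = {
            "head_W1": np.array([[1.0, 0.0], [0.0, 1.0], [1.0, -1.0]]),
            "head_b1": np.array([0.0, -1.0]),
            "head_w2": np.array([2.0, 3.0]),
            "head_b2": np.asarray(0.5),
        }
        B = np.array([[[1.0, 2.0, 3.0], [0.0, -1.0, 1.0]]])
        # cat 0: hidden = relu([1+3, 2-3-1]) = [4, 0] -> 2*4 + 0.5 = 8.5
        # cat 1: hidden = relu([0+1, -1-1-1]) = [1, 0] -> 2*1 + 0.5 = 2.5
        logits, _ = heads_forward(B, p)
        np.testing.assert_allclose(logits[0], [8.5, 2.5], atol=1e-12)


class TestSigmoid:
    def test_basic_identities(self):
        assert predict_proba(np.zeros(3)).tolist() == [0.5, 0.5, 0.5]
        out = predict_proba(np.array([-1e4, 1e4]))
        assert out[0] == pytest.approx(0.0, abs=1e-12)
        assert out[1] == pytest.approx(1.0, abs=1e-12)
        x = np.random.default_rng(9).standard_normal(50)
        np.testing.assert_allclose(predict_proba(x) + predict_proba(-x), 1.0,
                                   atol=1e-12)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, mini_params):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((3, 6, 5))
        mask = np.ones((3, 6), dtype=bool)
        mask[0, 4:] = False
        y = rng.integers(0, 2, (3, MINI.n_labels))
        p = mini_params

        probs, cache = forward_batch(X, mask, p, MINI, return_cache=True)
        grads = backward_batch(bce_loss_grad_logits(probs, y), cache, p, MINI)

        eps = 1e-6
        for key in ("att_Wq", "lstm_Wx_f", "lstm_Wh_r", "head_W1", "att_Wo"):
            num = np.zeros_like(p[key])
            for idx in np.ndindex(p[key].shape):
                orig = p[key][idx]
                p[key][idx] = orig + eps
                lp = bce_loss(forward_batch(X, mask, p, MINI), y)
                p[key][idx] = orig - eps
                lm = bce_loss(forward_batch(X, mask, p, MINI), y)
                p[key][idx] = orig
                num[idx] = (lp - lm) / (2 * eps)
            np.testing.assert_allclose(grads[key], num, atol=1e-4,
                                       err_msg=f"gradient mismatch for {key}")


class TestRecurrentEncoder:
    def test_sequence_reversal_swaps_direction_blocks(self):
        # with both directions sharing weights, reversing the inputs swaps
        # the forward- and backward-state blocks (read in reverse)
        cfg = MINI
        p = init_params(cfg, seed=11, dtype=np.float64)
        for name in ("Wx", "Wh", "b"):
            p[f"lstm_{name}_r"] = p[f"lstm_{name}_f"].copy()
        rng = np.random.default_rng(12)
        X = rng.standard_normal((1, 6, 5))
        mask = np.ones((1, 6), dtype=bool)
        H_fwd, _ = bilstm_forward(X, mask, p)
        H_rev, _ = bilstm_forward(X[:, ::-1].copy(), mask, p)
        hid = cfg.rnn_hidden
        np.testing.assert_allclose(H_rev[0, ::-1, :hid], H_fwd[0, :, hid:], atol=1e-10)
        np.testing.assert_allclose(H_rev[0, ::-1, hid:], H_fwd[0, :, :hid], atol=1e-10)


class TestCheckpoint:
    def test_bit_exact_roundtrip(self, tmp_path, mini_params):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, mini_params, MINI)
        params2, cfg2 = load_checkpoint(path)
        assert cfg2 == MINI
        assert set(params2) == set(mini_params)
        for k in mini_params:
            assert np.array_equal(params2[k], mini_params[k])
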