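"""Network forward/backward: cell equations, masking, modes, gradients."""

import numpy as np
import pytest

from ddipair import tokenizer as tk
from ddipair.model import (
    LSTMParams,
    MLPParams,
    ModelConfig,
    ModelParameters,
    _copy_branch,
    backward_pairs,
    batchify,
    bilstm_encode,
    count_parameters,
    forward_pairs,
    init_parameters,
    lstm_cell_step,
    mlp_forward,
    predict_batch,
    predict_pair,
)
from ddipair.training import bce_loss

from conftest import random_seqs


def scalar_lstm(w=1.0, b=0.0, dim=1):
    W = np.full((dim, 2 * dim), w)
    bias = np.full(dim, b)
    return LSTMParams(*(W.copy() for _ in range(4)), *(bias.copy() for _ in range(4)))


class TestLstmCell:
    def test_zero_weights_closed_form(self):
        # sigma(0)=0.5, tanh(0)=0: c' = 0.5 c0, h' = 0.5 tanh(0.5 c0)
        p = scalar_lstm(w=0.0, dim=3)
        c0 = np.array([1.0, -2.0, 0.3])
        h, c = lstm_cell_step(np.zeros(3), (np.zeros(3), c0), p)
        np.testing.assert_allclose(c, 0.5 * c0, atol=1e-15)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c0), atol=1e-15)

    def test_scalar_hand_evaluation(self):
        # w_g = [1, 1], b = 0, x = 1, h0 = c0 = 0:
        # f = i = o = sigma(1), c~ = tanh(1), c1 = i*c~, h1 = o*tanh(c1)
        p = scalar_lstm(w=1.0)
        h, c = lstm_cell_step(np.array([1.0]), (np.zeros(1), np.zeros(1)), p)
        sig1, th1 = 1 / (1 + np.exp(-1)), np.tanh(1.0)
        assert abs(c[0] - sig1 * th1) < 1e-10           # 0.5568...
        assert abs(h[0] - sig1 * np.tanh(sig1 * th1)) < 1e-10  # 0.3694...
        assert abs(c[0] - 0.5568) < 1e-4
        assert abs(h[0] - 0.3696) < 1e-4

    def test_gate_outputs_strictly_in_unit_interval(self):
        rng = np.random.default_rng(0)
        p = LSTMParams(
            *(rng.normal(size=(4, 10)) for _ in range(4)),
            *(rng.normal(size=4) for _ in range(4)),
        )
        # gates are sigmoids of finite affine maps: h stays within (-1, 1)
        h, c = lstm_cell_step(rng.normal(size=6), (rng.normal(size=4), rng.normal(size=4)), p)
        assert np.all(np.abs(h) < 1.0)

    def test_dimension_mismatch_raises(self):
        p = scalar_lstm()
        with pytest.raises(ValueError, match="mismatch"):
            lstm_cell_step(np.ones(3), (np.zeros(1), np.zeros(1)), p)


class TestBiLstmEncode:
    def test_matches_explicit_double_unidirectional_pass(self):
        rng = np.random.default_rng(3)
        D, H = 3, 2
        emb = rng.normal(scale=0.5, size=(10, D))
        def rand_lstm():
            return LSTMParams(
                *(rng.normal(scale=0.4, size=(H, D + H)) for _ in range(4)),
                *(rng.normal(scale=0.1, size=H) for _ in range(4)),
            )
        fwd, bwd = rand_lstm(), rand_lstm()
        seq = tk.TokenSequence((1, 4, 5, 6, 2, 0), (1, 1, 1, 1, 1, 0))
        out = bilstm_encode(seq, emb, fwd, bwd)

        real = [1, 4, 5, 6, 2]
        def run(params, id_order):
            state = (np.zeros(H), np.zeros(H))
            for i in id_order:
                state = lstm_cell_step(emb[i], state, params)
            return state[0]
        expected = np.concatenate([run(fwd, real), run(bwd, real[::-1])])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_single_real_token_concatenates_two_single_steps(self):
        rng = np.random.default_rng(5)
        D, H = 2, 2
        emb = rng.normal(size=(6, D))
        p = LSTMParams(
            *(rng.normal(size=(H, D + H)) for _ in range(4)),
            *(np.zeros(H) for _ in range(4)),
        )
        seq = tk.TokenSequence((4, 0, 0), (1, 0, 0))
        out = bilstm_encode(seq, emb, p, p)
        h1, _ = lstm_cell_step(emb[4], (np.zeros(H), np.zeros(H)), p)
        np.testing.assert_allclose(out, np.concatenate([h1, h1]), atol=1e-14)

    def test_padding_invariance(self, toy_params):
        seq_short = tk.TokenSequence((1, 4, 2, 0, 0, 0, 0, 0), (1, 1, 1, 0, 0, 0, 0, 0))
        # same real content, re-expressed at a longer max_len
        seq_long = tk.TokenSequence(tuple([1, 4, 2] + [0] * 13), tuple([1, 1, 1] + [0] * 13))
        br = toy_params.branch_a
        a = bilstm_encode(seq_short, br.embedding, br.fwd, br.bwd)
        b = bilstm_encode(seq_long, br.embedding, br.fwd, br.bwd)
        np.testing.assert_array_equal(a, b)

    def test_all_pad_rejected(self, toy_params):
        seq = tk.TokenSequence((0, 0, 0), (0, 0, 0))
        br = toy_params.branch_a
        with pytest.raises(ValueError):
            bilstm_encode(seq, br.embedding, br.fwd, br.bwd)


class TestMlp:
    def test_zero_weights_give_bias(self):
        p = MLPParams(np.zeros((3, 2)), np.zeros(3), np.zeros((2, 3)), np.array([0.7, -0.2]))
        np.testing.assert_array_equal(mlp_forward([1.0, 2.0], p), [0.7, -0.2])

    def test_relu_zeroes_negative_coordinate(self):
        p = MLPParams(np.eye(2), np.zeros(2), np.eye(2), np.zeros(2))
        np.testing.assert_array_equal(mlp_forward([1.0, -1.0], p), [1.0, 0.0])

    def test_default_dims_256_128_4(self):
        cfg = ModelConfig(vocab_size=10)
        p = init_parameters(cfg, 0)
        assert p.branch_a.mlp.W_h.shape == (128, 256)
        assert p.branch_a.mlp.W_o.shape == (4, 128)
        assert cfg.bilstm_out == 256

    def test_dimension_mismatch(self):
        p = MLPParams(np.eye(2), np.zeros(2), np.eye(2), np.zeros(2))
        with pytest.raises(ValueError):
            mlp_forward([1.0, 2.0, 3.0], p)


class TestPredictPair:
    def test_zero_predictor_gives_half(self, toy_params):
        toy_params.pred_w[:] = 0.0
        toy_params.pred_b[...] = 0.0
        seqs = random_seqs(np.random.default_rng(0), 2, 12, 8)
        assert predict_pair(seqs[0], seqs[1], toy_params) == 0.5

    def test_sharing_mode_identical_inputs_identical_features(self, toy_params):
        seq = random_seqs(np.random.default_rng(1), 1, 12, 8)[0]
        from ddipair.model import _branch_forward
        ids, mask = batchify([seq])
        oa, _ = _branch_forward(toy_params.branch_a, ids, mask)
        ob, _ = _branch_forward(toy_params.branch_b, ids, mask)
        np.testing.assert_array_equal(oa, ob)

    def test_full_forward_equals_chained_oracles(self, toy_params):
        seq_a = tk.TokenSequence((1, 4, 2, 0, 0, 0, 0, 0), (1, 1, 1, 0, 0, 0, 0, 0))
        seq_b = tk.TokenSequence((1, 5, 6, 2, 0, 0, 0, 0), (1, 1, 1, 1, 0, 0, 0, 0))
        p = predict_pair(seq_a, seq_b, toy_params)
        feats = []
        for s in (seq_a, seq_b):
            br = toy_params.branch_a
            h = bilstm_encode(s, br.embedding, br.fwd, br.bwd)
            feats.append(mlp_forward(h, br.mlp))
        logit = np.concatenate(feats) @ toy_params.pred_w + toy_params.pred_b
        assert abs(p - 1 / (1 + np.exp(-logit))) < 1e-12

    def test_output_strictly_in_unit_interval(self, toy_params):
        rng = np.random.default_rng(2)
        seqs = random_seqs(rng, 10, 12, 8)
        probs = predict_batch(list(zip(seqs[:5], seqs[5:])), toy_params)
        assert np.all((probs > 0) & (probs < 1))

    def test_out_of_range_token_id_rejected(self, toy_params):
        bad = tk.TokenSequence((1, 99, 2), (1, 1, 1))
        ok = tk.TokenSequence((1, 4, 2), (1, 1, 1))
        with pytest.raises(ValueError):
            predict_pair(bad, ok, toy_params)

    def test_determinism(self, toy_params):
        seqs = random_seqs(np.random.default_rng(4), 4, 12, 8)
        pairs = list(zip(seqs[:2], seqs[2:]))
        np.testing.assert_array_equal(
            predict_batch(pairs, toy_params), predict_batch(pairs, toy_params)
        )


class TestCountParameters:
    def test_toy_closed_form(self):
        cfg = ModelConfig(vocab_size=10, embed_dim=4, lstm_hidden=3,
                          mlp_hidden=5, mlp_out=2, mode="sharing", max_len=8)
        counts = count_parameters(cfg)
        # embedding 40; per-direction LSTM 4*(3*(4+3)+3)=96; BiLSTM 192;
        # MLP (6*5+5)+(5*2+2)=47; branch 279; predictor 4+1=5
        assert counts == {"encoder_params": 279, "predictor_params": 5, "total": 284}

    def test_independent_doubles_encoder_only(self):
        for kwargs in ({}, {"embed_dim": 16, "lstm_hidden": 8, "mlp_hidden": 4, "mlp_out": 3}):
            share = count_parameters(ModelConfig(vocab_size=50, mode="sharing", **kwargs))
            indep = count_parameters(ModelConfig(vocab_size=50, mode="independent", **kwargs))
            assert indep["encoder_params"] == 2 * share["encoder_params"]
            assert indep["predictor_params"] == share["predictor_params"]

    def test_counts_match_actual_arrays(self):
        for mode in ("sharing", "independent"):
            cfg = ModelConfig(vocab_size=9, embed_dim=4, lstm_hidden=3,
                              mlp_hidden=5, mlp_out=2, mode=mode, max_len=8)
            params = init_parameters(cfg, 0)
            actual = sum(a.size for _, a in params.named_arrays())
            assert actual == count_parameters(cfg)["total"]


class TestModes:
    def test_sharing_is_one_storage(self):
        p = init_parameters(ModelConfig(vocab_size=8, embed_dim=2, lstm_hidden=2,
                                        mlp_hidden=2, mlp_out=2, mode="sharing", max_len=6), 0)
        assert p.branch_a is p.branch_b

    def test_identically_initialized_independent_matches_sharing(self, toy_config, toy_params):
        from dataclasses import replace
        cfg_ind = replace(toy_config, mode="independent")
        ind = ModelParameters(
            cfg_ind,
            _copy_branch(toy_params.branch_a),
            _copy_branch(toy_params.branch_a),
            toy_params.pred_w.copy(),
            toy_params.pred_b.copy(),
        )
        seqs = random_seqs(np.random.default_rng(6), 8, 12, 8)
        pairs = list(zip(seqs[:4], seqs[4:]))
        np.testing.assert_array_equal(
            predict_batch(pairs, toy_params), predict_batch(pairs, ind)
        )


class TestGradients:
    @pytest.mark.parametrize("mode", ["sharing", "independent"])
    def test_finite_difference_agreement(self, mode):
        cfg = ModelConfig(vocab_size=8, embed_dim=3, lstm_hidden=2,
                          mlp_hidden=3, mlp_out=2, mode=mode, max_len=6)
        params = init_parameters(cfg, 1)
        seqs_a = [tk.TokenSequence((1, 4, 5, 2, 0, 0), (1, 1, 1, 1, 0, 0)),
                  tk.TokenSequence((1, 6, 2, 0, 0, 0), (1, 1, 1, 0, 0, 0))]
        seqs_b = [tk.TokenSequence((1, 5, 2, 0, 0, 0), (1, 1, 1, 0, 0, 0)),
                  tk.TokenSequence((1, 7, 4, 6, 2, 0), (1, 1, 1, 1, 1, 0))]
        t = np.array([1.0, 0.0])
        ia, ma = batchify(seqs_a)
        ib, mb = batchify(seqs_b)

        def loss():
            p, _ = forward_pairs(params, ia, ma, ib, mb)
            return bce_loss(p, t)

        p, cache = forward_pairs(params, ia, ma, ib, mb)
        grads = backward_pairs(params, cache, (p - t) / len(t))
        eps = 1e-4
        for name, arr in params.named_arrays():
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                old = arr[idx]
                arr[idx] = old + eps
                lp = loss()
                arr[idx] = old - eps
                lm = loss()
                arr[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[name][idx]
                if max(abs(num), abs(ana)) < 1e-10:
                    continue
                rel = abs(num - ana) / max(abs(num), abs(ana))
                assert rel < 1e-4, f"{name}[{idx}]: analytic {ana}, numeric {num}"
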