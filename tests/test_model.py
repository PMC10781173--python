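"""Transformer encoder: attention algebra, invariances, gradients, training."""

import numpy as np
import pytest

from stseize.features import FeatureMap
from stseize.model import (
    EncoderConfig,
    TrainConfig,
    channel_attention,
    classify,
    encoder_forward,
    init_params,
    load_checkpoint,
    multi_head_attention,
    parameter_count,
    predict_proba,
    save_checkpoint,
    self_attention,
    train,
)
from stseize.model import _backward_loss, _forward_loss


def test_config_invariants():
    with pytest.raises(ValueError, match="d_k = d_v"):
        EncoderConfig(d_model=12, h=3, d_k=6, d_v=6)
    with pytest.raises(ValueError, match="L"):
        EncoderConfig(L=0)
    EncoderConfig()  # the defaults are valid


def test_single_token_attention_is_identity_mix(rng):
    """With one token the softmax weight is exactly 1: output = S W_V."""
    S = rng.standard_normal((1, 6))
    Wq, Wk, Wv = (rng.standard_normal((6, 3)) for _ in range(3))
    out, att = self_attention(S, Wq, Wk, Wv)
    np.testing.assert_allclose(att, [[1.0]])
    np.testing.assert_allclose(out, S @ Wv)


def test_attention_rows_sum_to_one(rng):
    S = rng.standard_normal((7, 6))
    out, att = self_attention(S, *(rng.standard_normal((6, 3)) for _ in range(3)))
    np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-12)
    assert att.min() >= 0 and att.max() <= 1


def test_two_token_attention_hand_computed(rng):
    """Brute-force arithmetic on a 2-token example reproduces the output."""
    S = rng.standard_normal((2, 4))
    Wq, Wk = rng.standard_normal((4, 2)), rng.standard_normal((4, 2))
    Wv = rng.standard_normal((4, 2))
    Q, K, V = S @ Wq, S @ Wk, S @ Wv
    expected = np.empty((2, 2))
    for i in range(2):
        logits = np.array([Q[i] @ K[0], Q[i] @ K[1]]) / np.sqrt(2.0)
        w = np.exp(logits - logits.max())
        w = w / w.sum()
        expected[i] = w[0] * V[0] + w[1] * V[1]
    out, _ = self_attention(S, Wq, Wk, Wv)
    np.testing.assert_allclose(out, expected, atol=1e-12)


def test_multi_head_shapes_and_tied_heads(rng):
    d, h, dk = 12, 3, 4
    Wq = np.broadcast_to(rng.standard_normal((d, dk)), (h, d, dk)).copy()
    Wk = np.broadcast_to(rng.standard_normal((d, dk)), (h, d, dk)).copy()
    Wv = np.broadcast_to(rng.standard_normal((d, dk)), (h, d, dk)).copy()
    Wo = rng.standard_normal((h * dk, d))
    S = rng.standard_normal((5, d))
    out, att = multi_head_attention(S, Wq, Wk, Wv, Wo)
    assert out.shape == (5, d)
    # tied parameters -> identical per-head attention
    np.testing.assert_allclose(att[0], att[1], atol=1e-12)
    np.testing.assert_allclose(att[1], att[2], atol=1e-12)


def test_single_head_reduces_to_self_attention(rng):
    d = 6
    Wq, Wk, Wv = (rng.standard_normal((1, d, d)) for _ in range(3))
    Wo = rng.standard_normal((d, d))
    S = rng.standard_normal((4, d))
    out, _ = multi_head_attention(S, Wq, Wk, Wv, Wo)
    sa, _ = self_attention(S, Wq[0], Wk[0], Wv[0])
    np.testing.assert_allclose(out, sa @ Wo, atol=1e-12)


def test_zero_weights_pure_residual_path(tiny_config, rng):
    """Zeroed MSA and MLP outputs leave the stream untouched: S_L = S_0."""
    params = init_params(tiny_config)
    for i in range(tiny_config.L):
        params[f"layer{i}/Wo"] = np.zeros_like(params[f"layer{i}/Wo"])
        params[f"layer{i}/W2"] = np.zeros_like(params[f"layer{i}/W2"])
    S0 = rng.standard_normal((5, tiny_config.d_model))
    S_L, att = encoder_forward(S0, params, tiny_config)
    np.testing.assert_allclose(S_L, S0, atol=1e-12)
    assert len(att) == tiny_config.L


def test_attention_rows_sum_to_one_every_layer(tiny_config, rng):
    params = init_params(tiny_config)
    S0 = rng.standard_normal((3, 9, tiny_config.d_model))
    _, att = encoder_forward(S0, params, tiny_config)
    for a in att:
        assert a.shape == (3, tiny_config.h, 9, 9)
        np.testing.assert_allclose(a.sum(axis=-1), 1.0, atol=1e-6)


def test_forward_deterministic_across_runs(tiny_config, rng):
    S0 = rng.standard_normal((2, 4, tiny_config.d_model))
    out1, _ = encoder_forward(S0, init_params(tiny_config), tiny_config)
    out2, _ = encoder_forward(S0, init_params(tiny_config), tiny_config)
    np.testing.assert_array_equal(out1, out2)


def test_classify_probabilities(tiny_config, rng):
    params = init_params(tiny_config)
    S_L = rng.standard_normal((4, 8, tiny_config.d_model))
    p = classify(S_L, params)
    assert p.shape == (4, 2)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
    assert (p > 0).all() and (p < 1).all()
    with pytest.raises(ValueError, match="empty"):
        classify(np.empty((1, 0, tiny_config.d_model)), params)


def test_classify_channel_permutation_and_duplication(tiny_config, rng):
    params = init_params(tiny_config)
    S_L = rng.standard_normal((6, tiny_config.d_model))
    p = classify(S_L, params)
    perm = rng.permutation(6)
    np.testing.assert_allclose(classify(S_L[perm], params), p, atol=1e-12)
    dup = np.vstack([S_L, S_L[:2]])
    np.testing.assert_allclose(classify(dup, params), p, atol=1e-12)


def test_full_model_channel_permutation_invariance(tiny_config, rng):
    """No positional encoding + max-pool: probabilities ignore channel order."""
    params = init_params(tiny_config)
    X = rng.standard_normal((8, tiny_config.d_model))
    perm = rng.permutation(8)
    p1 = classify(encoder_forward(X, params, tiny_config)[0], params)
    p2 = classify(encoder_forward(X[perm], params, tiny_config)[0], params)
    np.testing.assert_allclose(p1, p2, atol=1e-10)


def test_gradients_match_finite_differences(tiny_config, rng):
    params = init_params(tiny_config)
    X = rng.standard_normal((3, 4, tiny_config.d_model))
    y = np.array([0, 1, 1])
    _, _, cache = _forward_loss(X, y, params, tiny_config)
    grads = _backward_loss(X, y, params, tiny_config, cache)
    eps = 1e-6
    for key in ["layer0/Wq", "layer0/Wv", "layer1/Wo", "layer0/ln1_g",
                "layer1/W1", "layer1/ln2_b", "head/W1", "head/b2"]:
        arr = params[key]
        flat_indices = list(np.ndindex(arr.shape))[:4]
        for idx in flat_indices:
            orig = arr[idx]
            arr[idx] = orig + eps
            lp, _, _ = _forward_loss(X, y, params, tiny_config)
            arr[idx] = orig - eps
            lm, _, _ = _forward_loss(X, y, params, tiny_config)
            arr[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert grads[key][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8), key


def test_standard_block_differs_from_printed_block(rng):
    cfg_a = EncoderConfig(d_model=6, h=2, d_k=3, d_v=3, L=2, d_ff=8, mlp_hidden=5, seed=1)
    cfg_b = EncoderConfig(d_model=6, h=2, d_k=3, d_v=3, L=2, d_ff=8, mlp_hidden=5, seed=1,
                          standard_block=True)
    params = init_params(cfg_a)
    X = rng.standard_normal((2, 4, 6))
    out_a, _ = encoder_forward(X, params, cfg_a)
    out_b, _ = encoder_forward(X, params, cfg_b)
    assert not np.allclose(out_a, out_b)


def test_parameter_count_closed_form(tiny_config):
    params = init_params(tiny_config)
    assert sum(v.size for v in params.arrays.values()) == parameter_count(tiny_config)
    assert parameter_count(EncoderConfig()) == sum(
        v.size for v in init_params(EncoderConfig()).arrays.values()
    )


def _gaussian_maps(rng, n_per_class, n_ch=4, sep=2.5):
    d = 12
    maps, labels = [], []
    names = tuple(f"c{i}" for i in range(n_ch))
    for label in (0, 1):
        mu = label * sep
        for _ in range(n_per_class):
            maps.append(FeatureMap(rng.standard_normal((n_ch, d)) + mu, names))
            labels.append(label)
    return maps, np.array(labels)


def test_training_separates_gaussian_classes(fast_train_config):
    rng = np.random.default_rng(0)
    maps, labels = _gaussian_maps(rng, 60)
    cfg = EncoderConfig(d_model=12, h=3, d_k=4, d_v=4, L=2, d_ff=24, mlp_hidden=16, seed=0)
    params, log = train(maps[::2] + maps[1::2], np.concatenate([labels[::2], labels[1::2]]),
                        cfg, fast_train_config)
    held, held_y = _gaussian_maps(np.random.default_rng(99), 25)
    probs = predict_proba(held, params, cfg)
    acc = ((probs[:, 1] >= 0.5).astype(int) == held_y).mean()
    assert acc > 0.95
    # smoothed loss trajectory is non-increasing overall
    losses = np.array([e["train_loss"] for e in log])
    k = max(3, len(losses) // 5)
    smoothed = np.convolve(losses, np.ones(k) / k, mode="valid")
    assert smoothed[-1] <= smoothed[0]


def test_training_single_class_rejected(tiny_config, fast_train_config, rng):
    maps = [FeatureMap(rng.standard_normal((3, 6)), ("a", "b", "c")) for _ in range(8)]
    with pytest.raises(ValueError, match="both classes"):
        train(maps, np.zeros(8, dtype=int), tiny_config, fast_train_config)


def test_training_seeded_determinism(fast_train_config):
    rng = np.random.default_rng(5)
    maps, labels = _gaussian_maps(rng, 10, n_ch=3)
    cfg = EncoderConfig(d_model=12, h=3, d_k=4, d_v=4, L=1, d_ff=16, mlp_hidden=8, seed=11)
    tc = TrainConfig(max_epochs=5, patience=5, batch_size=8)
    p1, log1 = train(maps, labels, cfg, tc)
    p2, log2 = train(maps, labels, cfg, tc)
    assert log1 == log2
    for k in p1.keys():
        np.testing.assert_array_equal(p1[k], p2[k])


def test_channel_attention_uniform_and_hand_computed(rng):
    n = 3
    uniform = np.full((3, n, n), 1.0 / n)
    w = channel_attention(uniform)
    np.testing.assert_allclose(w, np.full(n, 1.0), atol=1e-12)  # 3 heads summed
    heads = rng.random((3, n, n))
    expected = heads.sum(axis=0).mean(axis=0)
    np.testing.assert_allclose(channel_attention(heads), expected, atol=1e-12)
    assert channel_attention(np.full((3, 23, 23), 1 / 23)).shape == (23,)


def test_checkpoint_round_trip(tmp_path, tiny_config, rng):
    params = init_params(tiny_config)
    path = tmp_path / "model.npz"
    save_checkpoint(path, params, tiny_config)
    params2, cfg2 = load_checkpoint(path)
    assert cfg2 == tiny_config
    for k in params.keys():
        np.testing.assert_array_equal(params[k], params2[k])
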