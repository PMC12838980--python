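"""Dual-attention architecture: oracle equivalence, fixed points, shapes."""

import numpy as np
import pytest

from painattn.autodiff import Tensor
from painattn.model import (ChannelAttention, DualAttentionCNN, ModelConfig,
                            SpatialAttention, channel_attention,
                            spatial_attention, triple_pool)

# ---------------------------------------------------------------------------
# brute-force oracles: nested loops, no vectorization
# ---------------------------------------------------------------------------

def oracle_spatial(f, weights):
    C, H, W = f.shape
    refined = np.zeros((C, H, W))
    maps = []
    for head in weights:
        w1, b1 = head["w1"], head["b1"]
        w2, b2 = head["w2"], head["b2"]
        K = w1.shape[0]
        a = np.zeros((H, W))
        for i in range(H):
            for j in range(W):
                hid = [max(sum(w1[k, c, 0, 0] * f[c, i, j] for c in range(C))
                           + b1[k], 0.0) for k in range(K)]
                pre = sum(w2[0, k, 0, 0] * hid[k] for k in range(K)) + b2[0]
                a[i, j] = 1.0 / (1.0 + np.exp(-pre))
        maps.append(a)
        for c in range(C):
            for i in range(H):
                for j in range(W):
                    refined[c, i, j] += a[i, j] * f[c, i, j]
    return refined, np.stack(maps)


def oracle_triple_pool(f):
    C = f.shape[0]
    avg = [float(np.mean(f[c])) for c in range(C)]
    mx = [float(np.max(f[c])) for c in range(C)]
    std = []
    for c in range(C):
        m = avg[c]
        std.append(np.sqrt(sum((v - m) ** 2 for v in f[c].ravel())
                           / f[c].size))
    return np.array(avg + mx + std)


def oracle_channel(f, w1, b1, w2, b2):
    z = oracle_triple_pool(f)
    hid = [max(sum(w1[k, i] * z[i] for i in range(z.size)) + b1[k], 0.0)
           for k in range(w1.shape[0])]
    s = np.array([1.0 / (1.0 + np.exp(-(sum(w2[c, k] * hid[k]
                                            for k in range(len(hid)))
                                        + b2[c])))
                  for c in range(w2.shape[0])])
    out = np.empty_like(f, dtype=float)
    for c in range(f.shape[0]):
        out[c] = s[c] * f[c]
    return out, s


def random_head_weights(rng, c, hidden=3):
    return {
        "w1": rng.normal(0, 1, (hidden, c, 1, 1)),
        "b1": rng.normal(0, 1, hidden),
        "w2": rng.normal(0, 1, (1, hidden, 1, 1)),
        "b2": rng.normal(0, 1, 1),
    }


class TestSpatialAttention:
    def test_matches_loop_oracle_on_small_tensors(self, rng):
        for trial in range(25):
            c, h, w = rng.integers(1, 5, 3)
            f = rng.normal(0, 1, (c, h, w))
            weights = [random_head_weights(rng, c)
                       for _ in range(rng.integers(1, 4))]
            got_f, got_a = spatial_attention(f, weights)
            exp_f, exp_a = oracle_spatial(f, weights)
            assert np.allclose(got_f, exp_f, atol=1e-9)
            assert np.allclose(got_a, exp_a, atol=1e-9)

    def test_zero_weights_give_half_gates_and_2f(self, rng):
        f = rng.normal(0, 1, (3, 4, 4))
        zero = [{k: np.zeros_like(v) for k, v in
                 random_head_weights(rng, 3).items()} for _ in range(4)]
        refined, maps = spatial_attention(f, zero)
        assert np.allclose(maps, 0.5)
        assert np.allclose(refined, 2.0 * f)

    def test_large_bias_approaches_identity(self, rng):
        f = rng.normal(0, 1, (2, 3, 3))
        head = {k: np.zeros_like(v) for k, v in
                random_head_weights(rng, 2).items()}
        head["b2"] = np.array([50.0])  # sigmoid -> 1
        refined, maps = spatial_attention(f, [head])
        assert np.allclose(maps, 1.0, atol=1e-9)
        assert np.allclose(refined, f, atol=1e-9)

    def test_maps_strictly_inside_unit_interval(self, rng):
        f = rng.normal(0, 1, (3, 4, 4))
        weights = [random_head_weights(rng, 3) for _ in range(2)]
        _, maps = spatial_attention(f, weights)
        assert (maps > 0).all() and (maps < 1).all()

    def test_module_matches_functional(self, rng):
        torch_rng = np.random.default_rng(3)
        mod = SpatialAttention(4, 2, torch_rng)
        f = rng.normal(0, 1, (1, 4, 5, 5)).astype(np.float32)
        out, maps = mod(Tensor(f))
        weights = [{
            "w1": pair[0].weight.data, "b1": pair[0].bias.data,
            "w2": pair[1].weight.data, "b2": pair[1].bias.data,
        } for pair in mod.heads]
        exp_f, exp_a = spatial_attention(f[0], weights)
        assert np.allclose(out.data[0], exp_f, atol=1e-5)
        assert np.allclose(np.stack([m.data[0, 0] for m in maps]), exp_a,
                           atol=1e-5)


class TestTriplePool:
    def test_constant_channel(self):
        f = np.full((1, 3, 3), 2.5)
        assert np.allclose(triple_pool(f), [2.5, 2.5, 0.0])

    def test_half_zero_half_two(self):
        f = np.array([[0.0, 2.0], [0.0, 2.0]])[None]
        # population std of {0,0,2,2} is 1
        assert np.allclose(triple_pool(f), [1.0, 2.0, 1.0])

    def test_order_statistics_and_oracle(self, rng):
        for _ in range(25):
            c, h, w = rng.integers(1, 5, 3)
            f = rng.normal(0, 1, (c, h, w))
            z = triple_pool(f)
            assert np.allclose(z, oracle_triple_pool(f), atol=1e-9)
            avg, mx, std = z[:c], z[c:2 * c], z[2 * c:]
            assert (avg <= mx + 1e-12).all()
            assert (std >= 0).all()


class TestChannelAttention:
    def test_matches_oracle(self, rng):
        for _ in range(25):
            c, h, w = 4, 2, 2
            hidden = 2
            f = rng.normal(0, 1, (c, h, w))
            w1 = rng.normal(0, 1, (hidden, 3 * c))
            b1 = rng.normal(0, 1, hidden)
            w2 = rng.normal(0, 1, (c, hidden))
            b2 = rng.normal(0, 1, c)
            got_f, got_s = channel_attention(f, w1, b1, w2, b2)
            exp_f, exp_s = oracle_channel(f, w1, b1, w2, b2)
            assert np.allclose(got_f, exp_f, atol=1e-9)
            assert np.allclose(got_s, exp_s, atol=1e-9)

    def test_zero_weights_halve_features(self, rng):
        c = 4
        f = rng.normal(0, 1, (c, 3, 3))
        out, s = channel_attention(f, np.zeros((2, 3 * c)), np.zeros(2),
                                   np.zeros((c, 2)), np.zeros(c))
        assert np.allclose(s, 0.5)
        assert np.allclose(out, 0.5 * f)

    def test_gates_strictly_in_unit_interval(self, rng):
        c = 3
        f = rng.normal(0, 10, (c, 2, 2))
        _, s = channel_attention(f, rng.normal(0, 1, (2, 3 * c)),
                                 rng.normal(0, 1, 2),
                                 rng.normal(0, 1, (c, 2)), rng.normal(0, 1, c))
        assert (s > 0).all() and (s < 1).all()

    def test_dimension_mismatch_rejected(self, rng):
        f = rng.normal(0, 1, (4, 2, 2))
        with pytest.raises(ValueError):
            channel_attention(f, np.zeros((2, 9)), np.zeros(2),
                              np.zeros((4, 2)), np.zeros(4))

    def test_module_descriptor_order_is_avg_max_std(self, rng):
        mod = ChannelAttention(3, 2, np.random.default_rng(0))
        f = rng.normal(0, 1, (1, 3, 4, 4)).astype(np.float32)
        z = mod.descriptor(Tensor(f)).data[0]
        assert np.allclose(z, triple_pool(f[0]), atol=1e-5)


class TestForward:
    def test_default_flatten_length_is_8192(self):
        assert ModelConfig().flatten_length == 8192

    def test_shape_walk_is_config_determined(self):
        cfg = ModelConfig(channels=(8, 16, 32, 32))
        model = DualAttentionCNN(cfg, rng=0)
        x = Tensor(np.zeros((2, 3, 64, 64), np.float32))
        logits, inter = model.eval().forward(x, return_intermediates=True)
        assert inter["backbone"].shape == (2, 32, 8, 8)
        assert inter["features"].shape == (2, 32, 8, 8)
        assert logits.shape == (2, 5)

    def test_softmax_normalizes(self, rng):
        model = DualAttentionCNN(ModelConfig(channels=(8, 8, 8, 8)), rng=1)
        proba = model.predict_proba(
            rng.normal(0, 1, (3, 3, 64, 64)).astype(np.float32))
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert (proba >= 0).all()

    def test_attention_ablation_preserves_output_shape(self, rng):
        x = rng.normal(0, 1, (2, 3, 64, 64)).astype(np.float32)
        for spatial in (True, False):
            for channel in (True, False):
                cfg = ModelConfig(channels=(8, 8, 8, 8),
                                  use_spatial_attention=spatial,
                                  use_channel_attention=channel)
                model = DualAttentionCNN(cfg, rng=2).eval()
                assert model.forward(Tensor(x)).shape == (2, 5)

    def test_wrong_input_shape_rejected(self):
        model = DualAttentionCNN(ModelConfig(channels=(8, 8, 8, 8)), rng=0)
        with pytest.raises(ValueError, match="expected"):
            model.forward(Tensor(np.zeros((1, 3, 32, 32), np.float32)))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        from painattn.model import load_checkpoint, save_checkpoint

        cfg = ModelConfig(channels=(8, 8, 8, 8))
        model = DualAttentionCNN(cfg, rng=5).eval()
        x = rng.normal(0, 1, (2, 3, 64, 64)).astype(np.float32)
        before = model.predict_proba(x)
        save_checkpoint(model, tmp_path / "ckpt.pkl", extra={"note": "test"})
        loaded, extra = load_checkpoint(tmp_path / "ckpt.pkl")
        assert extra["note"] == "test"
        assert np.allclose(loaded.predict_proba(x), before, atol=1e-7)
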