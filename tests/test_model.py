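"""Architecture tests: parameter count, MAC count, GRN, shapes, checkpoints."""

import numpy as np
import pytest

from afdet.nn.layers import GRN, LayerNorm
from afdet.nn.models import (BaselineConfig, ModelConfig, build_baseline,
                             build_model, count_flops, count_parameters,
                             load_checkpoint, save_checkpoint, softmax)


def closed_form_convnext_params(dims=(16, 32, 64, 128), depths=(3, 3, 9, 3),
                                in_ch=1, num_classes=2):
    """Independent spreadsheet-style parameter sum over layers."""
    total = in_ch * 4 * dims[0] + dims[0]          # stem conv k=4
    total += 2 * dims[0]                           # stem LayerNorm
    for i, (d, depth) in enumerate(zip(dims, depths)):
        if i > 0:
            total += 2 * dims[i - 1]               # downsample LayerNorm
            total += dims[i - 1] * 2 * d + d       # downsample conv k=2
        per_block = (d * 7 + d) + 2 * d \
            + (d * 4 * d + 4 * d) + 2 * (4 * d) \
            + (4 * d * d + d)                      # dw + LN + expand + GRN + reduce
        total += depth * per_block
    total += 2 * dims[-1]                          # head LayerNorm
    total += dims[-1] * num_classes + num_classes  # head linear
    return total


def closed_form_convnext_macs(input_len=1250, dims=(16, 32, 64, 128),
                              depths=(3, 3, 9, 3), in_ch=1, num_classes=2):
    t = input_len // 4
    macs = t * dims[0] * in_ch * 4
    for i, (d, depth) in enumerate(zip(dims, depths)):
        if i > 0:
            t //= 2
            macs += t * d * dims[i - 1] * 2
        macs += depth * (t * d * 7 + 2 * t * 4 * d * d)
    macs += dims[-1] * num_classes
    return macs


class TestParameterCount:
    def test_default_config_rounds_to_770k(self):
        n = count_parameters(build_model())
        assert round(n / 10_000) * 10 == 770

    def test_matches_closed_form(self):
        assert count_parameters(build_model()) == closed_form_convnext_params()
        cfg = ModelConfig(dims=(8, 16, 24, 48), depths=(2, 2, 4, 2))
        assert count_parameters(build_model(cfg)) == \
            closed_form_convnext_params(cfg.dims, cfg.depths)

    def test_baseline_lands_near_70k(self):
        n = count_parameters(build_baseline())
        assert 60_000 <= n <= 85_000

    def test_single_linear_layer(self):
        from afdet.nn.layers import Linear

        lin = Linear(128, 2, np.random.default_rng(0))
        assert sum(v.size for v in lin.params.values()) == 258


class TestFlops:
    def test_within_5pct_of_printed_budget(self):
        assert count_flops(build_model(), 1250) == pytest.approx(46.3, rel=0.05)

    def test_matches_closed_form_exactly(self):
        assert count_flops(build_model(), 1250) * 1e6 == \
            closed_form_convnext_macs()

    def test_single_patch_conv_cost(self):
        from afdet.nn.layers import PatchConv

        conv = PatchConv(1, 16, 4, np.random.default_rng(0))
        macs, t = conv.flops(1250)
        assert (macs, t) == (312 * 16 * 1 * 4, 312)

    def test_stage3_cost_additive_in_depth(self):
        base = count_flops(build_model(ModelConfig()), 1250)
        deeper = count_flops(
            build_model(ModelConfig(depths=(3, 3, 18, 3))), 1250)
        per_block_stage3 = (78 * 64 * 7 + 2 * 78 * 256 * 64) / 1e6
        assert deeper - base == pytest.approx(9 * per_block_stage3)


class TestTopology:
    def test_temporal_lengths_after_stem_and_downsamplers(self):
        model = build_model()
        lengths = []
        t = 1250
        for layer in model.features.layers:
            _, t = layer.flops(t)
            lengths.append(t)
        assert 312 in lengths and 156 in lengths and 78 in lengths
        assert lengths[-1] == 39

    def test_forward_smoke_and_softmax(self):
        model = build_model()
        x = np.random.default_rng(0).normal(size=(2, 1, 1250))
        logits = model.forward(x)
        assert logits.shape == (2, 2)
        assert np.isfinite(logits).all()
        p = softmax(logits)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()

    def test_baseline_temporal_lengths_and_forward(self):
        model = build_baseline()
        t = 1250
        lengths = []
        for layer in model.features.layers:
            _, t = layer.flops(t)
            lengths.append(t)
        assert [l for l in lengths if l != 1250][:0] == []  # only convs shrink
        assert sorted(set(lengths), reverse=True) == [625, 313, 157, 79]
        x = np.random.default_rng(1).normal(size=(3, 1, 1250))
        logits = model.forward(x)
        assert logits.shape == (3, 2) and np.isfinite(logits).all()

    def test_shift_tolerance_on_periodic_input(self, small_model):
        """Global average pooling makes logits nearly invariant to circular
        shifts by the total stride (32 samples) on periodic inputs."""
        t = np.arange(1248)
        x = np.sin(2 * np.pi * t / 96)[None, None, :].astype(np.float32)
        x_shift = np.roll(x, 32, axis=2)
        a = small_model.forward(x)
        b = small_model.forward(x_shift)
        assert np.abs(a - b).max() < 1e-3


class TestGRN:
    def test_identity_at_initialization(self):
        grn = GRN(8)
        x = np.random.default_rng(0).normal(size=(2, 20, 8)).astype(np.float32)
        assert np.allclose(grn.forward(x), x, atol=1e-6)

    def test_identical_channels_normalize_to_one(self):
        grn = GRN(4)
        grn.params["g"] = np.ones(4, dtype=np.float32)
        x = np.tile(np.random.default_rng(1).normal(size=(1, 30, 1)),
                    (1, 1, 4)).astype(np.float32)
        # with N(x)_c = 1 for all c, output = g*x + b + x = 2x
        assert np.allclose(grn.forward(x), 2 * x, atol=1e-5)

    def test_matches_direct_two_line_evaluation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 17, 6)).astype(np.float32)
        grn = GRN(6)
        grn.params["g"] = np.ones(6, dtype=np.float32)
        out = grn.forward(x)
        G = np.linalg.norm(x, axis=1)
        N = G / (G.mean(-1, keepdims=True) + 1e-6)
        assert np.allclose(out, x * N[:, None, :] + x, atol=1e-5)


class TestLayerNorm:
    def test_normalizes_channel_axis(self):
        ln = LayerNorm(16)
        x = np.random.default_rng(0).normal(2.0, 3.0, (4, 10, 16)).astype(np.float32)
        y = ln.forward(x)
        assert np.allclose(y.mean(-1), 0.0, atol=1e-5)
        assert np.allclose(y.std(-1), 1.0, atol=1e-3)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, small_model):
        x = np.random.default_rng(3).normal(size=(4, 1, 1250))
        before = small_model.forward(x)
        save_checkpoint(small_model, tmp_path / "ckpt.npz")
        back = load_checkpoint(tmp_path / "ckpt.npz")
        assert np.allclose(back.forward(x), before, atol=1e-7)

    def test_baseline_round_trip(self, tmp_path):
        model = build_baseline(BaselineConfig(channels=(4, 8, 12, 16), seed=2))
        x = np.random.default_rng(4).normal(size=(2, 1, 1250))
        before = model.forward(x)
        save_checkpoint(model, tmp_path / "b.npz")
        assert np.allclose(load_checkpoint(tmp_path / "b.npz").forward(x),
                           before, atol=1e-7)
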