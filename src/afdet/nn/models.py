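"""The 1D ConvNeXtV2 classifier and the four-block CNN baseline.

Both networks map a single-lead 10 s window (1×1250 samples at 125 Hz) to a
two-dimensional logit vector (l_NSR, l_AFib); softmax turns the logits into
class posteriors. The ConvNeXt topology is

    stem (conv k=4, s=4 + LayerNorm)
    -> stage 1 (3 blocks, 16 ch) -> downsample (LayerNorm + conv k=2, s=2)
    -> stage 2 (3 blocks, 32 ch) -> downsample
    -> stage 3 (9 blocks, 64 ch) -> downsample
    -> stage 4 (3 blocks, 128 ch)
    -> global average pool -> LayerNorm -> linear to 2 logits

with each block = depthwise conv (k=7) -> LayerNorm -> pointwise expand x4 ->
GELU -> GRN -> pointwise reduce -> residual. Temporal lengths on a 1250-sample
input are 312 / 156 / 78 / 39. The stage depths (3, 3, 9, 3) are the canonical
ConvNeXt pattern; with dims (16, 32, 64, 128) they give 766,882 trainable
parameters (~770 k) and ~45.9 M multiply-accumulates per window, consistent
with the published size and compute budget. No recurrent or attention layers
are used anywhere.

The baseline stacks four [strided conv k=7 s=2 ('same' padding) -> batch norm
-> dropout 0.25 -> ReLU] blocks with 16/32/64/128 channels, then concatenated
global average + max pooling and a linear head (~77 k parameters).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .layers import (F32, GELU, GRN, BatchNorm, DepthwiseConv, Dropout,
                     GlobalAvgMaxPool, GlobalAvgPool, LayerNorm, Linear,
                     Module, PatchConv, ReLU, Residual, Sequential, StridedConv)

__all__ = ["ModelConfig", "BaselineConfig", "Model", "build_model",
           "build_baseline", "count_parameters", "count_flops", "softmax",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 1
    dims: tuple[int, ...] = (16, 32, 64, 128)
    depths: tuple[int, ...] = (3, 3, 9, 3)
    stem_kernel: int = 4
    stem_stride: int = 4
    down_kernel: int = 2
    down_stride: int = 2
    dw_kernel: int = 7
    expansion: int = 4
    num_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dims) != len(self.depths):
            raise ValueError("dims and depths must have equal length")
        if min(self.dims) < 1 or min(self.depths) < 1:
            raise ValueError("dims and depths must be positive")
        if self.stem_kernel != self.stem_stride or self.down_kernel != self.down_stride:
            raise ValueError("stem/downsample layers are patchifying: kernel "
                             "must equal stride")


@dataclass(frozen=True)
class BaselineConfig:
    channels: tuple[int, ...] = (16, 32, 64, 128)
    kernel: int = 7
    stride: int = 2
    dropout: float = 0.25
    in_channels: int = 1
    num_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


class Model:
    """A feature extractor plus classification head over N×C×L inputs.

    ``forward`` accepts ``(N, C, L)`` (or ``(N, L)``) float arrays and returns
    ``(N, num_classes)`` logits. ``forward_features`` exposes the last-stage
    feature map (batch, time, channels) for class-activation mapping, and
    ``backward`` propagates a logit gradient back to the input, optionally
    with guided-backpropagation gating.
    """

    def __init__(self, features: Sequential, head: Sequential, config) -> None:
        self.features = features
        self.head = head
        self.config = config

    # -- plumbing ----------------------------------------------------------
    def modules(self):
        yield from self.features.modules()
        yield from self.head.modules()

    def zero_grad(self) -> None:
        self.features.zero_grad()
        self.head.zero_grad()

    def parameters(self):
        for m in self.modules():
            for k in m.params:
                yield m, k

    # -- compute -----------------------------------------------------------
    @staticmethod
    def _to_internal(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        if x.ndim == 2:
            x = x[:, None, :]
        if x.ndim != 3:
            raise ValueError("input must be (N, C, L) or (N, L)")
        return x.transpose(0, 2, 1)  # -> (N, L, C)

    def forward_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.features.forward(self._to_internal(x), train=train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.forward_features(x, train=train), train=train)

    def backward(self, dlogits: np.ndarray, guided: bool = False) -> np.ndarray:
        dfeat = self.head.backward(dlogits, guided=guided)
        dx = self.features.backward(dfeat, guided=guided)
        return dx.transpose(0, 2, 1)  # back to (N, C, L)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax posteriors (p_NSR, p_AFib) per window, computed in batches."""
        x = np.asarray(x)
        out = []
        for lo in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[lo:lo + batch_size])))
        return np.concatenate(out) if out else np.empty((0, 2))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _convnext_block(dim: int, cfg: ModelConfig, rng) -> Module:
    hidden = cfg.expansion * dim
    return Residual(Sequential(
        DepthwiseConv(dim, cfg.dw_kernel, rng),
        LayerNorm(dim),
        Linear(dim, hidden, rng),
        GELU(),
        GRN(hidden),
        Linear(hidden, dim, rng),
    ))


def build_model(cfg: ModelConfig = ModelConfig()) -> Model:
    """Instantiate the 1D ConvNeXtV2 classifier from its configuration."""
    rng = np.random.default_rng(cfg.seed)
    layers: list[Module] = [
        PatchConv(cfg.in_channels, cfg.dims[0], cfg.stem_kernel, rng),
        LayerNorm(cfg.dims[0]),
    ]
    for stage, (dim, depth) in enumerate(zip(cfg.dims, cfg.depths)):
        if stage > 0:
            layers += [LayerNorm(cfg.dims[stage - 1]),
                       PatchConv(cfg.dims[stage - 1], dim, cfg.down_kernel, rng)]
        layers += [_convnext_block(dim, cfg, rng) for _ in range(depth)]
    head = Sequential(
        GlobalAvgPool(),
        LayerNorm(cfg.dims[-1]),
        Linear(cfg.dims[-1], cfg.num_classes, rng),
    )
    return Model(Sequential(*layers), head, cfg)


def build_baseline(cfg: BaselineConfig = BaselineConfig()) -> Model:
    """Instantiate the four-block strided-CNN baseline."""
    rng = np.random.default_rng(cfg.seed)
    layers: list[Module] = []
    in_ch = cfg.in_channels
    for i, ch in enumerate(cfg.channels):
        layers += [
            StridedConv(in_ch, ch, cfg.kernel, cfg.stride, rng),
            BatchNorm(ch),
            Dropout(cfg.dropout, seed=cfg.seed + 1000 + i),
            ReLU(),
        ]
        in_ch = ch
    head = Sequential(
        GlobalAvgMaxPool(),
        Linear(2 * cfg.channels[-1], cfg.num_classes, rng),
    )
    return Model(Sequential(*layers), head, cfg)


def count_parameters(model: Model) -> int:
    """Exact number of trainable scalars (batch-norm running stats excluded)."""
    return model.features.n_params() + model.head.n_params()


def count_flops(model: Model, input_len: int = 1250) -> float:
    """Multiply-accumulate count of one forward pass, in MFLOP (1 MAC = 1 FLOP).

    Convolutions cost out_len × out_ch × in_ch_per_group × kernel, linear
    layers in × out; normalizations, activations and pooling are excluded.
    This is the convention of the common FLOP-counting tools.
    """
    mac_f, t = model.features.flops(input_len)
    mac_h, _ = model.head.flops(t)
    return (mac_f + mac_h) / 1e6


def save_checkpoint(model: Model, path: str | os.PathLike) -> None:
    """Save parameters, buffers and config as a compressed .npz."""
    import json
    from dataclasses import asdict

    state = {f"f:{k}": v for k, v in model.features.state_entries()}
    state |= {f"h:{k}": v for k, v in model.head.state_entries()}
    kind = "baseline" if isinstance(model.config, BaselineConfig) else "convnext"
    meta = np.array(json.dumps({"kind": kind, "config": asdict(model.config)}))
    np.savez_compressed(os.fspath(path), __meta__=meta, **state)


def load_checkpoint(path: str | os.PathLike) -> Model:
    import json

    with np.load(os.fspath(path), allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k: z[k] for k in z.files if k != "__meta__"}
    cfg_d = meta["config"]
    for key in ("dims", "depths", "channels"):
        if key in cfg_d:
            cfg_d[key] = tuple(cfg_d[key])
    if meta["kind"] == "baseline":
        model = build_baseline(BaselineConfig(**cfg_d))
    else:
        model = build_model(ModelConfig(**cfg_d))
    model.features.load_state({k[2:]: v for k, v in state.items()
                               if k.startswith("f:")})
    model.head.load_state({k[2:]: v for k, v in state.items()
                           if k.startswith("h:")})
    return model
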