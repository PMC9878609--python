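"""Dense-residual 3D convolutional classifier with deep supervision.

The architecture template: a stack of dense blocks, each a sequence of units
that receive the channel-concatenation of everything before them. One unit is

    bottleneck:  u0 = leaky(conv1x1x1(BN(x)))          (mixes to `growth` ch)
    residual:    u1 = u0 + leaky(conv3x3x3(BN(u0)))
    residual:    u2 = u1 + leaky(conv7x7x7(BN(u1)))    -> appended to the state

so batch-norm precedes every convolution, a leaky rectifier follows it, every
unit contains identity-skip residual paths, and all three kernel scales
(1, 3, 7 voxels) appear in every unit. Between blocks, max-pooled and
average-pooled (2^3, stride 2) maps are averaged. Each dense block feeds an
auxiliary classification head (global average pooling -> dropout -> linear),
and a final 1x1x1 feature layer feeds the main head; during training all
heads enter the loss (deep supervision), at inference only the final head is
read.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .layers import (
    BatchNorm,
    Parameter,
    Tensor,
    add,
    concat_channels,
    conv3d,
    dropout,
    dual_pool,
    global_avg_pool,
    leaky_relu,
    linear,
    softmax,
)


@dataclass(frozen=True)
class CnnConfig:
    """Desk-scalable architecture hyperparameters."""

    n_classes: int
    in_channels: int = 2
    n_dense_blocks: int = 3
    units_per_block: tuple[int, ...] = (2, 2, 2)
    growth: int = 8
    kernel_sizes: tuple[int, ...] = (1, 3, 7)
    leaky_slope: float = 0.01
    dropout: float = 0.2
    head_channels: int = 32
    aux_heads: bool = True
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_dense_blocks < 1:
            raise ValueError("n_dense_blocks must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be odd")
        ub = self.units_per_block
        if isinstance(ub, int):
            object.__setattr__(self, "units_per_block", (ub,) * self.n_dense_blocks)
        elif len(ub) != self.n_dense_blocks:
            raise ValueError("units_per_block must have one entry per dense block")

    def np_dtype(self):
        return np.dtype(self.dtype)


def check_input_shape(config: CnnConfig, spatial_shape: tuple[int, int, int]) -> None:
    """Raise if the grid cannot survive the between-block poolings."""
    dims = list(spatial_shape)
    for b in range(config.n_dense_blocks - 1):
        if min(dims) < 2:
            raise ValueError(
                f"input grid {spatial_shape} cannot survive pooling {b + 1} "
                f"of {config.n_dense_blocks - 1} (dim fell below 2)"
            )
        dims = [d // 2 for d in dims]


class _Conv:
    def __init__(self, k, c_in, c_out, rng, dtype):
        fan_in = k**3 * c_in
        self.w = Parameter(
            (rng.standard_normal((k, k, k, c_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        )
        self.b = Parameter(np.zeros(c_out, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class _Unit:
    """One dense unit: bottleneck + residual convs at the remaining kernel scales."""

    def __init__(self, c_in, growth, kernels, rng, dtype):
        ks = sorted(kernels)
        self.bns = [BatchNorm(c_in, dtype)]
        self.convs = [_Conv(ks[0], c_in, growth, rng, dtype)]
        for k in ks[1:]:
            self.bns.append(BatchNorm(growth, dtype))
            self.convs.append(_Conv(k, growth, growth, rng, dtype))

    def __call__(self, x: Tensor, training: bool, slope: float) -> Tensor:
        h = leaky_relu(self.convs[0](self.bns[0](x, training)), slope)
        for bn, conv in zip(self.bns[1:], self.convs[1:]):
            h = add(h, leaky_relu(conv(bn(h, training)), slope))
        return h

    def parameters(self):
        out = []
        for bn in self.bns:
            out += bn.parameters()
        for c in self.convs:
            out += c.parameters()
        return out

    def batchnorms(self):
        return self.bns


class _Head:
    def __init__(self, c_in, n_classes, rng, dtype):
        self.w = Parameter((rng.standard_normal((c_in, n_classes)) / np.sqrt(c_in)).astype(dtype))
        self.b = Parameter(np.zeros(n_classes, dtype=dtype))

    def __call__(self, feat: Tensor, p_drop, training, rng) -> Tensor:
        h = dropout(global_avg_pool(feat), p_drop, training, rng)
        return linear(h, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class DenseResNet3D:
    """The classifier. ``forward`` returns one logits tensor per head (final last)."""

    def __init__(self, config: CnnConfig, rng_seed: int = 0):
        self.config = config
        dtype = config.np_dtype()
        rng = np.random.default_rng(rng_seed)
        self.blocks: list[list[_Unit]] = []
        self.heads: list[_Head] = []
        c = config.in_channels
        for b in range(config.n_dense_blocks):
            units = []
            for _ in range(config.units_per_block[b]):
                units.append(_Unit(c, config.growth, config.kernel_sizes, rng, dtype))
                c += config.growth
            self.blocks.append(units)
            if config.aux_heads:
                self.heads.append(_Head(c, config.n_classes, rng, dtype))
        # final feature layer and final head
        self.final_bn = BatchNorm(c, dtype)
        self.final_conv = _Conv(1, c, config.head_channels, rng, dtype)
        self.final_head = _Head(config.head_channels, config.n_classes, rng, dtype)

    # -- plumbing ---------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        out = []
        for units in self.blocks:
            for u in units:
                out += u.parameters()
        for h in self.heads:
            out += h.parameters()
        out += self.final_bn.parameters() + self.final_conv.parameters()
        out += self.final_head.parameters()
        return out

    def batchnorms(self) -> list[BatchNorm]:
        out = []
        for units in self.blocks:
            for u in units:
                out += u.batchnorms()
        out.append(self.final_bn)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i}"] = p.data
        for i, bn in enumerate(self.batchnorms()):
            state[f"bn_{i}_mean"] = bn.running_mean
            state[f"bn_{i}_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.array(state[f"param_{i}"])
        for i, bn in enumerate(self.batchnorms()):
            bn.running_mean = np.array(state[f"bn_{i}_mean"])
            bn.running_var = np.array(state[f"bn_{i}_var"])

    # -- forward ----------------------------------------------------------
    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> list[Tensor]:
        """x: (N, X, Y, Z, C) channels-last batch. Returns per-head logits, final last."""
        cfg = self.config
        check_input_shape(cfg, x.shape[1:4])
        if rng is None:
            rng = np.random.default_rng(0)
        t = Tensor(np.ascontiguousarray(x, dtype=cfg.np_dtype()))
        logits: list[Tensor] = []
        for b, units in enumerate(self.blocks):
            state = t
            for u in units:
                out = u(state, training, cfg.leaky_slope)
                state = concat_channels([state, out])
            if cfg.aux_heads:
                logits.append(self.heads[b](state, cfg.dropout, training, rng))
            if b < len(self.blocks) - 1:
                state = dual_pool(state)
            t = state
        feat = leaky_relu(self.final_conv(self.final_bn(t, training)), cfg.leaky_slope)
        logits.append(self.final_head(feat, cfg.dropout, training, rng))
        return logits

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Final-head softmax probabilities for a channels-last batch, (N, K)."""
        outs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], training=False)[-1]
            outs.append(softmax(logits.data))
        return np.concatenate(outs, axis=0)


def save_model(model: DenseResNet3D, path) -> None:
    """Single-file checkpoint: arrays plus the embedded architecture JSON."""
    cfg = json.dumps(asdict(model.config))
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **model.state_dict())


def load_model(path) -> DenseResNet3D:
    with np.load(path) as z:
        cfg_raw = json.loads(bytes(z["__config__"]).decode())
        cfg_raw["units_per_block"] = tuple(cfg_raw["units_per_block"])
        cfg_raw["kernel_sizes"] = tuple(cfg_raw["kernel_sizes"])
        config = CnnConfig(**cfg_raw)
        model = DenseResNet3D(config)
        model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
    return model
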