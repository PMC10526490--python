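"""Trainable layers built on the autodiff core."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from . import functional as F

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "DeformableConv2d",
    "BatchNorm2d",
    "ECAConfig",
    "eca_kernel_size",
    "ECABlock",
    "GRU",
    "BiGRU",
    "bigru_forward",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Tensor(rng.uniform(-bound, bound, (in_features, out_features)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int = 0,
        bias: bool = True,
        zero_init: bool = False,
    ):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        shape = (out_channels, in_channels, kernel_size, kernel_size)
        if zero_init:
            w = np.zeros(shape)
        else:
            w = rng.normal(0.0, math.sqrt(2.0 / fan_in), shape)  # He init
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.stride = stride
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class DeformableConv2d(Module):
    """3x3 (by default) convolution whose sampling grid is displaced by learned offsets.

    The offset-predicting convolution is zero-initialized so that at
    construction the layer is exactly a standard convolution; ``use_offsets``
    can be cleared to force the standard-convolution route with the same
    kernel weights (used as an equivalence oracle in tests).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        kernel_size: int = 3,
        stride: int = 1,
        pad: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        n_taps = kernel_size * kernel_size
        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng, stride=stride, pad=pad, bias=bias)
        self.offset_conv = Conv2d(
            in_channels, 2 * n_taps, kernel_size, rng, stride=stride, pad=pad, bias=True, zero_init=True
        )
        self.stride = stride
        self.pad = pad
        self.use_offsets = True

    def forward(self, x: Tensor) -> Tensor:
        if not self.use_offsets:
            return self.conv(x)
        offsets = self.offset_conv(x)
        return F.deform_conv2d(
            x, offsets, self.conv.weight, self.conv.bias, stride=self.stride, pad=self.pad
        )

    def offset_parameter_count(self) -> int:
        n = self.offset_conv.weight.data.size
        if self.offset_conv.bias is not None:
            n += self.offset_conv.bias.data.size
        return n


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
            xhat = centered * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        C = self.gamma.data.shape[0]
        return xhat * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


# --------------------------------------------------------------------------
# efficient channel attention
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ECAConfig:
    gamma: float = 2.0
    b: float = 1.0
    residual: bool = True

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


def eca_kernel_size(C: int, cfg: ECAConfig = ECAConfig()) -> int:
    """Adaptive 1D kernel size: the odd integer nearest to (log2(C) + b) / gamma.

    Exact half-way values round down to the smaller odd number; the result is
    clamped to be at least 1.
    """
    if C < 1:
        raise ValueError(f"channel count must be >= 1, got {C}")
    t = (math.log2(C) + cfg.b) / cfg.gamma
    lower = 2 * math.floor((t - 1.0) / 2.0) + 1  # greatest odd <= t
    upper = lower + 2
    k = lower if (t - lower) <= (upper - t) else upper
    return max(int(k), 1)


class ECABlock(Module):
    """Channel gate: global average pool -> size-k 1D conv across channels ->
    sigmoid -> rescale, optionally followed by an identity residual add."""

    def __init__(self, channels: int, rng: np.random.Generator, cfg: ECAConfig = ECAConfig()):
        super().__init__()
        self.cfg = cfg
        self.kernel_size = eca_kernel_size(channels, cfg)
        bound = 1.0 / math.sqrt(self.kernel_size)
        self.weight = Tensor(rng.uniform(-bound, bound, self.kernel_size), requires_grad=True)
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        B, C = x.data.shape[:2]
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        pooled = x.mean(axis=(2, 3))  # (B, C)
        gate = F.channel_conv1d(pooled, self.weight).sigmoid()
        out = x * gate.reshape(B, C, 1, 1)
        if self.cfg.residual:
            out = out + x
        return out

    def gate_values(self, x: Tensor) -> np.ndarray:
        """The (0,1) per-channel gate, for introspection/tests."""
        pooled = Tensor(x.data.mean(axis=(2, 3)))
        return F.channel_conv1d(pooled, Tensor(self.weight.data)).sigmoid().data


# --------------------------------------------------------------------------
# gated recurrent units
# --------------------------------------------------------------------------

class GRU(Module):
    """Single-direction GRU over a sequence of (B, input_size) steps."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        bound = 1.0 / math.sqrt(hidden_size)

        def mk(*shape):
            return Tensor(rng.uniform(-bound, bound, shape), requires_grad=True)

        self.w_z, self.u_z, self.b_z = mk(input_size, hidden_size), mk(hidden_size, hidden_size), mk(hidden_size)
        self.w_r, self.u_r, self.b_r = mk(input_size, hidden_size), mk(hidden_size, hidden_size), mk(hidden_size)
        self.w_h, self.u_h, self.b_h = mk(input_size, hidden_size), mk(hidden_size, hidden_size), mk(hidden_size)

    def forward(self, steps: list[Tensor]) -> list[Tensor]:
        if len(steps) == 0:
            raise ValueError("GRU requires a non-empty sequence")
        B = steps[0].data.shape[0]
        h = Tensor(np.zeros((B, self.hidden_size)))
        outputs = []
        for x in steps:
            z = (x @ self.w_z + h @ self.u_z + self.b_z).sigmoid()
            r = (x @ self.w_r + h @ self.u_r + self.b_r).sigmoid()
            h_tilde = (x @ self.w_h + (r * h) @ self.u_h + self.b_h).tanh()
            h = (1.0 - z) * h + z * h_tilde
            outputs.append(h)
        return outputs

    def weight_names(self):
        return ("w_z", "u_z", "b_z", "w_r", "u_r", "b_r", "w_h", "u_h", "b_h")


class BiGRU(Module):
    """Two GRUs over opposite directions, outputs concatenated per step."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.forward_gru = GRU(input_size, hidden_size, rng)
        self.backward_gru = GRU(input_size, hidden_size, rng)
        self.hidden_size = hidden_size

    def forward(self, steps: list[Tensor]) -> list[Tensor]:
        fwd = self.forward_gru(steps)
        bwd = self.backward_gru(steps[::-1])[::-1]
        return [concat([f, b], axis=1) for f, b in zip(fwd, bwd)]

    def final_state(self, steps: list[Tensor]) -> Tensor:
        """Concatenation of the last forward state and the last backward state."""
        fwd = self.forward_gru(steps)
        bwd = self.backward_gru(steps[::-1])
        return concat([fwd[-1], bwd[-1]], axis=1)

    def swap_directions(self) -> None:
        """Exchange the forward and backward weight sets (test utility)."""
        for name in self.forward_gru.weight_names():
            a, b = getattr(self.forward_gru, name), getattr(self.backward_gru, name)
            a.data, b.data = b.data.copy(), a.data.copy()


def bigru_forward(seq: np.ndarray, layer: BiGRU) -> np.ndarray:
    """Run a (T, B, F) array through a BiGRU; returns (T, B, 2*hidden)."""
    seq = np.asarray(seq, dtype=np.float64)
    if seq.ndim != 3 or seq.shape[0] < 1:
        raise ValueError("sequence must be (T, B, F) with T >= 1")
    steps = [Tensor(seq[t]) for t in range(seq.shape[0])]
    outs = layer(steps)
    return np.stack([o.data for o in outs], axis=0)
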