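"""Neural layers for the dual-head sequence models.

Conventions: sequence batches are (N, T, D) at the model boundary;
convolutional layers operate channel-first (N, C, T) internally.
All parameters are float64; initialisation uses a caller-supplied
``numpy.random.Generator`` so whole models are reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate

__all__ = [
    "Module", "Linear", "Conv1d", "MaxPool1d", "Dropout", "LSTM",
    "SERes2Block", "AttentiveStatsPool",
]


class Module:
    """Base class: parameter discovery by attribute scan."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()


def _fan_in_init(rng: np.random.Generator, shape: tuple, fan_in: int):
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = _fan_in_init(rng, (d_in, d_out), d_in)
        self.b = _fan_in_init(rng, (d_out,), d_in)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """1-D convolution over time, channel-first (N, C_in, T) -> (N, C_out, T')."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, dilation: int = 1,
                 padding: int = 0):
        fan_in = c_in * kernel
        self.w = _fan_in_init(rng, (c_in * kernel, c_out), fan_in)
        self.b = _fan_in_init(rng, (c_out,), fan_in)
        self.kernel, self.stride, self.dilation = kernel, stride, dilation
        self.padding = padding
        self.c_in, self.c_out = c_in, c_out

    def out_length(self, t_in: int) -> int:
        span = (self.kernel - 1) * self.dilation + 1
        return (t_in + 2 * self.padding - span) // self.stride + 1

    def __call__(self, x: Tensor) -> Tensor:
        n, c, t = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        if self.padding:
            pad = Tensor(np.zeros((n, c, self.padding)))
            x = concatenate([pad, x, pad], axis=2)
            t = t + 2 * self.padding
        span = (self.kernel - 1) * self.dilation + 1
        t_out = (t - span) // self.stride + 1
        if t_out < 1:
            raise ValueError("input too short for convolution")
        starts = np.arange(t_out) * self.stride
        idx = starts[:, None] + np.arange(self.kernel) * self.dilation
        cols = x.take_time(idx)                       # (N, C_in, T_out, K)
        cols = cols.transpose(0, 2, 1, 3).reshape(n, t_out,
                                                  self.c_in * self.kernel)
        out = cols @ self.w + self.b                  # (N, T_out, C_out)
        return out.transpose(0, 2, 1)


class MaxPool1d(Module):
    """Non-overlapping max pooling over time; trailing remainder is dropped."""

    def __init__(self, kernel: int = 3):
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        n, c, t = x.shape
        k = self.kernel
        if t < k:
            raise ValueError("sequence shorter than pooling kernel")
        t_out = t // k
        x = x[:, :, : t_out * k]
        return x.reshape(n, c, t_out, k).max(axis=3)


class Dropout(Module):
    """Inverted dropout; identity when `training` is False or p == 0."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        if not training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LSTM(Module):
    """Unidirectional LSTM; returns the full hidden-state sequence.

    Forget-gate bias initialised to 1 (standard recipe for short sequences).
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.wx = _fan_in_init(rng, (d_in, 4 * hidden), d_in)
        self.wh = _fan_in_init(rng, (hidden, 4 * hidden), hidden)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        n, t, _ = x.shape
        h = Tensor(np.zeros((n, self.hidden)))
        c = Tensor(np.zeros((n, self.hidden)))
        hs = []
        hid = self.hidden
        for step in range(t):
            z = x[:, step, :] @ self.wx + h @ self.wh + self.b
            i = z[:, :hid].sigmoid()
            f = z[:, hid:2 * hid].sigmoid()
            g = z[:, 2 * hid:3 * hid].tanh()
            o = z[:, 3 * hid:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs.append(h.reshape(n, 1, hid))
        return concatenate(hs, axis=1)            # (N, T, H)


class SERes2Block(Module):
    """Res2-style multi-scale dilated convolution with squeeze-excitation.

    The channel dimension is split into `scale` groups; each group past the
    first is convolved (dilated) and added to the running branch, giving a
    hierarchy of receptive fields. A squeeze-excitation gate then rescales
    channels using a global (time-averaged) descriptor. Residual throughout.
    """

    def __init__(self, channels: int, kernel: int, dilation: int,
                 rng: np.random.Generator, scale: int = 4,
                 se_bottleneck: int = 32):
        if channels % scale:
            raise ValueError("channels must be divisible by scale")
        width = channels // scale
        pad = dilation * (kernel - 1) // 2
        self.conv_in = Conv1d(channels, channels, 1, rng)
        self.scale_convs = [
            Conv1d(width, width, kernel, rng, dilation=dilation, padding=pad)
            for _ in range(scale - 1)
        ]
        self.conv_out = Conv1d(channels, channels, 1, rng)
        self.se_down = Linear(channels, se_bottleneck, rng)
        self.se_up = Linear(se_bottleneck, channels, rng)
        self.scale, self.width = scale, width

    def __call__(self, x: Tensor) -> Tensor:
        n, c, t = x.shape
        y = self.conv_in(x).relu()
        parts = [y[:, :self.width, :]]
        branch = parts[0]
        for s, conv in enumerate(self.scale_convs, start=1):
            chunk = y[:, s * self.width:(s + 1) * self.width, :]
            branch = conv(chunk + branch).relu()
            parts.append(branch)
        y = concatenate(parts, axis=1)
        y = self.conv_out(y).relu()
        # squeeze-excitation on the time-averaged descriptor
        s = self.se_up(self.se_down(y.mean(axis=2)).relu()).sigmoid()
        y = y * s.reshape(n, c, 1)
        return y + x


class AttentiveStatsPool(Module):
    """Attentive statistics pooling: (N, C, T) -> (N, 2C).

    A small tanh attention network scores each frame; the output is the
    attention-weighted mean and standard deviation per channel.
    """

    def __init__(self, channels: int, attention_dim: int,
                 rng: np.random.Generator):
        self.att_in = Linear(channels, attention_dim, rng)
        self.att_out = Linear(attention_dim, channels, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, t = x.shape
        frames = x.transpose(0, 2, 1)                       # (N, T, C)
        scores = self.att_out(self.att_in(frames).tanh())   # (N, T, C)
        alpha = scores.softmax(axis=1)
        mu = (alpha * frames).sum(axis=1)                   # (N, C)
        var = (alpha * frames * frames).sum(axis=1) - mu * mu
        from .autodiff import maximum
        sd = maximum(var, 1e-8).sqrt()
        return concatenate([mu, sd], axis=1)                # (N, 2C)
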