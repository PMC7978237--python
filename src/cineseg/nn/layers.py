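"""Neural-network layers built on the :mod:`cineseg.nn.tensor` autograd core.

Conventions: NCHW activations, float32 parameters, He-uniform init for
convolution kernels and orthogonal init for recurrent (ConvLSTM) kernels.
Every layer draws its initial weights from an explicit numpy Generator so
model construction is reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, conv2d, conv_transpose2d

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "LeakyReLU",
    "ConvLSTM2d",
]

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data, requires_grad: bool = True):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=requires_grad)


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if rows < cols:
        q = q.T
    return q[:rows, :cols].astype(DTYPE)


class Module:
    """Minimal module container with recursive parameter discovery."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{path}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{path}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def freeze(self, frozen: bool = True):
        for p in self.parameters():
            p.requires_grad = not frozen
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{path}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{path}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield path, value

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = []
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: "
                        f"{params[name].data.shape} vs {arr.shape}"
                    )
                params[name].data[...] = arr
            elif name in buffers:
                buffers[name][...] = arr
            elif strict:
                missing.append(name)
        if strict and missing:
            raise KeyError(f"unknown entries in state dict: {missing[:5]}")
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 padding: int | None = None, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if padding is None:  # 'same' for stride 1
            padding = dilation * (kernel - 1) // 2
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(he_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int,
                 padding: int = 0, output_padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding, self.output_padding = stride, padding, output_padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(he_uniform(rng, (in_ch, out_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride,
                                padding=self.padding, output_padding=self.output_padding)


class BatchNorm2d(Module):
    """Channel-wise batch normalization.

    With ``track_running_stats=False`` the layer always normalizes with the
    current batch's statistics (also at evaluation time) — used inside the
    recurrent module, where normalization operates per time step.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 track_running_stats: bool = True):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.track_running_stats = track_running_stats
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x):
        c = x.shape[1]
        if self.training or not self.track_running_stats:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            if self.track_running_stats and self.training:
                self.running_mean += self.momentum * (
                    mean.data.reshape(c) - self.running_mean
                )
                self.running_var += self.momentum * (
                    var.data.reshape(c) - self.running_var
                )
            xhat = centered * ((var + self.eps) ** -0.5)
        else:
            mean = self.running_mean.reshape(1, c, 1, 1)
            inv = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(1, c, 1, 1)
            xhat = (x - Tensor(mean)) * Tensor(inv)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.10):
        super().__init__()
        self.alpha = alpha

    def forward(self, x):
        return x.leaky_relu(self.alpha)


class ConvLSTM2d(Module):
    """Convolutional LSTM over a sequence of NCHW maps.

    Gate transformations are dilated convolutions (the dilation applies to
    both the input-to-state and state-to-state kernels).  ``reverse=True``
    runs the cell over the time-reversed sequence and re-reverses the
    outputs, which is how a "backward" layer is realised.
    """

    def __init__(self, in_ch: int, filters: int, kernel: int = 3, *, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.filters = filters
        self.kernel = kernel
        self.dilation = dilation
        self.padding = dilation * (kernel - 1) // 2
        fan_in = in_ch * kernel * kernel
        self.w_x = Parameter(he_uniform(rng, (4 * filters, in_ch, kernel, kernel), fan_in))
        wh = np.stack(
            [
                orthogonal(rng, filters, filters * kernel * kernel).reshape(
                    filters, filters, kernel, kernel
                )
                for _ in range(4)
            ]
        ).reshape(4 * filters, filters, kernel, kernel)
        self.w_h = Parameter(wh)
        bias = np.zeros(4 * filters)
        bias[filters : 2 * filters] = 1.0  # forget-gate bias
        self.bias = Parameter(bias)

    def forward(self, seq: list[Tensor], reverse: bool = False) -> list[Tensor]:
        frames = list(reversed(seq)) if reverse else list(seq)
        n, _, h, w = frames[0].shape
        f = self.filters
        hstate = Tensor(np.zeros((n, f, h, w), dtype=DTYPE))
        cstate = Tensor(np.zeros((n, f, h, w), dtype=DTYPE))
        outputs = []
        for x in frames:
            z = conv2d(x, self.w_x, self.bias, padding=self.padding,
                       dilation=self.dilation)
            z = z + conv2d(hstate, self.w_h, None, padding=self.padding,
                           dilation=self.dilation)
            i = z[:, 0 * f : 1 * f].sigmoid()
            fg = z[:, 1 * f : 2 * f].sigmoid()
            g = z[:, 2 * f : 3 * f].tanh()
            o = z[:, 3 * f : 4 * f].sigmoid()
            cstate = fg * cstate + i * g
            hstate = o * cstate.tanh()
            outputs.append(hstate)
        if reverse:
            outputs.reverse()
        return outputs


class BidirectionalConvLSTMBlock(Module):
    """Paired forward and backward ConvLSTM layers: concat, BN, LeakyReLU."""

    def __init__(self, in_ch: int, filters: int, kernel: int = 3, *, dilation: int = 1,
                 leaky_alpha: float = 0.10, rng: np.random.Generator | None = None):
        super().__init__()
        self.fwd = ConvLSTM2d(in_ch, filters, kernel, dilation=dilation, rng=rng)
        self.bwd = ConvLSTM2d(in_ch, filters, kernel, dilation=dilation, rng=rng)
        # per-time-step normalization: always current statistics
        self.bn = BatchNorm2d(2 * filters, track_running_stats=False)
        self.alpha = leaky_alpha

    def forward(self, seq: list[Tensor]) -> list[Tensor]:
        fo = self.fwd(seq, reverse=False)
        bo = self.bwd(seq, reverse=True)
        out = []
        for a, b in zip(fo, bo):
            y = self.bn(concat([a, b], axis=1))
            out.append(y.leaky_relu(self.alpha))
        return out
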