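"""Neural-network modules (conv, batch-norm, pooling, upsampling, dropout).

Convolution uses a per-tap tensordot formulation: a 3x3 kernel costs nine
BLAS matrix products instead of one large im2col buffer, which keeps memory
flat for the decoder's full-resolution maps.  Every module exposes
``forward`` on :class:`~funduseg.nn.autograd.Tensor` inputs and registers
its backward pass on the tape.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, from_op

__all__ = [
    "Module",
    "Sequential",
    "ModuleList",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "UpsampleBilinear2d",
    "Dropout2d",
]


class Module:
    """Base class: parameter/submodule discovery, train/eval switching."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def modules(self):
        """Yield self and every submodule, depth first."""
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    params.append(v)
        return params

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        """Flat name->array mapping of parameters and buffers."""
        state: dict[str, np.ndarray] = {}
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                if isinstance(v, Parameter):
                    state[f"{i}.{k}"] = v.data.copy()
                elif isinstance(v, np.ndarray) and k.startswith("running_"):
                    state[f"{i}.{k}"] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                key = f"{i}.{k}"
                if key in state:
                    if isinstance(v, Parameter):
                        v.data = state[key].copy()
                    else:
                        setattr(m, k, state[key].copy())


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self.mods = list(mods)

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]


class Conv2d(Module):
    """2-D convolution with stride and dilation; 'same'-style padding.

    Padding defaults to ``dilation * (k - 1) // 2`` so stride-1 convs
    preserve spatial size for any dilation rate.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {dilation}")
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = in_channels * k * k
        # He initialisation, appropriate for ReLU nets
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, k, k))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.dilation = dilation
        self.kernel_size = k
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.padding = dilation * (k - 1) // 2

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        s, d, p, k = self.stride, self.dilation, self.padding, self.kernel_size
        xd = x.data
        B, C, H, W = xd.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        Ho = (H + 2 * p - d * (k - 1) - 1) // s + 1
        Wo = (W + 2 * p - d * (k - 1) - 1) // s + 1
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
        out = np.zeros((B, self.out_channels, Ho, Wo))
        taps = []
        for i in range(k):
            for j in range(k):
                sl = (slice(None), slice(None),
                      slice(i * d, i * d + (Ho - 1) * s + 1, s),
                      slice(j * d, j * d + (Wo - 1) * s + 1, s))
                taps.append(sl)
                xs = xp[sl]
                out += np.tensordot(w.data[:, :, i, j], xs, axes=(1, 1)).transpose(1, 0, 2, 3)
        if b is not None:
            out += b.data[None, :, None, None]

        def bwd(g):
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            gxp = np.zeros_like(xp) if x.requires_grad else None
            gw = np.zeros_like(w.data) if w.requires_grad else None
            for idx, (i, j) in enumerate((i, j) for i in range(k) for j in range(k)):
                sl = taps[idx]
                if gw is not None:
                    gw[:, :, i, j] = np.tensordot(g, xp[sl], axes=([0, 2, 3], [0, 2, 3]))
                if gxp is not None:
                    gxp[sl] += np.tensordot(w.data[:, :, i, j], g, axes=(0, 1)).transpose(1, 0, 2, 3)
            if gw is not None:
                w._accumulate(gw)
            if gxp is not None:
                if p:
                    gxp = gxp[:, :, p:-p, p:-p]
                x._accumulate(gxp)

        parents = (x, w) if b is None else (x, w, b)
        return from_op(out, parents, bwd)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        g, b = self.gamma, self.beta
        xd = x.data
        axes = (0, 2, 3)
        if self.training:
            mean = xd.mean(axis=axes)
            var = xd.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mean[None, :, None, None]) * invstd[None, :, None, None]
        out = g.data[None, :, None, None] * xhat + b.data[None, :, None, None]
        training = self.training

        def bwd(grad):
            if b.requires_grad:
                b._accumulate(grad.sum(axis=axes))
            if g.requires_grad:
                g._accumulate((grad * xhat).sum(axis=axes))
            if not x.requires_grad:
                return
            gi = g.data[None, :, None, None] * invstd[None, :, None, None]
            if not training:
                x._accumulate(grad * gi)
                return
            N = xd.shape[0] * xd.shape[2] * xd.shape[3]
            gsum = grad.sum(axis=axes)[None, :, None, None]
            gxsum = (grad * xhat).sum(axis=axes)[None, :, None, None]
            x._accumulate(gi * (grad - gsum / N - xhat * gxsum / N))

        return from_op(out, (x, g, b), bwd)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2d(Module):
    """2x2 max pooling with stride 2 (the network's single pooling layer)."""

    def __init__(self):
        super().__init__()

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        B, C, H, W = xd.shape
        Ho, Wo = H // 2, W // 2
        win = xd[:, :, : Ho * 2, : Wo * 2].reshape(B, C, Ho, 2, Wo, 2)
        win = win.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, 4)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

        def bwd(g):
            gw = np.zeros((B, C, Ho, Wo, 4))
            np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
            gx = np.zeros_like(xd)
            gx[:, :, : Ho * 2, : Wo * 2] = (
                gw.reshape(B, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho * 2, Wo * 2)
            )
            x._accumulate(gx)

        return from_op(out, (x,), bwd)


def _linear_interp_1d(n_in: int, factor: int):
    """Index/weight tables for half-pixel-centred linear upsampling."""
    out = np.arange(n_in * factor)
    src = (out + 0.5) / factor - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    w1 = np.clip(src - np.floor(src), 0.0, 1.0)
    w1[src < 0] = 0.0
    return i0, i1, w1


class UpsampleBilinear2d(Module):
    """Bilinear upsampling by an integer factor, with an exact adjoint."""

    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        B, C, H, W = xd.shape
        f = self.factor
        r0, r1, wr = _linear_interp_1d(H, f)
        c0, c1, wc = _linear_interp_1d(W, f)
        rows = xd[:, :, r0, :] * (1 - wr)[None, None, :, None] + xd[:, :, r1, :] * wr[None, None, :, None]
        out = rows[:, :, :, c0] * (1 - wc)[None, None, None, :] + rows[:, :, :, c1] * wc[None, None, None, :]

        def bwd(g):
            grows = np.zeros((B, C, H * f, W))
            np.add.at(grows.transpose(3, 0, 1, 2), c0, (g * (1 - wc)[None, None, None, :]).transpose(3, 0, 1, 2))
            np.add.at(grows.transpose(3, 0, 1, 2), c1, (g * wc[None, None, None, :]).transpose(3, 0, 1, 2))
            gx = np.zeros_like(xd)
            np.add.at(gx.transpose(2, 0, 1, 3), r0, (grows * (1 - wr)[None, None, :, None]).transpose(2, 0, 1, 3))
            np.add.at(gx.transpose(2, 0, 1, 3), r1, (grows * wr[None, None, :, None]).transpose(2, 0, 1, 3))
            x._accumulate(gx)

        return from_op(out, (x,), bwd)


class Dropout2d(Module):
    """Inverted channel dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        B, C = x.data.shape[:2]
        keep = (self.rng.random((B, C, 1, 1)) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(keep)
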