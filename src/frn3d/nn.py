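"""Neural-network building blocks on top of :mod:`frn3d.autograd`.

Provides the layers the volumetric backbone needs: 3D convolution (im2col +
BLAS matmul, with an exact scatter-add backward), batch normalisation extended
to 3D feature maps, a dense layer, and module/parameter bookkeeping with
checkpoint save/load.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor, is_grad_enabled

__all__ = [
    "Parameter",
    "Module",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "Linear",
    "Sequential",
    "conv3d",
]


class Parameter(Tensor):
    """A tensor that is registered as trainable by its owning module."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """3D cross-correlation of ``x`` (N, C_in, D, H, W) with ``weight``
    (C_out, C_in, k, k, k), isotropic stride and zero padding.

    Forward lowers the input to a column matrix and multiplies; backward
    scatters the column gradient back with one slice-add per kernel offset.
    """
    n, c_in, d, h, w = x.shape
    c_out, c_in_w, k, _, _ = weight.shape
    if c_in != c_in_w:
        raise ValueError(f"input has {c_in} channels, weight expects {c_in_w}")
    s, p = int(stride), int(padding)
    if d + 2 * p < k or h + 2 * p < k or w + 2 * p < k:
        raise ValueError("kernel larger than padded input")

    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
    # win: (N, C_in, Do, Ho, Wo, k, k, k)
    _, _, do, ho, wo, *_ = win.shape
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        n * do * ho * wo, c_in * k**3
    )
    wmat = weight.data.reshape(c_out, c_in * k**3)
    out = col @ wmat.T
    if bias is not None:
        out += bias.data
    out = out.reshape(n, do, ho, wo, c_out).transpose(0, 4, 1, 2, 3)

    def backward(g, _out=None):
        g_col = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, c_out)
        if weight.requires_grad:
            gw = g_col.T @ col
            weight._accum(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g_col.sum(axis=0))
        if x.requires_grad:
            gx_col = (g_col @ wmat).reshape(n, do, ho, wo, c_in, k, k, k)
            gx_col = gx_col.transpose(0, 4, 1, 2, 3, 5, 6, 7)
            gxp = np.zeros((n, c_in, d + 2 * p, h + 2 * p, w + 2 * p))
            for a in range(k):
                for b in range(k):
                    for c in range(k):
                        gxp[:, :, a : a + s * do : s, b : b + s * ho : s, c : c + s * wo : s] += gx_col[
                            :, :, :, :, :, a, b, c
                        ]
            x._accum(gxp[:, :, p : p + d, p : p + h, p : p + w] if p else gxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, backward)


class Module:
    """Base class with parameter discovery, train/eval mode and checkpoints."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffers", ()):  # noqa: B009
            yield prefix + name, getattr(self, name)
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- checkpointing --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, val in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data[...] = val
            else:
                obj = self
                *path, leaf = name.split(".")
                for part in path:
                    obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
                getattr(obj, leaf)[...] = val

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict(dict(data.items()))


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size**3
        std = np.sqrt(2.0 / fan_in)  # He initialisation for rectifier nets
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels,
                                                      kernel_size, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm3d(Module):
    """Per-channel normalisation over the batch and the three spatial axes."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self._buffers = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        shape = (1, c, 1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3, 4), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
            xhat = xc / (var + self.eps).sqrt()
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight.T + self.bias


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def __getitem__(self, i: int) -> Module:
        return self.layers[i]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
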