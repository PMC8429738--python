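"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for a small fully-convolutional encoder-decoder:
broadcast arithmetic, matmul, im2col-based convolution, 2x2 max pooling,
nearest-neighbour upsampling, channel concatenation, softmax, and an Adam
optimizer.  Everything runs on the CPU in float32 and is bit-reproducible
for a fixed seed (no threading, no nondeterministic reductions).
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Optional, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, parents: Sequence["Tensor"] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None,
                 requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may alias a producer's buffer that is reused elsewhere
            self.grad = np.array(g, dtype=np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topological sort (graphs can be deep)
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.ones_like(self.data))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        out._backward = back
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = back
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    __radd__ = __add__
    __rmul__ = __mul__

    def power(self, exponent: float) -> "Tensor":
        out = Tensor(np.power(self.data, exponent), (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * exponent * np.power(self.data, exponent - 1.0))
        out._backward = back
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = back
        return out

    def clip_min(self, lo: float) -> "Tensor":
        """Lower clip; gradient is blocked where the input was clipped."""
        out = Tensor(np.maximum(self.data, lo), (self,))
        mask = (self.data >= lo).astype(np.float32)

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = back
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        mask = (self.data > 0).astype(np.float32)

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = back
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, (self, other))

        def back(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        out._backward = back
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        shape = self.shape

        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).copy())
        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), (self,))
        orig = self.shape

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))
        out._backward = back
        return out

    def transpose(self, axes) -> "Tensor":
        out = Tensor(self.data.transpose(axes), (self,))
        inv = np.argsort(axes)

        def back(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        out._backward = back
        return out


# ---------------------------------------------------------------------------
# spatial ops on (N, C, H, W) tensors
# ---------------------------------------------------------------------------

def im2col(x: Tensor, k: int, pad: int) -> tuple[Tensor, tuple[int, int]]:
    """Unfold k x k patches: (N, C, H, W) -> (N*H*W, C*k*k) at stride 1."""
    n, c, h, w = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, OH, OW, k, k) with OH = H, OW = W for same-padding
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
    out = Tensor(np.ascontiguousarray(cols), (x,))

    def back(g):
        if not x.requires_grad:
            return
        gw = g.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                gx[:, :, di:di + oh, dj:dj + ow] += gw[:, :, :, :, di, dj]
        x._accum(gx[:, :, pad:pad + h, pad:pad + w])
    out._backward = back
    return out, (oh, ow)


def maxpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = win.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], (x,))

    def back(g):
        if not x.requires_grad:
            return
        gflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gx.reshape(n, c, h, w))
    out._backward = back
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), (x,))
    n, c, h, w = x.shape

    def back(g):
        if x.requires_grad:
            x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))
    out._backward = back
    return out


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(np.concatenate([a.data, b.data], axis=1), (a, b))
    ca = a.shape[1]

    def back(g):
        if a.requires_grad:
            a._accum(g[:, :ca])
        if b.requires_grad:
            b._accum(g[:, ca:])
    out._backward = back
    return out


def softmax_channels(x: Tensor) -> Tensor:
    """Numerically stable softmax over axis 1 with an analytic JVP."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    out = Tensor(p, (x,))

    def back(g):
        if x.requires_grad:
            x._accum(p * (g - (g * p).sum(axis=1, keepdims=True)))
    out._backward = back
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        params = self.parameters()
        arrays = list(arrays)
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float32)


class Conv2d(Module):
    """Same-padded stride-1 convolution via im2col."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        scale = math.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(fan_in, cout)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.k = k

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        cols, (oh, ow) = im2col(x, self.k, self.k // 2)
        y = cols.matmul(self.weight) + self.bias
        return y.reshape(n, oh, ow, -1).transpose((0, 3, 1, 2))


class GroupNorm(Module):
    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        if channels % groups:
            groups = 1
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.groups = groups
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, c // g * h * w)
        m = xg.mean(axis=2, keepdims=True)
        centred = xg - m
        var = (centred * centred).mean(axis=2, keepdims=True)
        inv = (var + self.eps).power(-0.5)
        xn = (centred * inv).reshape(n, c, h, w)
        return xn * self.gamma + self.beta


class ResidualBlock(Module):
    """Pre-activation residual block: GN-ReLU-Conv, GN-ReLU-Conv, + skip."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.norm1 = GroupNorm(cin)
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.norm2 = GroupNorm(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.proj = Conv2d(cin, cout, 1, rng) if cin != cout else None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv1(self.norm1(x).relu())
        y = self.conv2(self.norm2(y).relu())
        skip = self.proj(x) if self.proj is not None else x
        return skip + y


class Adam:
    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
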