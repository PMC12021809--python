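"""Minimal reverse-mode autodiff over numpy arrays, with the layers needed by
the generative model and the outcome classifier.

This is a deliberately small engine (a `Tensor` with a tape, a `Module`
hierarchy, Adam) rather than a general framework: only the ops used by the
U-Net denoiser and the Siamese fusion classifier are implemented.  Gradients
are checked against central differences in the test suite.

Conventions follow the big frameworks: NCHW image layout, fan-in-scaled
uniform initialization, `requires_grad` leaf parameters, `backward()` on a
scalar loss.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._saved = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._saved
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = (),
                 _backward: Callable[[], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        # outside autograd, keep no graph edges (avoids closure ref cycles)
        self._prev = _prev if _GRAD_ENABLED else ()
        self._backward = _backward

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs here can be ~1e3 nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # break closure reference cycles so buffers free by refcount
        for node in topo:
            node._backward = None
            node._prev = ()
            if not node.requires_grad:
                node.grad = None

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _needs(*ts: "Tensor") -> bool:
        return _GRAD_ENABLED and any(t.requires_grad or t._prev for t in ts)

    # -- elementwise arithmetic --------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw():
            self._accum(_unbroadcast(out.grad, self.data.shape))
            other._accum(_unbroadcast(out.grad, other.data.shape))
        if self._needs(self, other):
            out._backward = _bw
        return out

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw():
            self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.data.shape))
        if self._needs(self, other):
            out._backward = _bw
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __radd__(self, other):
        return self + other

    def __rmul__(self, other):
        return self * other

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw():
            self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            other._accum(_unbroadcast(-out.grad * self.data / other.data ** 2,
                                      other.data.shape))
        if self._needs(self, other):
            out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def _bw():
            self._accum(out.grad * p * self.data ** (p - 1))
        if self._needs(self):
            out._backward = _bw
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _bw():
            self._accum(out.grad * out.data)
        if self._needs(self):
            out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw():
            self._accum(out.grad / self.data)
        if self._needs(self):
            out._backward = _bw
        return out

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _bw():
            self._accum(out.grad * (self.data > 0))
        if self._needs(self):
            out._backward = _bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def _bw():
            self._accum(out.grad * s * (1.0 - s))
        if self._needs(self):
            out._backward = _bw
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))

        def _bw():
            self._accum(out.grad * (1.0 - t * t))
        if self._needs(self):
            out._backward = _bw
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, _prev=(self,))

        def _bw():
            self._accum(out.grad * (s + self.data * s * (1.0 - s)))
        if self._needs(self):
            out._backward = _bw
        return out

    def gelu(self):
        # tanh approximation (the variant standard in ConvNeXt-style nets)
        c = math.sqrt(2.0 / math.pi)
        x = self.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out = Tensor(0.5 * x * (1.0 + t), _prev=(self,))

        def _bw():
            dt = (1.0 - t * t) * c * (1.0 + 3 * 0.044715 * x ** 2)
            self._accum(out.grad * (0.5 * (1.0 + t) + 0.5 * x * dt))
        if self._needs(self):
            out._backward = _bw
        return out

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        if self._needs(self):
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def _bw():
            self._accum(out.grad.reshape(self.data.shape))
        if self._needs(self):
            out._backward = _bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))

        def _bw():
            self._accum(out.grad.transpose(inv))
        if self._needs(self):
            out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)
        if self._needs(self):
            out._backward = _bw
        return out

    def matmul(self, other):
        other = self._wrap(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))

        def _bw():
            ga = np.matmul(out.grad, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), out.grad)
            self._accum(_unbroadcast(ga, self.data.shape))
            other._accum(_unbroadcast(gb, other.data.shape))
        if self._needs(self, other):
            out._backward = _bw
        return out

    def __matmul__(self, other):
        return self.matmul(other)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(a, b)
            t._accum(out.grad[tuple(sl)])
    if Tensor._needs(*tensors):
        out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - x.data.max(axis=axis, keepdims=True)  # constant shift
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable binary cross entropy, mean over all elements."""
    z, y = logits.data, np.asarray(targets, dtype=np.float64)
    loss_val = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(np.array(loss_val.mean()), _prev=(logits,))

    def _bw():
        p = 1.0 / (1.0 + np.exp(-z))
        out_grad = out.grad  # scalar
        logits._accum(out_grad * (p - y) / y.size)
    if Tensor._needs(logits):
        out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# Structured ops
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2D convolution (cross-correlation), NCHW, via im2col."""
    N, C, H, W = x.data.shape
    O, C2, kh, kw = w.data.shape
    assert C == C2, "channel mismatch"
    p, s = padding, stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    Ho, Wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
    wf = w.data.reshape(O, -1)
    out_mat = cols @ wf.T
    out_data = out_mat.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data.reshape(1, O, 1, 1)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def _bw():
        g = out.grad.transpose(0, 2, 3, 1).reshape(-1, O)
        w._accum((g.T @ cols).reshape(w.data.shape))
        if b is not None:
            b._accum(g.sum(axis=0))
        dcols = (g @ wf).reshape(N, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[:, :, :, :, i, j]
        x._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)
    if Tensor._needs(*prev):
        out._backward = _bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """1D convolution over (N, C, L) via the 2D kernel with height 1."""
    x4 = x.reshape(x.shape[0], x.shape[1], 1, x.shape[2])
    w4 = w.reshape(w.shape[0], w.shape[1], 1, w.shape[2])
    # pad only along L: emulate with manual zero-pad through concat
    if padding:
        zeros = Tensor(np.zeros((x.shape[0], x.shape[1], 1, padding)))
        x4 = concat([zeros, x4, zeros], axis=3)
    out = conv2d(x4, w4, b, stride=1, padding=0)
    return out.reshape(out.shape[0], out.shape[1], out.shape[3])


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    N, C, H, W = x.shape
    assert H % k == 0 and W % k == 0, "pool size must divide spatial dims"
    r = x.reshape(N, C, H // k, k, W // k, k)
    return r.mean(axis=(3, 5))


def upsample_nearest(x: Tensor, k: int) -> Tensor:
    N, C, H, W = x.shape
    out = Tensor(np.repeat(np.repeat(x.data, k, axis=2), k, axis=3), _prev=(x,))

    def _bw():
        g = out.grad.reshape(N, C, H, k, W, k).sum(axis=(3, 5))
        x._accum(g)
    if Tensor._needs(x):
        out._backward = _bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3))


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
        collect(self)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = []

        def collect(obj):
            if isinstance(obj, Module):
                mods.append(obj)
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
        collect(self)
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        params = self.parameters()
        arrays = list(arrays)
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = a.copy()


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(1.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.w = Tensor(_kaiming_uniform(rng, (in_features, out_features), in_features),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.w
        return out + self.b if self.b is not None else out


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = True):
        super().__init__()
        padding = k // 2 if padding is None else padding
        fan_in = in_ch * k * k
        self.w = Tensor(_kaiming_uniform(rng, (out_ch, in_ch, k, k), fan_in),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class GroupNorm(Module):
    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        assert channels % groups == 0
        self.groups, self.eps = groups, eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        g = self.groups
        xg = x.reshape(N, g, C // g * H * W)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        xn = (xg - mu) / ((var + self.eps) ** 0.5)
        xn = xn.reshape(N, C, H, W)
        return xn * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Adam:
    """Adam with the standard bias-corrected moments."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
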