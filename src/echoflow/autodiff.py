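"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ``ndarray`` and
records a closure that propagates the upstream gradient to its parents.
Only the primitives needed by the video models live here — elementwise
arithmetic with broadcasting, 2-D "same" convolution (stride 1), 2×2 max
pooling, ×2 nearest upsampling, channel concatenation, the usual pointwise
nonlinearities, reductions, and numerically stable fused losses.

All floating point work is float64: the adaptive ODE solver built on top of
these primitives compares solutions at tolerances around 1e-4 and float32
round-off is uncomfortably close to that.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "maxpool2x2",
    "upsample2x",
    "relu",
    "sigmoid",
    "tanh",
    "softmax",
    "softmax_cross_entropy",
    "bce_with_logits",
    "Module",
    "Conv2d",
    "SGD",
]


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Reverse-mode sweep from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return _add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return _mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return _div(self, as_tensor(other))

    def __rtruediv__(self, other):
        return _div(as_tensor(other), self)

    def __pow__(self, p: float):
        return _pow(self, float(p))

    def sum(self, axis=None, keepdims=False):
        return _sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return _sum(self, axis, keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        return _reshape(self, shape)

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g.reshape(shape)


def _add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def _div(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _make(a.data / b.data, (a, b), backward)


def _pow(a: Tensor, p: float) -> Tensor:
    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(a.data ** p, (a,), backward)


def _sum(a: Tensor, axis, keepdims) -> Tensor:
    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape))
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape))

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def _reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


# -- pointwise nonlinearities ---------------------------------------------

def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                 np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), backward)


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)

    def backward(g):
        a._accumulate(g * (1.0 - t * t))

    return _make(t, (a,), backward)


# -- spatial primitives (NCHW) --------------------------------------------

def _pad_hw(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    n, c, h, w = x.shape
    out = np.zeros((n, c, h + 2 * ph, w + 2 * pw))
    out[:, :, ph:ph + h, pw:pw + w] = x
    return out


def _corr2d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 'same' cross-correlation of NCHW ``x`` with OIHW ``w``.

    Shift-and-GEMM: one (NHW, Cin)×(Cin, Cout) matmul per kernel tap —
    avoids strided-view gathers, which dominate an im2col formulation here.
    """
    n, c, h, wd = x.shape
    co, ci, kh, kw = w.shape
    assert ci == c, f"channel mismatch {ci} != {c}"
    xp = _pad_hw(x, kh // 2, kw // 2)
    xt = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))  # NHWC
    out = np.zeros((n, h, wd, co))
    for di in range(kh):
        for dj in range(kw):
            patch = xt[:, di:di + h, dj:dj + wd, :]
            out += patch @ w[:, :, di, dj].T
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


def _corr2d_backward(g: np.ndarray, x: np.ndarray, w: np.ndarray,
                     need_dx: bool, need_dw: bool):
    n, c, h, wd = x.shape
    co, ci, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * wd, co)
    dw = np.zeros_like(w) if need_dw else None
    dxp = np.zeros((n, h + 2 * ph, wd + 2 * pw, c)) if need_dx else None
    xt = None
    if need_dw:
        xp = _pad_hw(x, ph, pw)
        xt = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))
    for di in range(kh):
        for dj in range(kw):
            if need_dw:
                patch = np.ascontiguousarray(
                    xt[:, di:di + h, dj:dj + wd, :]).reshape(n * h * wd, c)
                dw[:, :, di, dj] = gt.T @ patch
            if need_dx:
                dxp[:, di:di + h, dj:dj + wd, :] += (
                    gt @ w[:, :, di, dj]).reshape(n, h, wd, c)
    dx = None
    if need_dx:
        dx = np.ascontiguousarray(
            dxp[:, ph:ph + h, pw:pw + wd, :].transpose(0, 3, 1, 2))
    return dx, dw


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1, 'same'-padded convolution (odd kernels only)."""
    out = _corr2d(x.data, w.data)
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        need_dx = bool(x.requires_grad or x._parents)
        need_dw = bool(w.requires_grad or w._parents)
        dx, dw = _corr2d_backward(g, x.data, w.data, need_dx, need_dw)
        if need_dw:
            w._accumulate(dw)
        if b is not None and (b.requires_grad or b._parents):
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if need_dx:
            x._accumulate(dx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "maxpool2x2 needs even spatial dims"
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gr.reshape(n, c, h, w))

    return _make(out, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour ×2 upsampling."""
    n, c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _make(out, (x,), backward)


# -- fused losses / heads --------------------------------------------------

def softmax(logits: Tensor, axis: int = 1) -> Tensor:
    z = logits.data - logits.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        logits._accumulate(p * (g - (g * p).sum(axis=axis, keepdims=True)))

    return _make(p, (logits,), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean pixelwise cross-entropy. ``logits`` (N,C,H,W), ``labels`` (N,H,W) int."""
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1)) + logits.data.max(axis=1)
    n, c, h, w = logits.data.shape
    ii, hh, ww = np.meshgrid(np.arange(n), np.arange(h), np.arange(w), indexing="ij")
    true_logit = logits.data[ii, labels, hh, ww]
    count = labels.size
    loss = float((lse - true_logit).sum() / count)

    def backward(g):
        p = np.exp(logits.data - lse[:, None])
        p[ii, labels, hh, ww] -= 1.0
        logits._accumulate(g * p / count)

    return _make(loss, (logits,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    t = np.asarray(targets, dtype=np.float64)
    z = logits.data
    loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    count = z.size

    def backward(g):
        s = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                     np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
        logits._accumulate(g * (s - t) / count)

    return _make(loss, (logits,), backward)


# -- modules / optimizer ---------------------------------------------------

class Module:
    """Parameter container with recursive discovery (no buffers, no modes)."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model has {len(params)}"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 zero_init: bool = False, bias: bool = True):
        fan_in = c_in * kernel * kernel
        if zero_init:
            w = np.zeros((c_out, c_in, kernel, kernel))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, kernel, kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class SGD:
    """Plain stochastic gradient descent: constant lr, no momentum/decay."""

    def __init__(self, params: list[Tensor], lr: float):
        if lr <= 0:
            raise ValueError("lr must be positive")
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
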