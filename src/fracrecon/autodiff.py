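"""Compact reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the reconstruction network needs:
elementwise arithmetic, ReLU, reductions, reshape/transpose/flip/concat,
stride-1 same-padding correlations (2D/3D convolution), kernel-2 stride-2
transposed convolutions, 2x max-pooling, instance normalisation,
log-softmax, plus an Adam optimizer and a minimal Module system.

Gradients are accumulated through a topologically sorted backward pass;
every primitive's backward closure returns one gradient per parent.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph -------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=True)
                else:
                    parent.grad += g

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, _wrap(np.array(-1.0, dtype=self.data.dtype)))

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise & reductions
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return _node(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _node(
        a.data * b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        ),
    )


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return _node(np.where(mask, a.data, 0.0), (a,), lambda g: (g * mask,))


def pow_const(a: Tensor, p: float) -> Tensor:
    return _node(
        a.data**p, (a,), lambda g: (g * p * np.power(a.data, p - 1.0),)
    )


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)
    return _node(out_data, (a,), lambda g: (g * out_data,))


def log(a: Tensor) -> Tensor:
    return _node(np.log(a.data), (a,), lambda g: (g / a.data,))


def clamp(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp; gradient passes only through the un-clamped region."""
    mask = (a.data > lo) & (a.data < hi)
    return _node(np.clip(a.data, lo, hi), (a,), lambda g: (g * mask,))


def mean(a: Tensor) -> Tensor:
    n = a.data.size
    return _node(
        np.asarray(a.data.mean()),
        (a,),
        lambda g: (np.broadcast_to(g / n, a.shape).astype(a.data.dtype),),
    )


def sum_all(a: Tensor) -> Tensor:
    return _node(
        np.asarray(a.data.sum()),
        (a,),
        lambda g: (np.broadcast_to(g, a.shape).astype(a.data.dtype),),
    )


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape
    return _node(a.data.reshape(shape), (a,), lambda g: (g.reshape(old),))


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _node(
        np.ascontiguousarray(a.data.transpose(axes)),
        (a,),
        lambda g: (g.transpose(inv),),
    )


def flip(a: Tensor, axis: int) -> Tensor:
    return _node(
        np.ascontiguousarray(np.flip(a.data, axis)),
        (a,),
        lambda g: (np.flip(g, axis),),
    )


def narrow(a: Tensor, start: int, length: int, axis: int = 1) -> Tensor:
    """Contiguous slice along one axis (keeps the axis)."""
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def backward(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        return (full,)

    return _node(np.ascontiguousarray(a.data[idx]), (a,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


# ---------------------------------------------------------------------------
# correlations (stride 1, same padding, odd kernels)
# ---------------------------------------------------------------------------

def _corr(x: np.ndarray, w: np.ndarray, nd: int) -> np.ndarray:
    """x (N,Ci,*S) ⋆ w (Co,Ci,*K) -> (N,Co,*S); stride 1, same padding."""
    pad = [(0, 0), (0, 0)] + [(k // 2, k // 2) for k in w.shape[2:]]
    xp = np.pad(x, pad)
    win = sliding_window_view(xp, w.shape[2:], axis=tuple(range(2, 2 + nd)))
    # win: (N, Ci, *S, *K)
    y = np.tensordot(
        win,
        w,
        axes=(
            [1] + list(range(2 + nd, 2 + 2 * nd)),
            [1] + list(range(2, 2 + nd)),
        ),
    )
    # y: (N, *S, Co)
    return np.ascontiguousarray(np.moveaxis(y, -1, 1))


def _corr_dw(x: np.ndarray, g: np.ndarray, kshape, nd: int) -> np.ndarray:
    """Gradient wrt kernel: (Co, Ci, *K)."""
    pad = [(0, 0), (0, 0)] + [(k // 2, k // 2) for k in kshape]
    xp = np.pad(x, pad)
    win = sliding_window_view(xp, kshape, axis=tuple(range(2, 2 + nd)))
    # dW[o,i,*k] = sum_{n,*s} g[n,o,*s] win[n,i,*s,*k]
    dw = np.tensordot(
        g,
        win,
        axes=([0] + list(range(2, 2 + nd)), [0] + list(range(2, 2 + nd))),
    )
    return np.ascontiguousarray(dw)


def _conv_nd(x: Tensor, w: Tensor, b: Tensor | None, nd: int) -> Tensor:
    y = _corr(x.data, w.data, nd)
    if b is not None:
        y = y + b.data.reshape((1, -1) + (1,) * nd)

    def backward(g):
        spatial = tuple(range(2, 2 + nd))
        wt = np.ascontiguousarray(
            np.swapaxes(np.flip(w.data, axis=spatial), 0, 1)
        )
        dx = _corr(g, wt, nd)
        dw = _corr_dw(x.data, g, w.data.shape[2:], nd)
        db = None
        if b is not None:
            db = g.sum(axis=(0,) + spatial).reshape(b.shape)
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w) if b is None else (x, w, b)
    return _node(y, parents, backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2D correlation, stride 1, same padding. x (N,Ci,H,W), w (Co,Ci,kh,kw)."""
    return _conv_nd(x, w, b, 2)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3D correlation, stride 1, same padding. x (N,Ci,D,H,W)."""
    return _conv_nd(x, w, b, 3)


# ---------------------------------------------------------------------------
# kernel-2 stride-2 transposed convolutions (non-overlapping upsampling)
# ---------------------------------------------------------------------------

def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (N,Ci,H,W), w (Ci,Co,2,2) -> (N,Co,2H,2W)."""
    n, ci, hh, ww = x.shape
    co = w.shape[1]
    y = np.einsum("nihw,ioab->nohawb", x.data, w.data).reshape(n, co, 2 * hh, 2 * ww)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1)

    def backward(g):
        gb = g.reshape(n, co, hh, 2, ww, 2)
        dx = np.einsum("nohawb,ioab->nihw", gb, w.data)
        dw = np.einsum("nihw,nohawb->ioab", x.data, gb)
        db = g.sum(axis=(0, 2, 3)).reshape(b.shape) if b is not None else None
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w) if b is None else (x, w, b)
    return _node(y, parents, backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (N,Ci,D,H,W), w (Ci,Co,2,2,2) -> (N,Co,2D,2H,2W)."""
    n, ci, dd, hh, ww = x.shape
    co = w.shape[1]
    y = np.einsum("nidhw,ioabc->nodahbwc", x.data, w.data).reshape(
        n, co, 2 * dd, 2 * hh, 2 * ww
    )
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1, 1)

    def backward(g):
        gb = g.reshape(n, co, dd, 2, hh, 2, ww, 2)
        dx = np.einsum("nodahbwc,ioabc->nidhw", gb, w.data)
        dw = np.einsum("nidhw,nodahbwc->ioabc", x.data, gb)
        db = g.sum(axis=(0, 2, 3, 4)).reshape(b.shape) if b is not None else None
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w) if b is None else (x, w, b)
    return _node(y, parents, backward)


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Gradient is split evenly among ties."""
    n, c, h, w = x.shape
    xb = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    y = xb.max(axis=(3, 5))

    def backward(g):
        ymax = y[:, :, :, None, :, None]
        mask = xb == ymax
        cnt = mask.sum(axis=(3, 5), keepdims=True)
        dxb = mask * (g[:, :, :, None, :, None] / cnt)
        return (dxb.reshape(n, c, h, w),)

    return _node(y, (x,), backward)


def instance_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalisation over spatial axes with affine."""
    spatial = tuple(range(2, x.data.ndim))
    mu = x.data.mean(axis=spatial, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=spatial, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    gshape = (1, -1) + (1,) * len(spatial)
    y = gain.data.reshape(gshape) * xhat + bias.data.reshape(gshape)
    m = int(np.prod([x.data.shape[i] for i in spatial]))

    def backward(g):
        dxhat = g * gain.data.reshape(gshape)
        s1 = dxhat.sum(axis=spatial, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=spatial, keepdims=True)
        dx = (inv / m) * (m * dxhat - s1 - xhat * s2)
        dgain = (g * xhat).sum(axis=(0,) + spatial).reshape(gain.shape)
        dbias = g.sum(axis=(0,) + spatial).reshape(bias.shape)
        return dx, dgain, dbias

    return _node(y, (x, gain, bias), backward)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    xmax = x.data.max(axis=axis, keepdims=True)
    z = x.data - xmax
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse

    def backward(g):
        softmax = np.exp(out_data)
        return (g - softmax * g.sum(axis=axis, keepdims=True),)

    return _node(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# modules & optimizer
# ---------------------------------------------------------------------------

class Module:
    """Minimal parameter container: walks attributes for Tensors/Modules."""

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

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def he_init(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)


class Conv(Module):
    """Stride-1 same-padding convolution layer (2D or 3D by kernel rank)."""

    def __init__(self, rng, c_in: int, c_out: int, kernel, nd: int):
        if isinstance(kernel, int):
            kernel = (kernel,) * nd
        fan_in = c_in * int(np.prod(kernel))
        self.nd = nd
        self.weight = he_init(rng, (c_out, c_in) + tuple(kernel), fan_in)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return _conv_nd(x, self.weight, self.bias, self.nd)


class ConvTranspose(Module):
    """Kernel-2 stride-2 transposed convolution (2D or 3D)."""

    def __init__(self, rng, c_in: int, c_out: int, nd: int):
        fan_in = c_in * 2**nd
        self.nd = nd
        self.weight = he_init(rng, (c_in, c_out) + (2,) * nd, fan_in)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if self.nd == 2:
            return conv_transpose2d(x, self.weight, self.bias)
        return conv_transpose3d(x, self.weight, self.bias)


class InstanceNorm(Module):
    def __init__(self, channels: int):
        self.gain = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gain, self.bias)


class Adam:
    """Adam optimizer with bias-corrected first and second moments."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.99), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
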