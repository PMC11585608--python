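"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The super-resolution network needs gradient-based training, and this
package is NumPy-native, so a compact tensor autograd engine is provided
here: a :class:`Tensor` wrapping a float32 ``ndarray``, the differentiable
primitives the model is built from (broadcast add/mul, batched matmul,
reshape/transpose/slice/concat/pad/roll, softmax, layer norm, GELU,
gather), and an AdamW optimizer.  Gradients are accumulated by a
topological backward sweep; everything is eager and single-threaded
(NumPy's BLAS does the heavy lifting inside matmuls).

The engine is deliberately small: only the operations the model uses are
implemented, and only float32.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# Tensor core
# ---------------------------------------------------------------------------


class Tensor:
    """A node in the autograd graph: value, gradient, and backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None  # callable(grad_out) -> None, writes into parents
        self._parents: tuple[Tensor, ...] = ()

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph mechanics ----------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        # Stores a reference on first accumulation (callers guarantee the
        # array is dead or uniquely owned); adds in place afterwards.
        if self.grad is None:
            self.grad = g if g.dtype == np.float32 else g.astype(np.float32)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen = set()
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
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])

    def item(self) -> float:
        return float(self.data)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, s) in enumerate(zip(g.shape, shape)):
        if s == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode):
    intermediates are not retained, so memory stays at working-set size."""

    def __enter__(self):
        global GRAD_ENABLED
        self._prev = GRAD_ENABLED
        GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global GRAD_ENABLED
        GRAD_ENABLED = self._prev
        return False


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        ga = _unbroadcast(g, a.shape)
        gb = _unbroadcast(g, b.shape)
        if gb is ga:  # same buffer: one parent must own a private copy
            gb = gb.copy()
        a._accum(ga)
        b._accum(gb)

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accum(_unbroadcast(ga, a.shape))
        b._accum(_unbroadcast(gb, b.shape))

    return _make(data, (a, b), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.shape
    data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(old))

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    data = a.data.transpose(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return _make(data, (a,), backward)


def _is_basic_index(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(i, (int, np.integer, slice, type(Ellipsis))) for i in items)


def getitem(a, idx) -> Tensor:
    a = _as_tensor(a)
    data = a.data[idx]
    basic = _is_basic_index(idx)

    def backward(g):
        full = np.zeros_like(a.data)
        if basic:  # views never repeat elements, so += is exact and fast
            full[idx] += g
        else:
            np.add.at(full, idx, g)
        a._accum(full)

    return _make(data, (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return _make(data, tuple(tensors), backward)


def pad(a, pad_width) -> Tensor:
    """Zero padding; ``pad_width`` is per-axis (before, after)."""
    a = _as_tensor(a)
    pad_width = tuple(tuple(p) for p in pad_width)
    data = np.pad(a.data, pad_width)
    slices = tuple(slice(b, b + s) for (b, _), s in zip(pad_width, a.shape))

    def backward(g):
        a._accum(g[slices])

    return _make(data, (a,), backward)


def roll(a, shift, axis) -> Tensor:
    a = _as_tensor(a)
    shift = tuple(np.atleast_1d(shift))
    axis = tuple(np.atleast_1d(axis))
    data = np.roll(a.data, shift, axis)

    def backward(g):
        a._accum(np.roll(g, tuple(-s for s in shift), axis))

    return _make(data, (a,), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.shape).copy())

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else a.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def tabs(a) -> Tensor:
    a = _as_tensor(a)
    data = np.abs(a.data)
    sign = np.sign(a.data)

    def backward(g):
        a._accum(g * sign)

    return _make(data, (a,), backward)


def square(a) -> Tensor:
    a = _as_tensor(a)
    data = a.data * a.data

    def backward(g):
        a._accum(2.0 * g * a.data)

    return _make(data, (a,), backward)


_GELU_C = math.sqrt(2.0 / math.pi)


def gelu(a) -> Tensor:
    """Gaussian error linear unit (tanh form)."""
    a = _as_tensor(a)
    x = a.data
    inner = _GELU_C * (x + np.float32(0.044715) * x * x * x)
    t = np.tanh(inner, out=inner)  # in-place; `t` aliases `inner`
    data = np.float32(0.5) * x * (1.0 + t)

    def backward(g):
        sech2 = 1.0 - t * t
        dinner = _GELU_C * (1.0 + np.float32(3 * 0.044715) * x * x)
        grad = np.float32(0.5) * ((1.0 + t) + x * sech2 * dinner)
        grad *= g
        a._accum(grad)

    return _make(data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=axis, keepdims=True)
    s = z

    def backward(g):
        inner = (g * s).sum(axis=axis, keepdims=True)
        a._accum(s * (g - inner))

    return _make(s, (a,), backward)


def layer_norm(a, weight, bias, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with affine parameters."""
    a, weight, bias = _as_tensor(a), _as_tensor(weight), _as_tensor(bias)
    x = a.data
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xc * inv).astype(np.float32)
    data = xhat * weight.data + bias.data

    def backward(g):
        gx_hat = g * weight.data
        m1 = gx_hat.mean(axis=-1, keepdims=True)
        m2 = (gx_hat * xhat).mean(axis=-1, keepdims=True)
        a._accum((inv * (gx_hat - m1 - xhat * m2)).astype(np.float32))
        axes = tuple(range(g.ndim - 1))
        weight._accum((g * xhat).sum(axis=axes))
        bias._accum(g.sum(axis=axes))

    return _make(data, (a, weight, bias), backward)


def linear(x, weight, bias) -> Tensor:
    """Fused affine map over the last axis: ``x @ weight + bias``.

    Leading axes are flattened into a single GEMM (much faster than the
    stacked matmul NumPy would run on rank>2 inputs)."""
    x, weight, bias = _as_tensor(x), _as_tensor(weight), _as_tensor(bias)
    lead = x.shape[:-1]
    d_in, d_out = weight.shape
    flat = x.data.reshape(-1, d_in)
    data = flat @ weight.data
    data += bias.data
    data = data.reshape(lead + (d_out,))

    def backward(g):
        gflat = g.reshape(-1, d_out)
        x._accum((gflat @ weight.data.T).reshape(x.shape))
        weight._accum(flat.T @ gflat)
        bias._accum(gflat.sum(axis=0))

    return _make(data, (x, weight, bias), backward)


def conv_channels_last(x, weight, bias, d: int) -> Tensor:
    """Kernel-3, stride-1, zero-padded, channel-preserving convolution over
    the ``d`` spatial axes of a channels-last tensor ``(B, *S, C)``.

    Implemented as im2col + one GEMM: ``weight`` has shape ``(3**d * C, C)``
    with rows ordered by offset-major (itertools.product order), then input
    channel.  The fused backward avoids per-offset scatter allocations.
    """
    x, weight, bias = _as_tensor(x), _as_tensor(weight), _as_tensor(bias)
    spatial = x.shape[1:-1]
    C = x.shape[-1]
    if weight.shape != (3**d * C, C):
        raise ValueError(f"weight must be ({3**d * C}, {C}), got {weight.shape}")
    xp = np.pad(x.data, [(0, 0)] + [(1, 1)] * d + [(0, 0)])
    offsets = list(np.ndindex(*([3] * d)))
    slices = [
        (slice(None),)
        + tuple(slice(o, o + s) for o, s in zip(off, spatial))
        + (slice(None),)
        for off in offsets
    ]
    cols = np.concatenate([xp[sl] for sl in slices], axis=-1)
    flat = cols.reshape(-1, 3**d * C)
    data = (flat @ weight.data + bias.data).reshape(x.shape)

    def backward(g):
        gflat = g.reshape(-1, C)
        weight._accum(flat.T @ gflat)
        bias._accum(gflat.sum(axis=0))
        gcols = (gflat @ weight.data.T).reshape(cols.shape)
        gxp = np.zeros_like(xp)
        for j, sl in enumerate(slices):
            gxp[sl] += gcols[..., j * C : (j + 1) * C]
        inner = (slice(None),) + tuple(slice(1, 1 + s) for s in spatial) + (
            slice(None),
        )
        x._accum(gxp[inner])

    return _make(data, (x, weight, bias), backward)


def take(table, index) -> Tensor:
    """Gather rows of a 2-D parameter table by an integer index array."""
    table = _as_tensor(table)
    index = np.asarray(index)
    data = table.data[index]

    def backward(g):
        full = np.zeros_like(table.data)
        np.add.at(full, index, g)
        table._accum(full)

    return _make(data, (table,), backward)


# ---------------------------------------------------------------------------
# Parameters, layers, optimizer
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    """A trainable tensor; ``decay=False`` exempts it from weight decay
    (biases, norm scales, tokens/embeddings, per the common convention)."""

    __slots__ = ("decay",)

    def __init__(self, data, decay: bool = True):
        super().__init__(data, requires_grad=True)
        self.decay = decay


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


class Module:
    """Base class with parameter discovery over attributes and lists."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)

        visit(self)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model {len(params)}")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {arr.shape}")
            p.data = arr.astype(np.float32).copy()


class Linear(Module):
    """Affine layer.  Default init is the Swin-style truncated normal
    (std 0.02), which keeps residual blocks near the identity at start;
    ``zero_init=True`` makes a block's output projection exactly zero
    (identity residual), which speeds up early training of deep stacks."""

    def __init__(self, rng, d_in: int, d_out: int, zero_init: bool = False):
        if zero_init:
            w = np.zeros((d_in, d_out), dtype=np.float32)
        else:
            w = trunc_normal(rng, (d_in, d_out))
        self.weight = Parameter(w, decay=True)
        self.bias = Parameter(np.zeros(d_out, dtype=np.float32), decay=False)

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Parameter(np.ones(dim, dtype=np.float32), decay=False)
        self.bias = Parameter(np.zeros(dim, dtype=np.float32), decay=False)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.weight, self.bias, self.eps)


class AdamW:
    """AdamW with decoupled weight decay (applied only to ``decay`` params)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 3e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            wd = self.weight_decay if p.decay else 0.0
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if wd > 0:
                update = update + wd * p.data
            p.data -= self.lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    return tmean(tabs(pred - Tensor(target)))


def l2_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    return tmean(square(pred - Tensor(target)))
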