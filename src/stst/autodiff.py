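"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to differentiate the two-stream feature models and the
synthesis losses with respect to a generated frame: elementwise arithmetic
with broadcasting, ReLU, absolute value, reductions, matrix products,
"same"-padded convolution, 2x decimation and bilinear resizing, and channel
concatenation.  Weights of the feature models are plain ndarrays (they are
never optimized), so no parameter gradients are tracked.

Gradients are accumulated by a topological-order sweep from a scalar output.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Var", "as_var", "concat", "conv2d", "avg_pool2", "downsample2", "resize_bilinear"]


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


class Var:
    """A node in the computation graph holding an ndarray value."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, value, requires_grad=False, _parents=(), _vjp=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._vjp = _vjp  # callable(grad_out) -> tuple of parent grads

    # -- graph bookkeeping ----------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    def item(self) -> float:
        return float(self.value)

    def backward(self) -> None:
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Var] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS postorder
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
        for node in order:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._vjp is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if parent.requires_grad and g is not None:
                    parent.grad = parent.grad + g if parent.grad is not None else g

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_var(other)
        a, b = self, other
        return Var(
            a.value + b.value,
            _parents=(a, b),
            _vjp=lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Var(-a.value, _parents=(a,), _vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_var(other))

    def __rsub__(self, other):
        return as_var(other) + (-self)

    def __mul__(self, other):
        other = as_var(other)
        a, b = self, other
        return Var(
            a.value * b.value,
            _parents=(a, b),
            _vjp=lambda g: (
                _unbroadcast(g * b.value, a.shape),
                _unbroadcast(g * a.value, b.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_var(other)
        a, b = self, other
        return Var(
            a.value / b.value,
            _parents=(a, b),
            _vjp=lambda g: (
                _unbroadcast(g / b.value, a.shape),
                _unbroadcast(-g * a.value / b.value**2, b.shape),
            ),
        )

    def __pow__(self, p: float):
        a = self
        return Var(a.value**p, _parents=(a,), _vjp=lambda g: (g * p * a.value ** (p - 1),))

    def __matmul__(self, other):
        other = as_var(other)
        a, b = self, other
        return Var(
            a.value @ b.value,
            _parents=(a, b),
            _vjp=lambda g: (g @ b.value.T, a.value.T @ g),
        )

    # -- nonlinearities and reductions ------------------------------------
    def relu(self):
        a = self
        mask = a.value > 0
        return Var(a.value * mask, _parents=(a,), _vjp=lambda g: (g * mask,))

    def abs(self):
        a = self
        s = np.sign(a.value)
        return Var(np.abs(a.value), _parents=(a,), _vjp=lambda g: (g * s,))

    def sum(self):
        a = self
        return Var(a.value.sum(), _parents=(a,), _vjp=lambda g: (np.broadcast_to(g, a.shape).copy(),))

    def mean(self):
        return self.sum() * (1.0 / self.value.size)

    def reshape(self, *shape):
        a = self
        old = a.shape
        return Var(a.value.reshape(*shape), _parents=(a,), _vjp=lambda g: (g.reshape(old),))

    @property
    def T(self):
        a = self
        return Var(a.value.T, _parents=(a,), _vjp=lambda g: (g.T,))

    def __getitem__(self, idx):
        a = self

        def vjp(g):
            dx = np.zeros(a.shape)
            dx[idx] = g
            return (dx,)

        return Var(a.value[idx], _parents=(a,), _vjp=vjp)


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


def concat(vars_: list[Var], axis: int = 0) -> Var:
    vars_ = [as_var(v) for v in vars_]
    sizes = [v.shape[axis] for v in vars_]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Var(np.concatenate([v.value for v in vars_], axis=axis), _parents=tuple(vars_), _vjp=vjp)


# -- convolution -----------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """x: (C, Hp, Wp) zero-padded input -> (C*kh*kw, H*W) patch matrix."""
    C, Hp, Wp = x.shape
    H, W = Hp - kh + 1, Wp - kw + 1
    s0, s1, s2 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (C, kh, kw, H, W), (s0, s1, s2, s1, s2), writeable=False
    )
    return cols.reshape(C * kh * kw, H * W), (H, W)


def conv2d(x: Var, weight: np.ndarray, bias: np.ndarray | None = None) -> Var:
    """'Same' zero-padded 2D convolution (cross-correlation).

    x: (C_in, H, W); weight: (C_out, C_in, kh, kw); odd kernel sizes only.
    Weights are constants — only the input gradient is propagated.
    """
    x = as_var(x)
    F, C, kh, kw = weight.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.value, ((0, 0), (ph, ph), (pw, pw)))
    cols, (H, W) = _im2col(xp, kh, kw)
    wmat = weight.reshape(F, C * kh * kw)
    out = (wmat @ cols).reshape(F, H, W)
    if bias is not None:
        out = out + bias[:, None, None]

    def vjp(g):
        dcols = wmat.T @ g.reshape(F, H * W)  # (C*kh*kw, H*W)
        dcols = dcols.reshape(C, kh, kw, H, W)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i : i + H, j : j + W] += dcols[:, i, j]
        return (dxp[:, ph : ph + x.shape[1], pw : pw + x.shape[2]],)

    return Var(out, _parents=(x,), _vjp=vjp)


def avg_pool2(x: Var) -> Var:
    """2x2 average pooling with stride 2 on (C, H, W); odd tails dropped."""
    x = as_var(x)
    C, H, W = x.shape
    h, w = H // 2, W // 2
    v = x.value[:, : 2 * h, : 2 * w].reshape(C, h, 2, w, 2)
    out = v.mean(axis=(2, 4))

    def vjp(g):
        dx = np.zeros(x.shape)
        dx[:, : 2 * h, : 2 * w] = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) * 0.25
        return (dx,)

    return Var(out, _parents=(x,), _vjp=vjp)


def downsample2(x: Var) -> Var:
    """Decimate (C, H, W) by 2 along both spatial axes."""
    x = as_var(x)

    def vjp(g):
        dx = np.zeros(x.shape)
        dx[:, ::2, ::2] = g
        return (dx,)

    return Var(x.value[:, ::2, ::2], _parents=(x,), _vjp=vjp)


def _lin_weights(n_out: int, n_in: int) -> np.ndarray:
    """Half-pixel-center bilinear interpolation matrix (n_out x n_in)."""
    if n_out == n_in:
        return np.eye(n_in)
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w = src - lo
    M = np.zeros((n_out, n_in))
    M[np.arange(n_out), lo] += 1.0 - w
    M[np.arange(n_out), hi] += w
    return M


def resize_bilinear(x: Var, h: int, w: int) -> Var:
    """Bilinear resize of (C, H, W) to (C, h, w); differentiable."""
    x = as_var(x)
    C, H, W = x.shape
    Mh = _lin_weights(h, H)
    Mw = _lin_weights(w, W)
    out = np.einsum("oh,chw,pw->cop", Mh, x.value, Mw, optimize=True)

    def vjp(g):
        return (np.einsum("oh,cop,pw->chw", Mh, g, Mw, optimize=True),)

    return Var(out, _parents=(x,), _vjp=vjp)
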