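"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports the operations needed by the convolutional generative models in
this package (dense/convolutional layers, normalisation, the usual
activations) and — crucially — higher-order gradients: every vjp is itself
expressed in terms of :class:`Tensor` operations, so differentiating through
a gradient (as the WGAN gradient penalty requires) works by calling
:func:`grad` with ``create_graph=True``.

Conventions: tensors wrap float64 numpy arrays; broadcasting follows numpy;
1-D convolutions operate on ``(batch, channels, length)`` arrays.
"""

from __future__ import annotations

import contextlib

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjp = None  # callable(upstream: Tensor) -> tuple of per-parent Tensors/None

    # -- construction -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other, float))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, powi(other, -1.0))
        return mul(self, 1.0 / np.asarray(other, float))

    def __rtruediv__(self, other):
        return mul(powi(self, -1.0), other)

    def __pow__(self, p):
        return powi(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def backward(self, grad_output=None):
        """Accumulate first-order gradients into ``.grad`` of all leaves."""
        if grad_output is None:
            grad_output = np.ones_like(self.data)
        grads = _backprop(self, Tensor(grad_output), create_graph=False)
        for t, g in grads.items():
            if t.requires_grad and t._vjp is None:
                t.grad = g.data if t.grad is None else t.grad + g.data


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, vjp) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad or p._vjp is not None for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


def _unbroadcast(g: Tensor, shape: tuple[int, ...]) -> Tensor:
    """Sum a gradient down to ``shape`` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = tsum(g, axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = tsum(g, axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------- primitives

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    return _node(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    return _node(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)))


def powi(a, p: float):
    a = _wrap(a)
    p = float(p)

    def vjp(g):
        return (mul(g, mul(powi(a, p - 1), p)),)

    return _node(a.data ** p, (a,), vjp)


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return _node(a.data @ b.data, (a, b),
                 lambda g: (matmul(g, transpose(b)), matmul(transpose(a), g)))


def texp(a):
    a = _wrap(a)
    out = _node(np.exp(a.data), (a,), None)
    if out.requires_grad:  # vjp reuses the output tensor: d exp = exp
        out._vjp = lambda g: (mul(g, out),)
    return out


def tlog(a):
    a = _wrap(a)
    return _node(np.log(a.data), (a,), lambda g: (mul(g, powi(a, -1.0)),))


def sigmoid(a):
    a = _wrap(a)
    y = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
    out = _node(y, (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, mul(out, add(mul(out, -1.0), 1.0))),)
    return out


def leaky_relu(a, slope: float = 0.01):
    a = _wrap(a)
    factor = np.where(a.data >= 0, 1.0, slope)
    return _node(a.data * factor, (a,), lambda g: (mul(g, Tensor(factor)),))


def tsum(a, axis=None, keepdims=False):
    a = _wrap(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        gd = g
        if axis is not None and not keepdims:
            gd = reshape(g, _keepdims_shape(a.shape, axis))
        return (broadcast_to(gd, a.shape),)

    return _node(data, (a,), vjp)


def _keepdims_shape(shape, axis):
    axes = (axis,) if isinstance(axis, int) else tuple(axis)
    axes = tuple(ax % len(shape) for ax in axes)
    return tuple(1 if i in axes else n for i, n in enumerate(shape))


def tmean(a, axis=None, keepdims=False):
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod([a.shape[ax] for ax in ((axis,) if isinstance(axis, int) else axis)])
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def broadcast_to(a, shape):
    a = _wrap(a)
    if a.shape == tuple(shape):
        return a
    return _node(np.broadcast_to(a.data, shape).copy(), (a,),
                 lambda g: (_unbroadcast(g, a.shape),))


def reshape(a, shape):
    a = _wrap(a)
    return _node(a.data.reshape(shape), (a,), lambda g: (reshape(g, a.shape),))


def transpose(a, axes=None):
    a = _wrap(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))
    return _node(a.data.transpose(axes), (a,), lambda g: (transpose(g, inv),))


def concat(tensors, axis=0):
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for k, t in enumerate(tensors):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(offsets[k]), int(offsets[k + 1]))
            outs.append(getitem(g, tuple(idx)))
        return tuple(outs)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), vjp)


def getitem(a, idx):
    a = _wrap(a)

    def vjp(g):
        return (_scatter(g, a.shape, idx),)

    return _node(a.data[idx], (a,), vjp)


def _scatter(g: Tensor, shape, idx) -> Tensor:
    # linear adjoint of slicing: place g into zeros at idx
    def vjp(gg):
        return (getitem(gg, idx),)

    out = np.zeros(shape)
    np.add.at(out, idx, g.data)
    return _node(out, (g,), vjp)


def sqrt(a):
    return powi(a, 0.5)


# --------------------------------------------------------- conv building blocks

def _out_len(L: int, K: int, stride: int, pad: int) -> int:
    return (L + 2 * pad - K) // stride + 1


def unfold1d(a, K: int, stride: int = 1, pad: int = 0):
    """im2col: (N, C, L) -> (N, C*K, Lo) with zero padding."""
    a = _wrap(a)
    N, C, L = a.shape
    Lo = _out_len(L, K, stride, pad)

    def forward(x):
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad))) if pad else x
        cols = np.empty((N, C, K, Lo))
        for k in range(K):
            cols[:, :, k, :] = xp[:, :, k : k + stride * Lo : stride]
        return cols.reshape(N, C * K, Lo)

    def vjp(g):
        return (fold1d(g, (N, C, L), K, stride, pad),)

    return _node(forward(a.data), (a,), vjp)


def fold1d(g, out_shape, K: int, stride: int = 1, pad: int = 0):
    """col2im: adjoint of :func:`unfold1d` (overlap-add into the input shape)."""
    g = _wrap(g)
    N, C, L = out_shape
    Lo = _out_len(L, K, stride, pad)

    def forward(x):
        xr = x.reshape(N, C, K, Lo)
        out = np.zeros((N, C, L + 2 * pad))
        for k in range(K):  # slices with a fixed offset never self-overlap
            out[:, :, k : k + stride * Lo : stride] += xr[:, :, k, :]
        return out[:, :, pad : pad + L] if pad else out

    def vjp(gg):
        return (unfold1d(gg, K, stride, pad),)

    return _node(forward(g.data), (g,), vjp)


def dilate1d(a, stride: int):
    """Insert stride-1 zeros between entries along the last axis."""
    a = _wrap(a)
    if stride == 1:
        return a
    N, C, L = a.shape
    Lo = (L - 1) * stride + 1

    def vjp(g):
        return (getitem(g, (slice(None), slice(None), slice(None, None, stride))),)

    out = np.zeros((N, C, Lo))
    out[:, :, ::stride] = a.data
    return _node(out, (a,), vjp)


def flip_last(a):
    a = _wrap(a)
    return _node(a.data[..., ::-1].copy(), (a,), lambda g: (flip_last(g),))


def conv1d(x, w, b=None, stride: int = 1, pad: int = 0):
    """1-D convolution (cross-correlation): x (N,C,L), w (Co,C,K) -> (N,Co,Lo)."""
    x, w = _wrap(x), _wrap(w)
    N, C, L = x.shape
    Co, Cw, K = w.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    cols = unfold1d(x, K, stride, pad)                 # (N, C*K, Lo)
    Lo = cols.shape[2]
    flat = reshape(transpose(cols, (0, 2, 1)), (N * Lo, C * K))
    out = matmul(flat, transpose(reshape(w, (Co, C * K))))
    out = transpose(reshape(out, (N, Lo, Co)), (0, 2, 1))
    if b is not None:
        out = add(out, reshape(_wrap(b), (1, Co, 1)))
    return out


def conv_transpose1d(x, w, b=None, stride: int = 1, pad: int = 0):
    """1-D transposed convolution: x (N,Ci,L), w (Ci,Co,K) -> (N,Co,(L-1)*stride-2*pad+K)."""
    x, w = _wrap(x), _wrap(w)
    K = w.shape[2]
    xd = dilate1d(x, stride)
    w_conv = transpose(flip_last(w), (1, 0, 2))  # (Co, Ci, K)
    return conv1d(xd, w_conv, b, stride=1, pad=K - 1 - pad)


def linear(x, w, b=None):
    """x (N, D) @ w (D, M) + b."""
    out = matmul(_wrap(x), _wrap(w))
    if b is not None:
        out = add(out, _wrap(b))
    return out


# ----------------------------------------------------------------- backprop

def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order


def _backprop(output: Tensor, grad_output: Tensor, create_graph: bool) -> dict[Tensor, Tensor]:
    grads: dict[int, Tensor] = {id(output): grad_output}
    by_id: dict[int, Tensor] = {id(output): output}
    order = _toposort(output)
    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(order):
            by_id[id(node)] = node
            g = grads.get(id(node))
            if g is None or node._vjp is None:
                continue
            parent_grads = node._vjp(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = add(grads[id(p)], pg)
                else:
                    grads[id(p)] = pg
                by_id[id(p)] = p
    return {by_id[i]: g for i, g in grads.items()}


def grad(output: Tensor, wrt, grad_output=None, create_graph: bool = False) -> list[Tensor]:
    """Gradients of a scalar ``output`` w.r.t. each tensor in ``wrt``.

    With ``create_graph=True`` the returned gradients carry their own graph
    and can be differentiated again.
    """
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    grads = _backprop(output, _wrap(grad_output), create_graph)
    out = []
    for t in wrt:
        out.append(grads.get(t, Tensor(np.zeros_like(t.data))))
    return out
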