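"""Minimal vectorized reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core the package's neural networks are built on.  It
supports exactly the operations the models need: dense linear algebra,
element-wise nonlinearities, reductions, reshaping, and a valid 1-D
cross-correlation for the convolutional classifier.

Dense operations (matmul, add, mul, pow, sqrt, sum, leaky_relu, sigmoid, ...)
express their backward pass in terms of the same ``Tensor`` operations, so
gradients are themselves differentiable: calling :func:`grad` with
``create_graph=True`` and differentiating the result again yields correct
second-order derivatives.  This is required by the Wasserstein-GAN gradient
penalty, whose loss contains the norm of an input gradient.  ``conv1d`` is the
one first-order-only operation (its backward returns constants); :func:`grad`
raises if a ``create_graph`` pass would cross it.

All data is float64.  There is no implicit graph retention: each forward pass
builds a fresh graph that is garbage-collected once its gradients are taken.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "grad", "as_tensor", "conv1d", "leaky_relu", "sigmoid",
           "logsigmoid", "tsum", "tmean", "add", "mul", "matmul", "tpow",
           "sqrt", "exp", "log", "reshape", "transpose", "broadcast_to",
           "Adam"]


class Tensor:
    """A NumPy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "requires_grad", "parents", "vjp", "op")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), vjp: Callable | None = None,
                 op: str = "leaf"):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.parents = parents
        self.vjp = vjp
        self.op = op

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(op={self.op}, shape={self.shape}, grad={self.requires_grad})"

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, tpow(other, -1.0))

    def __pow__(self, c):
        return tpow(self, c)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes or None)

    @property
    def T(self):
        return transpose(self, None)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, vjp, op) -> Tensor:
    if any(p.requires_grad for p in parents):
        return Tensor(data, True, parents, vjp, op)
    return Tensor(data, False, (), None, op)


# ---------------------------------------------------------------------------
# broadcasting helpers
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = tsum(g, axis=0)
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape))
                 if s == 1 and gs != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


def broadcast_to(x: Tensor, shape) -> Tensor:
    x = as_tensor(x)
    data = np.broadcast_to(x.data, shape)
    return _node(data, (x,), lambda g: (_unbroadcast(g, x.shape),), "broadcast")


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
                 "add")


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(mul(g, b), a.shape),
                            _unbroadcast(mul(g, a), b.shape)),
                 "mul")


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(a.data @ b.data, (a, b),
                 lambda g: (matmul(g, transpose(b, None)),
                            matmul(transpose(a, None), g)),
                 "matmul")


def tpow(a, c: float) -> Tensor:
    a = as_tensor(a)
    c = float(c)
    return _node(a.data ** c, (a,),
                 lambda g: (mul(g, mul(tpow(a, c - 1.0), c)),),
                 "pow")


def sqrt(a) -> Tensor:
    return tpow(a, 0.5)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)
    out = _node(out_data, (a,), None, "exp")
    if out.requires_grad:
        out.vjp = lambda g: (mul(g, out),)
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    return _node(np.log(a.data), (a,),
                 lambda g: (mul(g, tpow(a, -1.0)),), "log")


# ---------------------------------------------------------------------------
# reductions & shaping
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        gg = g
        if not keepdims and axis is not None:
            shp = list(a.shape)
            axes = (axis,) if isinstance(axis, int) else axis
            for ax in axes:
                shp[ax] = 1
            gg = reshape(gg, tuple(shp))
        elif not keepdims and axis is None:
            gg = reshape(gg, (1,) * a.ndim)
        return (broadcast_to(gg, a.shape),)

    return _node(data, (a,), vjp, "sum")


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in ((axis,) if isinstance(axis, int) else axis)])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return _node(a.data.reshape(shape), (a,),
                 lambda g: (reshape(g, a.shape),), "reshape")


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    if axes is None:
        inv = None
    else:
        inv = tuple(np.argsort(axes))
    return _node(a.data.transpose(axes), (a,),
                 lambda g: (transpose(g, inv),), "transpose")


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = as_tensor(a)
    mask = np.where(a.data >= 0, 1.0, slope)
    return _node(a.data * mask, (a,),
                 lambda g: (mul(g, Tensor(mask)),), "leaky_relu")


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    with np.errstate(over="ignore"):
        s_data = 1.0 / (1.0 + np.exp(-a.data))
    out = _node(s_data, (a,), None, "sigmoid")
    if out.requires_grad:
        out.vjp = lambda g: (mul(g, mul(out, 1.0 - out)),)
    return out


def logsigmoid(a) -> Tensor:
    """Numerically stable log(sigmoid(x)); gradient is sigmoid(-x)."""
    a = as_tensor(a)
    data = -np.logaddexp(0.0, -a.data)
    return _node(data, (a,),
                 lambda g: (mul(g, sigmoid(mul(a, -1.0))),), "logsigmoid")


# ---------------------------------------------------------------------------
# valid 1-D cross-correlation (first-order only)
# ---------------------------------------------------------------------------

def conv1d(x, w) -> Tensor:
    """Valid cross-correlation along the length axis.

    ``x`` has shape (batch, length, channels); ``w`` has shape
    (filters, kernel, channels).  Output is (batch, length-kernel+1, filters):

        out[b, i, f] = sum_m sum_c w[f, m, c] * x[b, i+m, c]

    Backward returns constant tensors; second-order differentiation through
    this op is not supported.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, L, C = x.shape
    F, M, Cw = w.shape
    if Cw != C:
        raise ValueError(f"kernel channels {Cw} != input channels {C}")
    if M > L:
        raise ValueError(f"kernel size {M} larger than input length {L}")
    windows = np.lib.stride_tricks.sliding_window_view(x.data, M, axis=1)
    # windows: (B, L-M+1, C, M)
    out_data = np.einsum("bicm,fmc->bif", windows, w.data, optimize=True)

    def vjp(g):
        gd = g.data  # (B, Lo, F)
        dw = np.einsum("bicm,bif->fmc", windows, gd, optimize=True)
        gpad = np.pad(gd, ((0, 0), (M - 1, M - 1), (0, 0)))
        gwin = np.lib.stride_tricks.sliding_window_view(gpad, M, axis=1)
        # gwin: (B, L, F, M)
        dx = np.einsum("blfm,fmc->blc", gwin, w.data[:, ::-1, :], optimize=True)
        return (Tensor(dx), Tensor(dw))

    return _node(out_data, (x, w), vjp, "conv1d")


# ---------------------------------------------------------------------------
# reverse-mode driver
# ---------------------------------------------------------------------------

def grad(output: Tensor, wrt: Sequence[Tensor],
         create_graph: bool = False) -> list[Tensor]:
    """Gradients of scalar ``output`` with respect to each tensor in ``wrt``.

    With ``create_graph=True`` the returned gradients carry their own graph
    and can be differentiated again (dense ops only).
    """
    if output.data.size != 1:
        raise ValueError("grad expects a scalar output")

    # iterative topological sort over the subgraph that requires grad
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited or not node.requires_grad:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))

    grads: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    for node in reversed(topo):
        g = grads.get(id(node))
        if g is None or node.vjp is None:
            continue
        if create_graph and node.op == "conv1d":
            raise NotImplementedError(
                "conv1d supports first-order differentiation only")
        for p, pg in zip(node.parents, node.vjp(g)):
            if pg is None or not p.requires_grad:
                continue
            acc = grads.get(id(p))
            grads[id(p)] = pg if acc is None else add(acc, pg)

    out = []
    for w in wrt:
        g = grads.get(id(w))
        if g is None:
            g = Tensor(np.zeros_like(w.data))
        out.append(g if create_graph else g.detach())
    return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam optimizer over a name -> Tensor parameter mapping.

    Updates parameter ``.data`` in place; safe because no graph outlives a
    training step.
    """

    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for k, p in self.params.items():
            g = grads[k]
            m = self._m[k] = b1 * self._m[k] + (1 - b1) * g
            v = self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
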