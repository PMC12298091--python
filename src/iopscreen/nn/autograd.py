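"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A compact define-by-run engine: every operation builds a node holding its
parents and a closure that maps the output gradient to parent gradients.
``Tensor.backward()`` runs a topological sweep. Gradients are materialized
for every node in the graph, so intermediate activations (e.g. backbone
stage features for Grad-CAM) can be inspected after a backward pass.

Float64 throughout: the engine trades speed for exactness at the desk
scales this package runs at.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """N-d array with gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    # -- helpers ----------------------------------------------------------
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

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'None'})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                a2 = a[None, :]
                ga = (g[None, :] if g.ndim == 1 else g) @ np.swapaxes(b, -1, -2)
                ga = ga.reshape(a.shape) if ga.size == a.size else _unbroadcast(ga, a.shape)
                gb = a2.T @ (g[None, :] if g.ndim == 1 else g)
                return ga, _unbroadcast(gb, b.shape)
            if b.ndim == 1:
                ga = g[..., :, None] @ b[None, :]
                gb = np.swapaxes(a, -1, -2) @ g[..., :, None]
                return _unbroadcast(ga, a.shape), _unbroadcast(gb[..., 0], b.shape)
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)
        out._backward = backward
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: (g.transpose(inv),)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)
        out._backward = backward
        return out

    def roll(self, shift, axis):
        out = Tensor(np.roll(self.data, shift, axis=axis), parents=(self,))
        out._backward = lambda g: (np.roll(g, tuple(-s for s in np.atleast_1d(shift)), axis=axis),)
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: (g * (self.data > 0),)
        return out

    def leaky_relu(self, alpha: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, alpha * self.data), parents=(self,))
        out._backward = lambda g: (g * np.where(self.data > 0, 1.0, alpha),)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: (g * s * (1 - s),)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = lambda g: (g * (1 - t * t),)
        return out

    def gelu(self):
        # tanh approximation
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out = Tensor(0.5 * x * (1 + t), parents=(self,))
        def backward(g):
            dt = (1 - t * t) * c * (1 + 3 * 0.044715 * x**2)
            return (g * (0.5 * (1 + t) + 0.5 * x * dt),)
        out._backward = backward
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: (g * e,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), parents=(self,))
        out._backward = lambda g: (g * np.sign(self.data),)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; zero gradient outside the active range."""
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        mask = (self.data > lo) & (self.data < hi)
        out._backward = lambda g: (g * mask,)
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, parents=(self,))
        def backward(g):
            return (s * (g - (g * s).sum(axis=axis, keepdims=True)),)
        out._backward = backward
        return out

    def dropout(self, p: float, rng: np.random.Generator, training: bool = True):
        """Inverted dropout; identity when not training or p == 0."""
        if not training or p <= 0.0:
            return self
        mask = (rng.random(self.shape) >= p) / (1.0 - p)
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: (g * mask,)
        return out

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2-D cross-correlation: x (N,C,H,W) * w (O,C,kh,kw) -> (N,O,Ho,Wo)."""
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        o, c2, kh, kw = w.shape
        if c != c2:
            raise ValueError("channel mismatch in conv2d")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]  # (N,C,Ho,Wo,kh,kw)
        y = np.einsum("nchwij,ocij->nohw", win, w, optimize=True)
        if bias is not None:
            y = y + bias.data[None, :, None, None]
        parents = (self, weight) if bias is None else (self, weight, bias)
        out = Tensor(y, parents=parents)
        ho, wo = y.shape[2], y.shape[3]
        def backward(g):
            gw = np.einsum("nohw,nchwij->ocij", g, win, optimize=True)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                        np.einsum("nohw,oc->nchw", g, w[:, :, i, j], optimize=True)
                    )
            gx = gxp[:, :, padding : padding + h, padding : padding + wd] if padding else gxp
            if bias is None:
                return gx, gw
            return gx, gw, g.sum(axis=(0, 2, 3))
        out._backward = backward
        return out

    # -- backward ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
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
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pg in zip(node._parents, node._backward(node.grad)):
                if pg is None:
                    continue
                if parent.grad is None:
                    parent.grad = pg.copy()
                else:
                    parent.grad = parent.grad + pg


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy from raw logits (numerically stable)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    n = logits.shape[0]
    labels = np.asarray(labels, dtype=int)
    loss_val = -logp[np.arange(n), labels].mean()
    out = Tensor(loss_val, parents=(logits,))
    def backward(g):
        soft = np.exp(logp)
        soft[np.arange(n), labels] -= 1.0
        return (g * soft / n,)
    out._backward = backward
    return out
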