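"""Compact reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the graph-attention network and the
multi-instance pooling objective need: dense affine maps, element-wise
nonlinearities, row gather/scatter (segment sums) for message passing on
edge lists, and numerically shifted segment softmax / log-sum-exp.

Gradients accumulate into ``Tensor.grad`` after calling ``backward()`` on a
scalar-valued tensor.  All data is float64; shapes follow NumPy broadcasting
only where explicitly implemented (bias addition).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant"]


class Tensor:
    """A node in the computation graph wrapping an ``ndarray``."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self._grad_owned = False

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray, own: bool = True) -> None:
        """Accumulate a gradient contribution.

        ``own=True`` promises ``g`` is a freshly allocated array no other
        node references, so it can be stored and mutated in place;
        otherwise copy-on-write applies on the second contribution.
        """
        if self.grad is None:
            self.grad = g
            self._grad_owned = own
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def zero_grad(self) -> None:
        self.grad = None
        self._grad_owned = False

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            ga = _unbroadcast(g, self.data.shape)
            self._accum(ga, own=ga is not g)
            gb = _unbroadcast(g, other.data.shape)
            other._accum(gb, own=gb is not g)

        out._backward = bw
        return out

    def __sub__(self, other: "Tensor") -> "Tensor":
        out = _node(self.data - other.data, (self, other))

        def bw(g):
            ga = _unbroadcast(g, self.data.shape)
            self._accum(ga, own=ga is not g)
            other._accum(_unbroadcast(-g, other.data.shape))

        out._backward = bw
        return out

    def __mul__(self, other: "Tensor") -> "Tensor":
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    def __neg__(self) -> "Tensor":
        return self.scale(-1.0)

    def scale(self, c: float) -> "Tensor":
        out = _node(self.data * c, (self,))
        out._backward = lambda g: self._accum(g * c)
        return out

    def shift(self, c) -> "Tensor":
        """Add a gradient-free constant (scalar or array)."""
        out = _node(self.data + c, (self,))
        out._backward = lambda g: self._accum(g, own=False)
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = _node(self.data @ other.data, (self, other))

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bw
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        return self.matmul(other)

    # -- nonlinearities ----------------------------------------------------

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(y, (self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = _node(y, (self,))
        out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def leaky_relu(self, alpha: float = 0.01) -> "Tensor":
        pos = self.data > 0
        out = _node(np.where(pos, self.data, alpha * self.data), (self,))
        out._backward = lambda g: self._accum(g * np.where(pos, 1.0, alpha))
        return out

    def elu(self) -> "Tensor":
        pos = self.data > 0
        e = np.exp(np.minimum(self.data, 0.0))
        out = _node(np.where(pos, self.data, e - 1.0), (self,))
        out._backward = lambda g: self._accum(g * np.where(pos, 1.0, e))
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = _node(y, (self,))
        out._backward = lambda g: self._accum(g * y)
        return out

    def log(self) -> "Tensor":
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def square(self) -> "Tensor":
        out = _node(self.data * self.data, (self,))
        out._backward = lambda g: self._accum(2.0 * g * self.data)
        return out

    # -- reductions & structure -------------------------------------------

    def mean(self) -> "Tensor":
        out = _node(np.array(self.data.mean()), (self,))
        n = self.data.size
        out._backward = lambda g: self._accum(np.full_like(self.data, float(g) / n))
        return out

    def gather(self, idx: np.ndarray) -> "Tensor":
        """Select rows ``self[idx]``; gradient scatter-adds back."""
        out = _node(self.data[idx], (self,))

        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)

        out._backward = bw
        return out

    def segment_sum(self, seg: np.ndarray, n_segments: int) -> "Tensor":
        """Sum rows into ``n_segments`` buckets given per-row segment ids."""
        shape = (n_segments,) + self.data.shape[1:]
        acc = np.zeros(shape, dtype=np.float64)
        np.add.at(acc, seg, self.data)
        out = _node(acc, (self,))
        out._backward = lambda g: self._accum(g[seg])
        return out

    def concat(self, other: "Tensor") -> "Tensor":
        out = _node(np.concatenate([self.data, other.data], axis=1), (self, other))
        k = self.data.shape[1]

        def bw(g):
            self._accum(np.ascontiguousarray(g[:, :k]))
            other._accum(np.ascontiguousarray(g[:, k:]))

        out._backward = bw
        return out

    def dropout(self, rate: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout; the mask is a constant w.r.t. the graph."""
        if rate <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= rate) / (1.0 - rate)
        out = _node(self.data * mask, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- composite segment ops --------------------------------------------

    def segment_softmax(self, seg: np.ndarray, n_segments: int) -> "Tensor":
        """Softmax of a column vector within each segment, shift-stabilized.

        The per-segment max used for stabilization is treated as a constant;
        the resulting gradient is exact (the shift cancels analytically).
        """
        m = np.full(n_segments, -np.inf)
        np.maximum.at(m, seg, self.data[:, 0])
        z = self.shift(-m[seg][:, None]).exp()
        denom = z.segment_sum(seg, n_segments)
        return z * denom.gather(seg).pow_inv()

    def pow_inv(self) -> "Tensor":
        out = _node(1.0 / self.data, (self,))
        out._backward = lambda g: self._accum(-g / (self.data * self.data))
        return out

    def segment_logsumexp(self, seg: np.ndarray, n_segments: int) -> "Tensor":
        """Per-segment log(sum(exp(x))) of a column vector, shift-stabilized."""
        m = np.full(n_segments, -np.inf)
        np.maximum.at(m, seg, self.data[:, 0])
        m = np.where(np.isfinite(m), m, 0.0)
        z = self.shift(-m[seg][:, None]).exp()
        s = z.segment_sum(seg, n_segments)
        return s.log().shift(m[:, None])


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents)
    out.requires_grad = True
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to ``shape`` after broadcast addition."""
    if g.shape == shape:
        return g
    # bias rows broadcast over axis 0
    extra = g.ndim - len(shape)
    for _ in range(extra):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def constant(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64))
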