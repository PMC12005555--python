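"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the graph network needs: broadcasting
arithmetic, matmul, reshape/transpose, reductions, leaky ReLU, masked
softmax, concatenation, a signed-log transform, 2x block upsampling and
Toeplitz construction from diagonal values.  Written so the network is
trainable on CPU without any deep-learning framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to the original operand shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_sum_to_shape(grad, self.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(grad, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, out):
            if self.requires_grad:
                self._accum(-grad)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_sum_to_shape(grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(grad * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ grad)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- shape ops -------------------------------------------------------

    @property
    def T(self):
        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad.T)

        return self._make(self.data.T, (self,), backward)

    def reshape(self, *shape):
        old = self.shape

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(grad, out):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * grad.ndim
                    idx[axis] = slice(lo, hi)
                    t._accum(grad[tuple(idx)])

        data = np.concatenate([t.data for t in tensors], axis=axis)
        out = Tensor(data)
        if any(t.requires_grad for t in tensors):
            out.requires_grad = True
            out._parents = tuple(tensors)
            out._backward = backward
        return out

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(grad, out):
            if not self.requires_grad:
                return
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities --------------------------------------------------

    def leaky_relu(self, slope: float = 0.01):
        mask = np.where(self.data > 0, 1.0, slope)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * mask)

        return self._make(self.data * mask, (self,), backward)

    def exp(self):
        val = np.exp(self.data)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * val)

        return self._make(val, (self,), backward)

    def signed_log(self):
        """Elementwise sign(x) * ln(|x| + 1); derivative 1 / (|x| + 1)."""
        val = np.sign(self.data) * np.log1p(np.abs(self.data))
        deriv = 1.0 / (np.abs(self.data) + 1.0)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * deriv)

        return self._make(val, (self,), backward)

    def masked_softmax(self, mask: np.ndarray, axis: int = -1):
        """Softmax along ``axis`` over entries where mask is True; masked
        entries receive exactly zero weight."""
        neg = np.where(mask, 0.0, -np.inf)
        shifted = self.data + neg
        shifted = shifted - shifted.max(axis=axis, keepdims=True)
        with np.errstate(invalid="ignore"):
            e = np.exp(shifted)
        e = np.where(mask, e, 0.0)
        denom = e.sum(axis=axis, keepdims=True)
        denom = np.where(denom > 0, denom, 1.0)
        soft = e / denom

        def backward(grad, out):
            if self.requires_grad:
                dot = (grad * soft).sum(axis=axis, keepdims=True)
                self._accum(soft * (grad - dot))

        return self._make(soft, (self,), backward)

    # -- structured ops --------------------------------------------------

    def upsample2(self):
        """Replicate each entry of a square matrix into a 2x2 block."""
        data = np.kron(self.data, np.ones((2, 2)))

        def backward(grad, out):
            if self.requires_grad:
                n = self.data.shape[0]
                self._accum(grad.reshape(n, 2, n, 2).sum(axis=(1, 3)))

        return self._make(data, (self,), backward)

    def toeplitz_from_diags(self):
        """Build a symmetric Toeplitz matrix whose d-th diagonal is entry d
        of this length-m vector."""
        t = self.data.ravel()
        m = t.shape[0]
        i, j = np.indices((m, m))
        dist = np.abs(i - j)
        data = t[dist]

        def backward(grad, out):
            if self.requires_grad:
                g = np.zeros(m)
                np.add.at(g, dist.ravel(), grad.ravel())
                self._accum(g.reshape(self.shape))

        return self._make(data, (self,), backward)

    @staticmethod
    def edge_project(E: np.ndarray, W: "Tensor") -> "Tensor":
        """Project fixed (n, n, c) edge features with a learnable (c, d)
        matrix: out_ijd = sum_c E_ijc W_cd."""
        def backward(grad, out):
            if W.requires_grad:
                W._accum(np.tensordot(E, grad, axes=([0, 1], [0, 1])))

        data = np.tensordot(E, W.data, axes=([2], [0]))
        out = Tensor(data)
        if W.requires_grad:
            out.requires_grad = True
            out._parents = (W,)
            out._backward = backward
        return out

    # -- backprop --------------------------------------------------------

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=float)
        else:
            self.grad += grad

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
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad, node)


class Adam:
    """Adam optimizer over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
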