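"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The auto-encoder's computation graph is small and fixed (a handful of dense
matrix products, per-edge gathers/scatters expressed as constant sparse
matrix products, and elementwise nonlinearities), so a compact tape-based
engine suffices. Gradients are exact and are checked against central finite
differences in the test suite.

Only the operations the model needs are implemented; there is no
broadcasting beyond the explicit column-scaling op.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np
import scipy.sparse as sp


class Tensor:
    """A node in the computation tape: value, gradient, and backward rule."""

    __slots__ = (
        "data",
        "grad",
        "parents",
        "_backward",
        "requires_grad",
        "_grad_owned",
    )

    def __init__(
        self,
        data: np.ndarray,
        parents: tuple = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._grad_owned = False

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        # first contribution is stored by reference (grads of finished nodes
        # are never mutated, so sharing is safe); later ones allocate
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif not self._grad_owned:
            self.grad = self.grad + g
            self._grad_owned = True
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) node."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def param(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


def const(data: np.ndarray) -> Tensor:
    return Tensor(data)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return Tensor(out_data, (a, b), backward)


def matmul_t(a: Tensor, b: Tensor) -> Tensor:
    """a @ b.T with gradient flowing to both operands (tied-weight decoder)."""
    out_data = a.data @ b.data.T

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data)
        if b.requires_grad:
            b._accumulate(g.T @ a.data)

    return Tensor(out_data, (a, b), backward)


def smm(m: sp.spmatrix, x: Tensor, mt: Optional[sp.spmatrix] = None) -> Tensor:
    """Constant-sparse-matrix product m @ x (gather / scatter-add).

    Pass the precomputed transpose ``mt`` to skip rebuilding it on every
    backward pass.
    """

    def backward(g):
        if x.requires_grad:
            x._accumulate((m.T.tocsr() if mt is None else mt) @ g)

    return Tensor(m @ x.data, (x,), backward)


def attn_aggregate(
    z: Tensor,
    att: Tensor,
    recv: np.ndarray,
    neigh: np.ndarray,
    template: sp.csr_matrix,
) -> Tensor:
    """Fused neighborhood aggregation: out_i = sum_j att_ij * z_j.

    ``template`` is an (N, N) CSR whose sparsity equals the edge set in
    canonical order; a per-call matrix sharing its index structure carries
    the attention values, so the whole aggregation is one sparse-dense
    product. ``att`` is the per-edge attention tensor aligned to that order.
    """
    a = sp.csr_matrix(
        (att.data.reshape(-1).copy(), template.indices, template.indptr),
        shape=template.shape,
    )
    out_data = a @ z.data

    def backward(g):
        if z.requires_grad:
            z._accumulate(a.T.tocsr() @ g)
        if att.requires_grad:
            att._accumulate(
                np.einsum("ij,ij->i", g[recv], z.data[neigh]).reshape(att.data.shape)
            )

    return Tensor(out_data, (z, att), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return Tensor(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(-g)

    return Tensor(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g * b.data)
        if b.requires_grad:
            b._accumulate(g * a.data)

    return Tensor(a.data * b.data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g / b.data)
        if b.requires_grad:
            b._accumulate(-g * a.data / b.data**2)

    return Tensor(a.data / b.data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g * c)

    return Tensor(a.data * c, (a,), backward)


def colmul(mat: Tensor, vec: Tensor) -> Tensor:
    """Scale row i of ``mat`` by ``vec[i]`` (per-edge attention weighting)."""
    out_data = mat.data * vec.data[:, None]

    def backward(g):
        if mat.requires_grad:
            mat._accumulate(g * vec.data[:, None])
        if vec.requires_grad:
            vec._accumulate((g * mat.data).sum(axis=1))

    return Tensor(out_data, (mat, vec), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    return Tensor(s, (a,), backward)


def exp(a: Tensor) -> Tensor:
    e = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * e)

    return Tensor(e, (a,), backward)


def elu(a: Tensor) -> Tensor:
    x = a.data
    out_data = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * np.where(x > 0, 1.0, out_data + 1.0))

    return Tensor(out_data, (a,), backward)


def reshape(a: Tensor, shape: tuple) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return Tensor(a.data.reshape(shape), (a,), backward)


def sum_all(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(np.full_like(a.data, float(g)))

    return Tensor(np.array(a.data.sum()), (a,), backward)


def square(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g * 2.0 * a.data)

    return Tensor(a.data**2, (a,), backward)


def row_norms(a: Tensor, eps: float = 1e-12) -> Tensor:
    """Per-row Euclidean norms of a 2-D tensor."""
    norms = np.sqrt((a.data**2).sum(axis=1))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[:, None] * a.data / (norms[:, None] + eps))

    return Tensor(norms, (a,), backward)


class Adam:
    """Adam with L2-coupled weight decay (grad += wd * param)."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-4,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
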