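"""A minimal reverse-mode automatic differentiation engine on numpy arrays.

Provides exactly the operations a pre-norm transformer encoder with a
masked-language-modeling head needs: broadcast-aware arithmetic, batched
matmul, embedding lookup, layer normalization, GELU, softmax, dropout and
a fused weighted cross-entropy. Gradients are accumulated by topological
traversal from a scalar loss. An AdamW optimizer with decoupled weight
decay and a one-cycle learning-rate schedule live here too.

All forward math is float64-free: arrays are kept in float32 for speed;
gradient checks in the test-suite compare against float64 central
differences at loose-but-honest tolerances.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    n_extra = grad.ndim - len(shape)
    if n_extra > 0:
        grad = grad.sum(axis=tuple(range(n_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: Array | float,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[Array], tuple[Array | None, ...]] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph traversal ----------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this scalar through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if g.dtype != np.float32:
                    g = g.astype(np.float32)
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "Tensor | Array | float") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g: Array):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor(out_data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __mul__(self, other: "Tensor | Array | float") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data
        a, b = self, other

        def backward(g: Array):
            return (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            )

        return Tensor(out_data, parents=(a, b), backward=backward)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: "Tensor | Array | float") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        # batched (..., m, k) @ 2-d (k, n): one flat GEMM beats a loop of
        # small batched GEMMs, both forward and backward
        if a.data.ndim > 2 and b.data.ndim == 2:
            m, k = a.data.shape[:-1], a.data.shape[-1]
            a2 = a.data.reshape(-1, k)
            out_data = (a2 @ b.data).reshape(*m, b.data.shape[1])

            def backward(g: Array):
                g2 = g.reshape(-1, b.data.shape[1])
                ga = (g2 @ b.data.T).reshape(a.data.shape)
                gb = a2.T @ g2
                return ga, gb

            return Tensor(out_data, parents=(a, b), backward=backward)

        out_data = a.data @ b.data

        def backward(g: Array):
            ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape)
            gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape)
            return ga, gb

        return Tensor(out_data, parents=(a, b), backward=backward)

    __matmul__ = matmul

    def reshape(self, *shape: int) -> "Tensor":
        out_data = self.data.reshape(*shape)
        orig = self.shape

        def backward(g: Array):
            return (g.reshape(orig),)

        return Tensor(out_data, parents=(self,), backward=backward)

    def transpose(self, *axes: int) -> "Tensor":
        out_data = self.data.transpose(*axes)
        inv = np.argsort(axes)

        def backward(g: Array):
            return (g.transpose(*inv),)

        return Tensor(out_data, parents=(self,), backward=backward)

    def sum(self, axis: int | tuple[int, ...] | None = None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g: Array):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_exp, shape).copy(),)

        return Tensor(out_data, parents=(self,), backward=backward)

    def mean(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# -- nonlinearities and normalization ---------------------------------------

_GELU_C = math.sqrt(2.0 / math.pi)


def gelu(x: Tensor) -> Tensor:
    """GELU activation (tanh approximation)."""
    xd = x.data
    x2 = xd * xd
    t = x2 * xd
    t *= np.float32(0.044715)
    t += xd
    t *= np.float32(_GELU_C)
    np.tanh(t, out=t)
    out_data = t + np.float32(1.0)
    out_data *= xd
    out_data *= np.float32(0.5)

    def backward(g: Array):
        np.multiply(x2, np.float32(3 * 0.044715), out=x2)
        np.add(x2, np.float32(1.0), out=x2)
        np.multiply(x2, np.float32(_GELU_C), out=x2)  # d(inner)/dx
        dx = t * t
        np.subtract(np.float32(1.0), dx, out=dx)
        dx *= x2
        dx *= xd
        dx += t
        dx += np.float32(1.0)
        dx *= np.float32(0.5)
        dx *= g
        return (dx,)

    return Tensor(out_data, parents=(x,), backward=backward)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned gain and bias."""
    xd = x.data
    mu = xd.mean(axis=-1, keepdims=True)
    xhat = xd - mu
    var = np.mean(xhat * xhat, axis=-1, keepdims=True)
    var += eps
    inv_sigma = 1.0 / np.sqrt(var)
    xhat *= inv_sigma
    out_data = xhat * gain.data
    out_data += bias.data

    def backward(g: Array):
        gg = g * gain.data
        m1 = gg.mean(axis=-1, keepdims=True)
        m2 = (gg * xhat).mean(axis=-1, keepdims=True)
        dx = inv_sigma * (gg - m1 - xhat * m2)
        dgain = _unbroadcast(g * xhat, gain.shape)
        dbias = _unbroadcast(g, bias.shape)
        return dx, dgain, dbias

    return Tensor(out_data, parents=(x, gain, bias), backward=backward)


def softmax(x: Tensor, key_mask: Array | None = None) -> Tensor:
    """Softmax over the last axis; ``key_mask`` (float 0/1, broadcastable)
    zeroes the probability of masked keys and receives no gradient."""
    y = x.data - x.data.max(axis=-1, keepdims=True)
    np.exp(y, out=y)
    if key_mask is not None:
        y *= key_mask
    y /= y.sum(axis=-1, keepdims=True)

    def backward(g: Array):
        dot = (g * y).sum(axis=-1, keepdims=True)
        out = g - dot
        out *= y
        return (out,)

    return Tensor(y, parents=(x,), backward=backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (eval mode) or p == 0."""
    if rng is None or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)

    def backward(g: Array):
        return (g * keep,)

    return Tensor(x.data * keep, parents=(x,), backward=backward)


def embedding(weight: Tensor, ids: Array) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add backward."""
    out_data = weight.data[ids]

    def backward(g: Array):
        dw = np.zeros_like(weight.data)
        np.add.at(dw, ids, g)
        return (dw,)

    return Tensor(out_data, parents=(weight,), backward=backward)


def take_rows(x: Tensor, row_idx: Array, col_idx: Array) -> Tensor:
    """Gather ``x[row_idx, col_idx]`` from a 3-d tensor, shape (m, d)."""
    out_data = x.data[row_idx, col_idx]
    shape = x.shape

    def backward(g: Array):
        dx = np.zeros(shape, dtype=np.float32)
        np.add.at(dx, (row_idx, col_idx), g)
        return (dx,)

    return Tensor(out_data, parents=(x,), backward=backward)


def weighted_cross_entropy(
    logits: Tensor, targets: Array, weights: Array
) -> Tensor:
    """Weighted sum of per-position cross-entropies.

    ``logits`` has shape (..., V); ``targets`` integer ids of shape (...);
    ``weights`` float per-position weights of shape (...). Returns the
    scalar sum of ``weights * CE``; positions with weight 0 contribute
    nothing to the value or the gradient.
    """
    # zero-weight positions may carry out-of-vocabulary targets (padding);
    # they contribute nothing, so index them safely at 0
    targets = np.where(weights != 0, targets, 0)
    ld = logits.data
    z = ld - ld.max(axis=-1, keepdims=True)
    expz = np.exp(z)
    sumexp = expz.sum(axis=-1, dtype=np.float64)
    true_logit = np.take_along_axis(z, targets[..., None], axis=-1)[..., 0]
    ce = np.log(sumexp) - true_logit
    out = float((weights * ce).sum())

    def backward(g: Array):
        p = expz / sumexp[..., None].astype(np.float32)
        p[tuple(np.indices(targets.shape)) + (targets,)] -= 1.0
        w = (g * weights)[..., None].astype(np.float32)
        p *= w
        return (p,)

    return Tensor(out, parents=(logits,), backward=backward)


# -- parameters and optimization ---------------------------------------------


def parameter(data: Array) -> Tensor:
    return Tensor(data, requires_grad=True)


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-5,
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def one_cycle_lr(
    step: int, total_steps: int, max_lr: float, pct_start: float = 0.3,
    div_factor: float = 25.0, final_div_factor: float = 1e4,
) -> float:
    """One-cycle schedule: cosine warmup to ``max_lr`` over ``pct_start`` of
    the run, then cosine anneal down to ``max_lr / final_div_factor``."""
    warmup_steps = max(1, int(pct_start * total_steps))
    initial_lr = max_lr / div_factor
    final_lr = max_lr / final_div_factor
    if step < warmup_steps:
        frac = step / warmup_steps
        return initial_lr + (max_lr - initial_lr) * 0.5 * (1 - math.cos(math.pi * frac))
    frac = (step - warmup_steps) / max(1, total_steps - warmup_steps)
    return final_lr + (max_lr - final_lr) * 0.5 * (1 + math.cos(math.pi * frac))


def clip_grad_norm(params: Iterable[Tensor], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most max_norm."""
    params = [p for p in params if p.grad is not None]
    total = math.sqrt(sum(float((p.grad**2).sum()) for p in params))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            p.grad *= scale
    return total
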