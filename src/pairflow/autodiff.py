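"""A compact reverse-mode automatic-differentiation engine on numpy.

Just enough machinery to express and train the transformer denoiser:
tensors with a gradient tape, broadcast-aware arithmetic, matmul,
layer norm, GELU, softmax, embedding lookup and a fused masked
cross-entropy — plus an Adam optimizer.  Everything is float32 by
default for speed; gradients accumulate in the same dtype.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional backward closure on the tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("implicit gradient only for scalar outputs")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    order.append(node)
                    stack.pop()

        visit(self)
        self.grad = grad.astype(np.float32)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32).copy()
        else:
            self.grad += grad


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


_grad_enabled = True


class no_grad:
    """Context manager suppressing graph construction (inference mode)."""

    def __enter__(self) -> None:
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc) -> None:
        global _grad_enabled
        _grad_enabled = self._prev


def _make(
    data: np.ndarray, parents: Sequence[Tensor], backward: Callable[[np.ndarray], None]
) -> Tensor:
    req = _grad_enabled and any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(parents) if req else (),
                  backward=backward if req else None)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul_scalar(a: Tensor, c: float) -> Tensor:
    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g * c)

    return _make(a.data * c, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            if b.data.ndim == 2:
                ga = (g.reshape(-1, g.shape[-1]) @ b.data.T).reshape(a.shape)
            else:
                ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape)
            a.accumulate(ga)
        if b.requires_grad:
            if b.data.ndim == 2 and a.data.ndim >= 2:
                # shared weight matrix: fold batch dims into one big gemm
                a2 = np.ascontiguousarray(a.data).reshape(-1, a.shape[-1])
                g2 = g.reshape(-1, g.shape[-1])
                b.accumulate(a2.T @ g2)
            else:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b.accumulate(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


def gelu(a: Tensor) -> Tensor:
    """tanh-approximation GELU."""
    x = a.data
    c = np.float32(np.sqrt(2.0 / np.pi))
    x2 = x * x
    inner = c * (x + np.float32(0.044715) * x2 * x)
    th = np.tanh(inner)
    out_data = np.float32(0.5) * x * (1.0 + th)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            sech2 = 1.0 - th * th
            d = 0.5 * (1.0 + th) + 0.5 * x * sech2 * c * (
                1.0 + np.float32(3 * 0.044715) * x2
            )
            a.accumulate(g * d)

    return _make(out_data, (a,), backward)


def layer_norm(a: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise the last axis to zero mean / unit variance, then scale-shift."""
    x = a.data
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def backward(g: np.ndarray) -> None:
        n = x.shape[-1]
        if gamma.requires_grad:
            gamma.accumulate(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta.accumulate(_unbroadcast(g, beta.shape))
        if a.requires_grad:
            gx = g * gamma.data
            term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(
                axis=-1, keepdims=True
            )
            a.accumulate((term * inv).astype(np.float32))

    return _make(out_data, (a, gamma, beta), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            a.accumulate(s * (g - dot))

    return _make(s, (a,), backward)


def embedding(table: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx)
    out_data = table.data[idx]

    def backward(g: np.ndarray) -> None:
        if table.requires_grad:
            acc = np.zeros_like(table.data)
            np.add.at(acc, idx, g)
            table.accumulate(acc)

    return _make(out_data, (table,), backward)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    old = a.shape

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    inv = np.argsort(axes)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), backward)


def masked_cross_entropy(
    logits: Tensor, targets: np.ndarray, weights: np.ndarray
) -> tuple[Tensor, float]:
    """Weighted-mean softmax cross-entropy over the last axis.

    ``targets`` holds class indices, ``weights`` nonnegative per-entry
    weights (e.g. a masked-position indicator).  Returns the scalar loss
    tensor (sum of weighted CE divided by total weight) and the total
    weight, so callers can recombine batch statistics.
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1))
    picked = np.take_along_axis(z, targets[..., None], axis=-1)[..., 0]
    ce = lse - picked  # (...,)
    total_w = float(weights.sum())
    if total_w <= 0:
        raise ValueError("cross-entropy needs positive total weight")
    loss_val = float((ce * weights).sum() / total_w)

    def backward(g: np.ndarray) -> None:
        if logits.requires_grad:
            p = np.exp(z - lse[..., None])
            onehot = np.zeros_like(p)
            np.put_along_axis(onehot, targets[..., None], 1.0, axis=-1)
            grad = (p - onehot) * (weights / total_w)[..., None]
            logits.accumulate(grad.astype(np.float32) * g)

    out = _make(np.float32(loss_val), (logits,), backward)
    return out, total_w


class Adam:
    """Standard Adam with bias correction."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

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
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
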