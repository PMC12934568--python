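"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sized for the recurrent propagation networks in
this package: elementwise arithmetic with broadcasting, matrix products,
reductions, the activations/trigonometry the direction head needs, and two
custom linear ops (row gather for im2col convolution and weighted gather
for trilinear sampling of a feature volume).  Backpropagation through time
falls out of the tape; no special RNN handling is required.

Gradients accumulate on leaf tensors with ``requires_grad=True``.  Wrapping
code in :class:`no_grad` skips tape construction (inference mode), leaving
the numerical forward path identical.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to the shape it was broadcast from."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = parents
        self._backward = backward

    # -- graph helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        if _GRAD_ENABLED and any(
            p.requires_grad or p._parents for p in parents
        ):
            return Tensor(data, parents=parents, backward=backward)
        return Tensor(data)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents and not node.requires_grad:
                node.grad = None  # free intermediate storage

    # -- elementwise arithmetic ---------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        return Tensor._make(out_data, (self, other), bwd)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def bwd(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return Tensor._make(out_data, (self, other), bwd)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), bwd)

    def mean(self):
        n = self.data.size
        return self.sum() * (1.0 / n)

    # -- activations & trig -------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def sin(self):
        def bwd(g):
            self._accumulate(g * np.cos(self.data))

        return Tensor._make(np.sin(self.data), (self,), bwd)

    def cos(self):
        def bwd(g):
            self._accumulate(-g * np.sin(self.data))

        return Tensor._make(np.cos(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bwd)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def bwd(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(out_data, (self,), bwd)

    def slice_cols(self, start: int, stop: int):
        """Column slice of a 2-D tensor (zero-padded gradient)."""
        out_data = self.data[:, start:stop]

        def bwd(g):
            full = np.zeros_like(self.data)
            full[:, start:stop] = g
            self._accumulate(full)

        return Tensor._make(out_data, (self,), bwd)

    # -- custom linear ops --------------------------------------------
    def gather_rows(self, idx: np.ndarray):
        """Row gather ``self.data[idx]`` for a 2-D tensor (rows, C).

        ``idx`` may have any shape; the result has shape
        ``idx.shape + (C,)``.  The backward pass scatter-adds per channel
        with bincount, so a sentinel zero row (e.g. for convolution padding)
        simply collects and discards its gradient if it is the last row.
        """
        idx = np.asarray(idx)
        out_data = self.data[idx]
        n_rows, n_ch = self.data.shape

        def bwd(g):
            flat_idx = idx.ravel()
            gf = g.reshape(-1, n_ch)
            acc = np.empty((n_rows, n_ch), dtype=self.data.dtype)
            for c in range(n_ch):
                acc[:, c] = np.bincount(flat_idx, weights=gf[:, c], minlength=n_rows)
            self._accumulate(acc)

        return Tensor._make(out_data, (self,), bwd)

    def weighted_gather(self, idx: np.ndarray, weights: np.ndarray):
        """Trilinear-style sampling ``out[m] = sum_k w[m,k] * self[idx[m,k]]``.

        ``self`` is (rows, C); ``idx`` and ``weights`` are (M, K).  Linear in
        ``self``, so the backward pass is a weighted scatter-add.
        """
        idx = np.asarray(idx)
        w = np.asarray(weights, dtype=self.data.dtype)
        out_data = np.einsum("mk,mkc->mc", w, self.data[idx])
        n_rows, n_ch = self.data.shape

        def bwd(g):
            contrib = w[:, :, None] * g[:, None, :]  # (M, K, C)
            flat_idx = idx.ravel()
            gf = contrib.reshape(-1, n_ch)
            acc = np.empty((n_rows, n_ch), dtype=self.data.dtype)
            for c in range(n_ch):
                acc[:, c] = np.bincount(flat_idx, weights=gf[:, c], minlength=n_rows)
            self._accumulate(acc)

        return Tensor._make(out_data, (self,), bwd)
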