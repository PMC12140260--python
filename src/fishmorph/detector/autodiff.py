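"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a convolutional encoder-decoder: 2D convolution
(im2col), ReLU, 2x2 max pooling, 2x nearest-neighbour upsampling, addition
and mean-squared-error reduction.  Tensors form a DAG; ``backward`` walks it
in reverse topological order accumulating gradients.  Activations default to
float32 (training) but every op is dtype-agnostic, so gradient checks can run
in float64.

Array layout is NCHW throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "relu", "add", "maxpool2", "upsample2", "mse"]


class Tensor:
    """A node in the autodiff graph wrapping one ndarray."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data: np.ndarray, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents = tuple(parents)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs are deep for nested hourglasses
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_graph(self) -> None:
        self.grad = None


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, Ho, Wo, C, kh, kw) view-based patch extraction."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
    return win.transpose(0, 2, 3, 1, 4, 5)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2D convolution, weights (F, C, kh, kw), bias (F,)."""
    n, c, h, width = x.data.shape
    f, c2, kh, kw = w.data.shape
    assert c == c2, f"channel mismatch {c} vs {c2}"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (width + 2 * pad - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride).reshape(n * ho * wo, c * kh * kw)
    w_flat = w.data.reshape(f, -1)
    out_data = (cols @ w_flat.T + b.data).reshape(n, ho, wo, f).transpose(0, 3, 1, 2)
    out = Tensor(out_data, parents=(x, w, b))

    def _bw(g: np.ndarray) -> None:
        g_flat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, f)
        if w.requires_grad:
            w._accumulate((g_flat.T @ cols).reshape(w.data.shape))
        if b.requires_grad:
            b._accumulate(g_flat.sum(axis=0))
        if x.requires_grad:
            dcols = (g_flat @ w_flat).reshape(n, ho, wo, c, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            x._accumulate(dxp[:, :, pad : pad + h, pad : pad + width] if pad else dxp)

    out._backward = _bw
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))

    def _bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = _bw
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def _bw(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    out._backward = _bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; ties route the gradient to the first max."""
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "maxpool2 needs even spatial dims"
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], parents=(x,))

    def _bw(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(x.data.shape)
        x._accumulate(dx)

    out._backward = _bw
    return out


def upsample2(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling; backward sums each 2x2 block."""
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), parents=(x,))

    def _bw(g: np.ndarray) -> None:
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            x._accumulate(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    out._backward = _bw
    return out


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target array (scalar output)."""
    diff = pred.data - target
    out = Tensor(np.asarray(np.mean(diff * diff)), parents=(pred,))

    def _bw(g: np.ndarray) -> None:
        if pred.requires_grad:
            pred._accumulate((2.0 / diff.size) * diff * g)

    out._backward = _bw
    return out
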