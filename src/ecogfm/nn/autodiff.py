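"""Minimal reverse-mode automatic differentiation on numpy arrays.

Exactly the operations the channel-classification networks need: dense
(affine) maps, 1-D convolution over the window axis, an LSTM returning its
final hidden state, ReLU, concatenation, global average pooling over time,
tiling a vector across time steps, and inverted dropout. Gradients flow only
into tensors created with ``requires_grad=True`` (the model parameters);
network inputs are constants, so branching topologies can slice their numpy
inputs freely before wrapping.

Everything is float64 and deterministic: a fixed parameter state and input
always produce bit-identical outputs.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: Optional[np.ndarray] = None
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents = parents

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | float = 1.0) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs include per-step LSTM nodes
            node, processed = stack.pop()
            if id(node) in seen:
                continue
            if processed:
                seen.add(id(node))
                topo.append(node)
                continue
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.broadcast_to(np.asarray(grad, dtype=np.float64), self.data.shape))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data, parents=parents)
    if out.requires_grad:
        out._backward = backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


def mul_const(a: Tensor, c: np.ndarray) -> Tensor:
    """Elementwise product with a constant array (dropout masks)."""

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * c)

    return _make(a.data * c, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine map on the trailing axis: (..., D) @ (D, H) + (H,)."""

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.tensordot(x.data, g, axes=(range(x.data.ndim - 1),) * 2))
        if b.requires_grad:
            b._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))
        if x.requires_grad:
            x._accumulate(g @ w.data.T)

    return _make(x.data @ w.data + b.data, (x, w, b), backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 1-D convolution: x (B, T, Cin), w (K, Cin, Cout), b (Cout,)."""
    B, T, Cin = x.data.shape
    K, _, Cout = w.data.shape
    left = (K - 1) // 2
    right = K - 1 - left
    xp = np.pad(x.data, ((0, 0), (left, right), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)  # (B,T,Cin,K)
    out = np.einsum("btck,kco->bto", win, w.data, optimize=True) + b.data

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.einsum("btck,bto->kco", win, g, optimize=True))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):  # K is small; scatter per tap
                gxp[:, k : k + T, :] += g @ w.data[k].T
            x._accumulate(gxp[:, left : left + T, :])

    return _make(out, (x, w, b), backward)


def gap(x: Tensor) -> Tensor:
    """Global average pooling over the time axis: (B, T, C) -> (B, C)."""
    T = x.data.shape[1]

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.repeat(g[:, None, :], T, axis=1) / T)

    return _make(x.data.mean(axis=1), (x,), backward)


def tile_time(v: Tensor, T: int) -> Tensor:
    """Broadcast a (B, F) vector along a new time axis -> (B, T, F)."""

    def backward(g):
        if v.requires_grad:
            v._accumulate(g.sum(axis=1))

    return _make(np.repeat(v.data[:, None, :], T, axis=1), (v,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def lstm_last(x: Tensor, wx: Tensor, wh: Tensor, b: Tensor) -> Tensor:
    """Single-layer LSTM over (B, T, D); returns the final hidden state (B, H).

    Gate layout along the 4H axis is [input, forget, candidate, output]. The
    full backward-through-time pass is implemented here as one graph node.
    """
    B, T, D = x.data.shape
    H = wh.data.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = []
    for t in range(T):
        z = x.data[:, t, :] @ wx.data + h @ wh.data + b.data
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g_ = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g_
        tc = np.tanh(c_new)
        cache.append((h, c, i, f, g_, o, tc))
        h = o * tc
        c = c_new

    def backward(grad_h):
        dwx = np.zeros_like(wx.data)
        dwh = np.zeros_like(wh.data)
        db = np.zeros_like(b.data)
        dx = np.zeros_like(x.data) if x.requires_grad else None
        dh = grad_h.copy()
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g_, o, tc = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g_
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g_ * g_),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dwx += x.data[:, t, :].T @ dz
            dwh += h_prev.T @ dz
            db += dz.sum(axis=0)
            if dx is not None:
                dx[:, t, :] = dz @ wx.data.T
            dh = dz @ wh.data.T
            dc = dc * f
        if wx.requires_grad:
            wx._accumulate(dwx)
        if wh.requires_grad:
            wh._accumulate(dwh)
        if b.requires_grad:
            b._accumulate(db)
        if dx is not None:
            x._accumulate(dx)

    return _make(h, (x, wx, wh, b), backward)
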