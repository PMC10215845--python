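"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the segmentation network needs: 1D
cross-correlation ("convolution" in NN parlance) with same padding,
elementwise integer powers, tanh / sigmoid / relu, instance normalization,
max-pooling and linear upsampling by small integer factors, channel
concatenation, and a numerically stable binary cross-entropy on logits.

Activations are laid out as ``(batch, channels, length)``. Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`, which walks the
recorded graph in reverse topological order. The engine is intentionally
eager and tape-free in the torch sense: each op closes over exactly the
arrays its backward rule needs, so a training step builds and frees one
graph.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Convenience arithmetic (used sparingly; the named ops below do the work).
    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)

    def __mul__(self, other: "Tensor") -> "Tensor":
        return mul(self, other)


def as_tensor(x, dtype=None) -> Tensor:
    arr = np.asarray(x, dtype=dtype)
    return Tensor(arr)


def parameter(x, dtype=None) -> Tensor:
    arr = np.array(x, dtype=dtype, copy=True)
    return Tensor(arr, requires_grad=True)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(
        data,
        requires_grad=req,
        _parents=tuple(p for p in parents if p.requires_grad),
        _backward=backward if req else None,
    )


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bw)


def pow_int(x: Tensor, k: int) -> Tensor:
    """Elementwise integer power x**k, k >= 1."""
    if k == 1:
        return x
    xd = x.data
    out_data = xd * xd
    for _ in range(k - 2):
        out_data = out_data * xd

    def bw(g):
        x._accumulate(g * k * xd ** (k - 1))

    return _make(out_data, (x,), bw)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)

    def bw(g):
        x._accumulate(g * (1.0 - y * y))

    return _make(y, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    y = _sigmoid_np(x.data)

    def bw(g):
        x._accumulate(g * y * (1.0 - y))

    return _make(y, (x,), bw)


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0)

    def bw(g):
        x._accumulate(g * (x.data > 0))

    return _make(y, (x,), bw)


def _sigmoid_np(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _pack_channels_last(x: np.ndarray, p: int) -> tuple[np.ndarray, int]:
    """Zero-pad each batch item by ``p`` per side and flatten to rows.

    x: (N, C, L) -> V: (N * (L + 2p), C) channels-last. Every tap slice
    ``V[j : j + T]`` is then a contiguous view, so the correlation reduces
    to K accumulated BLAS GEMMs with no im2col gather; padding gaps keep
    batch items from bleeding into each other, and outputs falling on the
    gaps are discarded.
    """
    n, c, L = x.shape
    seg = L + 2 * p
    z = np.zeros((n, seg, c), dtype=x.dtype)
    z[:, p : p + L, :] = x.transpose(0, 2, 1)
    return z.reshape(n * seg, c), seg


def _valid_rows_view(y_rows: np.ndarray, n: int, L: int, seg: int) -> np.ndarray:
    """View (T, O) flat output rows as (N, L, O), one block per batch item."""
    s0, s1 = y_rows.strides
    return np.lib.stride_tricks.as_strided(
        y_rows, shape=(n, L, y_rows.shape[1]), strides=(seg * s0, s0, s1)
    )


def correlate1d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Plain-numpy 'same'-padded cross-correlation.

    x: (N, C, L); w: (O, C, K) with K odd. Returns (N, O, L).
    """
    n, c, L = x.shape
    o, c2, k = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c} vs kernel {c2}")
    p = (k - 1) // 2
    V, seg = _pack_channels_last(x, p)
    T = V.shape[0] - (k - 1)
    wt = np.ascontiguousarray(w.transpose(2, 1, 0))  # (K, C, O)
    y = V[0:T] @ wt[0]
    for j in range(1, k):
        y += V[j : j + T] @ wt[j]
    return np.ascontiguousarray(_valid_rows_view(y, n, L, seg).transpose(0, 2, 1))


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded 1D cross-correlation with optional per-channel bias."""
    n, c, L = x.data.shape
    o, _, k = w.data.shape
    p = (k - 1) // 2
    out_data = correlate1d_same(x.data, w.data)
    if b is not None:
        out_data += b.data[None, :, None]

    def bw(g):
        V, seg = _pack_channels_last(x.data, p)
        T = V.shape[0] - (k - 1)
        gz = np.zeros((T, o), dtype=g.dtype)
        _valid_rows_view(gz, n, L, seg)[...] = g.transpose(0, 2, 1)
        wt = w.data.transpose(2, 1, 0)  # (K, C, O)
        if w.requires_grad:
            gw = np.empty((k, c, o), dtype=w.data.dtype)
            for j in range(k):
                gw[j] = V[j : j + T].T @ gz
            w._accumulate(gw.transpose(2, 1, 0))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gxbuf = np.zeros((n * seg, c), dtype=g.dtype)
            for j in range(k):
                gxbuf[j : j + T] += gz @ wt[j].T
            gx = gxbuf.reshape(n, seg, c)[:, p : p + L, :].transpose(0, 2, 1)
            x._accumulate(np.ascontiguousarray(gx))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bw)


def selfonn_conv1d(x: Tensor, w: Tensor, b: Tensor | None, q: int) -> Tensor:
    """Fused generative-neuron layer: powers 1..q of x, correlated and summed.

    ``w`` holds the q kernel banks stacked power-major along its input-
    channel axis: shape (O, q*C, K). Equivalent to concatenating
    x, x^2, ..., x^q along channels and applying :func:`conv1d`, but packs
    the input once and forms the powers on the packed copy, which roughly
    halves the memory traffic of a training step.
    """
    n, c, L = x.data.shape
    o, qc, k = w.data.shape
    if qc != q * c:
        raise ValueError(f"weight expects {qc} input columns, got q*C={q * c}")
    p = (k - 1) // 2
    V, seg = _pack_channels_last(x.data, p)
    R = V.shape[0]
    T = R - (k - 1)
    if q == 1:
        P = V
    else:
        P = np.empty((R, qc), dtype=V.dtype)
        P[:, :c] = V
        for kk in range(2, q + 1):
            np.multiply(P[:, (kk - 2) * c : (kk - 1) * c], V, out=P[:, (kk - 1) * c : kk * c])
    wt = np.ascontiguousarray(w.data.transpose(2, 1, 0))  # (K, qC, O)
    y = P[0:T] @ wt[0]
    for j in range(1, k):
        y += P[j : j + T] @ wt[j]
    out_data = np.ascontiguousarray(_valid_rows_view(y, n, L, seg).transpose(0, 2, 1))
    if b is not None:
        out_data += b.data[None, :, None]

    def bw(g):
        gz = np.zeros((T, o), dtype=g.dtype)
        _valid_rows_view(gz, n, L, seg)[...] = g.transpose(0, 2, 1)
        if w.requires_grad:
            gw = np.empty((k, qc, o), dtype=w.data.dtype)
            for j in range(k):
                gw[j] = P[j : j + T].T @ gz
            w._accumulate(gw.transpose(2, 1, 0))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gp = np.zeros((R, qc), dtype=g.dtype)
            for j in range(k):
                gp[j : j + T] += gz @ wt[j].T
            # d(x^k)/dx = k * x^(k-1); column block k-1 of P holds x^(k-1)
            gv = gp[:, :c].copy()
            for kk in range(2, q + 1):
                gv += kk * gp[:, (kk - 1) * c : kk * c] * P[:, (kk - 2) * c : (kk - 1) * c]
            gx = gv.reshape(n, seg, c)[:, p : p + L, :].transpose(0, 2, 1)
            x._accumulate(np.ascontiguousarray(gx))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bw)


def maxpool2(x: Tensor) -> Tensor:
    """Max pooling with window 2, stride 2 over the last axis."""
    n, c, L = x.data.shape
    if L % 2:
        raise ValueError("maxpool2 requires even length")
    x2 = x.data.reshape(n, c, L // 2, 2)
    idx = x2.argmax(axis=-1)
    y = np.take_along_axis(x2, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gx = np.zeros_like(x2)
        np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
        x._accumulate(gx.reshape(n, c, L))

    return _make(y, (x,), bw)


_UPSAMPLE_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _upsample_indices(L: int, scale: int):
    key = (L, scale)
    if key not in _UPSAMPLE_CACHE:
        src = (np.arange(L * scale) + 0.5) / scale - 0.5
        src = np.clip(src, 0.0, L - 1.0)
        i0 = np.floor(src).astype(np.intp)
        i1 = np.minimum(i0 + 1, L - 1)
        f = src - i0
        _UPSAMPLE_CACHE[key] = (i0, i1, f)
    return _UPSAMPLE_CACHE[key]


def upsample_linear(x: Tensor, scale: int) -> Tensor:
    """Linear interpolation upsampling by an integer factor (edge-clamped)."""
    n, c, L = x.data.shape
    i0, i1, f = _upsample_indices(L, scale)
    fw = f.astype(x.data.dtype)
    y = x.data[..., i0] * (1.0 - fw) + x.data[..., i1] * fw

    def bw(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (Ellipsis, i0), g * (1.0 - fw))
        np.add.at(gx, (Ellipsis, i1), g * fw)
        x._accumulate(gx)

    return _make(y, (x,), bw)


def concat_channels(tensors: Sequence[Tensor]) -> Tensor:
    sizes = [t.data.shape[1] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=1)
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accumulate(g[:, lo:hi, :])

    return _make(out_data, tuple(tensors), bw)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the length axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    std = np.sqrt(var + eps)
    xhat = (x.data - mu) / std
    y = gamma.data[None, :, None] * xhat + beta.data[None, :, None]

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gh = g * gamma.data[None, :, None]
            m1 = gh.mean(axis=-1, keepdims=True)
            m2 = (gh * xhat).mean(axis=-1, keepdims=True)
            x._accumulate((gh - m1 - xhat * m2) / std)

    return _make(y, (x, gamma, beta), bw)


def bce_with_logits(
    logits: Tensor, targets: np.ndarray, pos_weight: float = 1.0
) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against binary targets.

    Stable formulation; ``pos_weight`` rescales the positive class.
    """
    z = logits.data
    y = np.asarray(targets, dtype=z.dtype)
    w = 1.0 + (pos_weight - 1.0) * y
    softplus_neg = np.maximum(-z, 0) + np.log1p(np.exp(-np.abs(z)))
    loss = (1.0 - y) * z + w * softplus_neg
    # (1-y)*z + w*log(1+e^{-z}) == -[pw*y*log s + (1-y)*log(1-s)] for w as above
    mean = loss.mean()

    def bw(g):
        s = _sigmoid_np(z)
        dz = (1.0 - y) - w * (1.0 - s)
        logits._accumulate(g * dz / z.size)

    return _make(np.asarray(mean, dtype=z.dtype), (logits,), bw)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
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
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
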