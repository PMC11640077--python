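"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps an ``ndarray``
and records its parents plus a backward closure; :meth:`Tensor.backward`
topologically sorts the graph and accumulates gradients.  Only the operations
the segmentation network needs are provided — 2-D convolution (NHWC, same
padding, im2col), stride-1 same-padded max pooling, nearest/bilinear
upsampling, batch normalization, elementwise add/multiply, ReLU/sigmoid,
depth concatenation, and fused mean cross-entropy losses.

Convolution recomputes its patch matrix during the backward pass instead of
caching it, trading a second im2col for a much smaller activation footprint;
large patch matrices are additionally processed in row blocks, so a full
forward pass at 256 x 512 with encoder depths up to 2048 stays within a few
hundred MB.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "add", "mul", "relu", "sigmoid", "concat",
    "conv2d", "maxpool_same", "upsample_nearest", "upsample_bilinear",
    "batchnorm2d", "bce_with_logits_mean", "softmax_ce_mean", "softmax",
]

_DTYPE = np.float32

# cap on the im2col block, in floats (~64 MB at float32)
_BLOCK_FLOATS = 16_000_000


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(g)
        if b.requires_grad:
            b._accum(g)

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(g * b.data)
        if b.requires_grad:
            b._accum(g * a.data)

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def sigmoid_array(x: np.ndarray) -> np.ndarray:
    """Logistic function clamped to the open interval (0, 1).

    At float32, |x| > ~17 would round the output to exactly 0 or 1; the
    gate/probability contracts require the open interval, so the result is
    clipped to the nearest representable interior values (the gradient there
    is already at rounding level)."""
    with np.errstate(over="ignore"):  # exp overflow saturates, then clips
        s = 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=_DTYPE)))
    hi = np.nextafter(_DTYPE(1), _DTYPE(0))
    return np.clip(s, np.finfo(_DTYPE).tiny, hi)


def sigmoid(x: Tensor) -> Tensor:
    s = sigmoid_array(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=backward)


def concat(tensors, axis: int = 3) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _same_pad(n: int, k: int, s: int) -> tuple[int, int]:
    out = -(-n // s)
    total = max((out - 1) * s + k - n, 0)
    return total // 2, total - total // 2


def _patches(xp: np.ndarray, kh: int, kw: int, s: int,
             r0: int, r1: int) -> np.ndarray:
    """im2col rows for output rows [r0, r1): (N, r1-r0, Wo, kh*kw*C)."""
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
    win = win[:, r0 * s:(r1 - 1) * s + 1:s, ::s]
    # (N, rows, Wo, C, kh, kw) -> (N, rows, Wo, kh, kw, C)
    win = win.transpose(0, 1, 2, 4, 5, 3)
    n, rows, wo = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n, rows, wo, -1)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """Same-padded 2-D convolution. x: (N,H,W,C); w: (kh,kw,C,Co); b: (Co,)."""
    N, H, W, C = x.data.shape
    kh, kw, cin, co = w.data.shape
    if cin != C:
        raise ValueError(f"conv2d: input depth {C} != weight depth {cin}")
    s = stride
    ph0, ph1 = _same_pad(H, kh, s)
    pw0, pw1 = _same_pad(W, kw, s)
    xp = np.pad(x.data, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0)))
    Ho, Wo = -(-H // s), -(-W // s)
    wm = w.data.reshape(-1, co)

    block = max(1, _BLOCK_FLOATS // max(N * Wo * kh * kw * C, 1))
    out_data = np.empty((N, Ho, Wo, co), dtype=_DTYPE)
    for r0 in range(0, Ho, block):
        r1 = min(r0 + block, Ho)
        cols = _patches(xp, kh, kw, s, r0, r1)
        out_data[:, r0:r1] = cols @ wm + b.data

    def backward(g):
        gm = g.reshape(-1, co)
        if b.requires_grad:
            b._accum(gm.sum(axis=0))
        need_x = x.requires_grad
        need_w = w.requires_grad
        if not (need_x or need_w):
            return
        dw = np.zeros_like(w.data) if need_w else None
        dxp = np.zeros_like(xp) if need_x else None
        for r0 in range(0, Ho, block):
            r1 = min(r0 + block, Ho)
            gblk = g[:, r0:r1].reshape(-1, co)
            if need_w:
                cols = _patches(xp, kh, kw, s, r0, r1).reshape(-1, kh * kw * C)
                dw += (cols.T @ gblk).reshape(kh, kw, C, co)
            if need_x:
                dcols = (gblk @ wm.T).reshape(N, r1 - r0, Wo, kh, kw, C)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, r0 * s + i:(r1 - 1) * s + i + 1:s,
                            j:j + Wo * s:s] += dcols[:, :, :, i, j]
        if need_w:
            w._accum(dw)
        if need_x:
            x._accum(dxp[:, ph0:ph0 + H, pw0:pw0 + W])

    return Tensor(out_data, parents=(x, w, b), backward=backward)


# ---------------------------------------------------------------------------
# pooling and resampling
# ---------------------------------------------------------------------------

def maxpool_same(x: Tensor, k: int = 3) -> Tensor:
    """k x k max pooling, stride 1, same padding (output shape = input)."""
    p0, p1 = _same_pad(x.data.shape[1], k, 1)
    q0, q1 = _same_pad(x.data.shape[2], k, 1)
    xp = np.pad(x.data, ((0, 0), (p0, p1), (q0, q1), (0, 0)),
                constant_values=-np.inf)
    win = sliding_window_view(xp, (k, k), axis=(1, 2))
    out_data = win.max(axis=(4, 5))

    def backward(g):
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        H, W = x.data.shape[1:3]
        for i in range(k):
            for j in range(k):
                sl = xp[:, i:i + H, j:j + W]
                dxp[:, i:i + H, j:j + W] += g * (sl == out_data)
        x._accum(dxp[:, p0:p0 + H, q0:q0 + W])

    return Tensor(out_data, parents=(x,), backward=backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbor (replicating) upsampling by an integer factor."""
    f = int(factor)
    out_data = x.data.repeat(f, axis=1).repeat(f, axis=2)

    def backward(g):
        if not x.requires_grad:
            return
        N, H, W, C = x.data.shape
        x._accum(g.reshape(N, H, f, W, f, C).sum(axis=(2, 4)))

    return Tensor(out_data, parents=(x,), backward=backward)


def _linear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel centers)."""
    A = np.zeros((n_out, n_in), dtype=_DTYPE)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        A[i, lo_c] += 1.0 - frac
        A[i, hi_c] += frac
    return A


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    f = int(factor)
    N, H, W, C = x.data.shape
    Ah = _linear_matrix(H * f, H)
    Aw = _linear_matrix(W * f, W)
    out_data = np.einsum("oh,nhwc->nowc", Ah, x.data)
    out_data = np.einsum("pw,nowc->nopc", Aw, out_data)

    def backward(g):
        if not x.requires_grad:
            return
        gh = np.einsum("pw,nopc->nowc", Aw, g)
        x._accum(np.einsum("oh,nowc->nhwc", Ah, gh))

    return Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, state: dict,
                training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over the (N, H, W) axes.

    ``state`` holds ``running_mean``/``running_var`` and is updated in place
    during training steps.
    """
    if training:
        m = x.data.mean(axis=(0, 1, 2))
        v = x.data.var(axis=(0, 1, 2))
        state["running_mean"] = (1 - momentum) * state["running_mean"] + momentum * m
        state["running_var"] = (1 - momentum) * state["running_var"] + momentum * v
    else:
        m = state["running_mean"]
        v = state["running_var"]
    inv_std = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m) * inv_std
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 1, 2)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 1, 2)))
        if not x.requires_grad:
            return
        if training:
            M = g.shape[0] * g.shape[1] * g.shape[2]
            dxhat = g * gamma.data
            term1 = dxhat
            term2 = dxhat.mean(axis=(0, 1, 2))
            term3 = xhat * (dxhat * xhat).mean(axis=(0, 1, 2))
            x._accum((term1 - term2 - term3) * inv_std)
        else:
            x._accum(g * gamma.data * inv_std)

    return Tensor(out_data, parents=(x, gamma, beta), backward=backward)


# ---------------------------------------------------------------------------
# losses and activations
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def bce_with_logits_mean(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy with a numerically stable logits form."""
    t = np.asarray(targets, dtype=_DTYPE)
    if t.shape != logits.data.shape:
        raise ValueError(f"targets shape {t.shape} != logits shape {logits.data.shape}")
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out_data = loss.mean(dtype=np.float64)

    def backward(g):
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-z))
            logits._accum(g * (p - t) / z.size)

    return Tensor(out_data, parents=(logits,), backward=backward)


def softmax_ce_mean(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-pixel categorical cross-entropy.

    ``labels`` is an integer map of shape ``logits.shape[:-1]`` indexing the
    channel axis.
    """
    lab = np.asarray(labels)
    if lab.shape != logits.data.shape[:-1]:
        raise ValueError("labels shape must match logits spatial shape")
    p = softmax(logits.data, axis=-1)
    n_pix = lab.size
    idx = tuple(np.indices(lab.shape)) + (lab,)
    out_data = -np.log(np.maximum(p[idx], 1e-12)).mean(dtype=np.float64)

    def backward(g):
        if not logits.requires_grad:
            return
        grad = p.copy()
        grad[idx] -= 1.0
        logits._accum(g * grad / n_pix)

    return Tensor(out_data, parents=(logits,), backward=backward)
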