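"""Minimal reverse-mode autodiff on numpy arrays.

Only the operations the localization network needs are implemented:
2-D convolution (im2col + BLAS matmul), batch normalization, ReLU,
sigmoid, max pooling, nearest-neighbour upsampling, channel
concatenation, elementwise add, and the two training losses
(penalty-reduced focal loss and masked L1). Everything is float32.

Gradients for every op are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "batchnorm2d",
    "relu",
    "sigmoid",
    "maxpool2d",
    "upsample_nearest2",
    "concat",
    "add",
    "focal_loss",
    "masked_l1",
]

DTYPE = np.float32


class Tensor:
    """An ndarray plus gradient and the tape edges that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- scalar algebra (used to combine loss terms) ------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        out = _node(self.data + other.data, (self, other))

        def bwd(g):
            _accum(self, np.array(g))
            _accum(other, np.array(g))

        out._backward = bwd
        return out

    def __mul__(self, k: float) -> "Tensor":
        k = float(k)
        out = _node(self.data * k, (self,))

        def bwd(g):
            _accum(self, g * k)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    # -- reverse pass -------------------------------------------------
    def backward(self) -> None:
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


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._parents = parents
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    # callers pass freshly-allocated arrays, so storing the reference is safe
    if t.grad is None:
        t.grad = np.asarray(g, dtype=DTYPE)
    else:
        t.grad += g


# ---------------------------------------------------------------------------
# convolution


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int, oh: int, ow: int):
    """Patch matrix in (C*KH*KW, N*OH*OW) layout so GEMMs see one big matrix."""
    n, c = xp.shape[:2]
    cols = np.empty((c, kh, kw, n, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            np.copyto(
                cols[:, i, j],
                xp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw].transpose(1, 0, 2, 3),
            )
    return cols.reshape(c * kh * kw, n * oh * ow)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """NCHW convolution; weight (OC, C, KH, KW), optional bias (OC,)."""
    n, c, h, wd = x.data.shape
    oc, cin, kh, kw = w.data.shape
    if cin != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {cin}")
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (wd + 2 * padding - kw) // stride + 1
    if oh <= 0 or ow <= 0:
        raise ValueError("conv2d: non-positive output size")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    cols = _im2col(xp, kh, kw, stride, stride, oh, ow)  # (K, N*P)
    wm = w.data.reshape(oc, -1)
    out_data = np.ascontiguousarray(
        np.matmul(wm, cols).reshape(oc, n, oh, ow).transpose(1, 0, 2, 3)
    )
    if b is not None:
        out_data += b.data.reshape(1, oc, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = _node(out_data, parents)

    def bwd(g):
        gm = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(oc, n * oh * ow)
        _accum(w, np.matmul(gm, cols.T).reshape(w.data.shape))
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))
        dcols = np.matmul(wm.T, gm).reshape(c, kh, kw, n, oh, ow)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[
                    :, i, j
                ].transpose(1, 0, 2, 3)
        _accum(x, dxp[:, :, padding : padding + h, padding : padding + wd] if padding else dxp)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# normalization / activations


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    c = x.data.shape[1]
    gr = gamma.data.reshape(1, c, 1, 1)
    br = beta.data.reshape(1, c, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
        var = x.data.var(axis=(0, 2, 3), keepdims=True)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu.ravel()
        running_var *= 1.0 - momentum
        running_var += momentum * var.ravel()
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu) * inv
        out = _node(gr * xhat + br, (x, gamma, beta))
        m = x.data.size / c

        def bwd(g):
            _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
            _accum(beta, g.sum(axis=(0, 2, 3)))
            dxhat = g * gr
            # standard batch-norm backward, vectorized per channel
            s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            _accum(x, inv * (dxhat - s1 / m - xhat * s2 / m))

        out._backward = bwd
        return out
    inv = 1.0 / np.sqrt(running_var.reshape(1, c, 1, 1) + eps)
    xhat = (x.data - running_mean.reshape(1, c, 1, 1)) * inv
    out = _node(gr * xhat + br, (x, gamma, beta))

    def bwd_eval(g):
        _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        _accum(beta, g.sum(axis=(0, 2, 3)))
        _accum(x, g * gr * inv)

    out._backward = bwd_eval
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = _node(x.data * mask, (x,))

    def bwd(g):
        _accum(x, g * mask)

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _node(s, (x,))

    def bwd(g):
        _accum(x, g * s * (1.0 - s))

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# pooling / resampling / shape ops


def maxpool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    """Max pooling, computed as two separable 1-D max passes.

    Gradient is routed to one argmax per window (the first along each
    axis on ties), matching the usual subgradient convention.
    """
    stride = stride or kernel
    n, c, h, w = x.data.shape
    oh = (h + 2 * padding - kernel) // stride + 1
    ow = (w + 2 * padding - kernel) // stride + 1
    if padding:
        xp = np.full((n, c, h + 2 * padding, w + 2 * padding), -np.inf, dtype=x.data.dtype)
        xp[:, :, padding : padding + h, padding : padding + w] = x.data
    else:
        xp = x.data
    hp, wp = xp.shape[2:]
    # pass 1: max over the W axis
    win_w = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=3)[:, :, :, ::stride]
    arg_w = win_w.argmax(axis=-1)  # (n, c, hp, ow)
    max_w = np.take_along_axis(win_w, arg_w[..., None], axis=-1)[..., 0]
    # pass 2: max over the H axis
    win_h = np.lib.stride_tricks.sliding_window_view(max_w, kernel, axis=2)[:, :, ::stride]
    win_h = np.moveaxis(win_h, -1, 3)  # (n, c, oh, kernel, ow)
    arg_h = win_h.argmax(axis=3)  # (n, c, oh, ow)
    out = _node(np.take_along_axis(win_h, arg_h[:, :, :, None], axis=3)[:, :, :, 0], (x,))

    def bwd(g):
        ni, ci, ohi, owi = np.indices(g.shape, sparse=True)
        d_maxw = np.zeros((n, c, hp, ow), dtype=x.data.dtype)
        np.add.at(d_maxw, (ni, ci, ohi * stride + arg_h, owi), g)
        dxp = np.zeros_like(xp)
        ni, ci, hi, owi = np.indices(d_maxw.shape, sparse=True)
        np.add.at(dxp, (ni, ci, hi, owi * stride + arg_w), d_maxw)
        _accum(x, dxp[:, :, padding : padding + h, padding : padding + w] if padding else dxp)

    out._backward = bwd
    return out


def upsample_nearest2(x: Tensor) -> Tensor:
    out = _node(x.data.repeat(2, axis=2).repeat(2, axis=3), (x,))
    n, c, h, w = x.data.shape

    def bwd(g):
        _accum(x, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    out = _node(np.concatenate([t.data for t in tensors], axis=1), tuple(tensors))
    splits = np.cumsum([t.data.shape[1] for t in tensors])[:-1]

    def bwd(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=1)):
            _accum(t, np.ascontiguousarray(gpart))

    out._backward = bwd
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError("add: shape mismatch")
    out = _node(a.data + b.data, (a, b))

    def bwd(g):
        _accum(a, np.array(g))
        _accum(b, np.array(g))

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# losses


def focal_loss(pred: Tensor, target: np.ndarray, alpha: float = 2.0, beta: float = 4.0) -> Tensor:
    """Penalty-reduced pixelwise focal loss for Gaussian-splat heatmaps.

    ``pred`` holds probabilities in (0, 1); ``target`` the encoded heatmap
    whose value is exactly 1 at annotated center cells. Normalized by the
    number of those peak cells (or 1 when the image is empty).
    """
    eps = 1e-6
    p = np.clip(pred.data, eps, 1.0 - eps)
    pos = target >= 1.0
    npos = max(int(pos.sum()), 1)
    neg_w = np.power(1.0 - target, beta, where=~pos, out=np.zeros_like(p))
    pos_term = np.power(1.0 - p, alpha) * np.log(p)
    neg_term = neg_w * np.power(p, alpha) * np.log(1.0 - p)
    loss = -(pos_term[pos].sum() + neg_term[~pos].sum()) / npos
    out = _node(np.asarray(loss, dtype=DTYPE), (pred,))

    def bwd(g):
        dpos = -alpha * np.power(1.0 - p, alpha - 1) * np.log(p) + np.power(1.0 - p, alpha) / p
        dneg = neg_w * (alpha * np.power(p, alpha - 1) * np.log(1.0 - p) - np.power(p, alpha) / (1.0 - p))
        dp = np.where(pos, dpos, dneg) * (-float(g) / npos)
        dp[(pred.data <= eps) | (pred.data >= 1.0 - eps)] = 0.0
        _accum(pred, dp)

    out._backward = bwd
    return out


def masked_l1(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean absolute difference over cells where ``mask`` is true (0 if none).

    ``mask`` broadcasts against the channel axis, matching offset/depth maps
    that are only supervised at ground-truth center cells.
    """
    m = np.broadcast_to(mask, pred.data.shape)
    n = max(int(m.sum()), 1)
    diff = np.where(m, pred.data - target, 0.0)
    out = _node(np.asarray(np.abs(diff).sum() / n, dtype=DTYPE), (pred,))

    def bwd(g):
        _accum(pred, np.sign(diff) * (float(g) / n))

    out._backward = bwd
    return out
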