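"""Minimal reverse-mode autodiff on NumPy arrays.

Supports exactly the operations the cascade network needs: 2-D (dilated)
convolution with "same" zero padding, 2x2 max pooling, bilinear resampling
to an arbitrary target size, elementwise ReLU/sigmoid/add, channel
concatenation, and the class-balanced cross-entropy / L1 losses.  Data
layout is NCHW throughout.  Gradients accumulate into ``Tensor.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "add_n",
    "balanced_bce_op",
    "concat",
    "conv2d",
    "l1_loss_op",
    "maxpool2x2",
    "relu",
    "scale",
    "sigmoid",
    "upsample_bilinear",
]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return float(self.data)

    def detach(self):
        return np.array(self.data, copy=True)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Reverse-mode sweep from this node; seeds with ones if no grad given."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        _accumulate(self, np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _accumulate(t, g):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=t.data.dtype, copy=True)
    else:
        t.grad += g


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------- arithmetic


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        _accumulate(a, g)
        _accumulate(b, g)

    return Tensor(out_data, parents=(a, b), backward=bwd)


def add_n(tensors):
    tensors = [_as_tensor(t) for t in tensors]
    out_data = tensors[0].data.copy()
    for t in tensors[1:]:
        out_data += t.data

    def bwd(g):
        for t in tensors:
            _accumulate(t, g)

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


def scale(a, s):
    a = _as_tensor(a)
    s = float(s)

    def bwd(g):
        _accumulate(a, g * s)

    return Tensor(a.data * s, parents=(a,), backward=bwd)


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0

    def bwd(g):
        _accumulate(a, g * mask)

    return Tensor(a.data * mask, parents=(a,), backward=bwd)


def sigmoid(a):
    a = _as_tensor(a)
    # numerically stable logistic
    out_data = np.empty_like(a.data)
    pos = a.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ex = np.exp(a.data[~pos])
    out_data[~pos] = ex / (1.0 + ex)

    def bwd(g):
        _accumulate(a, g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(a,), backward=bwd)


def concat(tensors, axis=1):
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accumulate(t, piece)

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


# --------------------------------------------------------------- convolution


def conv2d(x, w, b=None, dilation=1):
    """Same-padding 2-D convolution (cross-correlation) with dilation.

    x: [N,C,H,W]; w: [O,C,kh,kw] with odd kh,kw; b: [O] or None.
    output(i,j) = sum_{c,p,q} x[c, i + r*p - pad, j + r*q - pad] * w[o,c,p,q]
    with pad = r*(k-1)/2 so the spatial size is preserved.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    if b is not None:
        b = _as_tensor(b)
    r = int(dilation)
    if r < 1:
        raise ValueError(f"dilation rate must be >= 1, got {r}")
    N, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input has {C}, kernel expects {Cw}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel dims must be odd for same padding")
    ph, pw = r * (kh - 1) // 2, r * (kw - 1) // 2
    # im2col buffer: one batched GEMM instead of per-tap contractions
    if kh == 1 and kw == 1:
        cols = x.data.reshape(N, C, H * W)
    else:
        xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        cols = np.empty((N, kh * kw, C, H * W), dtype=x.data.dtype)
        for p in range(kh):
            for q in range(kw):
                cols[:, p * kw + q] = xp[
                    :, :, p * r : p * r + H, q * r : q * r + W
                ].reshape(N, C, H * W)
        cols = cols.reshape(N, kh * kw * C, H * W)
    # kernel laid out to match the (tap, channel) ordering of the buffer
    wmat = w.data.transpose(2, 3, 1, 0).reshape(kh * kw * C, O)
    out_data = np.matmul(wmat.T[None], cols).reshape(N, O, H, W)
    if b is not None:
        out_data += b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gf = g.reshape(N, O, H * W)
        if w.requires_grad:
            dwmat = np.matmul(cols, gf.transpose(0, 2, 1)).sum(axis=0)
            dw = dwmat.reshape(kh, kw, C, O).transpose(3, 2, 0, 1)
            _accumulate(w, dw)
        if x.requires_grad:
            dcols = np.matmul(wmat[None], gf)  # [N, kh*kw*C, H*W]
            if kh == 1 and kw == 1:
                _accumulate(x, dcols.reshape(N, C, H, W))
            else:
                dxp = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=g.dtype)
                dtaps = dcols.reshape(N, kh * kw, C, H, W)
                for p in range(kh):
                    for q in range(kw):
                        dxp[:, :, p * r : p * r + H, q * r : q * r + W] += (
                            dtaps[:, p * kw + q]
                        )
                _accumulate(x, dxp[:, :, ph : ph + H, pw : pw + W])
        if b is not None and b.requires_grad:
            _accumulate(b, g.sum(axis=(0, 2, 3)))

    return Tensor(out_data, parents=parents, backward=bwd)


# ------------------------------------------------------------------- pooling


def maxpool2x2(x):
    """2x2 max pooling with stride 2; trailing odd row/col dropped."""
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    H2, W2 = H // 2, W // 2
    xc = x.data[:, :, : 2 * H2, : 2 * W2]
    windows = xc.reshape(N, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5)
    windows = windows.reshape(N, C, H2, W2, 4)
    amax = windows.argmax(axis=-1)
    out_data = np.take_along_axis(windows, amax[..., None], axis=-1)[..., 0]

    def bwd(g):
        if not x.requires_grad:
            return
        dwin = np.zeros_like(windows)
        np.put_along_axis(dwin, amax[..., None], g[..., None], axis=-1)
        dxc = dwin.reshape(N, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dxc = dxc.reshape(N, C, 2 * H2, 2 * W2)
        if 2 * H2 == H and 2 * W2 == W:
            _accumulate(x, dxc)
        else:
            dx = np.zeros_like(x.data)
            dx[:, :, : 2 * H2, : 2 * W2] = dxc
            _accumulate(x, dx)

    return Tensor(out_data, parents=(x,), backward=bwd)


# ---------------------------------------------------------------- upsampling

_interp_cache: dict[tuple[int, int, str], np.ndarray] = {}


def _interp_matrix(n_in, n_out, dtype=np.float64):
    """Row-interpolation matrix for bilinear resize, half-pixel centres."""
    key = (n_in, n_out, np.dtype(dtype).str)
    m = _interp_cache.get(key)
    if m is not None:
        return m
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
    else:
        src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        src = np.clip(src, 0.0, n_in - 1.0)
        i0 = np.floor(src).astype(int)
        i0 = np.minimum(i0, n_in - 2)
        frac = src - i0
        m[np.arange(n_out), i0] += 1.0 - frac
        m[np.arange(n_out), i0 + 1] += frac
    _interp_cache[key] = m
    return m


def upsample_bilinear(x, size):
    """Bilinear resize of [N,C,H,W] to spatial ``size`` (rows, cols)."""
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    Ho, Wo = int(size[0]), int(size[1])
    if (Ho, Wo) == (H, W):
        def bwd_id(g):
            _accumulate(x, g)
        return Tensor(x.data.copy(), parents=(x,), backward=bwd_id)
    Mr = _interp_matrix(H, Ho, x.data.dtype)
    Mc = _interp_matrix(W, Wo, x.data.dtype)
    out_data = Mr @ x.data @ Mc.T

    def bwd(g):
        if x.requires_grad:
            _accumulate(x, Mr.T @ g @ Mc)

    return Tensor(out_data, parents=(x,), backward=bwd)


# -------------------------------------------------------------------- losses

EPS = 1e-7


def balanced_bce_breakdown(pred, target, eta, lam):
    """Forward pass of the class-balanced BCE; returns (loss, dL/dpred).

    Positive set: target > eta.  Negative set: target == 0.  Pixels with
    0 < target <= eta are excluded.  Positive weight beta = |Y-| / (|Y+|+|Y-|);
    negative weight (1-beta) = lam * |Y+| / (|Y+|+|Y-|).  Normalised by the
    total pixel count so the scale is resolution independent.
    """
    target = np.asarray(target, dtype=np.float64)
    p = np.clip(np.asarray(pred, dtype=np.float64), EPS, 1.0 - EPS)
    pos = target > eta
    neg = target == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    m = target.size
    grad = np.zeros_like(p)
    if n_pos + n_neg == 0:
        import warnings

        warnings.warn("balanced_bce: no positive or negative pixels; loss is 0")
        return 0.0, grad
    beta = n_neg / (n_pos + n_neg)
    one_minus_beta = lam * n_pos / (n_pos + n_neg)
    loss = (
        -beta * np.log(p[pos]).sum() - one_minus_beta * np.log1p(-p[neg]).sum()
    ) / m
    grad[pos] = -beta / p[pos] / m
    grad[neg] = one_minus_beta / (1.0 - p[neg]) / m
    # clipped pixels carry no gradient
    clipped = (np.asarray(pred) <= EPS) | (np.asarray(pred) >= 1.0 - EPS)
    grad[clipped] = 0.0
    return float(loss), grad


def balanced_bce_op(pred, target, eta=0.4, lam=1.1):
    """Class-balanced BCE as a graph node; ``target`` is a constant array."""
    pred = _as_tensor(pred)
    loss, dpred = balanced_bce_breakdown(pred.data, target, eta, lam)

    def bwd(g):
        _accumulate(pred, (g * dpred).astype(pred.data.dtype))

    return Tensor(np.float64(loss), parents=(pred,), backward=bwd)


def l1_loss_op(pred, target):
    """Mean absolute error as a graph node."""
    pred = _as_tensor(pred)
    target = np.asarray(target, dtype=np.float64)
    diff = pred.data.astype(np.float64) - target
    m = target.size

    def bwd(g):
        _accumulate(pred, (g * np.sign(diff) / m).astype(pred.data.dtype))

    return Tensor(np.float64(np.abs(diff).sum() / m), parents=(pred,), backward=bwd)
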