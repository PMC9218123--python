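"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the nested-U density-map network needs:
3x3 (optionally dilated) convolutions via patch gathering, 2x2 max/average
pooling, factor-2 bilinear upsampling, channel concatenation, sigmoid/ReLU,
spatial (channel-wise) dropout, global average pooling, dense layers and a
numerically stable pixel-sum binary cross entropy on logits.

Arrays are NHWC: with channels last, the im2col patch matrix and all
gradient reshapes are plain contiguous views, which is what makes a NumPy
training loop viable.  Tensors keep whatever float dtype they are given;
the network runs in float32, while gradient checks run the same code in
float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "sub", "mul", "pow_const", "sum_all", "relu", "sigmoid",
    "conv2d", "maxpool2", "avgpool2", "upsample2x", "concat", "global_avg_pool",
    "linear", "dropout_channels", "bce_with_logits_sum", "gradcheck",
]


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype})"


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(_needs(p) for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------- elementwise

def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))
    return _make(a.data + b.data, (a, b), bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, -_unbroadcast(g, b.data.shape))
    return _make(a.data - b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))
    return _make(a.data * b.data, (a, b), bw)


def pow_const(a: Tensor, p: float) -> Tensor:
    def bw(g):
        _accum(a, g * p * np.power(a.data, p - 1))
    return _make(np.power(a.data, p), (a,), bw)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    def bw(g):
        _accum(a, g.reshape(a.data.shape))
    return _make(a.data.reshape(shape), (a,), bw)


def sum_all(a: Tensor) -> Tensor:
    def bw(g):
        _accum(a, np.broadcast_to(g, a.data.shape).astype(a.data.dtype))
    return _make(a.data.sum(), (a,), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    def bw(g):
        _accum(a, g * mask)
    return _make(a.data * mask, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    out = np.empty_like(a.data)
    pos = a.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ez = np.exp(a.data[~pos])
    out[~pos] = ez / (1.0 + ez)
    def bw(g):
        _accum(a, g * out * (1.0 - out))
    return _make(out, (a,), bw)


# ---------------------------------------------------------------- convolution

def _gather_patches(xp: np.ndarray, H: int, W: int, k: int, d: int) -> np.ndarray:
    """Concatenate the k*k shifted views along channels: (N, H, W, k*k*C)."""
    views = [xp[:, i * d:i * d + H, j * d:j * d + W, :]
             for i in range(k) for j in range(k)]
    return np.concatenate(views, axis=3)


def conv2d(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """Same-padded kxk convolution, NHWC; w is (k, k, C_in, C_out)."""
    N, H, W, C = x.data.shape
    k, _, Ci, Co = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    pad = dilation * (k - 1) // 2
    if k == 1:
        P = x.data.reshape(N * H * W, C)
        xp = None
    else:
        xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        P = _gather_patches(xp, H, W, k, dilation).reshape(N * H * W, k * k * C)
    Wm = w.data.reshape(k * k * C, Co)
    y = (P @ Wm).reshape(N, H, W, Co) + b.data

    def bw(g):
        g2 = g.reshape(N * H * W, Co)
        if w.requires_grad or w._parents:
            _accum(w, (P.T @ g2).reshape(k, k, C, Co))
        if b.requires_grad or b._parents:
            _accum(b, g.sum(axis=(0, 1, 2)))
        if x.requires_grad or x._parents:
            dP = g2 @ Wm.T
            if k == 1:
                _accum(x, dP.reshape(N, H, W, C))
            else:
                dP = dP.reshape(N, H, W, k * k, C)
                dxp = np.zeros_like(xp)
                idx = 0
                for i in range(k):
                    for j in range(k):
                        dxp[:, i * dilation:i * dilation + H,
                            j * dilation:j * dilation + W, :] += dP[:, :, :, idx]
                        idx += 1
                _accum(x, dxp[:, pad:pad + H, pad:pad + W, :])

    return _make(y, (x, w, b), bw)


# -------------------------------------------------------------------- pooling

def maxpool2(x: Tensor) -> Tensor:
    N, H, W, C = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2 requires even spatial dims")
    r = x.data.reshape(N, H // 2, 2, W // 2, 2, C)
    m = r.max(axis=(2, 4))
    mask = r == m[:, :, None, :, None, :]
    cnt = mask.sum(axis=(2, 4))
    def bw(g):
        dr = mask * (g / cnt)[:, :, None, :, None, :]
        _accum(x, dr.reshape(N, H, W, C))
    return _make(m, (x,), bw)


def avgpool2(x: Tensor) -> Tensor:
    N, H, W, C = x.data.shape
    r = x.data.reshape(N, H // 2, 2, W // 2, 2, C)
    m = r.mean(axis=(2, 4))
    def bw(g):
        dr = np.broadcast_to((g / 4.0)[:, :, None, :, None, :],
                             (N, H // 2, 2, W // 2, 2, C))
        _accum(x, dr.reshape(N, H, W, C).astype(x.data.dtype))
    return _make(m, (x,), bw)


# ---------------------------------------------------------------- upsampling

def _up2_fwd(a: np.ndarray, axis: int) -> np.ndarray:
    """Bilinear x2 along one axis, half-pixel centers:
    out[2i] = .75 x[i] + .25 x[i-1], out[2i+1] = .75 x[i] + .25 x[i+1]."""
    a = np.moveaxis(a, axis, 0)
    n = a.shape[0]
    left = np.concatenate([a[:1], a[:-1]], axis=0)
    right = np.concatenate([a[1:], a[-1:]], axis=0)
    out = np.empty((2 * n,) + a.shape[1:], dtype=a.dtype)
    out[0::2] = 0.75 * a + 0.25 * left
    out[1::2] = 0.75 * a + 0.25 * right
    return np.moveaxis(out, 0, axis)


def _up2_bwd(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, 0)
    ge, go = g[0::2], g[1::2]
    dx = 0.75 * (ge + go)
    dx[:-1] += 0.25 * ge[1:]
    dx[0] += 0.25 * ge[0]
    dx[1:] += 0.25 * go[:-1]
    dx[-1] += 0.25 * go[-1]
    return np.moveaxis(dx, 0, axis)


def upsample2x(x: Tensor) -> Tensor:
    """Factor-2 bilinear upsampling of the spatial axes (1, 2) of NHWC."""
    y = _up2_fwd(_up2_fwd(x.data, 1), 2)
    def bw(g):
        _accum(x, _up2_bwd(_up2_bwd(g, 2), 1))
    return _make(y, (x,), bw)


# -------------------------------------------------------------------- tensors

def concat(ts: list[Tensor], axis: int = 3) -> Tensor:
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)
    def bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])
    return _make(data, tuple(ts), bw)


def global_avg_pool(x: Tensor) -> Tensor:
    N, H, W, C = x.data.shape
    y = x.data.mean(axis=(1, 2))
    def bw(g):
        _accum(x, np.broadcast_to(g[:, None, None, :] / (H * W),
                                  x.data.shape).astype(x.data.dtype))
    return _make(y, (x,), bw)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x: (N, F_in); w: (F_in, F_out); b: (F_out,)."""
    y = x.data @ w.data + b.data
    def bw(g):
        _accum(x, g @ w.data.T)
        _accum(w, x.data.T @ g)
        _accum(b, g.sum(axis=0))
    return _make(y, (x, w, b), bw)


def dropout_channels(x: Tensor, rate: float, rng: np.random.Generator,
                     training: bool) -> Tensor:
    """Spatial dropout: zeroes whole feature maps, rescales survivors."""
    if not training or rate <= 0.0:
        return x
    N, C = x.data.shape[0], x.data.shape[3]
    keep = (rng.random((N, 1, 1, C)) >= rate).astype(x.data.dtype) / (1.0 - rate)
    def bw(g):
        _accum(x, g * keep)
    return _make(x.data * keep, (x,), bw)


# ----------------------------------------------------------------------- loss

def bce_with_logits_sum(z: Tensor, target: np.ndarray) -> Tensor:
    """Pixel-sum binary cross entropy of sigmoid(z) against target in [0,1].

    Stable form: sum( max(z,0) - z*t + log(1 + exp(-|z|)) ).
    """
    t = np.asarray(target, dtype=z.data.dtype)
    val = (np.maximum(z.data, 0) - z.data * t + np.log1p(np.exp(-np.abs(z.data)))).sum()
    def bw(g):
        s = np.empty_like(z.data)
        pos = z.data >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-z.data[pos]))
        ez = np.exp(z.data[~pos])
        s[~pos] = ez / (1.0 + ez)
        _accum(z, g * (s - t))
    return _make(np.asarray(val, dtype=z.data.dtype), (z,), bw)


# ------------------------------------------------------------------ gradcheck

def gradcheck(fn, tensors: list[Tensor], eps: float = 1e-5,
              rtol: float = 1e-4, atol: float = 1e-6) -> bool:
    """Compare analytic gradients of scalar fn(*tensors) to central differences.

    Tensors should be float64 for meaningful tolerances.
    """
    out = fn(*tensors)
    for t in tensors:
        t.zero_grad()
    out = fn(*tensors)
    out.backward()
    ok = True
    for t in tensors:
        if not t.requires_grad:
            continue
        num = np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        nflat = num.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            fp = fn(*tensors).item()
            flat[i] = orig - eps
            fm = fn(*tensors).item()
            flat[i] = orig
            nflat[i] = (fp - fm) / (2 * eps)
        if not np.allclose(t.grad, num, rtol=rtol, atol=atol):
            ok = False
    return ok
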