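"""Minimal reverse-mode autodiff on numpy arrays.

Supports exactly the operations the segmentation and classification
networks need: broadcast arithmetic, matmul, n-d "same" convolution with
odd kernels and stride 1, factor pooling/upsampling, concatenation,
batch normalization, dropout and the fused losses. Gradients are checked
numerically in the test suite.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "relu", "sigmoid", "conv_nd", "maxpool_nd", "upsample_nd",
    "concat", "matmul", "reshape", "mean_all", "dropout", "batchnorm",
    "softmax_crossentropy", "bce_with_logits", "softmax", "dice_loss_batch_tensor",
]


class Tensor:
    """Array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ---------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        g = g.astype(np.float32, copy=False)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    def __neg__(self):
        return self * np.float32(-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    __radd__ = __add__
    __rmul__ = __mul__


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (reverse numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- activations -----------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,),
                 backward=lambda g: x._accumulate(g * mask))
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))

    def backward(g):
        x._accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    return Tensor(s, parents=(x,), backward=backward)


# -- linear algebra --------------------------------------------------------

def matmul(x: Tensor, w: Tensor) -> Tensor:
    out = x.data @ w.data

    def backward(g):
        x._accumulate(g @ w.data.T)
        w._accumulate(x.data.T @ g)

    return Tensor(out, parents=(x, w), backward=backward)


def reshape(x: Tensor, shape) -> Tensor:
    orig = x.data.shape
    return Tensor(x.data.reshape(shape), parents=(x,),
                  backward=lambda g: x._accumulate(g.reshape(orig)))


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return Tensor(out, parents=tuple(tensors), backward=backward)


def mean_all(x: Tensor) -> Tensor:
    n = x.data.size

    def backward(g):
        x._accumulate(np.full(x.data.shape, g.item() / n, dtype=np.float32))

    return Tensor(x.data.mean(), parents=(x,), backward=backward)


# -- convolution -----------------------------------------------------------

def _pad_channels_last(x: np.ndarray, kernel) -> np.ndarray:
    """Move channels last (contiguously) and zero-pad the spatial axes.

    x: (N, C, *sp) -> (N, *sp_padded, C). The channels-last layout keeps
    the contraction axis contiguous so the per-offset matmuls below hit
    BLAS without gather copies.
    """
    xl = np.ascontiguousarray(np.moveaxis(x, 1, -1))
    pads = [(0, 0)] + [((k - 1) // 2, (k - 1) // 2) for k in kernel] + [(0, 0)]
    return np.pad(xl, pads)


def _offsets(kernel):
    import itertools
    return itertools.product(*(range(k) for k in kernel))


def _corr_from_padded(xp: np.ndarray, w: np.ndarray, sp) -> np.ndarray:
    """Shift-and-matmul correlation given a padded channels-last input.

    xp: (N, *sp_padded, Cin), w: (Cout, Cin, *k) -> (N, Cout, *sp).
    """
    kernel = w.shape[2:]
    wl = np.ascontiguousarray(np.moveaxis(np.moveaxis(w, 1, -1), 0, -1))
    out = np.zeros(xp.shape[:1] + tuple(sp) + (w.shape[0],), dtype=np.float32)
    tmp = np.empty_like(out)
    for off in _offsets(kernel):
        sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, sp))
        np.matmul(xp[sl], wl[off], out=tmp)
        out += tmp
    return np.ascontiguousarray(np.moveaxis(out, -1, 1))


def _corr_nd(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 "same" cross-correlation.

    x: (N, Cin, *sp), w: (Cout, Cin, *k) -> (N, Cout, *sp).
    """
    return _corr_from_padded(_pad_channels_last(x, w.shape[2:]), w, x.shape[2:])


def _corr_grad_w(xp: np.ndarray, g: np.ndarray, kernel) -> np.ndarray:
    """Weight gradient from the padded channels-last input of the forward
    pass. xp: (N, *sp_padded, Cin), g: (N, Cout, *sp) -> (Cout, Cin, *k)."""
    sp = g.shape[2:]
    cin, cout = xp.shape[-1], g.shape[1]
    glt = np.ascontiguousarray(
        np.moveaxis(g, 1, -1).reshape(-1, cout).T)       # (Cout, N*sp)
    gw = np.empty((cout, cin) + tuple(kernel), dtype=np.float32)
    for off in _offsets(kernel):
        sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, sp))
        xs = xp[sl].reshape(-1, cin)                     # (N*sp, Cin)
        gw[(slice(None), slice(None)) + off] = glt @ xs
    return gw


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """N-d convolution, stride 1, zero "same" padding, odd kernels only."""
    kernel = w.data.shape[2:]
    if any(k % 2 == 0 for k in kernel):
        raise ValueError(f"odd kernel sizes required, got {kernel}")
    sp = x.data.shape[2:]
    xp = _pad_channels_last(x.data, kernel)
    out = _corr_from_padded(xp, w.data, sp)
    if b is not None:
        bshape = (1, -1) + (1,) * len(kernel)
        out = out + b.data.reshape(bshape)

    def backward(g):
        nk = len(kernel)
        sp_axes = tuple(range(2, 2 + nk))
        w._accumulate(_corr_grad_w(xp, g, kernel))
        # data gradient: correlate g with spatially flipped, transposed kernels
        w_flip = np.flip(w.data, axis=tuple(range(2, w.data.ndim)))
        w_t = np.swapaxes(w_flip, 0, 1)  # (Cin, Cout, *k)
        x._accumulate(_corr_nd(g, w_t))
        if b is not None:
            b._accumulate(g.sum(axis=(0,) + sp_axes))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents=parents, backward=backward)


# -- pooling / resampling --------------------------------------------------

def maxpool_nd(x: Tensor, factor) -> Tensor:
    """Non-overlapping max pooling by integer factors per spatial axis."""
    factor = tuple(factor)
    sp = x.data.shape[2:]
    if any(s % f for s, f in zip(sp, factor)):
        raise ValueError(f"spatial shape {sp} not divisible by pooling factor {factor}")
    n, c = x.data.shape[:2]
    newshape = (n, c)
    for s, f in zip(sp, factor):
        newshape += (s // f, f)
    xr = x.data.reshape(newshape)
    # move the factor axes to the end
    fac_axes = tuple(range(3, xr.ndim, 2))
    keep_axes = (0, 1) + tuple(range(2, xr.ndim, 2))
    xt = xr.transpose(keep_axes + fac_axes)
    flat = xt.reshape(xt.shape[: 2 + len(sp)] + (-1,))
    out = flat.max(axis=-1)
    amax = flat.argmax(axis=-1)

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, amax[..., None], g[..., None], axis=-1)
        gt = gflat.reshape(xt.shape)
        inv = np.argsort(keep_axes + fac_axes)
        x._accumulate(gt.transpose(inv).reshape(x.data.shape))

    return Tensor(out, parents=(x,), backward=backward)


def upsample_nd(x: Tensor, factor) -> Tensor:
    """Nearest-neighbour upsampling by integer factors per spatial axis."""
    factor = tuple(factor)
    out = x.data
    for ax, f in enumerate(factor):
        out = np.repeat(out, f, axis=2 + ax)

    def backward(g):
        gr = g
        for ax, f in reversed(list(enumerate(factor))):
            s = x.data.shape[2 + ax]
            shape = gr.shape[: 2 + ax] + (s, f) + gr.shape[3 + ax:]
            gr = gr.reshape(shape).sum(axis=3 + ax)
        x._accumulate(gr)

    return Tensor(out, parents=(x,), backward=backward)


# -- regularization --------------------------------------------------------

def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(np.float32) / keep
    return Tensor(x.data * mask, parents=(x,),
                  backward=lambda g: x._accumulate(g * mask))


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
              running_var: np.ndarray, momentum: float, eps: float,
              training: bool) -> Tensor:
    """Channel-wise batch normalization; channel axis 1.

    ``running_mean``/``running_var`` are updated in place during training.
    """
    axes = (0,) + tuple(range(2, x.data.ndim))
    cshape = (1, -1) + (1,) * (x.data.ndim - 2)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mu
        running_var *= momentum
        running_var += (1.0 - momentum) * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(cshape)) * inv.reshape(cshape)
    out = gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape)

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=axes))
        beta._accumulate(g.sum(axis=axes))
        gx_hat = g * gamma.data.reshape(cshape)
        if training:
            m = x.data.size / x.data.shape[1]
            term = (gx_hat - gx_hat.mean(axis=axes, keepdims=True)
                    - xhat * (gx_hat * xhat).sum(axis=axes, keepdims=True) / m)
            x._accumulate(term * inv.reshape(cshape))
        else:
            x._accumulate(gx_hat * inv.reshape(cshape))

    return Tensor(out, parents=(x, gamma, beta), backward=backward)


# -- fused losses ----------------------------------------------------------

def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on sigmoid(logits); numerically stable."""
    z, y = logits.data, np.asarray(target, dtype=np.float32)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-z))
        logits._accumulate(g.item() * (s - y) / z.size)

    return Tensor(loss.mean(), parents=(logits,), backward=backward)


def dice_loss_batch_tensor(probs: Tensor, target: np.ndarray,
                           eps: float = 1e-6) -> Tensor:
    """Mean over batch samples of (1 - smoothed Dice).

    The Dice overlap (2 sum(s*y) + eps) / (sum(s^2 + y^2) + eps) is
    computed per batch sample and averaged, so small and large lesions
    weigh equally within a batch.
    """
    s = probs.data
    y = np.asarray(target, dtype=np.float32)
    if s.shape != y.shape:
        raise ValueError(f"shape mismatch {s.shape} vs {y.shape}")
    axes = tuple(range(1, s.ndim))
    num = 2.0 * (s * y).sum(axis=axes) + eps
    den = (s * s + y * y).sum(axis=axes) + eps
    n = s.shape[0]
    loss = float((1.0 - num / den).mean())

    def backward(g):
        shp = (-1,) + (1,) * (s.ndim - 1)
        grad = -(2.0 * y * den.reshape(shp) - 2.0 * s * num.reshape(shp))
        grad /= (den ** 2).reshape(shp)
        probs._accumulate(g.item() * grad / n)

    return Tensor(loss, parents=(probs,), backward=backward)


def softmax_crossentropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy on softmax(logits); classes on axis 1."""
    z = logits.data
    y = np.asarray(onehot, dtype=np.float32)
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = z.shape[0]
    loss = -(y * logp).sum() / n

    def backward(g):
        p = np.exp(logp)
        logits._accumulate(g.item() * (p - y) / n)

    return Tensor(loss, parents=(logits,), backward=backward)
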