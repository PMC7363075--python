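"""Shared mini-batch training loop for the segmentation networks."""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError
from .nn import (Adam, Tensor, bce_with_logits, dice_loss_batch_tensor,
                 sigmoid)


def _loss_on(net, X, Y, loss: str, batch_size: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(X), batch_size):
        xb, yb = X[i:i + batch_size], Y[i:i + batch_size]
        logits = net(Tensor(xb[:, None]))
        if loss == "bce":
            lb = bce_with_logits(logits, yb[:, None])
        else:
            lb = dice_loss_batch_tensor(sigmoid(logits), yb[:, None])
        total += float(lb.data) * len(xb)
        n += len(xb)
    return total / max(n, 1)


def _accuracy_on(net, X, Y, batch_size: int) -> float:
    correct, n = 0, 0
    for i in range(0, len(X), batch_size):
        xb, yb = X[i:i + batch_size], Y[i:i + batch_size]
        prob = net.predict_proba(xb)
        correct += int(((prob >= 0.5) == (yb >= 0.5)).sum())
        n += yb.size
    return correct / max(n, 1)


def default_augment(x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                    rotation_deg: float = 0.0, shift_frac: float = 0.0,
                    zoom_range: float = 0.0):
    """Random in-plane rotation, shift and zoom of one training sample.

    Works for 2D (H, W) and 3D (D, H, W) inputs; 3D transforms act on the
    last two axes.
    """
    axes = (x.ndim - 2, x.ndim - 1)
    if rotation_deg > 0:
        a = rng.uniform(-rotation_deg, rotation_deg)
        x = ndimage.rotate(x, a, axes=axes, reshape=False, order=1, prefilter=False)
        y = ndimage.rotate(y, a, axes=axes, reshape=False, order=0)
    if shift_frac > 0:
        shift = [0.0] * x.ndim
        for ax in axes:
            shift[ax] = rng.uniform(-shift_frac, shift_frac) * x.shape[ax]
        x = ndimage.shift(x, shift, order=1, prefilter=False)
        y = ndimage.shift(y, shift, order=0)
    if zoom_range > 0:
        z = rng.uniform(1.0 - zoom_range, 1.0 + zoom_range)
        zoom = [1.0] * x.ndim
        for ax in axes:
            zoom[ax] = z
        xz = ndimage.zoom(x, zoom, order=1, prefilter=False)
        yz = ndimage.zoom(y, zoom, order=0)
        x, y = _center_to(xz, x.shape), _center_to(yz, y.shape)
    return np.clip(x, 0.0, 1.0), (y >= 0.5).astype(np.float32)


def _center_to(a: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=a.dtype)
    src, dst = [], []
    for s_out, s_in in zip(shape, a.shape):
        if s_in >= s_out:
            start = (s_in - s_out) // 2
            src.append(slice(start, start + s_out))
            dst.append(slice(0, s_out))
        else:
            start = (s_out - s_in) // 2
            src.append(slice(0, s_in))
            dst.append(slice(start, start + s_in))
    out[tuple(dst)] = a[tuple(src)]
    return out


def fit_segmentation(net, X_train, Y_train, X_val, Y_val, *, loss: str = "bce",
                     lr: float = 1e-4, epochs: int = 10, batch_size: int = 8,
                     seed: int = 0, select: str = "val_loss",
                     augment=None) -> pd.DataFrame:
    """Train ``net`` and restore the validation-best epoch weights.

    ``loss`` is "bce" or "dice"; ``select`` is "val_loss" (minimize) or
    "val_acc" (maximize). Returns the per-epoch history.
    """
    if len(X_train) == 0 or len(X_val) == 0:
        raise DataError("need at least one training and one validation sample")
    if epochs <= 0 or lr <= 0:
        raise DataError("epochs and learning rate must be positive")
    rng = np.random.default_rng(seed)
    opt = Adam(net.parameters(), lr=lr)
    rows = []
    best_state, best_score = None, None
    for epoch in range(epochs):
        order = rng.permutation(len(X_train))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            xb = X_train[idx].astype(np.float32)
            yb = Y_train[idx].astype(np.float32)
            if augment is not None:
                xb = xb.copy()
                yb = yb.copy()
                for j in range(len(xb)):
                    xb[j], yb[j] = augment(xb[j], yb[j], rng)
            logits = net(Tensor(xb[:, None]))
            if loss == "bce":
                lb = bce_with_logits(logits, yb[:, None])
            else:
                lb = dice_loss_batch_tensor(sigmoid(logits), yb[:, None])
            opt.zero_grad()
            lb.backward()
            opt.step()
            epoch_loss += float(lb.data) * len(idx)
            seen += len(idx)
        val_loss = _loss_on(net, X_val, Y_val, loss, batch_size)
        val_acc = _accuracy_on(net, X_val, Y_val, batch_size)
        rows.append({"epoch": epoch, "train_loss": epoch_loss / seen,
                     "val_loss": val_loss, "val_acc": val_acc})
        score = -val_loss if select == "val_loss" else val_acc
        if best_score is None or score > best_score:
            best_score = score
            best_state = {k: v.copy() for k, v in net.state_dict().items()}
    if best_state is not None:
        net.load_state_dict(best_state)
    return pd.DataFrame(rows)
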