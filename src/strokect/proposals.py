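"""Stage 2: slice-wise stroke region proposals.

A 2D encoder-decoder (5x5 kernels) is trained with a per-sample smoothed
Dice loss, averaged over the batch so small and large lesions weigh
equally, on lesion-bearing slices only. Inference runs slice-wise,
thresholds at 0.5 and stacks to 3D; connected components smaller than a
physical volume floor (default 0.2 cm^3, below the smallest lesion worth
proposing) are removed. Sensitivity is prioritized: surviving false
positives are eliminated by the stage-3 classifier.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from ._train import default_augment, fit_segmentation
from .ctio import NormalizedVolume, SegmentationMask
from .errors import ConfigError, DataError, ParameterError
from .nn import UNet

__all__ = ["ProposalModelConfig", "ProposalModel", "dice_coefficient",
           "dice_loss_batch", "build_proposal_model", "train_region_proposal",
           "propose_regions", "filter_small_components", "CONNECTIVITY_26"]

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)
DICE_EPS = 1e-6


@dataclass
class ProposalModelConfig:
    input_size: tuple = (256, 256)
    filters: tuple = (8, 16, 32)
    learning_rate: float = 1e-4
    epochs: int = 30
    batch_size: int = 8
    stroke_slices_only: bool = True
    augment_rotation_deg: float = 5.0
    augment_shift_frac: float = 0.05
    augment_zoom: float = 0.0

    def __post_init__(self):
        if self.epochs <= 0:
            raise ConfigError("epochs must be positive")
        self.input_size = tuple(int(s) for s in self.input_size)
        depth = len(self.filters) - 1
        if any(s % 2 ** depth for s in self.input_size):
            raise ConfigError(f"input size {self.input_size} not divisible by "
                              f"pooling factor {2 ** depth}")

    kernel = (5, 5)

    @classmethod
    def desk_scale(cls, **kw) -> "ProposalModelConfig":
        defaults = dict(input_size=(96, 96), filters=(8, 16, 32), epochs=10,
                        batch_size=4, learning_rate=1e-3)
        defaults.update(kw)
        return cls(**defaults)


class ProposalModel:
    def __init__(self, config: ProposalModelConfig, seed: int = 0):
        self.config = config
        self.net = UNet(in_ch=1, filters=config.filters, kernel=(5, 5),
                        input_size=config.input_size, seed=seed)

    def save(self, path) -> None:
        np.savez_compressed(path, **self.net.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.net.load_state_dict(dict(data))


def build_proposal_model(config: ProposalModelConfig, seed: int = 0) -> ProposalModel:
    return ProposalModel(config, seed=seed)


# ---------------------------------------------------------------------------
# Dice


def dice_coefficient(S, y, eps: float = DICE_EPS) -> float:
    """Smoothed Dice overlap (2 sum(S*y) + eps) / (sum(S^2 + y^2) + eps).

    ``S`` may be a probability map or a binary mask; on binary inputs this
    equals 2|S n y| / (|S| + |y|) up to the smoothing constant.
    """
    s = np.asarray(S.voxels if hasattr(S, "voxels") else S, dtype=np.float64)
    t = np.asarray(y.voxels if hasattr(y, "voxels") else y, dtype=np.float64)
    if s.shape != t.shape:
        raise ParameterError(f"shape mismatch {s.shape} vs {t.shape}")
    num = 2.0 * (s * t).sum() + eps
    den = (s * s + t * t).sum() + eps
    return float(num / den)


def dice_loss_batch(predictions, truths, eps: float = DICE_EPS) -> float:
    """Mean over batch samples of (1 - Dice)."""
    preds, ys = list(predictions), list(truths)
    if len(preds) != len(ys):
        raise ParameterError("batch sizes differ")
    if not preds:
        raise ParameterError("empty batch")
    return float(np.mean([1.0 - dice_coefficient(s, t, eps)
                          for s, t in zip(preds, ys)]))


# ---------------------------------------------------------------------------
# training / inference


def _lesion_slices(samples, config: ProposalModelConfig):
    """Slice-level training pairs; only slices whose ground truth
    contains lesion voxels when ``stroke_slices_only`` is set."""
    X, Y = [], []
    for vol, mask in samples:
        v = vol.voxels if hasattr(vol, "voxels") else np.asarray(vol)
        m = mask.voxels if hasattr(mask, "voxels") else np.asarray(mask)
        for sl_v, sl_m in zip(v, m):
            if config.stroke_slices_only and not sl_m.any():
                continue
            X.append(resize(sl_v, config.input_size, order=1,
                            preserve_range=True, anti_aliasing=False))
            Y.append(resize(sl_m.astype(float), config.input_size, order=0,
                            preserve_range=True))
    if not X:
        raise DataError("no lesion-bearing slices in the training data")
    return (np.clip(np.stack(X), 0, 1).astype(np.float32),
            (np.stack(Y) >= 0.5).astype(np.float32))


def train_region_proposal(model: ProposalModel, train_samples, val_samples,
                          seed: int = 0) -> pd.DataFrame:
    """Train on lesion-bearing slices; returns per-epoch history and
    leaves the model at its best-validation-epoch weights."""
    cfg = model.config
    Xt, Yt = _lesion_slices(train_samples, cfg)
    Xv, Yv = _lesion_slices(val_samples, cfg)

    def augment(x, y, rng):
        return default_augment(x, y, rng, rotation_deg=cfg.augment_rotation_deg,
                               shift_frac=cfg.augment_shift_frac,
                               zoom_range=cfg.augment_zoom)

    aug = augment if (cfg.augment_rotation_deg or cfg.augment_shift_frac
                      or cfg.augment_zoom) else None
    return fit_segmentation(model.net, Xt, Yt, Xv, Yv, loss="dice",
                            lr=cfg.learning_rate, epochs=cfg.epochs,
                            batch_size=cfg.batch_size, seed=seed,
                            select="val_loss", augment=aug)


def propose_regions(model: ProposalModel, volume: NormalizedVolume,
                    threshold: float = 0.5) -> SegmentationMask:
    """Slice-wise inference, thresholded and stacked to a 3D mask on the
    volume's grid."""
    v = volume.voxels
    cfg = model.config
    slices = np.stack([
        resize(s, cfg.input_size, order=1, preserve_range=True,
               anti_aliasing=False).astype(np.float32) for s in v])
    probs = []
    for i in range(0, len(slices), cfg.batch_size):
        probs.append(model.net.predict_proba(slices[i:i + cfg.batch_size]))
    prob = np.concatenate(probs)
    mask = np.stack([
        resize(p, v.shape[1:], order=1, preserve_range=True,
               anti_aliasing=False) for p in prob]) >= threshold
    return SegmentationMask(mask.astype(np.uint8), volume.spacing,
                            z_thickness=volume.z_thickness)


def component_volumes_cm3(mask_voxels: np.ndarray, spacing,
                          z_thickness=None):
    """Label 26-connected components and return (labels, volumes in cm^3).

    Physical volume uses the per-slice z thickness when it varies:
    sum over component voxels of in-plane area x slice thickness.
    """
    labels, n = ndimage.label(mask_voxels, structure=CONNECTIVITY_26)
    if n == 0:
        return labels, np.empty(0)
    area_mm2 = spacing[1] * spacing[2]
    zt = (np.full(mask_voxels.shape[0], spacing[0])
          if z_thickness is None else np.asarray(z_thickness, dtype=float))
    voxel_mm3 = (area_mm2 * zt)[:, None, None] * np.ones(mask_voxels.shape)
    sums = ndimage.sum_labels(voxel_mm3, labels, index=np.arange(1, n + 1))
    return labels, sums / 1000.0


def filter_small_components(mask: SegmentationMask, spacing=None,
                            min_cm3: float = 0.2) -> SegmentationMask:
    """Remove every 26-connected component with physical volume strictly
    below ``min_cm3``; all other components are kept intact."""
    spacing = spacing if spacing is not None else mask.spacing
    if spacing is None:
        raise ParameterError("voxel spacing required to compute volumes")
    labels, vols = component_volumes_cm3(mask.voxels, spacing,
                                         mask.z_thickness)
    if vols.size == 0:
        return SegmentationMask(np.zeros_like(mask.voxels), spacing,
                                mask.z_thickness)
    keep = np.flatnonzero(vols >= min_cm3) + 1
    out = np.isin(labels, keep).astype(np.uint8)
    return SegmentationMask(out, spacing, mask.z_thickness)
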