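"""Stage 1: cranial cavity segmentation and boundary refinement.

Two encoder-decoder variants are provided: a slice-wise 2D network
(5x5 kernels, slices resampled to a square input resolution) and a
volumetric 3D network (3x3x3 kernels) operating on a downsampled volume
whose prediction is upsampled back to the original grid. Both train with
unweighted binary cross-entropy. Because upsampling blurs the mask
border, a refinement step re-decides membership on a stripe around the
boundary using a Hounsfield threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from ._train import default_augment, fit_segmentation
from .ctio import CTVolume, NormalizedVolume, SegmentationMask
from .errors import ConfigError, DataError, ParameterError
from .nn import UNet

__all__ = ["CavityModelConfig", "CavityModel", "build_cavity_model",
           "train_cavity", "segment_cavity", "refine_boundary"]


@dataclass
class CavityModelConfig:
    """Configuration for either cavity-segmenter variant.

    Full-scale defaults follow the published setup (2D: 512x512 slices,
    30 epochs; 3D: 40x64x64 volumes, 320 epochs; Adam at 1e-4); the
    ``desk_scale`` preset shrinks input sizes, filter widths and epochs
    for CPU-sized experiments.
    """

    variant: str = "3d"
    input_size: tuple = None  # type: ignore[assignment]
    filters: tuple = (8, 16, 32)
    learning_rate: float = 1e-4
    epochs: int = None  # type: ignore[assignment]
    batch_size: int = None  # type: ignore[assignment]
    augment_rotation_deg: float = 5.0
    augment_shift_frac: float = 0.05
    augment_zoom: float = 0.05

    def __post_init__(self):
        if self.variant not in ("2d", "3d"):
            raise ConfigError(f"variant must be '2d' or '3d', got {self.variant!r}")
        if self.input_size is None:
            self.input_size = (512, 512) if self.variant == "2d" else (40, 64, 64)
        self.input_size = tuple(int(s) for s in self.input_size)
        if len(self.input_size) != (2 if self.variant == "2d" else 3):
            raise ConfigError(f"input size {self.input_size} does not match "
                              f"variant {self.variant!r}")
        if self.epochs is None:
            self.epochs = 30 if self.variant == "2d" else 320
        if self.batch_size is None:
            self.batch_size = 8 if self.variant == "2d" else 2
        if self.epochs <= 0:
            raise ConfigError("epochs must be positive")
        if self.learning_rate <= 0:
            raise ConfigError("learning rate must be positive")
        depth = len(self.filters) - 1
        if any(s % 2 ** depth for s in self.input_size):
            raise ConfigError(f"input size {self.input_size} not divisible by "
                              f"pooling factor {2 ** depth}")

    @property
    def kernel(self) -> tuple:
        return (5, 5) if self.variant == "2d" else (3, 3, 3)

    @classmethod
    def desk_scale(cls, variant: str = "3d", **kw) -> "CavityModelConfig":
        if variant == "2d":
            defaults = dict(variant="2d", input_size=(96, 96), filters=(8, 16, 32),
                            epochs=6, batch_size=8, learning_rate=1e-3)
        else:
            defaults = dict(variant="3d", input_size=(8, 32, 32), filters=(8, 16, 32),
                            epochs=40, batch_size=2, learning_rate=1e-3)
        defaults.update(kw)
        return cls(**defaults)


class CavityModel:
    """Trainable cavity segmenter: UNet plus resampling glue."""

    def __init__(self, config: CavityModelConfig, seed: int = 0):
        self.config = config
        self.net = UNet(in_ch=1, filters=config.filters, kernel=config.kernel,
                        input_size=config.input_size, seed=seed)

    # resampling -----------------------------------------------------------
    def _to_input(self, voxels: np.ndarray) -> np.ndarray:
        if self.config.variant == "2d":
            return np.stack([
                resize(s, self.config.input_size, order=1, preserve_range=True,
                       anti_aliasing=False).astype(np.float32) for s in voxels])
        return resize(voxels, self.config.input_size, order=1,
                      preserve_range=True, anti_aliasing=False)[None].astype(np.float32)

    def save(self, path) -> None:
        np.savez_compressed(path, **self.net.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.net.load_state_dict(dict(data))


def build_cavity_model(config: CavityModelConfig, seed: int = 0) -> CavityModel:
    """Encoder-decoder with skip connections, sigmoid output, BCE loss;
    glorot-uniform weights and zero biases."""
    return CavityModel(config, seed=seed)


def _prep_arrays(model: CavityModel, samples):
    """Resample (normalized volume, cavity mask) pairs to network size."""
    X, Y = [], []
    for vol, mask in samples:
        v = vol.voxels if hasattr(vol, "voxels") else np.asarray(vol)
        m = mask.voxels if hasattr(mask, "voxels") else np.asarray(mask)
        if model.config.variant == "2d":
            for sl_v, sl_m in zip(v, m):
                X.append(resize(sl_v, model.config.input_size, order=1,
                                preserve_range=True, anti_aliasing=False))
                Y.append(resize(sl_m.astype(float), model.config.input_size,
                                order=0, preserve_range=True))
        else:
            X.append(resize(v, model.config.input_size, order=1,
                            preserve_range=True, anti_aliasing=False))
            Y.append(resize(m.astype(float), model.config.input_size, order=0,
                            preserve_range=True))
    X = np.clip(np.stack(X), 0.0, 1.0).astype(np.float32)
    Y = (np.stack(Y) >= 0.5).astype(np.float32)
    return X, Y


def train_cavity(model: CavityModel, train_samples, val_samples,
                 seed: int = 0) -> pd.DataFrame:
    """Train on (normalized volume, cavity mask) pairs; the returned model
    carries the weights of the epoch with the best validation loss."""
    if not train_samples or not val_samples:
        raise DataError("need at least one training and one validation sample")
    cfg = model.config
    Xt, Yt = _prep_arrays(model, train_samples)
    Xv, Yv = _prep_arrays(model, val_samples)

    def augment(x, y, rng):
        return default_augment(x, y, rng, rotation_deg=cfg.augment_rotation_deg,
                               shift_frac=cfg.augment_shift_frac,
                               zoom_range=cfg.augment_zoom)

    aug = augment if (cfg.augment_rotation_deg or cfg.augment_shift_frac
                      or cfg.augment_zoom) else None
    return fit_segmentation(model.net, Xt, Yt, Xv, Yv, loss="bce",
                            lr=cfg.learning_rate, epochs=cfg.epochs,
                            batch_size=cfg.batch_size, seed=seed,
                            select="val_loss", augment=aug)


def segment_cavity(model: CavityModel, volume: NormalizedVolume,
                   threshold: float = 0.5) -> SegmentationMask:
    """Probability map thresholded at 0.5, resampled to the input grid."""
    v = volume.voxels
    if model.config.variant == "2d":
        probs = []
        bs = max(1, model.config.batch_size)
        slices = model._to_input(v)
        for i in range(0, len(slices), bs):
            probs.append(model.net.predict_proba(slices[i:i + bs]))
        prob = np.concatenate(probs)
        mask = np.stack([
            resize(p, v.shape[1:], order=1, preserve_range=True,
                   anti_aliasing=False) for p in prob])
    else:
        prob = model.net.predict_proba(model._to_input(v))[0]
        mask = resize(prob, v.shape, order=1, preserve_range=True,
                      anti_aliasing=False)
    return SegmentationMask((mask >= threshold).astype(np.uint8), volume.spacing,
                            z_thickness=volume.z_thickness)


_CROSS = ndimage.generate_binary_structure(2, 1)


def refine_boundary(mask: SegmentationMask, volume: CTVolume,
                    band_px: int = 11, hu_max: float = 50.0) -> SegmentationMask:
    """Re-decide mask membership on a stripe around the boundary.

    Voxels strictly inside the mask and farther (in-plane) than
    ``band_px`` from the boundary are kept unconditionally; voxels within
    ``band_px`` of the boundary — on either side — are kept iff their HU
    value is strictly below ``hu_max``; everything else is removed. The
    default 11-pixel stripe and 50 HU ceiling keep hypodense infarcts
    (profile values below 32 HU) while cutting bone spill-over from the
    upsampled prediction.
    """
    if band_px < 0:
        raise ParameterError(f"band_px must be >= 0, got {band_px}")
    if mask.shape != volume.shape:
        raise ParameterError("mask and volume must be aligned")
    m = mask.voxels.astype(bool)
    out = np.zeros_like(m)
    hu = volume.voxels
    for z in range(m.shape[0]):
        sl = m[z]
        if not sl.any():
            continue
        interior = ndimage.binary_erosion(sl, structure=_CROSS, border_value=0)
        boundary = sl & ~interior
        if boundary.any():
            dist = ndimage.distance_transform_edt(~boundary)
        else:
            dist = np.full(sl.shape, np.inf)
        in_band = dist <= band_px
        out[z] = (sl & ~in_band) | (in_band & (hu[z] < hu_max))
    return SegmentationMask(out.astype(np.uint8), mask.spacing, mask.z_thickness)
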