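"""Stage 3: border-patch extraction and dual-pathway classification.

Connected lesions are labeled (26-connectivity), their in-plane border
is extracted, 70 random border positions are sampled per lesion, and a
pair of patches (a fine 3x32x32 window and a coarse 3x64x64 window
downsampled to 3x32x32) is cut at each position. Positive patches come
from ground-truth lesion borders of stroke subjects; negative patches
are mined from the false-positive proposals the stage-2 network makes on
healthy subjects (hard-negative mining). The minority class is
oversampled to parity before training the dual-pathway densely connected
classifier.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .ctio import NormalizedVolume, SegmentationMask
from .errors import ConfigError, DataError, ParameterError
from .nn import Adam, DualPathwayDenseNet, Tensor, softmax_crossentropy
from .proposals import (ProposalModel, component_volumes_cm3,
                        filter_small_components, propose_regions)

__all__ = [
    "Lesion", "BorderPointSet", "DualResolutionPatch", "PatchClassifierConfig",
    "PatchClassifier", "label_lesions", "lesion_border",
    "sample_border_positions", "extract_dual_patch", "mine_hard_negatives",
    "build_patch_dataset", "build_patch_classifier", "train_patch_classifier",
    "classify_patches", "PATCHES_PER_LESION", "save_patch_dataset",
    "load_patch_dataset",
]

PATCHES_PER_LESION = 70


@dataclass
class Lesion:
    lesion_id: int
    coords: np.ndarray  # (k, 3) voxel coordinates (z, y, x)
    volume_cm3: float
    subject_id: str = ""

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=np.uint8)
        m[tuple(self.coords.T)] = 1
        return m


@dataclass
class BorderPointSet:
    lesion_id: int
    points: np.ndarray  # (k, 3) coordinates on the lesion border


@dataclass
class DualResolutionPatch:
    fine: np.ndarray    # 3x32x32 window at native resolution
    coarse: np.ndarray  # 3x32x32, downsampled from a 3x64x64 window
    center: tuple[int, int, int]
    label: str = "unlabeled"  # stroke | non-stroke | unlabeled

    def __post_init__(self):
        if self.fine.shape != (3, 32, 32) or self.coarse.shape != (3, 32, 32):
            raise ParameterError("patches must be exactly 3x32x32")


@dataclass
class PatchClassifierConfig:
    """Dual-pathway densely connected classifier hyperparameters.

    Dense blocks use 3x3x3 kernels, transitions 1x1x1; batch-norm
    momentum 0.99 with epsilon 1e-3; dropout 0.2; Adam at 1e-5 for 5
    epochs at full scale.
    """

    blocks: int = 2
    layers_per_block: int = 2
    growth: int = 6
    compression: float = 0.5
    dropout: float = 0.2
    stem_filters: int = 8
    hidden_units: int = 32
    learning_rate: float = 1e-5
    epochs: int = 5
    batch_size: int = 16
    bn_momentum: float = 0.99
    bn_eps: float = 1e-3

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.blocks < 1 or self.layers_per_block < 1 or self.growth < 1:
            raise ConfigError("invalid dense block specification")

    @classmethod
    def desk_scale(cls, **kw) -> "PatchClassifierConfig":
        defaults = dict(blocks=2, layers_per_block=2, growth=4, stem_filters=6,
                        hidden_units=24, epochs=5, batch_size=16,
                        learning_rate=3e-4)
        defaults.update(kw)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# lesion geometry


def label_lesions(mask: SegmentationMask, spacing=None) -> list[Lesion]:
    """One Lesion per 26-connected component, with physical volume."""
    spacing = spacing if spacing is not None else mask.spacing
    labels, vols = component_volumes_cm3(mask.voxels, spacing, mask.z_thickness)
    lesions = []
    for i, v in enumerate(vols, start=1):
        coords = np.argwhere(labels == i)
        lesions.append(Lesion(lesion_id=i, coords=coords, volume_cm3=float(v)))
    return lesions


_CROSS2D = ndimage.generate_binary_structure(2, 2)  # in-plane 8-neighbourhood


def lesion_border(mask) -> BorderPointSet:
    """In-plane edge of a lesion mask: lesion voxels whose slice-wise
    gradient is non-zero, i.e. whose 3x3 in-plane neighbourhood contains
    a non-lesion pixel. The border is a subset of the lesion."""
    m = (mask.voxels if hasattr(mask, "voxels") else np.asarray(mask)).astype(bool)
    if not m.any():
        raise ParameterError("lesion mask is empty")
    border = np.zeros_like(m)
    for z in range(m.shape[0]):
        if not m[z].any():
            continue
        interior = ndimage.binary_erosion(m[z], structure=_CROSS2D, border_value=0)
        border[z] = m[z] & ~interior
    return BorderPointSet(lesion_id=0, points=np.argwhere(border))


def sample_border_positions(border: BorderPointSet, n: int = PATCHES_PER_LESION,
                            seed: int = 0) -> np.ndarray:
    """Exactly ``n`` border coordinates: without replacement when the
    border has at least ``n`` points, uniformly with replacement
    otherwise."""
    pts = np.asarray(border.points)
    if pts.size == 0:
        raise ParameterError("border is empty")
    rng = np.random.default_rng(seed)
    if len(pts) >= n:
        idx = rng.choice(len(pts), size=n, replace=False)
    else:
        idx = rng.integers(0, len(pts), size=n)
    return pts[idx]


# ---------------------------------------------------------------------------
# patch extraction


def _window(voxels: np.ndarray, center, half_z: int, half_xy: int) -> np.ndarray:
    """Axis-aligned window around ``center``; outside the volume is
    zero-padded (0 HU background after normalization). Even in-plane
    windows put the center at index ``half_xy``."""
    cz, cy, cx = (int(c) for c in center)
    out = np.zeros((2 * half_z + 1, 2 * half_xy, 2 * half_xy), dtype=np.float32)
    z0, z1 = cz - half_z, cz + half_z + 1
    y0, y1 = cy - half_xy, cy + half_xy
    x0, x1 = cx - half_xy, cx + half_xy
    zs, ys, xs = voxels.shape
    sz0, sz1 = max(z0, 0), min(z1, zs)
    sy0, sy1 = max(y0, 0), min(y1, ys)
    sx0, sx1 = max(x0, 0), min(x1, xs)
    out[sz0 - z0:sz1 - z0, sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = \
        voxels[sz0:sz1, sy0:sy1, sx0:sx1]
    return out


def extract_dual_patch(volume: NormalizedVolume, center,
                       label: str = "unlabeled") -> DualResolutionPatch:
    """Fine 3x32x32 window plus a coarse 3x64x64 window average-pooled
    2x2 in-plane to 3x32x32, both centered on ``center``."""
    v = volume.voxels if hasattr(volume, "voxels") else np.asarray(volume)
    cz, cy, cx = (int(c) for c in center)
    if not (0 <= cz < v.shape[0] and 0 <= cy < v.shape[1] and 0 <= cx < v.shape[2]):
        raise ParameterError(f"center {center} outside volume of shape {v.shape}")
    fine = _window(v, center, half_z=1, half_xy=16)
    wide = _window(v, center, half_z=1, half_xy=32)
    coarse = wide.reshape(3, 32, 2, 32, 2).mean(axis=(2, 4))
    return DualResolutionPatch(fine=fine, coarse=coarse.astype(np.float32),
                               center=(cz, cy, cx), label=label)


def patches_for_lesion(volume, lesion_mask, n: int = PATCHES_PER_LESION,
                       seed: int = 0, label: str = "unlabeled"):
    border = lesion_border(lesion_mask)
    centers = sample_border_positions(border, n=n, seed=seed)
    return [extract_dual_patch(volume, c, label=label) for c in centers]


# ---------------------------------------------------------------------------
# dataset assembly


def mine_hard_negatives(healthy_subjects, proposal_model: ProposalModel,
                        min_cm3: float = 0.2, n_per_lesion: int = PATCHES_PER_LESION,
                        seed: int = 0, threshold: float = 0.5) -> list[DualResolutionPatch]:
    """Non-stroke patches from stage-2 false positives on healthy volumes.

    ``healthy_subjects`` is an iterable of normalized (preprocessed)
    volumes. Each surviving proposal component contributes
    ``n_per_lesion`` border patches labeled "non-stroke". ``threshold``
    sets the stage-2 operating point used for mining; a well-calibrated
    proposer may make no false positives at 0.5, in which case callers
    can soften the threshold to harvest the regions the network found
    most stroke-like.
    """
    patches: list[DualResolutionPatch] = []
    for i, vol in enumerate(healthy_subjects):
        proposal = propose_regions(proposal_model, vol, threshold=threshold)
        proposal = filter_small_components(proposal, min_cm3=min_cm3)
        for lesion in label_lesions(proposal):
            lm = lesion.mask(proposal.shape)
            patches.extend(patches_for_lesion(
                vol, lm, n=n_per_lesion,
                seed=seed + 7919 * i + lesion.lesion_id, label="non-stroke"))
    return patches


def build_patch_dataset(positives, negatives, seed: int = 0,
                        val_fraction: float = 0.0):
    """Balanced labeled patch set: the minority class is oversampled with
    replacement until both classes are equally frequent."""
    positives, negatives = list(positives), list(negatives)
    if not positives or not negatives:
        raise DataError("both patch classes must be non-empty")
    rng = np.random.default_rng(seed)
    if len(positives) < len(negatives):
        extra = rng.integers(0, len(positives), size=len(negatives) - len(positives))
        positives = positives + [positives[i] for i in extra]
    elif len(negatives) < len(positives):
        extra = rng.integers(0, len(negatives), size=len(positives) - len(negatives))
        negatives = negatives + [negatives[i] for i in extra]
    patches = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    order = rng.permutation(len(patches))
    return [patches[i] for i in order], labels[order]


def save_patch_dataset(patches, labels, path) -> None:
    """Cache a labeled patch set: arrays in ``<path>.npz`` plus a JSON
    sidecar ``<path>.json`` with labels, centers and class names."""
    import json
    import os

    fine, coarse = _stack(patches)
    np.savez_compressed(os.fspath(path) + ".npz", fine=fine, coarse=coarse)
    sidecar = {
        "labels": [int(v) for v in np.asarray(labels)],
        "centers": [list(map(int, p.center)) for p in patches],
        "class_names": [p.label for p in patches],
    }
    with open(os.fspath(path) + ".json", "w") as fh:
        json.dump(sidecar, fh)


def load_patch_dataset(path):
    """Inverse of :func:`save_patch_dataset`."""
    import json
    import os

    with np.load(os.fspath(path) + ".npz") as data:
        fine, coarse = data["fine"], data["coarse"]
    with open(os.fspath(path) + ".json") as fh:
        sidecar = json.load(fh)
    patches = [DualResolutionPatch(fine=f, coarse=c, center=tuple(ctr), label=name)
               for f, c, ctr, name in zip(fine, coarse, sidecar["centers"],
                                          sidecar["class_names"])]
    return patches, np.asarray(sidecar["labels"], dtype=int)


# ---------------------------------------------------------------------------
# classifier


class PatchClassifier:
    def __init__(self, config: PatchClassifierConfig, seed: int = 0):
        self.config = config
        self.net = DualPathwayDenseNet(
            stem_filters=config.stem_filters, blocks=config.blocks,
            layers_per_block=config.layers_per_block, growth=config.growth,
            compression=config.compression, dropout_rate=config.dropout,
            hidden_units=config.hidden_units, bn_momentum=config.bn_momentum,
            bn_eps=config.bn_eps, seed=seed)

    def save(self, path) -> None:
        np.savez_compressed(path, **self.net.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.net.load_state_dict(dict(data))


def build_patch_classifier(config: PatchClassifierConfig,
                           seed: int = 0) -> PatchClassifier:
    """Two dense-block pathways (fine, coarse) merged before the fully
    connected head; 2-unit softmax, categorical cross-entropy."""
    return PatchClassifier(config, seed=seed)


def _stack(patches):
    fine = np.stack([p.fine for p in patches]).astype(np.float32)
    coarse = np.stack([p.coarse for p in patches]).astype(np.float32)
    return fine, coarse


def train_patch_classifier(model: PatchClassifier, patches, labels,
                           val_patches=None, val_labels=None,
                           seed: int = 0) -> pd.DataFrame:
    """Train with categorical cross-entropy; restores the epoch weights
    with the best validation accuracy."""
    if len(patches) == 0:
        raise DataError("empty patch dataset")
    labels = np.asarray(labels, dtype=int)
    if val_patches is None:
        # deterministic tail split when no explicit validation set is given
        n_val = max(1, len(patches) // 5)
        val_patches, val_labels = patches[-n_val:], labels[-n_val:]
        patches, labels = patches[:-n_val], labels[:-n_val]
    val_labels = np.asarray(val_labels, dtype=int)
    cfg = model.config
    rng = np.random.default_rng(seed)
    fine, coarse = _stack(patches)
    onehot = np.eye(2, dtype=np.float32)[labels]
    opt = Adam(model.net.parameters(), lr=cfg.learning_rate)
    rows = []
    best_state, best_acc = None, -1.0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(patches))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model.net(Tensor(fine[idx][:, None]),
                               Tensor(coarse[idx][:, None]),
                               rng=rng, training=True)
            loss = softmax_crossentropy(logits, onehot[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            seen += len(idx)
        val_prob = classify_patches(model, val_patches)
        val_acc = float(((val_prob >= 0.5) == (val_labels == 1)).mean())
        rows.append({"epoch": epoch, "train_loss": epoch_loss / seen,
                     "val_acc": val_acc})
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = {k: v.copy() for k, v in model.net.state_dict().items()}
    if best_state is not None:
        model.net.load_state_dict(best_state)
    return pd.DataFrame(rows)


def classify_patches(model: PatchClassifier, patches,
                     batch_size: int = 64) -> np.ndarray:
    """Stroke-class probability in [0, 1] for each patch (dropout off)."""
    if len(patches) == 0:
        return np.empty(0)
    fine, coarse = _stack(patches)
    out = []
    for i in range(0, len(patches), batch_size):
        out.append(model.net.predict_proba(fine[i:i + batch_size],
                                           coarse[i:i + batch_size])[:, 1])
    return np.concatenate(out)
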