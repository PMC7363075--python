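"""Volume containers, preprocessing and file I/O.

Covers slice-to-volume assembly, stroke-window clipping and
normalization (0-80 HU mapped to [0, 1]), in-plane midline alignment and
background cropping, plus NIfTI and DICOM-series readers.

Conventions: voxel arrays are indexed (z, y, x), 0-based, z ascending;
the midline is the x = center plane, so left-right mirroring flips the
last axis. Masks always share their volume's grid and spacing.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, AssemblyError, ParameterError

HU_MIN = 0.0
HU_MAX = 80.0
AIR_HU = -1000.0


# ---------------------------------------------------------------------------
# containers


@dataclass
class CTVolume:
    """3D scalar grid in Hounsfield units.

    ``spacing`` is (z, y, x) in mm. ``z_thickness`` optionally carries a
    per-slice thickness when it varies within one scan; ``spacing[0]`` then
    holds the mean thickness.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    subject_id: str = ""
    z_thickness: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ParameterError(f"volume must be 3D, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ParameterError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be positive, got {self.spacing}")
        if self.z_thickness is not None:
            self.z_thickness = np.asarray(self.z_thickness, dtype=np.float64)
            if self.z_thickness.shape != (self.voxels.shape[0],):
                raise ParameterError("z_thickness must have one entry per slice")
            if np.any(self.z_thickness <= 0):
                raise ParameterError("z_thickness entries must be positive")

    @property
    def shape(self):
        return self.voxels.shape

    def slice_thicknesses(self) -> np.ndarray:
        if self.z_thickness is not None:
            return self.z_thickness
        return np.full(self.voxels.shape[0], self.spacing[0])


@dataclass
class NormalizedVolume:
    """Unitless intensities in [0, 1] derived from a CTVolume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    subject_id: str = ""
    z_thickness: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        lo, hi = float(self.voxels.min(initial=0.0)), float(self.voxels.max(initial=0.0))
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ParameterError(f"normalized values outside [0,1]: [{lo}, {hi}]")

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class SegmentationMask:
    """Binary grid aligned to a volume (cavity, proposal or lesion truth)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    z_thickness: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if not np.isin(v, (0, 1)).all():
            raise ParameterError("mask values must be 0 or 1")
        self.voxels = v.astype(np.uint8)

    @property
    def shape(self):
        return self.voxels.shape

    def is_empty(self) -> bool:
        return not self.voxels.any()

    def slice_thicknesses(self) -> np.ndarray:
        if self.z_thickness is not None:
            return np.asarray(self.z_thickness, dtype=np.float64)
        return np.full(self.voxels.shape[0], self.spacing[0])


# ---------------------------------------------------------------------------
# preprocessing operations


def assemble_volume(slices, in_plane_spacing=(1.0, 1.0), subject_id: str = "",
                    default_thickness: float = 5.0) -> CTVolume:
    """Stack (z_position, 2D slice) pairs into a CTVolume, sorted by z.

    Per-slice thickness is derived from consecutive z gaps; mixed
    thicknesses within one scan are preserved. A single slice falls back
    to ``default_thickness``.
    """
    slices = list(slices)
    if not slices:
        raise AssemblyError("no slices given")
    zs = np.array([float(z) for z, _ in slices])
    if len(np.unique(zs)) != len(zs):
        raise AssemblyError("duplicate slice z positions")
    shapes = {np.asarray(a).shape for _, a in slices}
    if len(shapes) != 1:
        raise AssemblyError(f"inconsistent in-plane shapes: {sorted(shapes)}")
    order = np.argsort(zs)
    stack = np.stack([np.asarray(slices[i][1], dtype=np.float32) for i in order])
    zs = zs[order]
    if len(zs) > 1:
        gaps = np.diff(zs)
        thickness = np.concatenate([gaps, gaps[-1:]])
    else:
        thickness = np.array([default_thickness])
    return CTVolume(stack, (float(thickness.mean()),) + tuple(in_plane_spacing),
                    subject_id=subject_id, z_thickness=thickness)


def clip_normalize(volume: CTVolume) -> NormalizedVolume:
    """Clip to the 0-80 HU stroke window and divide by 80."""
    v = np.clip(volume.voxels, HU_MIN, HU_MAX) / HU_MAX
    return NormalizedVolume(v.astype(np.float32), volume.spacing,
                            subject_id=volume.subject_id,
                            z_thickness=volume.z_thickness)


def _rotate_inplane(voxels: np.ndarray, angle_deg: float, order: int,
                    cval: float) -> np.ndarray:
    if angle_deg == 0.0:
        return voxels.copy()
    return ndimage.rotate(voxels, angle_deg, axes=(1, 2), reshape=False,
                          order=order, cval=cval, prefilter=False)


def _mirror_dice(mask: np.ndarray) -> float:
    flipped = mask[:, :, ::-1]
    inter = np.logical_and(mask, flipped).sum()
    total = mask.sum() + flipped.sum()
    return 2.0 * inter / total if total else 0.0


def estimate_midline_angle(cavity: SegmentationMask, angle_limit: float = 30.0,
                           step: float = 0.5, max_score_slices: int = 8) -> float:
    """In-plane angle (degrees) whose application maximizes left-right
    mirror symmetry (Dice of the mask with its x-flip); ties prefer the
    smaller magnitude.

    The grid search scores symmetry on up to ``max_score_slices`` of the
    largest mask slices; the full-volume rotation happens once, in the
    caller.
    """
    if cavity.is_empty():
        raise AlignmentError("cannot align an empty cavity mask")
    areas = cavity.voxels.sum(axis=(1, 2))
    nz = np.flatnonzero(areas)
    if len(nz) > max_score_slices:
        nz = nz[np.argsort(areas[nz])[-max_score_slices:]]
    sub = cavity.voxels[np.sort(nz)]
    angles = np.arange(-angle_limit, angle_limit + step / 2, step)
    best_angle, best_score = 0.0, -1.0
    for a in angles:
        rot = _rotate_inplane(sub, float(a), order=0, cval=0).astype(bool)
        score = _mirror_dice(rot)
        if score > best_score + 1e-12 or (
                abs(score - best_score) <= 1e-12 and abs(a) < abs(best_angle)):
            best_angle, best_score = float(a), score
    return best_angle


def align_midline(volume: CTVolume, cavity: SegmentationMask,
                  angle_limit: float = 30.0, step: float = 0.5):
    """Rotate head and cavity in-plane so the midline is vertical.

    Returns (rotated volume, rotated cavity, applied angle in degrees).
    Intensities use linear interpolation, the mask nearest-neighbour.
    """
    angle = estimate_midline_angle(cavity, angle_limit, step)
    rot_vox = _rotate_inplane(volume.voxels, angle, order=1, cval=AIR_HU)
    rot_mask = _rotate_inplane(cavity.voxels, angle, order=0, cval=0)
    return (CTVolume(rot_vox, volume.spacing, volume.subject_id, volume.z_thickness),
            SegmentationMask(rot_mask, cavity.spacing, cavity.z_thickness),
            angle)


def crop_background(volume, cavity: SegmentationMask, extra_masks=(),
                    margin=(0, 2, 2)):
    """Crop to the cavity bounding box plus a margin (air/table removal).

    Works on CTVolume or NormalizedVolume. Returns (cropped volume,
    cropped cavity, list of cropped extra masks, offset); ``offset`` is
    the (z, y, x) of the cropped origin in the original grid.
    """
    if cavity.is_empty():
        raise AlignmentError("cannot crop around an empty cavity mask")
    nz = np.nonzero(cavity.voxels)
    lo = [max(0, int(c.min()) - m) for c, m in zip(nz, margin)]
    hi = [min(s, int(c.max()) + 1 + m)
          for c, m, s in zip(nz, margin, cavity.voxels.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    zt = volume.z_thickness[sl[0]] if volume.z_thickness is not None else None
    cropped = type(volume)(volume.voxels[sl], volume.spacing,
                           getattr(volume, "subject_id", ""), zt)
    ccav = SegmentationMask(cavity.voxels[sl], cavity.spacing, zt)
    cextras = [SegmentationMask(m.voxels[sl], m.spacing, zt) for m in extra_masks]
    return cropped, ccav, cextras, tuple(lo)


# ---------------------------------------------------------------------------
# file I/O


def _affine(spacing) -> np.ndarray:
    # arrays are (z,y,x); on disk axes are stored (x,y,z)
    return np.diag([spacing[2], spacing[1], spacing[0], 1.0])


def write_nifti(path: str | os.PathLike, voxels: np.ndarray, spacing) -> None:
    import nibabel as nib

    data = np.asarray(voxels).transpose(2, 1, 0)
    nib.save(nib.Nifti1Image(data, _affine(spacing)), os.fspath(path))


def read_nifti(path: str | os.PathLike):
    """Return (voxels (z,y,x), spacing (z,y,x) in mm)."""
    import nibabel as nib

    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    return data, (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def read_volume_nifti(path, subject_id: str = "") -> CTVolume:
    voxels, spacing = read_nifti(path)
    return CTVolume(voxels, spacing, subject_id=subject_id)


def read_mask_nifti(path) -> SegmentationMask:
    voxels, spacing = read_nifti(path)
    return SegmentationMask((np.asarray(voxels) > 0.5).astype(np.uint8), spacing)


def read_dicom_series(directory: str | os.PathLike, subject_id: str = "") -> CTVolume:
    """Assemble a DICOM series, sorting slices by the z component of
    ImagePositionPatient and applying the rescale slope/intercept."""
    import pydicom

    files = sorted(os.path.join(os.fspath(directory), f)
                   for f in os.listdir(directory) if not f.startswith("."))
    if not files:
        raise AssemblyError(f"no DICOM files in {directory}")
    slices = []
    pixel_spacing = (1.0, 1.0)
    for f in files:
        ds = pydicom.dcmread(f)
        z = float(ds.ImagePositionPatient[2])
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append((z, arr * slope + intercept))
        ps = getattr(ds, "PixelSpacing", None)
        if ps is not None:
            pixel_spacing = (float(ps[0]), float(ps[1]))
    return assemble_volume(slices, in_plane_spacing=pixel_spacing,
                           subject_id=subject_id)
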