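"""Synthetic head-CT phantom cohorts with ground-truth masks.

Each phantom is an ellipsoidal head: a high-density skull shell encloses
a soft-tissue cavity filled with parenchyma near 35 HU, paired
near-midline ventricle-like hypodense confounders whose size grows with
age, and (for stroke subjects) one or more hypodense lesions well below
the 32 HU infarct ceiling. A patient-table slab sits outside and below
the skull. Per-scanner reconstruction texture is emulated by additive
Gaussian noise followed by scanner-specific in-plane Gaussian smoothing,
and an optional in-plane head rotation perturbs the pose.

Every downstream stage (cavity segmentation, region proposals, border
patch classification) is trainable on these cohorts without real data.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .ctio import AIR_HU, CTVolume, SegmentationMask, write_nifti
from .errors import ParameterError
from .evalstat import SubjectRecord
from ._seeds import subrng, subseed

__all__ = ["PhantomParams", "PhantomSample", "ScannerProfile", "SCANNER_PROFILES",
           "generate_phantom", "generate_cohort", "write_cohort"]


@dataclass(frozen=True)
class ScannerProfile:
    """Reconstruction-kernel surrogate: smoothing width and noise level."""

    name: str
    smooth_sigma: float  # in-plane Gaussian sigma, voxels
    noise_sd: float      # additive HU noise before smoothing


SCANNER_PROFILES: dict[str, ScannerProfile] = {
    "sharp-64": ScannerProfile("sharp-64", smooth_sigma=0.5, noise_sd=5.0),
    "smooth-128": ScannerProfile("smooth-128", smooth_sigma=1.1, noise_sd=7.0),
}


@dataclass
class PhantomParams:
    """Generator configuration; the seed fully determines the output."""

    shape: tuple[int, int, int] = (24, 96, 96)
    spacing: tuple[float, float, float] = (5.0, 2.0, 2.0)
    skull_hu: float = 900.0
    parenchyma_hu_mean: float = 35.0
    parenchyma_hu_sd: float = 2.0
    ventricle_hu_mean: float = 8.0
    lesion_hu_mean: float = 22.0
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_radius_range_mm: tuple[float, float] = (5.0, 12.0)
    table_artifact: bool = True
    rotation_range_deg: tuple[float, float] = (0.0, 0.0)
    scanner: str = "sharp-64"
    age: float = 70.0
    seed: int = 0

    def __post_init__(self):
        if self.lesion_hu_mean >= 32.0:
            raise ParameterError("lesion HU mean must be below 32 HU")
        if self.lesion_hu_mean >= self.parenchyma_hu_mean:
            raise ParameterError("lesion HU mean must be below parenchyma mean")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing must be positive")
        lo, hi = self.lesion_radius_range_mm
        if lo <= 0 or hi < lo:
            raise ParameterError("lesion radius range must be positive and ordered")
        clo, chi = self.lesion_count_range
        if clo < 0 or chi < clo:
            raise ParameterError("lesion count range must be non-negative and ordered")
        if self.scanner not in SCANNER_PROFILES:
            raise ParameterError(f"unknown scanner profile {self.scanner!r}")
        if self.age < 0:
            raise ParameterError("age must be >= 0")


@dataclass
class PhantomSample:
    volume: CTVolume
    cavity: SegmentationMask
    lesions: SegmentationMask
    record: SubjectRecord
    true_rotation_deg: float = 0.0

    def __post_init__(self):
        if self.cavity.shape != self.volume.shape or self.lesions.shape != self.volume.shape:
            raise ParameterError("masks must share the volume's shape")
        outside = self.lesions.voxels.astype(bool) & ~self.cavity.voxels.astype(bool)
        if outside.any():
            raise ParameterError("lesion mask must lie inside the cavity mask")


def _ellipsoid(shape, center, semi) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                             indexing="ij")
    d = (((zz - center[0]) / semi[0]) ** 2 + ((yy - center[1]) / semi[1]) ** 2
         + ((xx - center[2]) / semi[2]) ** 2)
    return d <= 1.0


def _head_geometry(shape):
    """Skull shell and cavity masks for a slice-varying ellipsoidal head."""
    nz, ny, nx = shape
    zc, yc, xc = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    semi_z = 0.46 * nz          # head spans most of the z extent
    ry, rx = 0.42 * ny, 0.34 * nx
    shell = 3.0                 # skull thickness, voxels (~6 mm)
    cavity = np.zeros(shape, dtype=bool)
    skull = np.zeros(shape, dtype=bool)
    yy, xx = np.meshgrid(np.arange(ny, dtype=np.float64),
                         np.arange(nx, dtype=np.float64), indexing="ij")
    for z in range(nz):
        s2 = 1.0 - ((z - zc) / semi_z) ** 2
        if s2 <= 0:
            continue
        s = np.sqrt(s2)
        outer = (((yy - yc) / (ry * s)) ** 2 + ((xx - xc) / (rx * s)) ** 2) <= 1.0
        iry, irx = max(ry * s - shell, 0.0), max(rx * s - shell, 0.0)
        if iry > 1 and irx > 1:
            inner = (((yy - yc) / iry) ** 2 + ((xx - xc) / irx) ** 2) <= 1.0
        else:
            inner = np.zeros_like(outer)
        cavity[z] = inner
        skull[z] = outer & ~inner
    return skull, cavity


def _ventricles(shape, cavity: np.ndarray, age: float) -> np.ndarray:
    """Paired near-midline hypodense ellipsoids, enlarged with age
    (atrophy surrogate: ~1.2% per year past age 40)."""
    nz, ny, nx = shape
    zc, yc, xc = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    factor = 1.0 + 0.012 * max(0.0, age - 40.0)
    semi = (max(1.5, 0.09 * nz), 0.10 * ny * factor, 0.035 * nx * factor)
    mask = np.zeros(shape, dtype=bool)
    for dx in (-0.09 * nx, 0.09 * nx):
        mask |= _ellipsoid(shape, (zc, yc - 0.04 * ny, xc + dx), semi)
    return mask & cavity


def generate_phantom(params: PhantomParams) -> PhantomSample:
    """Generate one phantom head with cavity and lesion ground truth."""
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.shape)
    skull, cavity = _head_geometry(shape)
    vol = np.full(shape, AIR_HU, dtype=np.float32)
    vol[skull] = params.skull_hu
    vol[cavity] = params.parenchyma_hu_mean
    ventricles = _ventricles(shape, cavity, params.age)
    vol[ventricles] = params.ventricle_hu_mean

    # lesions: connected hypodense blobs fully inside the cavity,
    # separated from each other and from the ventricles
    n_lesions = int(rng.integers(params.lesion_count_range[0],
                                 params.lesion_count_range[1] + 1))
    lesion_mask = np.zeros(shape, dtype=bool)
    blocked = ndimage.binary_dilation(ventricles, iterations=2)
    for _ in range(n_lesions):
        placed = False
        for _attempt in range(300):
            r_mm = rng.uniform(*params.lesion_radius_range_mm)
            semi = tuple(max(1.0, r_mm / sp) for sp in params.spacing)
            # mild anisotropy so lesions are not perfect spheres
            semi = tuple(s * f for s, f in zip(semi, rng.uniform(0.7, 1.3, 3)))
            center = tuple(rng.uniform(0.15 * s, 0.85 * s) for s in shape)
            blob = _ellipsoid(shape, center, semi)
            if not blob.any():
                continue
            if not (blob <= cavity).all():
                continue
            if (blob & blocked).any():
                continue
            lesion_mask |= blob
            blocked |= ndimage.binary_dilation(blob, iterations=2)
            placed = True
            break
        if not placed:
            raise ParameterError(
                "could not place a lesion inside the cavity; radius range "
                f"{params.lesion_radius_range_mm} mm too large for grid {shape}")
    vol[lesion_mask] = params.lesion_hu_mean

    # tissue texture, scanner noise and reconstruction-kernel smoothing
    profile = SCANNER_PROFILES[params.scanner]
    texture = rng.normal(0.0, params.parenchyma_hu_sd, size=shape)
    vol[cavity] += texture[cavity].astype(np.float32)
    vol += rng.normal(0.0, profile.noise_sd, size=shape).astype(np.float32)
    vol = ndimage.gaussian_filter(
        vol, sigma=(0.0, profile.smooth_sigma, profile.smooth_sigma))

    # patient table: a slab outside and below (larger y) the skull
    if params.table_artifact:
        ny = shape[1]
        y0 = min(int(np.nonzero(skull.any(axis=(0, 2)))[0].max()) + 3, ny - 3)
        table = np.zeros(shape, dtype=bool)
        table[:, y0:y0 + 2, shape[2] // 6: 5 * shape[2] // 6] = True
        table &= ~(skull | cavity)
        vol[table] = 150.0

    angle = 0.0
    lo, hi = params.rotation_range_deg
    if hi > lo or lo != 0.0:
        angle = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    if angle != 0.0:
        vol = ndimage.rotate(vol, angle, axes=(1, 2), reshape=False, order=1,
                             cval=AIR_HU, prefilter=False)
        cavity = ndimage.rotate(cavity.astype(np.uint8), angle, axes=(1, 2),
                                reshape=False, order=0, cval=0).astype(bool)
        lesion_mask = ndimage.rotate(lesion_mask.astype(np.uint8), angle,
                                     axes=(1, 2), reshape=False, order=0,
                                     cval=0).astype(bool)
        lesion_mask &= cavity

    record = SubjectRecord(subject_id=f"phantom-{params.seed:08d}",
                           age=params.age, scanner_model=params.scanner,
                           label=int(lesion_mask.any()))
    return PhantomSample(
        volume=CTVolume(vol, params.spacing, subject_id=record.subject_id),
        cavity=SegmentationMask(cavity.astype(np.uint8), params.spacing),
        lesions=SegmentationMask(lesion_mask.astype(np.uint8), params.spacing),
        record=record,
        true_rotation_deg=angle,
    )


DEFAULT_SPLIT_FRACTIONS = {"train": 0.48, "val": 0.12, "test": 0.40}


def generate_cohort(n: int, stroke_fraction: float, params: PhantomParams | None = None,
                    seed: int = 0, age_range=(40.0, 95.0),
                    scanners=("sharp-64", "smooth-128"),
                    split_fractions=None):
    """Generate ``n`` phantoms with round(n * stroke_fraction) stroke cases.

    Ages are drawn uniformly from ``age_range`` and scanner profiles
    uniformly from ``scanners``. Splits are assigned stratified by label
    with ``split_fractions`` (train/val/test). Returns (samples, table).
    """
    if n <= 0:
        raise ParameterError(f"cohort size must be positive, got {n}")
    if not 0.0 <= stroke_fraction <= 1.0:
        raise ParameterError("stroke_fraction must be in [0, 1]")
    params = params or PhantomParams()
    split_fractions = split_fractions or DEFAULT_SPLIT_FRACTIONS
    rng = subrng(seed, "cohort")
    n_stroke = int(round(n * stroke_fraction))
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_stroke]] = 1

    samples: list[PhantomSample] = []
    for i in range(n):
        count_range = params.lesion_count_range if labels[i] else (0, 0)
        if labels[i] and count_range[0] < 1:
            count_range = (1, max(1, count_range[1]))
        p = replace(
            params,
            lesion_count_range=count_range,
            age=float(np.floor(rng.uniform(*age_range))),
            scanner=str(scanners[int(rng.integers(len(scanners)))]),
            seed=subseed(seed, f"phantom-{i}"),
        )
        sample = generate_phantom(p)
        sample.record.subject_id = f"subj-{i:04d}"
        sample.volume.subject_id = sample.record.subject_id
        samples.append(sample)

    # label-stratified split assignment
    for label in (0, 1):
        idx = [i for i in range(n) if labels[i] == label]
        idx = [idx[j] for j in rng.permutation(len(idx))]
        n_train = int(round(len(idx) * split_fractions["train"]))
        n_val = int(round(len(idx) * split_fractions["val"]))
        for j, i in enumerate(idx):
            split = ("train" if j < n_train
                     else "val" if j < n_train + n_val else "test")
            samples[i].record.split = split

    table = pd.DataFrame([
        {"subject_id": s.record.subject_id, "age": s.record.age,
         "scanner_model": s.record.scanner_model, "label": s.record.label,
         "split": s.record.split} for s in samples])
    return samples, table


def write_cohort(samples, table: pd.DataFrame, out_dir) -> None:
    """Write volumes/masks as NIfTI (one file per subject per role) and
    the cohort table as CSV."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for s in samples:
        sid = s.record.subject_id
        write_nifti(os.path.join(out_dir, f"{sid}_volume.nii.gz"),
                    s.volume.voxels, s.volume.spacing)
        write_nifti(os.path.join(out_dir, f"{sid}_cavity.nii.gz"),
                    s.cavity.voxels, s.cavity.spacing)
        write_nifti(os.path.join(out_dir, f"{sid}_lesions.nii.gz"),
                    s.lesions.voxels, s.lesions.spacing)
    table.to_csv(os.path.join(out_dir, "cohort.csv"), index=False)
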