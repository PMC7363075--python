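"""Orchestration: three-stage training, end-to-end inference, evaluation.

Training order mirrors the inference flow: the cavity segmenter is
trained first (on healthy subjects' cavity annotations), the region
proposer second (on lesion-bearing slices of stroke subjects, after
stage-1 preprocessing), and the patch classifier last, with its negative
class mined from stage-2 false positives on healthy training subjects.
Split hygiene is enforced: no subject id may cross split boundaries.

The default experiment crops around the cranial cavity but leaves
pixel-wise cavity masking off; both are exposed as flags.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ValidationError

from ._seeds import subrng, subseed
from .cavity import (CavityModel, CavityModelConfig, build_cavity_model,
                     refine_boundary, segment_cavity, train_cavity)
from .ctio import (CTVolume, NormalizedVolume, SegmentationMask, align_midline,
                   clip_normalize, crop_background, estimate_midline_angle,
                   write_nifti)
from .errors import ConfigError, DataError, SplitLeakageError
from .evalstat import (bootstrap_auc_ci, confusion_at_threshold, lesion_score,
                       roc_auc, subject_score)
from .patchnet import (PatchClassifier, PatchClassifierConfig,
                       build_patch_classifier, classify_patches, label_lesions,
                       mine_hard_negatives, patches_for_lesion,
                       train_patch_classifier)
from .phantom import PhantomParams, generate_cohort
from .proposals import (ProposalModel, ProposalModelConfig,
                        build_proposal_model, filter_small_components,
                        propose_regions, train_region_proposal)

log = logging.getLogger("strokect")

__all__ = ["PipelineConfig", "TrainedPipeline", "load_config", "save_config",
           "save_report", "setup_logging", "run_training", "run_inference",
           "evaluate_cohort", "check_split_hygiene", "preprocess_subject"]


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML-serializable)."""

    seed: int = 0
    data_dir: Optional[str] = None
    models_dir: str = "models"
    output_dir: str = "outputs"
    desk_scale: bool = True
    cohort_n: int = 100
    stroke_fraction: float = 0.5
    cavity_variant: str = "3d"
    pixelwise_cavity_masking: bool = False
    align_midline: bool = True
    crop_margin: tuple[int, int, int] = (0, 2, 2)
    # boundary-refinement stripe width in pixels. The published 11-pixel
    # stripe refers to ~0.5 mm in-plane pixels (~5 mm); on the phantom's
    # 2 mm grid the same physical width is 3 pixels.
    band_px: int = 3
    hu_max: float = 50.0
    patches_per_lesion: int = 70
    min_component_cm3: float = 0.2
    threshold: float = 0.3
    bootstrap_reps: int = 1000
    bootstrap_m: int = 100
    max_patches_per_class: int = 300
    max_cavity_train_subjects: int = 12
    cavity_overrides: dict = {}
    proposal_overrides: dict = {}
    patch_overrides: dict = {}

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def stage_configs(self):
        try:
            if self.desk_scale:
                cav = CavityModelConfig.desk_scale(self.cavity_variant,
                                                   **self.cavity_overrides)
                prop = ProposalModelConfig.desk_scale(**self.proposal_overrides)
                patch = PatchClassifierConfig.desk_scale(**self.patch_overrides)
            else:
                cav = CavityModelConfig(variant=self.cavity_variant,
                                        **self.cavity_overrides)
                prop = ProposalModelConfig(**self.proposal_overrides)
                patch = PatchClassifierConfig(**self.patch_overrides)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        return cav, prop, patch


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        fields = ", ".join(".".join(str(p) for p in e["loc"]) for e in exc.errors())
        raise ConfigError(f"invalid configuration field(s): {fields}") from exc


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


def save_report(report: dict, path) -> None:
    os.makedirs(os.path.dirname(os.fspath(path)) or ".", exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)


def setup_logging(level=logging.INFO) -> None:
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s")


def check_split_hygiene(table: pd.DataFrame) -> None:
    """Raise SplitLeakageError naming subjects tagged with >1 split."""
    counts = table.groupby("subject_id")["split"].nunique()
    offenders = counts[counts > 1].index.tolist()
    dupes = table[table.duplicated("subject_id", keep=False)]
    for sid, grp in dupes.groupby("subject_id"):
        if grp["split"].nunique() > 1 and sid not in offenders:
            offenders.append(sid)
    if offenders:
        raise SplitLeakageError(offenders)


# ---------------------------------------------------------------------------
# preprocessing shared by training and inference


@dataclass
class PreprocessedSubject:
    volume: NormalizedVolume       # cropped (optionally cavity-masked)
    cavity: SegmentationMask
    lesions: Optional[SegmentationMask]
    angle_deg: float
    crop_offset: tuple[int, int, int]


def preprocess_subject(volume: CTVolume, cavity: SegmentationMask,
                       lesions: Optional[SegmentationMask],
                       config: PipelineConfig) -> PreprocessedSubject:
    """Boundary refinement, midline alignment, background cropping and
    normalization, applied consistently to the volume and its masks."""
    from scipy import ndimage

    refined = refine_boundary(cavity, volume, band_px=config.band_px,
                              hu_max=config.hu_max)
    if refined.is_empty():
        refined = cavity
    angle = 0.0
    hu = volume.voxels
    cav = refined.voxels
    les = lesions.voxels if lesions is not None else None
    if config.align_midline and not refined.is_empty():
        angle = estimate_midline_angle(refined)
        if angle != 0.0:
            hu = ndimage.rotate(hu, angle, axes=(1, 2), reshape=False, order=1,
                                cval=-1000.0, prefilter=False)
            cav = ndimage.rotate(cav, angle, axes=(1, 2), reshape=False, order=0)
            if les is not None:
                les = ndimage.rotate(les, angle, axes=(1, 2), reshape=False, order=0)
    vol_r = CTVolume(hu, volume.spacing, volume.subject_id, volume.z_thickness)
    cav_r = SegmentationMask(cav, volume.spacing, volume.z_thickness)
    extras = [SegmentationMask(les, volume.spacing, volume.z_thickness)] \
        if les is not None else []
    vol_c, cav_c, extras_c, offset = crop_background(
        vol_r, cav_r, extras, margin=config.crop_margin)
    norm = clip_normalize(vol_c)
    if config.pixelwise_cavity_masking:
        norm = NormalizedVolume(norm.voxels * cav_c.voxels, norm.spacing,
                                norm.subject_id, norm.z_thickness)
    return PreprocessedSubject(
        volume=norm, cavity=cav_c,
        lesions=extras_c[0] if extras_c else None,
        angle_deg=angle, crop_offset=offset)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedPipeline:
    config: PipelineConfig
    cavity_model: CavityModel
    proposal_model: ProposalModel
    patch_classifier: PatchClassifier
    histories: dict

    def save(self, models_dir) -> None:
        os.makedirs(models_dir, exist_ok=True)
        self.cavity_model.save(os.path.join(models_dir, "cavity.npz"))
        self.proposal_model.save(os.path.join(models_dir, "proposals.npz"))
        self.patch_classifier.save(os.path.join(models_dir, "patches.npz"))
        for name, hist in self.histories.items():
            hist.to_csv(os.path.join(models_dir, f"history_{name}.csv"), index=False)


def _by_split(samples, split):
    return [s for s in samples if s.record.split == split]


def run_training(config: PipelineConfig, samples=None,
                 table: pd.DataFrame | None = None) -> TrainedPipeline:
    """Train all three stages on a cohort; asserts split hygiene.

    When ``samples`` is None a synthetic cohort is generated from the
    configuration (size, stroke fraction, global seed).
    """
    seed = config.seed
    if samples is None:
        samples, table = generate_cohort(config.cohort_n, config.stroke_fraction,
                                         PhantomParams(), seed=subseed(seed, "cohort"))
    if table is None:
        from .evalstat import records_to_frame
        table = records_to_frame([s.record for s in samples])
    check_split_hygiene(table)
    cav_cfg, prop_cfg, patch_cfg = config.stage_configs()
    log.info("config hash %s; cohort n=%d", config.config_hash(), len(samples))

    train = _by_split(samples, "train")
    val = _by_split(samples, "val")
    if not train or not val:
        raise DataError("cohort must contain train and val subjects")

    # stage 1: cranial cavity -------------------------------------------
    t0 = time.time()
    cav_train = [s for s in train if s.record.label == 0] or train
    cav_train = cav_train[:config.max_cavity_train_subjects]
    cav_val = ([s for s in val if s.record.label == 0] or val)[:4]
    cavity_model = build_cavity_model(cav_cfg, seed=subseed(seed, "cavity-init"))
    hist_cav = train_cavity(
        cavity_model,
        [(clip_normalize(s.volume), s.cavity) for s in cav_train],
        [(clip_normalize(s.volume), s.cavity) for s in cav_val],
        seed=subseed(seed, "cavity-train"))
    log.info("stage 1 trained in %.1fs", time.time() - t0)

    # preprocessing for stages 2/3 uses the trained stage-1 model
    def prep(sample):
        norm = clip_normalize(sample.volume)
        cav = segment_cavity(cavity_model, norm)
        if cav.is_empty():
            cav = sample.cavity
        return preprocess_subject(sample.volume, cav, sample.lesions, config)

    # stage 2: region proposals -----------------------------------------
    t0 = time.time()
    prep_train = {s.record.subject_id: prep(s) for s in train}
    prep_val = {s.record.subject_id: prep(s) for s in val}
    stroke_train = [prep_train[s.record.subject_id] for s in train
                    if s.record.label == 1]
    stroke_val = [prep_val[s.record.subject_id] for s in val
                  if s.record.label == 1]
    if not stroke_train or not stroke_val:
        raise DataError("stage 2 needs stroke subjects in train and val splits")
    proposal_model = build_proposal_model(prop_cfg, seed=subseed(seed, "prop-init"))
    hist_prop = train_region_proposal(
        proposal_model,
        [(p.volume, p.lesions) for p in stroke_train],
        [(p.volume, p.lesions) for p in stroke_val],
        seed=subseed(seed, "prop-train"))
    log.info("stage 2 trained in %.1fs", time.time() - t0)

    # stage 3: patch classifier -----------------------------------------
    t0 = time.time()
    rng = subrng(seed, "patch-data")

    def positives_from(preps):
        out = []
        for p in preps:
            if p.lesions is None or p.lesions.is_empty():
                continue
            for lesion in label_lesions(p.lesions):
                lm = lesion.mask(p.lesions.shape)
                out.extend(patches_for_lesion(
                    p.volume, lm, n=config.patches_per_lesion,
                    seed=int(rng.integers(2 ** 31)), label="stroke"))
        return out

    healthy_train = [prep_train[s.record.subject_id].volume for s in train
                     if s.record.label == 0]
    healthy_val = [prep_val[s.record.subject_id].volume for s in val
                   if s.record.label == 0]
    pos_train = positives_from(stroke_train)

    # Mine stage-2 false positives at its operating point; if the proposer
    # makes none on the healthy training subjects, soften the mining
    # threshold so the negatives are still the regions stage 2 found most
    # stroke-like (inference always stays at 0.5).
    neg_train: list = []
    mining_threshold = 0.5
    for mining_threshold in (0.5, 0.25, 0.1, 0.02):
        neg_train = mine_hard_negatives(
            healthy_train, proposal_model, min_cm3=config.min_component_cm3,
            n_per_lesion=config.patches_per_lesion,
            seed=subseed(seed, "mine-train"), threshold=mining_threshold)
        if neg_train:
            break
        log.info("no hard negatives at stage-2 threshold %.2f; softening",
                 mining_threshold)
    pos_val = positives_from(stroke_val)
    neg_val = mine_hard_negatives(healthy_val, proposal_model,
                                  min_cm3=config.min_component_cm3,
                                  n_per_lesion=config.patches_per_lesion,
                                  seed=subseed(seed, "mine-val"),
                                  threshold=mining_threshold)
    cap = config.max_patches_per_class

    def _cap(patches, cap_n, tag):
        if len(patches) > cap_n:
            idx = subrng(seed, f"cap-{tag}").permutation(len(patches))[:cap_n]
            return [patches[i] for i in idx]
        return patches

    pos_train, neg_train = _cap(pos_train, cap, "pos"), _cap(neg_train, cap, "neg")
    pos_val, neg_val = _cap(pos_val, cap // 2, "posv"), _cap(neg_val, cap // 2, "negv")
    from .patchnet import build_patch_dataset
    patches, labels = build_patch_dataset(pos_train, neg_train,
                                          seed=subseed(seed, "balance"))
    if pos_val and neg_val:
        val_patches, val_labels = build_patch_dataset(
            pos_val, neg_val, seed=subseed(seed, "balance-val"))
    else:
        val_patches = val_labels = None
    patch_classifier = build_patch_classifier(patch_cfg,
                                              seed=subseed(seed, "patch-init"))
    hist_patch = train_patch_classifier(patch_classifier, patches, labels,
                                        val_patches, val_labels,
                                        seed=subseed(seed, "patch-train"))
    log.info("stage 3 trained in %.1fs (pos=%d neg=%d)", time.time() - t0,
             len(pos_train), len(neg_train))

    return TrainedPipeline(config=config, cavity_model=cavity_model,
                           proposal_model=proposal_model,
                           patch_classifier=patch_classifier,
                           histories={"cavity": hist_cav, "proposals": hist_prop,
                                      "patches": hist_patch})


# ---------------------------------------------------------------------------
# inference


def run_inference(trained: TrainedPipeline, volume: CTVolume,
                  cavity: SegmentationMask | None = None,
                  proposal_out: str | None = None,
                  use_stage3: bool = True) -> dict:
    """Full inference for one subject.

    Returns a report with per-lesion scores and the subject-level
    probability (maximum of lesion scores; 0.0 with no surviving
    proposal). ``cavity`` overrides the stage-1 prediction when given;
    ``use_stage3=False`` scores any surviving proposal as 1.0.
    """
    config = trained.config
    norm0 = clip_normalize(volume)
    if cavity is None:
        cavity = segment_cavity(trained.cavity_model, norm0)
    if cavity.is_empty():
        return {"subject_id": volume.subject_id, "subject_score": 0.0,
                "lesions": [], "angle_deg": 0.0, "note": "empty cavity"}
    prep = preprocess_subject(volume, cavity, None, config)
    proposal = propose_regions(trained.proposal_model, prep.volume)
    proposal = filter_small_components(proposal, min_cm3=config.min_component_cm3)
    if proposal_out:
        write_nifti(proposal_out, proposal.voxels, prep.volume.spacing)
    lesion_reports = []
    scores = []
    rng = subrng(config.seed, f"infer-{volume.subject_id}")
    for lesion in label_lesions(proposal):
        lm = lesion.mask(proposal.shape)
        if use_stage3:
            patches = patches_for_lesion(prep.volume, lm,
                                         n=config.patches_per_lesion,
                                         seed=int(rng.integers(2 ** 31)))
            probs = classify_patches(trained.patch_classifier, patches)
            score = lesion_score(probs)
        else:
            score = 1.0
        scores.append(score)
        lesion_reports.append({"lesion_id": lesion.lesion_id,
                               "volume_cm3": lesion.volume_cm3,
                               "score": score,
                               "n_patches": config.patches_per_lesion})
    return {"subject_id": volume.subject_id,
            "subject_score": subject_score(scores),
            "lesions": lesion_reports,
            "angle_deg": prep.angle_deg}


def evaluate_cohort(trained: TrainedPipeline, samples, threshold=None,
                    use_stage3: bool = True, bootstrap: bool = True) -> dict:
    """Run inference on a cohort and evaluate subject-level scores."""
    config = trained.config
    threshold = config.threshold if threshold is None else threshold
    scores, labels, per_subject = [], [], []
    for s in samples:
        report = run_inference(trained, s.volume, use_stage3=use_stage3)
        scores.append(report["subject_score"])
        labels.append(s.record.label)
        per_subject.append(report)
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    result = roc_auc(scores, labels)
    ci = (bootstrap_auc_ci(scores, labels, reps=config.bootstrap_reps,
                           m=min(config.bootstrap_m, len(scores)),
                           seed=subseed(config.seed, "bootstrap"))
          if bootstrap else None)
    return {"auc": result.auc, "ci": ci,
            "confusion": confusion_at_threshold(scores, labels, t=threshold),
            "threshold": threshold,
            "scores": scores.tolist(), "labels": labels.tolist(),
            "subjects": per_subject}
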