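# Methods

## Pipeline model and assumptions

The package classifies a head CT volume for ischemic infarction by
systematically shrinking the voxel set that the final classifier must
judge: first to the cranial cavity, then to candidate lesion regions,
then to 70 border patches per candidate. The underlying assumptions
are that (i) infarcts hypoattenuate — their profile values lie below
~32 HU while normal parenchyma sits near 30–40 HU, so a 0–80 HU window
divided by 80 preserves all discriminative contrast; (ii) candidate
generation may over-trigger, because a dedicated classifier trained on
exactly the over-triggered regions (hard negatives) can remove false
positives afterwards; and (iii) a lesion is better judged by many
local views of its border than by one global view, so a lesion score
is the mean of 70 patch probabilities and a subject score is the
maximum over its lesions. An empty proposal set forces a subject score
of 0.0 (predicted healthy).

Inference order: cavity segmentation → boundary refinement → midline
alignment → background cropping → slice-wise proposals → 0.2 cm³
component filter → border-patch scoring → lesion mean → subject max.
Midline alignment is applied after cavity segmentation, using the
cavity mask only.

## Stage parameters

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| HU window | 0–80, ÷80 | HU | stroke reading window; maps to [0,1] |
| refinement stripe `band_px` | 11 (operation) / 3 (desk pipeline) | px | see "stripe width" below |
| refinement ceiling `hu_max` | 50 | HU | keeps infarcts (<32 HU), cuts bone |
| proposal threshold | 0.5 | prob. | sigmoid midpoint; no calibration implied |
| component floor | 0.2 | cm³ | below the smallest lesion worth proposing |
| patches per lesion | 70 | — | bag-of-local-features sample size |
| fine / coarse patch | 3×32×32 / 3×64×64→3×32×32 | voxels | dual resolution around a border point |
| operating threshold | 0.3 | prob. | confusion-matrix operating point |
| bootstrap | 1000 reps × 100 samples | — | percentile 2.5–97.5 CI |
| dropout | 0.2 | — | patch classifier regularization |
| batch norm | momentum 0.99, ε 1e-3 | — | patch classifier |

Full-scale network defaults (learning rate 1e-4 Adam for both cavity
variants and proposals, 1e-5 for the patch classifier; 30 / 320 / 30 /
5 epochs; 512×512 slice input for 2D cavity, 40×64×64 for 3D cavity,
256×256 for proposals) are recorded in the config classes. The
`desk_scale` presets used by the tests and the acceptance script
shrink inputs to the phantom grid (96×96 slices, 8×32×32 volumes),
use 8–32 filters per level, and raise learning rates to 1e-3 (stages
1–2) and 3e-4 (stage 3) with 4–40 epochs: a desk-scale run sees two
orders of magnitude fewer optimizer steps than a 555-subject training
schedule, and the full-scale rates simply do not move the loss in that
budget. Checkpoint selection keeps the epoch with the best validation
loss (cavity) or best validation Dice (proposals — pixel accuracy is
degenerate for tiny foregrounds, so "validation accuracy" is read as
mean validation Dice) or best validation accuracy (patch classifier).

### Stripe width and voxel size

The 11-pixel refinement stripe was tuned on ~0.5 mm in-plane pixels,
i.e. a ~5 mm physical band. `refine_boundary` keeps 11 as its default,
but the pipeline configuration uses 3 px on the phantom's 2 mm grid —
the same physical width. Applying 11 px at 2 mm would push the band
through the skull and admit low-density air outside the head, which is
a unit artifact, not a modelling choice. The stripe extends to both
sides of the boundary (membership inside it is re-decided purely by
the HU < 50 rule), because upsampling blur spills both ways.

## The synthetic cohort

`generate_phantom` builds, on a 24×96×96 grid at 5×2×2 mm (head CT's
dominant 5 mm slice thickness; in-plane coarsened so CPU training is
feasible):

* an ellipsoidal head with slice-varying radii, a ~6 mm skull shell at
  900 HU, air at −1000 HU;
* parenchyma at 35 ± 2 HU with per-voxel texture;
* paired near-midline ventricle ellipsoids at 8 HU, scaled by
  ~1.2 %/year past age 40 (atrophy surrogate) — the hypodense
  confounders that make stage 3 non-trivial;
* 1–3 ellipsoidal lesions at 22 HU, radii 5–12 mm, fully inside the
  cavity and separated from the ventricles and from each other (so
  the drawn lesion count equals the connected-component count);
* a 150 HU table slab outside and below the skull;
* additive Gaussian noise then in-plane Gaussian smoothing per scanner
  profile ("sharp-64": σ 0.5 px / 5 HU; "smooth-128": σ 1.1 px /
  7 HU), emulating reconstruction-kernel texture differences;
* optional in-plane rotation (linear interpolation for intensities,
  nearest-neighbour for masks).

Cohorts draw ages uniformly from 40–95 years and scanners uniformly
from the two profiles; splits are assigned stratified by label at
48 % train / 12 % validation / 40 % test, so the default 100-phantom
cohort tests on 40 balanced subjects. One seed determines everything
through named sub-seeds per stage.

What the phantom does **not** emulate: realistic cortical/sulcal
anatomy, partial-volume gradients at tissue interfaces, beam
hardening, metal artifacts, hemorrhage, non-elliptical lesion shapes,
or inter-subject anatomical variability beyond size/rotation/age
scaling. Passing the end-to-end checks therefore demonstrates that the
pipeline machinery — training, mining, aggregation, evaluation — is
correct and recovers planted signal under realistic texture and
confounders; it does not certify clinical performance.

## Numerical and design choices

* **Midline estimation** (method unspecified in the source study):
  grid search over ±30° in 0.5° steps maximizing the Dice overlap of
  the cavity mask with its left-right mirror; ties break toward the
  smaller magnitude; symmetry is scored on the 8 largest mask slices.
* **Dice loss**: `1 − (2Σsy+ε)/(Σ(s²+y²)+ε)` with ε = 1e-6, computed
  per batch sample (a slice during stage-2 training) and averaged.
  On binary inputs the coefficient reduces to `2|S∩y|/(|S|+|y|)`.
* **Connectivity**: 26-connectivity in 3D throughout; physical
  component volume uses per-slice z thickness when mixed.
* **Lesion border**: mask minus its in-plane 8-connected erosion —
  equivalently, lesion pixels whose 3×3 in-plane neighbourhood touches
  background. This keeps the border inside the lesion (patch centers
  sit on lesion tissue) and equals the non-zero-gradient edge set
  except on single-pixel-wide structures, where centred difference
  kernels cancel; a single-voxel lesion is its own border.
* **Border sampling**: exactly 70 positions; without replacement when
  the border has ≥70 points, uniformly with replacement otherwise.
* **Patch windows**: even-sized windows place the center voxel at
  index 16; outside-volume regions are zero-padded (0 HU after
  normalization = background); the coarse patch is a 2×2 in-plane
  average pooling of the 64×64 window.
* **Oversampling**: minority patches resampled with replacement to
  exact parity, seeded.
* **Bootstrap**: resamples drawn with replacement; single-class
  resamples redrawn (cap 1000); CI endpoints are the nearest-rank
  2.5 % / 97.5 % order statistics of the sorted AUCs.
* **Stratified testing**: per stratum (scanner model or age decade),
  `min(n_stroke, n_healthy)` subjects of each class sampled without
  replacement; strata missing a class contribute nothing.
* **Threshold comparisons**: score ≥ t counts as predicted positive;
  component removal is strict (< 0.2 cm³ removed); refinement keeps
  HU strictly below 50.
* **Split hygiene**: a subject id appearing under more than one split
  tag aborts training, naming the offenders.
* **Determinism**: one global seed; sub-seeds derived per named
  stage (CRC-32 of the stage name into a seed sequence); numpy-only
  compute is single-threaded-deterministic.

## The network engine

No deep-learning framework is used; `strokect.nn` is a small
reverse-mode autodiff on numpy arrays providing exactly what the three
architectures need: stride-1 "same" convolution in 2D/3D (shift-and-
matmul over kernel offsets in channels-last layout, so the inner loops
are BLAS GEMMs), max pooling, nearest upsampling, concatenation (skip
connections and dense blocks), batch normalization, dropout, dense
layers, sigmoid/softmax, fused binary/categorical cross-entropy and
per-sample Dice losses, Adam, and glorot-uniform initialization with
zero biases. Every op's gradient is checked against central
differences in the test suite. The U-Net uses two convolutions per
level and factor-2 pooling; input sizes must be divisible by
2^(levels−1). The patch classifier runs two identical dense-block
pathways (BN→ReLU→3×3×3 conv, growth-rate concatenation; 1×1×1
transition conv with 0.5 compression, in-plane pooling, dropout),
merges them, and ends in a 2-unit softmax.

## Known limitations

* Desk-scale networks are far smaller than the published ones; their
  absolute scores are not comparable to results on clinical data.
* The 3D cavity variant depends on boundary refinement to sharpen its
  upsampled mask; with very thin skulls and coarse voxels the stripe
  rule can admit extra-cranial soft tissue (mitigated by the physical
  band scaling above).
* Hard-negative mining can return nothing when stage 2 makes no false
  positives on healthy training subjects at its 0.5 operating point.
  The trainer then softens the mining threshold stepwise (0.25, 0.1,
  0.02) until negatives appear: the negative class remains the regions
  stage 2 scored most stroke-like, never random positions, and the
  inference threshold stays at 0.5. If even the softest point yields
  nothing, training fails with a clear error.
* NIfTI headers carry a single z spacing; per-slice thickness (mixed
  3/6 mm scans) survives in-memory and through CSV metadata but is
  averaged when a volume is written to NIfTI.
* The DICOM reader handles geometry and rescale tags only.
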