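# Methods

## Problem

Cone-beam CT (CBCT) is the workhorse modality for craniomaxillofacial
imaging.  Assessing the pharyngeal airway — its volume, its cross-sectional
area profile, and the caliber of its narrowest point — is a routine step in
evaluating patients with obstructive sleep apnea (OSA) and in orthognathic
planning, but manual or semi-automatic tracing is slow and
operator-dependent.  `airseg` implements an automatic pipeline: a
coarse-to-fine cascade of 3D U-Nets segments five craniomaxillofacial
structures (upper skull, mandible, maxillary teeth, mandibular teeth,
airway) plus background, the airway mask is converted into the standard
morphometric measurements, and an agreement module quantifies how well two
or more measurement methods concur.

## Two-stage segmentation model

Both stages solve multiclass semantic segmentation with a 3D U-Net
(encoder–decoder, two 3³ convolutions + instance norm + ReLU per level,
2³ max-pooling, 2× up-convolutions, skip connections by channel
concatenation, 1³ output head).  Channel widths double per level from
`base_channels`; depth and width are configurable so that desk-scale tests
can use tiny models while the production configuration uses the same code.

* **Coarse stage** — the whole volume is processed in a single forward pass
  at coarse spacing (production 1.0 mm isotropic).  Its training targets
  are *soft*: the ground-truth label map is one-hot encoded and each class
  channel is trilinearly downsampled, so every coarse voxel carries the
  partial-volume distribution over classes.  The loss consumes these
  distributions directly.
* **Fine stage** — patch-based at fine spacing (production 0.25 mm,
  patches 144³).  Its input has `C + 1` channels: the intensity channel
  plus the coarse model's class probabilities upsampled to the fine grid
  (the *coarse hint*), which injects global context into local patches.
  Targets are hard labels resampled by nearest neighbor.

Intensities are min–max normalized inside a fixed window of (−1000, 2000):
values are clipped and mapped to [0, 1].  CBCT intensities are HU-like but
uncalibrated, which is why a fixed generic window rather than per-scan
statistics is used.

### Loss

`L = CE + (1 − mean_c J_c)` where CE is voxel-averaged cross-entropy
against the (possibly soft) target distribution and

`J_c = (Σ p_c g_c + ε) / (Σ p_c + Σ g_c − Σ p_c g_c + ε)`,  ε = 1e−6,

is the soft Jaccard index of class `c` (softmax probabilities `p`, target
`g`, sums over all voxels of the sample).  The Jaccard mean runs over all
classes including background; the epsilon keeps empty classes finite and
the term bounded in [0, 1].  The Jaccard component counteracts the extreme
class imbalance (airway and teeth occupy a tiny voxel fraction).

### Optimization

Adam (β = 0.9/0.999) with a one-cycle schedule: linear warmup from
`min_lr = 1e−6` to `max_lr = 1e−3` over the first 5% of steps, then cosine
annealing back to `min_lr` at the last step.  Batch size is 1 — one whole
volume per step at the coarse stage, one patch per step at the fine stage.
Default budgets are 100 coarse and 40 fine epochs (the desk-scale
experiment uses 15/10).  After every epoch the development loss is
recorded; the returned checkpoint is the parameter snapshot with the
lowest development loss.

Fine-stage patches are drawn by a bounded shuffling queue: each epoch, 20
random patches per volume are pushed into a queue of capacity 180; once
full, patches are retrieved in random order while new ones are pushed.
Patch origins are uniform over valid positions (no foreground bias).
Volumes smaller than the patch are zero-padded — zero is normalized air,
and padded labels are background.

### Augmentation

Geometric transforms (rotation up to ±10°, scaling 0.9–1.1, random
crop-and-resize, elastic deformation) are applied identically to image
(linear) and labels (nearest; soft targets channelwise linear with
renormalization); intensity transforms (Gaussian blur, Gaussian noise,
simulated slice anisotropy) touch only the intensity channel.  Each
transform fires with probability 0.25.  The fine stage skips elastic
deformation and anisotropy, which are disproportionately expensive on
large fine-resolution grids.  Augmentation operates on whole volumes
before patch sampling.

### Leakage-free hints

Hints for *training* subjects must not come from a coarse model that saw
them.  Training subjects are split into k = 3 folds; three coarse models
are trained, each on two folds, and a subject's hint is produced by the
model of its own fold.  `generate_hints` enforces this with a hard runtime
audit.  Development, test and inference subjects receive hints from the
coarse model trained on all training data — leak-free by construction.
Fold models are checkpoint-selected on the global development split, never
on their held-out fold, so checkpoint selection cannot leak either.

### Inference

The coarse stage runs on the whole volume (padded to the network's
divisibility requirement).  The fine stage tiles the volume with stride
`patch − overlap` (default overlap 16 voxels; the last tile per axis is
shifted inward to end at the boundary) and fuses per-patch softmax
probabilities with a separable squared-sine (Hann) weight map floored at
1% of its peak, so center voxels — where patch predictions are most
reliable — dominate and tile seams are suppressed.  Probabilities, not
logits, are averaged: that preserves the per-voxel probability simplex.
Final labels are the per-voxel argmax with ties broken toward the lowest
class index.

## Morphometry

From a segmentation, the airway class is restricted to an axial interval
(`AirwayBounds`, physical mm) and the largest 26-connected component is
kept.  The bounds stand in for the anatomical landmark planes used
clinically (palatal plane above, second-vertebra level below); automatic
landmark detection is out of scope, so the bounds are supplied by the
user or the experiment configuration.  Reported quantities:

* **volume (cc)** — voxel count × voxel volume / 1000;
* **cross-sectional areas (mm²)** — per axial slice, voxel count × in-plane
  voxel area; the **minimum CSA** is the smallest nonzero slice area (ties:
  lowest slice);
* **narrowest point (mm)** — a linear caliber of the largest in-plane
  8-connected component at the minimal-area slice.  The default is the
  anteroposterior (y) extent; mediolateral extent and equivalent diameter
  are selectable, since different clinical tools define the "narrow point
  distance" differently.

Surfaces are exported as STL via marching cubes at the 0.5 iso-level on a
one-voxel zero-padded mask (so boundary-touching masks still produce
closed surfaces), with vertices in mm.

## Agreement statistics

Methods are compared as raters in a two-way mixed-effects ANOVA;
reliability is ICC(3,1) — single-rater consistency:
`(MS_subjects − MS_error) / (MS_subjects + (k−1) MS_error)`.  Values above
0.75 are classified *good* and above 0.90 *excellent*.  The consistency
form is deliberately insensitive to a constant per-method offset; the
absolute-agreement question is answered separately by the location tests.
Location differences use the Mann–Whitney U test between two methods
(min-U convention, midrank ties; exact p by full enumeration when both
samples have ≤ 8 observations, otherwise a tie-corrected normal
approximation without continuity correction — chosen so the two-group
Kruskal–Wallis chi-square p coincides exactly, H = z²) and the
Kruskal–Wallis H test among three or more.  Significance is flagged at
α = 0.05.  These tests are implemented from their defining formulas and
cross-checked in the test suite against scipy, pingouin and brute-force
enumeration.

## Synthetic phantoms

The phantom generator provides ground-truth-complete stand-ins for patient
CBCT: an ellipsoidal head of soft tissue (background class), a calvarial
shell, an anterior mandible arc, two tooth rows, and a curved vertical
airway tube whose radius tapers quadratically from ~6 mm at the ends to a
~3 mm waist at a configurable height.  Mean intensities are CBCT-like
(air −1000, soft tissue 40, bone 1200, teeth 1800) with additive Gaussian
noise (SD 30); labels are exactly consistent with the painted geometry.
Cohorts vary waist/end radii, waist height and tube sway per subject.  An
optional "epiglottis flap" paints soft tissue into the lumen at the waist,
shrinking the minimal CSA by a configured fraction — a geometric analogue
of the soft-tissue confounders that bias automatic airway measurements in
real CBCT.

What the phantoms do **not** emulate: beam hardening, scatter, metal
artifacts, anatomically realistic skull shapes, or soft-tissue contrast
ambiguity.  Passing the phantom suite therefore demonstrates that the
pipeline's machinery (resampling, targets, training, hints, tiled fusion,
morphometry, statistics) is correct — not that the trained toy models
would transfer to patients.

## Desk-scale experiment

The standard experiment (`ExperimentConfig`) trains on 12 phantoms of 64³
voxels at 1.0 mm: coarse stage at 2.0 mm, fine stage at 1.0 mm, base-8
depth-3 U-Nets, 32³ patches with overlap 16, 15 coarse and 10 fine epochs,
and a 90/5/5 train/dev/test split (10/1/1 subjects).  These sizes keep a
full run on a single CPU core in the tens of minutes while exercising every
code path of the production configuration.  Held-out evaluation reports
airway Dice against ground truth and the airway measurements inside the
phantom's axial bounds (the tube's open ends are excluded, as the landmark
planes do clinically — an end slice clipped by the field of view would
otherwise masquerade as the narrow point).

The networks and their training loop are implemented directly on numpy
(im2col convolutions with hand-derived backward passes, hand-written Adam);
gradients are verified against finite differences and the convolution
against an independent correlation routine in the test suite.

## Numerical conventions

* Voxel indices are 0-based; a voxel's physical center is
  `origin + index · spacing`; resampling samples at output voxel centers
  with edge clamping; output shape is `ceil(extent / target_spacing)`.
* Axis order is `(z, y, x)` everywhere; NIfTI/DICOM I/O transposes to this
  canonical order and keeps only voxel spacing from the orientation
  metadata.
* Soft probability fields are clipped to [0, 1] and renormalized after
  interpolation; trilinear interpolation preserves the simplex exactly in
  exact arithmetic, renormalization absorbs float drift.
* Argmax ties break toward the lowest class index (numpy convention),
  making background win exact ties.
* All randomness flows through explicitly passed seeded generators; two
  runs with the same seed produce identical losses, checkpoints and
  predictions on the same machine.

## Known limitations

* DICOM reading assumes an axial, non-oblique, single-series directory;
  full orientation handling is out of scope.
* The narrow-point linear measure is convention-dependent; compare numbers
  across tools only after fixing the same convention.
* MWU is an unpaired test; for genuinely paired method comparisons a
  signed-rank test would have more power.  The unpaired form is provided
  because it is the battery's standard component; the pairing limitation
  is inherent to that choice.
* The numpy network engine targets correctness and CPU-scale experiments,
  not GPU-scale training throughput.
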