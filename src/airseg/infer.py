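"""Sliding-window inference and the full two-stage pipeline.

A volume is tiled into overlapping patches (minimum overlap 16 voxels per
axis by default); per-patch softmax probabilities are fused with a
center-heavy separable Hann weight map, so border voxels — where patch
predictions are least reliable — contribute least.  The full pipeline runs
the coarse model on the whole volume at coarse spacing, upsamples its
probabilities to the fine spacing as a hint, and refines patch-by-patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .hints import concat_hint, interpolate_hint
from .net3d import UNet3D
from .targets import SoftLabelVolume
from .volumes import (DEFAULT_WINDOW, LabelVolume, Volume, _as_triple,
                      normalize_intensity, resample)

DEFAULT_OVERLAP = 16


def _as_int_triple(x):
    arr = np.broadcast_to(np.asarray(x, dtype=int), (3,))
    return (int(arr[0]), int(arr[1]), int(arr[2]))


@dataclass
class TilingPlan:
    """Overlapping-patch geometry for one volume."""

    patch_size: tuple[int, int, int]
    overlap: int
    origins: list
    padded_shape: tuple[int, int, int]
    original_shape: tuple[int, int, int]


def plan_tiles(shape, patch_size, overlap: int = DEFAULT_OVERLAP) -> TilingPlan:
    """Plan tile origins so every voxel is covered and the overlap between
    consecutive tiles is at least ``overlap`` voxels per axis.

    The stride is ``patch - overlap``; the last tile on each axis is shifted
    inward to end exactly at the boundary.  Volumes smaller than the patch
    are padded up to the patch size.
    """
    shape = _as_int_triple(shape)
    patch = _as_int_triple(patch_size)
    if any(overlap >= p for p in patch):
        raise ValueError(f"overlap {overlap} must be < patch size {patch}")
    padded = tuple(max(s, p) for s, p in zip(shape, patch))
    per_axis = []
    for s, p in zip(padded, patch):
        stride = p - overlap
        origins = list(range(0, s - p + 1, stride))
        if origins[-1] + p < s:
            origins.append(s - p)
        per_axis.append(origins)
    origins = [(z, y, x) for z in per_axis[0] for y in per_axis[1]
               for x in per_axis[2]]
    return TilingPlan(patch, overlap, origins, padded, shape)


def make_weight_map(patch_size) -> np.ndarray:
    """Separable Hann (squared-sine) weight map, floored at 1% of its peak.

    Strictly positive, symmetric under axis reflection and maximal at the
    patch center.
    """
    patch = _as_int_triple(patch_size)
    if any(p < 2 for p in patch):
        raise ValueError("patch size must be >= 2 per axis")
    axes = [np.sin(np.pi * (np.arange(p) + 0.5) / p) ** 2 for p in patch]
    w = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return np.maximum(w, 0.01 * w.max()).astype(np.float64)


def aggregate(patch_preds, plan: TilingPlan, weights: np.ndarray,
              spacing=(1.0, 1.0, 1.0)) -> SoftLabelVolume:
    """Fuse per-patch probability maps into a volume by weighted averaging.

    Every voxel's output is the weight-normalized average of all patches
    covering it; the result is cropped back to the unpadded shape.
    """
    patch_preds = list(patch_preds)
    if len(patch_preds) != len(plan.origins):
        raise ValueError(
            f"{len(patch_preds)} predictions for {len(plan.origins)} tiles")
    c = patch_preds[0].shape[0]
    num = np.zeros((c,) + plan.padded_shape, dtype=np.float64)
    den = np.zeros(plan.padded_shape, dtype=np.float64)
    for pred, (oz, oy, ox) in zip(patch_preds, plan.origins):
        sl = (slice(oz, oz + plan.patch_size[0]),
              slice(oy, oy + plan.patch_size[1]),
              slice(ox, ox + plan.patch_size[2]))
        num[(slice(None),) + sl] += weights * pred
        den[sl] += weights
    probs = num / den
    crop = tuple(slice(0, s) for s in plan.original_shape)
    return SoftLabelVolume(probs[(slice(None),) + crop].astype(np.float32),
                           spacing, validate=False)


def predict_whole_volume(model: UNet3D, data: np.ndarray) -> np.ndarray:
    """Single forward pass over a whole volume, padding spatial dims up to
    the model's divisibility requirement (padded with 0 = normalized air)."""
    div = model.cfg.divisor
    shape = data.shape
    padded = tuple(-(-s // div) * div for s in shape)
    if padded != shape:
        x = np.zeros(padded, dtype=np.float32)
        x[:shape[0], :shape[1], :shape[2]] = data
    else:
        x = np.asarray(data, dtype=np.float32)
    probs = model.predict_probs(x[None])
    return probs[:, :shape[0], :shape[1], :shape[2]]


@dataclass
class PipelineConfig:
    """Spacings and tiling geometry of the two-stage pipeline.

    Production defaults follow the tool's intended operating point
    (1.0 mm coarse / 0.25 mm fine, 144^3 patches); desk-scale runs shrink
    all three.
    """

    coarse_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fine_spacing: tuple[float, float, float] = (0.25, 0.25, 0.25)
    patch_size: int = 144
    overlap: int = DEFAULT_OVERLAP
    window: tuple[float, float] = DEFAULT_WINDOW

    def __post_init__(self):
        self.coarse_spacing = _as_triple(self.coarse_spacing)
        self.fine_spacing = _as_triple(self.fine_spacing)


def predict_volume(v: Volume, coarse_model: UNet3D, fine_model: UNet3D,
                   cfg: PipelineConfig | None = None) -> LabelVolume:
    """Run the full coarse-to-fine pipeline on one volume.

    normalize -> resample to coarse spacing -> coarse forward (whole volume)
    -> hint interpolation to fine spacing -> concat with fine-resampled
    intensity -> tiled fine inference -> center-weighted aggregation ->
    per-voxel argmax (ties to the lowest class index).
    """
    cfg = cfg or PipelineConfig()
    norm = normalize_intensity(v, cfg.window)
    coarse_img = resample(norm, cfg.coarse_spacing, mode="linear")
    coarse_probs = predict_whole_volume(coarse_model, coarse_img.data)

    fine_img = resample(norm, cfg.fine_spacing, mode="linear")
    hint = interpolate_hint(coarse_probs, coarse_img.spacing, cfg.fine_spacing,
                            output_shape=fine_img.shape)
    x = concat_hint(fine_img, hint)

    plan = plan_tiles(fine_img.shape, cfg.patch_size, cfg.overlap)
    if plan.padded_shape != fine_img.shape:
        xp = np.zeros((x.shape[0],) + plan.padded_shape, dtype=np.float32)
        xp[:, :x.shape[1], :x.shape[2], :x.shape[3]] = x
        xp[1, x.shape[1]:, :, :] = 1.0  # padded voxels hinted as background
        xp[1, :, x.shape[2]:, :] = 1.0
        xp[1, :, :, x.shape[3]:] = 1.0
        x = xp
    weights = make_weight_map(cfg.patch_size)
    preds = []
    for oz, oy, ox in plan.origins:
        patch = x[:, oz:oz + plan.patch_size[0], oy:oy + plan.patch_size[1],
                  ox:ox + plan.patch_size[2]]
        preds.append(fine_model.predict_probs(patch))
    soft = aggregate(preds, plan, weights, spacing=cfg.fine_spacing)
    labels = np.argmax(soft.probs, axis=0).astype(np.int16)
    return LabelVolume(labels, cfg.fine_spacing, fine_model.cfg.num_classes,
                       v.origin)
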