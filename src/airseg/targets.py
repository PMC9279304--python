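"""Coarse soft targets and fine hard targets from ground-truth labels.

The coarse stage is trained against *soft targets*: the ground-truth class
map is one-hot encoded to a ``C x D x H x W`` tensor and each channel is
linearly interpolated down to the coarse voxel spacing.  Each coarse voxel
then carries a probability distribution over classes that reflects the
partial-volume mix of the fine voxels it covers.  The fine stage uses hard
labels obtained by nearest-neighbor interpolation at the fine spacing.
"""

from __future__ import annotations

import numpy as np

from .volumes import LabelVolume, _as_triple, resample_grid


class SoftLabelVolume:
    """Per-class probability field of shape ``(C, D, H, W)``.

    Invariant: probabilities are nonnegative and sum to 1 over the class
    axis at every voxel (within 1e-5).
    """

    def __init__(self, probs: np.ndarray, spacing, origin=(0.0, 0.0, 0.0), *, validate: bool = True):
        probs = np.asarray(probs, dtype=np.float32)
        if probs.ndim != 4:
            raise ValueError(f"probs must be 4D (C, D, H, W), got {probs.shape}")
        if validate:
            if probs.min() < -1e-6:
                raise ValueError("probabilities must be nonnegative")
            sums = probs.sum(axis=0)
            if np.abs(sums - 1.0).max() > 1e-4:
                raise ValueError("per-voxel class probabilities must sum to 1")
        self.probs = probs
        self.spacing = _as_triple(spacing)
        self.origin = _as_triple(origin)

    @property
    def num_classes(self) -> int:
        return self.probs.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probs.shape[1:]

    def argmax_labels(self, num_classes: int | None = None) -> LabelVolume:
        """Hard labels by per-voxel argmax (ties go to the lowest class index)."""
        return LabelVolume(
            np.argmax(self.probs, axis=0).astype(np.int16),
            self.spacing,
            num_classes or self.num_classes,
            self.origin,
        )


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """One-hot encode a 3D label grid into a ``(C, D, H, W)`` float tensor."""
    out = np.zeros((num_classes,) + labels.shape, dtype=np.float32)
    for c in range(num_classes):
        out[c] = labels == c
    return out


def make_soft_targets(gt: LabelVolume, coarse_spacing=1.0) -> SoftLabelVolume:
    """Downsample one-hot ground truth to soft class distributions.

    Each class channel is trilinearly interpolated to ``coarse_spacing``;
    since interpolation is linear, the channels still sum to 1 at every
    output voxel (up to float rounding).
    """
    if gt.labels.size == 0:
        raise ValueError("empty label volume")
    target = _as_triple(coarse_spacing)
    hot = one_hot(gt.labels, gt.num_classes)
    channels = [
        resample_grid(hot[c], gt.spacing, target, mode="linear")
        for c in range(gt.num_classes)
    ]
    probs = np.clip(np.stack(channels), 0.0, 1.0)
    probs /= probs.sum(axis=0, keepdims=True)
    return SoftLabelVolume(probs, target, gt.origin)


def make_fine_targets(gt: LabelVolume, fine_spacing=0.25) -> LabelVolume:
    """Resample ground-truth labels to the fine spacing by nearest neighbor."""
    target = _as_triple(fine_spacing)
    if any(t <= 0 for t in target):
        raise ValueError(f"fine spacing must be positive, got {target}")
    out = resample_grid(gt.labels, gt.spacing, target, mode="nearest")
    return LabelVolume(out.astype(gt.labels.dtype), target, gt.num_classes, gt.origin)


def write_soft_targets(soft: SoftLabelVolume, path) -> None:
    """Persist soft targets as a 4D NIfTI (x, y, z, channel on disk)."""
    import nibabel as nib

    from .volumes import _nifti_affine

    arr = soft.probs.transpose(3, 2, 1, 0)  # (C,D,H,W) -> (x,y,z,C)
    img = nib.Nifti1Image(arr.astype(np.float32), _nifti_affine(soft.spacing, soft.origin))
    nib.save(img, str(path))


def read_soft_targets(path) -> SoftLabelVolume:
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4:
        raise ValueError("soft targets must be a 4D NIfTI")
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(t) for t in img.affine[:3, 3][::-1])
    return SoftLabelVolume(arr.transpose(3, 2, 1, 0), spacing, origin)
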