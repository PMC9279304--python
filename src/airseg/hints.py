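"""Leakage-free coarse hints for the fine stage.

The fine model receives the coarse model's class probabilities, upsampled
to the fine spacing, as extra input channels.  For *training* subjects the
hint must come from a coarse model that never saw that subject, so coarse
models are trained in k-fold cross-validation (k = 3) and each subject's
hint is produced by the model of its own fold (trained on the other folds).
Subjects outside the cross-validation (dev/test/inference) get their hint
from the coarse model trained on all training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .net3d import UNet3D
from .targets import SoftLabelVolume
from .volumes import Volume, _as_triple, resample_grid


@dataclass
class FoldAssignment:
    """Mapping subject id -> fold index, with fold sizes differing by <= 1."""

    folds: dict
    k: int

    def ids_in_fold(self, f: int) -> list:
        return [i for i, ff in self.folds.items() if ff == f]

    def training_ids_for_fold(self, f: int) -> list:
        """Subjects the fold-f model is trained on (everything *outside* f)."""
        return [i for i, ff in self.folds.items() if ff != f]


def kfold_split(ids, k: int = 3, seed: int = 0) -> FoldAssignment:
    """Balanced, seed-reproducible k-fold assignment of subject ids."""
    ids = list(ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} ids for {k}-fold split, got {len(ids)}")
    order = np.random.default_rng(seed).permutation(len(ids))
    folds = {ids[int(j)]: int(pos % k) for pos, j in enumerate(order)}
    return FoldAssignment(folds, k)


def interpolate_hint(probs: np.ndarray, spacing, fine_spacing,
                     output_shape=None) -> SoftLabelVolume:
    """Linearly interpolate a coarse probability map to the fine spacing.

    Channels are interpolated independently, then clipped to [0, 1] and
    renormalized to absorb float drift (trilinear interpolation preserves
    the simplex in exact arithmetic).
    """
    fine = _as_triple(fine_spacing)
    channels = [
        resample_grid(probs[c], spacing, fine, mode="linear",
                      output_shape=output_shape)
        for c in range(probs.shape[0])
    ]
    out = np.clip(np.stack(channels), 0.0, 1.0)
    out /= np.maximum(out.sum(axis=0, keepdims=True), 1e-8)
    return SoftLabelVolume(out, fine)


def generate_hints(images: dict, assignment: FoldAssignment,
                   fold_models: dict, fine_spacing,
                   output_shapes: dict | None = None) -> dict:
    """Out-of-fold coarse hints for every cross-validated subject.

    Parameters
    ----------
    images
        subject id -> normalized coarse-spacing :class:`Volume`.
    assignment
        The k-fold assignment used to train ``fold_models``.
    fold_models
        fold index -> coarse :class:`UNet3D` trained on ids outside the fold.
    fine_spacing
        Target spacing (mm) of the hint.
    output_shapes
        Optional subject id -> exact fine-grid shape to interpolate onto.

    Each subject's hint is computed by the model of its *own* fold — the one
    model guaranteed never to have seen it.
    """
    from .infer import predict_whole_volume

    hints = {}
    for sid, vol in images.items():
        if sid not in assignment.folds:
            raise KeyError(f"subject {sid!r} has no fold assignment")
        f = assignment.folds[sid]
        if f not in fold_models:
            raise KeyError(f"missing coarse model for fold {f}")
        if sid in fold_models[f].train_ids:
            raise RuntimeError(
                f"leakage: subject {sid!r} is in the training set of its "
                f"hint-producing fold model {f}")
        probs = predict_whole_volume(fold_models[f].model, vol.data)
        shape = output_shapes.get(sid) if output_shapes else None
        hints[sid] = interpolate_hint(probs, vol.spacing, fine_spacing, shape)
    return hints


@dataclass
class FoldModel:
    """A coarse checkpoint bundled with the subject ids it was trained on."""

    model: UNet3D
    train_ids: frozenset = field(default_factory=frozenset)


def concat_hint(image: Volume, hint: SoftLabelVolume) -> np.ndarray:
    """Stack intensity (channel 0) and hint probabilities (channels 1..C)."""
    if image.shape != hint.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs hint {hint.shape}")
    if not np.allclose(image.spacing, hint.spacing, rtol=1e-6):
        raise ValueError(f"spacing mismatch: {image.spacing} vs {hint.spacing}")
    return np.concatenate(
        [image.data[None].astype(np.float32), hint.probs.astype(np.float32)], axis=0)
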