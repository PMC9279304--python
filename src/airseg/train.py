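"""Training machinery for the two segmentation stages.

The coarse stage trains on whole volumes at coarse spacing against soft
targets; the fine stage trains on randomly sampled patches against hard
labels, with the coarse hint concatenated to the intensity channel.  Both
use Adam with a one-cycle learning-rate schedule (linear warmup, cosine
annealing) and keep the parameter snapshot with the lowest validation loss.

The loss is the sum of cross-entropy and a soft multiclass Jaccard term::

    L = CE + (1 - mean_c J_c),
    J_c = (sum p_c g_c + eps) / (sum p_c + sum g_c - sum p_c g_c + eps)

where ``p`` are softmax probabilities and ``g`` the target distribution
(a one-hot for hard labels).  CE is averaged over voxels; the Jaccard mean
runs over all classes including background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .net3d import UNet3D

JACCARD_EPS = 1e-6


@dataclass
class TrainConfig:
    """Optimization hyperparameters shared by both stages."""

    epochs: int = 100
    max_lr: float = 1e-3
    min_lr: float = 1e-6
    warmup_frac: float = 0.05
    batch_size: int = 1
    patch_size: int = 144
    samples_per_volume: int = 20
    queue_capacity: int = 180
    seed: int = 0
    split_fracs: tuple[float, float, float] = (0.90, 0.05, 0.05)

    def __post_init__(self):
        if not 0 < self.warmup_frac < 1:
            raise ValueError("warmup_frac must be in (0, 1)")
        if self.min_lr >= self.max_lr:
            raise ValueError("min_lr must be < max_lr")
        if self.queue_capacity < self.samples_per_volume:
            raise ValueError("queue_capacity must be >= samples_per_volume")


# ---------------------------------------------------------------------------
# Dataset split
# ---------------------------------------------------------------------------

def split_dataset(ids, fracs=(0.90, 0.05, 0.05), seed: int = 0):
    """Randomly partition subject ids into (train, dev, test) lists.

    Split sizes are the rounded fractions of ``len(ids)`` for dev and test
    (at least 1 each when the fraction is nonzero), with the remainder going
    to train.  Reproducible for a given seed.
    """
    ids = list(ids)
    n = len(ids)
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_dev = max(int(math.floor(n * fracs[1] + 0.5)), 1 if fracs[1] > 0 else 0)
    n_test = max(int(math.floor(n * fracs[2] + 0.5)), 1 if fracs[2] > 0 else 0)
    n_train = n - n_dev - n_test
    if n_train < 1:
        raise ValueError(f"too few ids ({n}) to populate all splits")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    return (shuffled[:n_train],
            shuffled[n_train:n_train + n_dev],
            shuffled[n_train + n_dev:])


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def _target_probs(target: np.ndarray, num_classes: int) -> np.ndarray:
    """Accept a 3D hard-label grid or a 4D probability grid; return (C, ...)."""
    target = np.asarray(target)
    if target.ndim == 3:
        if np.issubdtype(target.dtype, np.integer):
            if target.size and (target.min() < 0 or target.max() >= num_classes):
                raise ValueError("target class out of range")
            g = np.zeros((num_classes,) + target.shape, dtype=np.float32)
            for c in range(num_classes):
                g[c] = target == c
            return g
        raise ValueError("3D targets must be integer class labels")
    if target.ndim == 4:
        if target.shape[0] != num_classes:
            raise ValueError("target channel count mismatch")
        return target.astype(np.float32, copy=False)
    raise ValueError(f"target must be 3D labels or 4D probabilities, got {target.ndim}D")


def combined_loss(scores: np.ndarray, target: np.ndarray) -> float:
    """Cross-entropy plus soft multiclass Jaccard loss (scalar, >= 0)."""
    loss, _ = combined_loss_and_grad(scores, target, need_grad=False)
    return loss


def combined_loss_and_grad(scores: np.ndarray, target: np.ndarray,
                           need_grad: bool = True):
    """Return ``(loss, dloss/dscores)``; gradient is None if not requested."""
    scores = np.asarray(scores)
    if not np.issubdtype(scores.dtype, np.floating):
        scores = scores.astype(np.float32)
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError("non-finite network scores")
    c = scores.shape[0]
    g = _target_probs(target, c)
    p = nn.Softmax.forward(scores).astype(np.float64)
    g64 = g.astype(np.float64)
    nvox = p[0].size

    logp = np.log(np.maximum(p, 1e-12))
    ce = -float((g64 * logp).sum() / nvox)

    inter = (p * g64).sum(axis=tuple(range(1, p.ndim)))
    psum = p.sum(axis=tuple(range(1, p.ndim)))
    gsum = g64.sum(axis=tuple(range(1, p.ndim)))
    num = inter + JACCARD_EPS
    den = psum + gsum - inter + JACCARD_EPS
    jac = num / den
    loss = ce + float(1.0 - jac.mean())

    if not need_grad:
        return loss, None

    # dCE/dscores via softmax: (p - g) / nvox
    dscores = (p - g64) / nvox
    # dJaccard/dp_c = (g*den - num*(1-g)) / den^2 ; loss term is -mean_c J_c
    shape = (c,) + (1,) * (p.ndim - 1)
    djac_dp = (g64 * den.reshape(shape) - num.reshape(shape) * (1.0 - g64)) \
        / (den.reshape(shape) ** 2)
    dloss_dp = -djac_dp / c
    dscores += p * (dloss_dp - (p * dloss_dp).sum(axis=0, keepdims=True))
    return loss, dscores.astype(scores.dtype)


# ---------------------------------------------------------------------------
# Learning-rate schedule
# ---------------------------------------------------------------------------

def one_cycle_lr(step: int, total_steps: int, cfg: TrainConfig) -> float:
    """One-cycle schedule: linear warmup to ``max_lr`` over the first
    ``warmup_frac`` of training, then cosine annealing to ``min_lr`` at the
    final step."""
    if total_steps < 2:
        raise ValueError("total_steps must be >= 2")
    if not 0 <= step < total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps})")
    warm = int(math.floor(cfg.warmup_frac * total_steps + 0.5))
    warm = min(warm, total_steps - 2)
    if step <= warm:
        if warm == 0:
            return cfg.max_lr
        return cfg.min_lr + (cfg.max_lr - cfg.min_lr) * step / warm
    frac = (step - warm) / (total_steps - 1 - warm)
    return cfg.min_lr + (cfg.max_lr - cfg.min_lr) * 0.5 * (1.0 + math.cos(math.pi * frac))


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    """Probabilities and parameter ranges for the training augmentations.

    Geometric transforms (rotation, scaling, crop, elastic deformation) are
    applied identically to the image (linear interpolation) and to the
    labels (nearest); intensity transforms (blur, noise, anisotropy) touch
    the intensity channel only.  The fine stage never applies elastic
    deformation or anisotropy.
    """

    p_blur: float = 0.25
    blur_sigma: tuple[float, float] = (0.3, 1.0)
    p_noise: float = 0.25
    noise_sd: tuple[float, float] = (0.01, 0.05)
    p_rotate: float = 0.25
    rotate_degrees: float = 10.0
    p_scale: float = 0.25
    scale_range: tuple[float, float] = (0.9, 1.1)
    p_crop: float = 0.25
    crop_frac: tuple[float, float] = (0.8, 1.0)
    p_elastic: float = 0.25
    elastic_max_disp: float = 2.0
    elastic_grid: int = 4
    p_aniso: float = 0.25
    aniso_factor: tuple[float, float] = (1.5, 3.0)


def _geom_apply(image, labels, func):
    """Apply a geometric transform to every image channel (linear) and to
    the label grid (nearest for hard labels, linear per channel for soft)."""
    img_out = np.stack([func(ch, 1) for ch in image])
    if labels.ndim == 3:
        lab_out = func(labels, 0)
    else:
        lab_out = np.stack([func(ch, 1) for ch in labels])
        s = lab_out.sum(axis=0, keepdims=True)
        lab_out = np.where(s > 0, lab_out / np.maximum(s, 1e-8), lab_out)
    return img_out, lab_out


def augment(image: np.ndarray, labels: np.ndarray, stage: str,
            rng: np.random.Generator, cfg: AugmentConfig | None = None):
    """Randomly augment one (image, label) pair; reproducible given ``rng``.

    ``image`` is ``(C, D, H, W)`` (channel 0 is intensity) or ``(D, H, W)``;
    ``labels`` is a 3D hard-label grid or a 4D soft-target grid.
    """
    cfg = cfg or AugmentConfig()
    squeeze = image.ndim == 3
    if squeeze:
        image = image[None]
    image = image.astype(np.float32, copy=True)
    labels = np.asarray(labels).copy()
    shape = image.shape[1:]

    if rng.random() < cfg.p_rotate:
        axes = [(1, 2), (0, 2), (0, 1)][rng.integers(3)]
        angle = float(rng.uniform(-cfg.rotate_degrees, cfg.rotate_degrees))
        image, labels = _geom_apply(
            image, labels,
            lambda a, o: ndimage.rotate(a, angle, axes=axes, reshape=False,
                                        order=o, mode="nearest"))

    if rng.random() < cfg.p_scale:
        s = float(rng.uniform(*cfg.scale_range))
        center = (np.asarray(shape) - 1) / 2.0
        matrix = np.eye(3) / s
        offset = center - matrix @ center
        image, labels = _geom_apply(
            image, labels,
            lambda a, o: ndimage.affine_transform(a, matrix, offset=offset,
                                                  order=o, mode="nearest"))

    if rng.random() < cfg.p_crop:
        fracs = rng.uniform(cfg.crop_frac[0], cfg.crop_frac[1], 3)
        crop = np.maximum((np.asarray(shape) * fracs).astype(int), 4)
        starts = [int(rng.integers(0, s - c + 1)) for s, c in zip(shape, crop)]
        sl = tuple(slice(st, st + c) for st, c in zip(starts, crop))
        zoom = [s / c for s, c in zip(shape, crop)]

        def crop_resize(a, o, sl=sl, zoom=zoom):
            out = ndimage.zoom(a[sl], zoom, order=o, mode="nearest",
                               grid_mode=True)
            return _fit_shape(out, shape)

        image, labels = _geom_apply(image, labels, crop_resize)

    if stage == "coarse" and rng.random() < cfg.p_elastic:
        disp = [
            ndimage.zoom(rng.normal(0, cfg.elastic_max_disp / 2,
                                    (cfg.elastic_grid,) * 3),
                         np.asarray(shape) / cfg.elastic_grid, order=3,
                         mode="nearest", grid_mode=True)
            for _ in range(3)
        ]
        coords = np.meshgrid(*[np.arange(s, dtype=np.float32) for s in shape],
                             indexing="ij")
        warp = np.stack([c + _fit_shape(d, shape) for c, d in zip(coords, disp)])

        def elastic(a, o, warp=warp):
            return ndimage.map_coordinates(a, warp, order=o, mode="nearest")

        image, labels = _geom_apply(image, labels, elastic)

    if stage == "coarse" and rng.random() < cfg.p_aniso:
        axis = int(rng.integers(3))
        f = float(rng.uniform(*cfg.aniso_factor))
        zoom_down = [1.0] * 3
        zoom_down[axis] = 1.0 / f
        small = ndimage.zoom(image[0], zoom_down, order=1, mode="nearest")
        back = ndimage.zoom(small, [s / t for s, t in zip(shape, small.shape)],
                            order=1, mode="nearest", grid_mode=True)
        image[0] = _fit_shape(back, shape)

    if rng.random() < cfg.p_blur:
        sigma = float(rng.uniform(*cfg.blur_sigma))
        image[0] = ndimage.gaussian_filter(image[0], sigma)

    if rng.random() < cfg.p_noise:
        sd = float(rng.uniform(*cfg.noise_sd))
        image[0] = image[0] + rng.normal(0, sd, shape).astype(np.float32)

    if squeeze:
        image = image[0]
    return image.astype(np.float32), labels


def _fit_shape(a: np.ndarray, shape) -> np.ndarray:
    """Crop or edge-pad an array to an exact shape (zoom rounding can be off
    by one voxel)."""
    out = a
    for ax, s in enumerate(shape):
        if out.shape[ax] > s:
            out = np.take(out, range(s), axis=ax)
        elif out.shape[ax] < s:
            pad = [(0, 0)] * out.ndim
            pad[ax] = (0, s - out.shape[ax])
            out = np.pad(out, pad, mode="edge")
    return out


# ---------------------------------------------------------------------------
# Patch sampling
# ---------------------------------------------------------------------------

def _pad_to_patch(image: np.ndarray, target: np.ndarray, patch: int):
    """Zero-pad (air intensity, background label) so every axis >= patch.
    Multi-channel inputs carry hint probabilities in channels 1..C: padded
    voxels there are marked as background (channel 1 set to 1)."""
    shape = image.shape[1:]
    pads = [max(patch - s, 0) for s in shape]
    if not any(pads):
        return image, target
    pw = [(0, 0)] + [(p // 2, p - p // 2) for p in pads]
    orig_shape = shape
    image = np.pad(image, pw, constant_values=0.0)
    if image.shape[0] > 1:
        interior = np.zeros(image.shape[1:], dtype=bool)
        interior[tuple(slice(lo, lo + s)
                       for (lo, _hi), s in zip(pw[1:], orig_shape))] = True
        image[1][~interior] = 1.0
    if target.ndim == 3:
        target = np.pad(target, pw[1:], constant_values=0)
    else:
        target = np.pad(target, [(0, 0)] + pw[1:], constant_values=0.0)
        target[0] = np.where(target.sum(axis=0) == 0, 1.0, target[0])
    return image, target


class PatchQueue:
    """Random patch sampler emulating a bounded shuffling queue.

    Per epoch, ``samples_per_volume`` patches are drawn uniformly from every
    volume and pushed into a queue of bounded capacity; once the queue is
    full, patches are retrieved in random order while new ones are pushed.
    ``max_occupancy`` records the high-water mark for auditing.
    """

    def __init__(self, volumes, cfg: TrainConfig, rng: np.random.Generator,
                 patch_size: int | None = None):
        if not volumes:
            raise ValueError("at least one volume required")
        self.volumes = volumes
        self.cfg = cfg
        self.rng = rng
        self.patch = patch_size or cfg.patch_size
        self.max_occupancy = 0

    def _sample_one(self, vol_idx):
        image, target = self.volumes[vol_idx]
        image = image if image.ndim == 4 else image[None]
        image, target = _pad_to_patch(image, target, self.patch)
        shape = image.shape[1:]
        oz, oy, ox = (int(self.rng.integers(0, s - self.patch + 1)) for s in shape)
        sl = (slice(oz, oz + self.patch), slice(oy, oy + self.patch),
              slice(ox, ox + self.patch))
        img_p = image[(slice(None),) + sl]
        tgt_p = target[sl] if target.ndim == 3 else target[(slice(None),) + sl]
        return img_p, tgt_p, {"volume": vol_idx, "origin": (oz, oy, ox)}

    def __iter__(self):
        queue: list = []
        order = self.rng.permutation(len(self.volumes))
        for vol_idx in order:
            for _ in range(self.cfg.samples_per_volume):
                queue.append(self._sample_one(int(vol_idx)))
                self.max_occupancy = max(self.max_occupancy, len(queue))
                if len(queue) >= self.cfg.queue_capacity:
                    yield queue.pop(int(self.rng.integers(len(queue))))
        while queue:
            yield queue.pop(int(self.rng.integers(len(queue))))


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def best_epoch_index(dev_losses) -> int:
    """Index of the epoch with the lowest validation loss (first on ties)."""
    return int(np.argmin(np.asarray(dev_losses)))


@dataclass
class TrainingResult:
    """Best parameter snapshot plus the per-epoch training log."""

    params: list
    best_epoch: int
    log: list = field(default_factory=list)  # (epoch, train_loss, dev_loss, lr)

    def dev_losses(self):
        return [row[2] for row in self.log]


def _dev_patches(image, target, patch: int):
    """Deterministic non-overlapping tiling of a dev volume for evaluation."""
    image = image if image.ndim == 4 else image[None]
    image, target = _pad_to_patch(image, target, patch)
    shape = image.shape[1:]
    out = []
    for oz in range(0, shape[0] - patch + 1, patch):
        for oy in range(0, shape[1] - patch + 1, patch):
            for ox in range(0, shape[2] - patch + 1, patch):
                sl = (slice(oz, oz + patch), slice(oy, oy + patch),
                      slice(ox, ox + patch))
                tp = target[sl] if target.ndim == 3 else target[(slice(None),) + sl]
                out.append((image[(slice(None),) + sl], tp))
    return out


def train_stage(dataset: dict, cfg: TrainConfig, stage: str, model: UNet3D,
                augment_cfg: AugmentConfig | None = None,
                patch_size: int | None = None,
                progress: bool = False) -> TrainingResult:
    """Train one stage and return the lowest-validation-loss snapshot.

    ``dataset`` maps ``"train"`` / ``"dev"`` to lists of ``(input, target)``
    pairs; inputs are ``(C, D, H, W)`` (or 3D for single-channel), targets
    are soft 4D grids (coarse) or hard 3D label grids (fine).  The coarse
    stage steps once per volume per epoch; the fine stage steps once per
    queued patch.
    """
    if stage not in ("coarse", "fine"):
        raise ValueError(f"unknown stage {stage!r}")
    if model.cfg.stage != stage:
        raise ValueError(f"model stage {model.cfg.stage!r} does not match {stage!r}")
    train, dev = dataset["train"], dataset.get("dev", [])
    if not train:
        raise ValueError("empty training split")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters())
    steps_per_epoch = (len(train) if stage == "coarse"
                       else len(train) * cfg.samples_per_volume)
    total_steps = cfg.epochs * steps_per_epoch
    aug = augment_cfg if augment_cfg is not None else AugmentConfig()
    patch = patch_size or cfg.patch_size

    result = TrainingResult(params=None, best_epoch=-1)
    best_dev = np.inf
    step = 0
    for epoch in range(cfg.epochs):
        losses = []
        lr = cfg.max_lr
        if stage == "coarse":
            batches = (augment(img, tgt, stage, rng, aug)
                       for img, tgt in (train[i] for i in rng.permutation(len(train))))
        else:
            augmented = [augment(img, tgt, stage, rng, aug) for img, tgt in train]
            batches = ((img, tgt) for img, tgt, _info in
                       PatchQueue(augmented, cfg, rng, patch))
        for image, target in batches:
            x = image if image.ndim == 4 else image[None]
            scores = model.forward(x)
            loss, grad = combined_loss_and_grad(scores, target)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {step}: {loss}")
            opt.zero_grad()
            model.backward(grad)
            lr = one_cycle_lr(step, total_steps, cfg)
            opt.step(lr)
            losses.append(loss)
            step += 1
        dev_losses = []
        for image, target in dev:
            if stage == "coarse":
                x = image if image.ndim == 4 else image[None]
                dev_losses.append(combined_loss(model.forward(x), target))
            else:
                for px, pt in _dev_patches(image, target, patch):
                    dev_losses.append(combined_loss(model.forward(px), pt))
        dev_loss = float(np.mean(dev_losses)) if dev_losses else float(np.mean(losses))
        result.log.append((epoch, float(np.mean(losses)), dev_loss, lr))
        if progress:
            print(f"[{stage}] epoch {epoch}: train={np.mean(losses):.4f} "
                  f"dev={dev_loss:.4f} lr={lr:.2e}", flush=True)
        if dev_loss < best_dev:
            best_dev = dev_loss
            result.params = [p.value.copy() for p in model.parameters()]
            result.best_epoch = epoch
    model.load_state(result.params)
    return result
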