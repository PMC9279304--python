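"""Synthetic CBCT-like head phantoms with ground-truth labels.

The phantom emulates the intensity structure of craniomaxillofacial CBCT —
air around -1000, soft tissue a few tens, bone and teeth far above the
normalization window's midpoint — together with the geometry the pipeline
cares about: an ellipsoidal head with a calvarial shell, a mandible arc,
two tooth rows, and a curved vertical airway tube whose caliber narrows to
a configurable waist.  Labels are exactly consistent with the geometry used
to paint intensities, so segmentation and morphometry can be validated
against known ground truth.  Soft tissue belongs to the background class,
as in the five-mask labeling scheme.

An optional "epiglottis flap" paints soft tissue into the airway lumen,
reducing the minimal cross-sectional area by a configured fraction — a
geometric stand-in for the soft-tissue confounders that inflate airway
measurements in real CBCT.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .agreement import MeasurementTable
from .volumes import AIRWAY_CLASS, NUM_CLASSES, LabelVolume, Volume, _as_triple


@dataclass
class PhantomConfig:
    """Geometry, intensity and noise parameters of one phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    # airway caliber profile (mm): end radii tapering to a waist
    waist_radius_mm: float = 3.0
    end_radius_mm: float = 6.0
    waist_z_frac: float = 0.5
    sway_mm: float = 3.0
    # per-tissue mean intensities (CBCT-like, uncalibrated HU)
    air_hu: float = -1000.0
    soft_hu: float = 40.0
    bone_hu: float = 1200.0
    teeth_hu: float = 1800.0
    noise_sd: float = 30.0
    include_epiglottis_flap: bool = False
    flap_csa_fraction: float = 0.4

    def __post_init__(self):
        self.spacing = _as_triple(self.spacing)
        if self.waist_radius_mm <= 0 or self.end_radius_mm <= 0:
            raise ValueError("airway radii must be positive")
        if not 0 < self.waist_z_frac < 1:
            raise ValueError("waist_z_frac must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def airway_radius_profile(cfg: PhantomConfig, z_fracs: np.ndarray) -> np.ndarray:
    """Tube radius (mm) per axial position: quadratic taper from the end
    radius to the waist radius, waist at ``waist_z_frac``."""
    t = np.where(z_fracs <= cfg.waist_z_frac,
                 z_fracs / cfg.waist_z_frac,
                 (1.0 - z_fracs) / (1.0 - cfg.waist_z_frac))
    # t = 1 at the waist, 0 at the ends
    return cfg.end_radius_mm + (cfg.waist_radius_mm - cfg.end_radius_mm) * t**2


def generate_head_phantom(cfg: PhantomConfig | None = None) -> tuple[Volume, LabelVolume]:
    """Generate one phantom; bit-reproducible for a given config and seed."""
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    nz, ny, nx = cfg.shape
    sz, sy, sx = cfg.spacing
    z, y, x = np.meshgrid(np.arange(nz) * sz, np.arange(ny) * sy,
                          np.arange(nx) * sx, indexing="ij")
    extent = (nz * sz, ny * sy, nx * sx)
    cz, cy, cx = (e / 2.0 for e in extent)

    labels = np.zeros(cfg.shape, dtype=np.int16)

    # head: ellipsoid filled with soft tissue (background class)
    semi = (0.46 * extent[0], 0.42 * extent[1], 0.40 * extent[2])
    head = (((z - cz) / semi[0]) ** 2 + ((y - cy) / semi[1]) ** 2
            + ((x - cx) / semi[2]) ** 2) <= 1.0

    # calvarial shell (upper skull) in the upper half of the head
    outer = (((z - cz) / semi[0]) ** 2 + ((y - cy) / semi[1]) ** 2
             + ((x - cx) / semi[2]) ** 2)
    inner_semi = tuple(s * 0.82 for s in semi)
    inner = (((z - cz) / inner_semi[0]) ** 2 + ((y - cy) / inner_semi[1]) ** 2
             + ((x - cx) / inner_semi[2]) ** 2)
    skull = (outer <= 1.0) & (inner > 1.0) & (z > cz + 0.1 * extent[0])
    labels[skull] = 1

    # mandible: anterior half-torus in the lower head
    mand_z = cz - 0.28 * extent[0]
    ring = np.sqrt((y - cy) ** 2 + (x - cx) ** 2)
    mand = ((np.sqrt((ring - 0.22 * extent[1]) ** 2 + (z - mand_z) ** 2)
             <= 0.06 * extent[1])
            & (y > cy + 0.02 * extent[1]) & head)
    labels[mand & (labels == 0)] = 2

    # tooth rows: small spheres along an anterior arc, two rows
    tooth_r = 0.035 * extent[1]
    arc_r = 0.24 * extent[1]
    for cls, row_z in ((3, cz - 0.12 * extent[0]), (4, cz - 0.20 * extent[0])):
        for ang in np.linspace(np.deg2rad(30), np.deg2rad(150), 7):
            ty = cy + arc_r * np.sin(ang)
            tx = cx + arc_r * np.cos(ang)
            tooth = ((z - row_z) ** 2 + (y - ty) ** 2 + (x - tx) ** 2) <= tooth_r**2
            labels[tooth & (labels == 0)] = cls

    # airway: curved vertical tube of z-varying radius, posterior of center
    z0, z1 = 0.08 * extent[0], 0.92 * extent[0]
    zf = np.clip((z[:, 0, 0] - z0) / (z1 - z0), 0.0, 1.0)
    radii = airway_radius_profile(cfg, zf)
    phase = rng.uniform(0, 2 * np.pi)
    yc = cy - 0.18 * extent[1] + cfg.sway_mm * np.sin(np.pi * zf + phase) * 0.3
    xc = cx + cfg.sway_mm * np.sin(2 * np.pi * zf + phase)
    margin = np.asarray(radii) + 1.0
    if (np.any(xc - margin < 0) or np.any(xc + margin > extent[2])
            or np.any(yc - margin < 0) or np.any(yc + margin > extent[1])):
        raise ValueError("airway tube exits lateral bounds")
    in_z = (z >= z0) & (z <= z1)
    lumen = (((y - yc[:, None, None]) ** 2 + (x - xc[:, None, None]) ** 2)
             <= (radii[:, None, None] ** 2)) & in_z
    labels[lumen] = AIRWAY_CLASS

    flap = np.zeros(cfg.shape, dtype=bool)
    if cfg.include_epiglottis_flap:
        k_w = int(round((z0 + cfg.waist_z_frac * (z1 - z0)) / sz))
        for k in range(max(k_w - 1, 0), min(k_w + 2, nz)):
            ys, xs = np.nonzero(labels[k] == AIRWAY_CLASS)
            if len(ys) == 0:
                continue
            n_block = int(np.ceil(cfg.flap_csa_fraction * len(ys)))
            order = np.argsort(ys)[::-1]  # most anterior voxels first
            flap[k, ys[order[:n_block]], xs[order[:n_block]]] = True
        labels[flap] = 0  # flap is soft tissue -> background class

    # paint intensities from the final labels / geometry
    intensity = np.full(cfg.shape, cfg.air_hu, dtype=np.float32)
    intensity[head] = cfg.soft_hu
    intensity[labels == 1] = cfg.bone_hu
    intensity[labels == 2] = cfg.bone_hu
    intensity[(labels == 3) | (labels == 4)] = cfg.teeth_hu
    intensity[labels == AIRWAY_CLASS] = cfg.air_hu
    intensity[flap] = cfg.soft_hu
    if cfg.noise_sd > 0:
        intensity = intensity + rng.normal(0, cfg.noise_sd, cfg.shape).astype(np.float32)

    return (Volume(intensity.astype(np.float32), cfg.spacing),
            LabelVolume(labels, cfg.spacing, NUM_CLASSES))


def airway_bounds(cfg: PhantomConfig, margin_mm: float = 3.0):
    """Axial measurement bounds for a phantom's airway.

    The tube's open ends are excluded (as the anatomical landmark planes do
    for the real pharyngeal airway), so end-of-column digitization effects
    do not masquerade as the narrow point.
    """
    from .morphometry import AirwayBounds

    nz, sz = cfg.shape[0], cfg.spacing[0]
    z0, z1 = 0.08 * nz * sz, 0.92 * nz * sz
    return AirwayBounds(superior_z=z1 - margin_mm, inferior_z=z0 + margin_mm)


def waist_slice_index(cfg: PhantomConfig) -> int:
    """Axial index of the configured waist."""
    nz = cfg.shape[0]
    sz = cfg.spacing[0]
    z0, z1 = 0.08 * nz * sz, 0.92 * nz * sz
    return int(round((z0 + cfg.waist_z_frac * (z1 - z0)) / sz))


def generate_phantom_dataset(n: int, base: PhantomConfig | None = None,
                             seed: int = 0) -> list:
    """A cohort of ``n`` phantoms with per-subject anatomical variation.

    Waist and end radii, waist position and the tube's sway vary subject to
    subject; each phantom is generated from its own derived seed.
    Returns ``[(subject_id, Volume, LabelVolume, PhantomConfig), ...]``.
    """
    base = base or PhantomConfig()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        cfg = replace(
            base,
            seed=int(rng.integers(2**31 - 1)),
            waist_radius_mm=float(base.waist_radius_mm * rng.uniform(0.8, 1.2)),
            end_radius_mm=float(base.end_radius_mm * rng.uniform(0.85, 1.15)),
            waist_z_frac=float(np.clip(base.waist_z_frac + rng.uniform(-0.1, 0.1),
                                       0.2, 0.8)),
        )
        vol, lab = generate_head_phantom(cfg)
        out.append((f"subj{i:03d}", vol, lab, cfg))
    return out


def generate_measurement_table(n: int, methods, per_method_bias=None,
                               noise_sd: float = 1.0,
                               between_subject_sd: float = 3.0,
                               mean: float = 18.0,
                               seed: int = 0) -> MeasurementTable:
    """Simulated subjects x methods table with additive structure.

    ``value(i, m) = mean + subject_i + bias_m + noise``, with
    ``subject_i ~ N(0, between_subject_sd^2)`` and iid
    ``noise ~ N(0, noise_sd^2)`` — the variance-components model under
    which ICC(3,1) = between / (between + noise) in expectation.
    """
    if isinstance(methods, int):
        methods = [f"method{j}" for j in range(methods)]
    k = len(methods)
    if n < 2 or k < 2:
        raise ValueError("need n >= 2 subjects and k >= 2 methods")
    if noise_sd < 0 or between_subject_sd < 0:
        raise ValueError("standard deviations must be nonnegative")
    bias = np.zeros(k) if per_method_bias is None else np.asarray(per_method_bias, float)
    if bias.shape != (k,):
        raise ValueError("per_method_bias length must match methods")
    rng = np.random.default_rng(seed)
    subj = rng.normal(0, between_subject_sd, n)
    values = mean + subj[:, None] + bias[None, :] + rng.normal(0, noise_sd, (n, k))
    return MeasurementTable([f"subj{i:03d}" for i in range(n)], list(methods), values)
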