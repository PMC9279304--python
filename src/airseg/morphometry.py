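"""Pharyngeal-airway morphometry from a multiclass segmentation.

Given a segmentation, the airway class is extracted between two axial
physical bounds (stand-ins for the anatomical landmark planes used
clinically), the largest 26-connected component is kept, and three
measurements are reported:

* total volume in cc (cm^3),
* the per-axial-slice cross-sectional area profile in mm^2 and its minimum,
* the "narrowest point" in mm — by default the anteroposterior (y) extent
  of the largest in-plane component at the minimal-area slice.

The airway surface can be exported as an STL mesh (marching cubes at the
0.5 iso-level, vertices in mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .volumes import AIRWAY_CLASS, LabelVolume


@dataclass
class AirwayBounds:
    """Axial physical bounds (mm) delimiting the pharyngeal airway.

    ``superior_z`` must exceed ``inferior_z``; voxels with slice-center z in
    ``[inferior_z, superior_z]`` are kept.
    """

    superior_z: float
    inferior_z: float

    def __post_init__(self):
        if self.superior_z <= self.inferior_z:
            raise ValueError("superior_z must be > inferior_z")


@dataclass
class AirwayMetrics:
    """Airway measurements for one subject."""

    volume_cc: float
    min_csa_mm2: float
    narrowest_mm: float
    narrow_slice_z: float


def extract_airway(labels: LabelVolume, bounds: AirwayBounds | None = None,
                   airway_class: int = AIRWAY_CLASS) -> np.ndarray:
    """Binary airway mask within the axial bounds; largest 26-connected
    component only.  Raises if no airway voxel lies within the bounds."""
    mask = labels.labels == airway_class
    if bounds is not None:
        z = labels.origin[0] + np.arange(labels.shape[0]) * labels.spacing[0]
        inside = (z >= bounds.inferior_z) & (z <= bounds.superior_z)
        mask = mask & inside[:, None, None]
    if not mask.any():
        raise ValueError("no airway in bounds")
    comp, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
        mask = comp == (1 + int(np.argmax(sizes)))
    return mask


def airway_volume_cc(mask: np.ndarray, spacing) -> float:
    """Voxel-count volume in cc: ``count * sz * sy * sx / 1000``."""
    sz, sy, sx = spacing
    return float(np.count_nonzero(mask) * sz * sy * sx / 1000.0)


def cross_sectional_areas(mask: np.ndarray, spacing) -> np.ndarray:
    """Per-axial-slice airway area (mm^2); empty slices report 0."""
    if not np.any(mask):
        raise ValueError("empty airway mask")
    _, sy, sx = spacing
    return mask.sum(axis=(1, 2)) * sy * sx


def narrowest_point(mask: np.ndarray, spacing,
                    linear_measure: str = "ap_extent",
                    origin_z: float = 0.0):
    """Locate the narrow point of the airway.

    The narrow slice is the axial slice with the minimal *nonzero*
    cross-sectional area (lowest z on ties).  ``narrowest_mm`` is a linear
    caliber of the largest in-plane 8-connected component of that slice:

    * ``"ap_extent"`` (default): anteroposterior (y) extent in mm;
    * ``"ml_extent"``: mediolateral (x) extent in mm;
    * ``"equiv_diameter"``: diameter of the circle with the same area.

    Returns ``(narrowest_mm, min_csa_mm2, narrow_slice_z)``.
    """
    areas = cross_sectional_areas(mask, spacing)
    nz = np.nonzero(areas)[0]
    k = int(nz[np.argmin(areas[nz])])
    min_csa = float(areas[k])

    sz, sy, sx = spacing
    sl = mask[k]
    comp, n = ndimage.label(sl, structure=np.ones((3, 3), dtype=bool))
    if n > 1:
        sizes = ndimage.sum_labels(sl, comp, index=np.arange(1, n + 1))
        sl = comp == (1 + int(np.argmax(sizes)))
    ys, xs = np.nonzero(sl)
    if linear_measure == "ap_extent":
        narrow = (ys.max() - ys.min() + 1) * sy
    elif linear_measure == "ml_extent":
        narrow = (xs.max() - xs.min() + 1) * sx
    elif linear_measure == "equiv_diameter":
        narrow = 2.0 * np.sqrt(len(ys) * sy * sx / np.pi)
    else:
        raise ValueError(f"unknown linear measure {linear_measure!r}")
    return float(narrow), min_csa, float(origin_z + k * sz)


def measure_airway(labels: LabelVolume, bounds: AirwayBounds | None = None,
                   linear_measure: str = "ap_extent") -> AirwayMetrics:
    """Extract the airway and compute all morphometric quantities."""
    mask = extract_airway(labels, bounds)
    vol = airway_volume_cc(mask, labels.spacing)
    narrow, min_csa, z = narrowest_point(mask, labels.spacing, linear_measure,
                                         origin_z=labels.origin[0])
    return AirwayMetrics(vol, min_csa, narrow, z)


def export_stl(mask: np.ndarray, spacing, path) -> None:
    """Export the mask surface as a binary STL mesh (vertices in mm).

    The mask is zero-padded by one voxel so surfaces of masks touching the
    grid boundary are closed; the isosurface is taken at level 0.5.
    """
    import trimesh

    if not np.any(mask):
        raise ValueError("empty airway mask")
    padded = np.pad(mask.astype(np.float32), 1)
    verts, faces, _normals, _vals = measure.marching_cubes(
        padded, level=0.5, spacing=tuple(float(s) for s in spacing))
    verts -= np.asarray(spacing, dtype=verts.dtype)  # undo the pad offset
    trimesh.Trimesh(vertices=verts, faces=faces).export(str(path))


def mesh_volume_cc(path) -> float:
    """Signed volume (cc) enclosed by an STL surface (divergence theorem)."""
    import trimesh

    mesh = trimesh.load(str(path))
    return float(abs(mesh.volume) / 1000.0)
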