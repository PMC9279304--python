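"""Volumetric image containers, I/O, intensity normalization and resampling.

The package works on CBCT-like scalar volumes.  A :class:`Volume` couples a
3D intensity grid (indexed ``(z, y, x)``) with its physical voxel spacing in
millimetres; a :class:`LabelVolume` does the same for an integer multiclass
segmentation.  Voxel ``(i, j, k)`` has its physical *center* at
``origin + index * spacing`` — resampling samples at output voxel centers,
with edge clamping outside the input grid.

NIfTI files are read and written through nibabel; DICOM series are read
through pydicom.  On read, data is reordered to the canonical ``(z, y, x)``
axis order and only the voxel spacing of the affine is kept (full oblique
orientation handling is out of scope for this tool).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Default CBCT intensity window used for min-max normalization.
DEFAULT_WINDOW = (-1000.0, 2000.0)

#: Class order used everywhere in the package.
CLASS_NAMES = (
    "background",
    "upper_skull",
    "mandible",
    "maxillary_teeth",
    "mandibular_teeth",
    "airway",
)
NUM_CLASSES = len(CLASS_NAMES)
AIRWAY_CLASS = CLASS_NAMES.index("airway")


def _as_triple(x) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class Volume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    data
        3D array indexed ``(z, y, x)``.
    spacing
        Millimetres per voxel along ``(z, y, x)``.
    origin
        Physical coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_z(self, index: int) -> float:
        """Physical z coordinate (mm) of an axial slice center."""
        return self.origin[0] + index * self.spacing[0]


@dataclass
class LabelVolume:
    """A 3D integer class map with physical voxel spacing."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    num_classes: int = NUM_CLASSES
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.num_classes
        ):
            raise ValueError(
                f"labels must lie in [0, {self.num_classes - 1}], got range "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _nifti_affine(spacing, origin) -> np.ndarray:
    # nibabel stores (x, y, z); our arrays are (z, y, x) and transposed on I/O
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing[2], spacing[1], spacing[0]
    aff[:3, 3] = (origin[2], origin[1], origin[0])
    return aff


def write_volume(v: Volume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI (.nii / .nii.gz)."""
    img = nib.Nifti1Image(
        np.asarray(v.data, dtype=np.float32).transpose(2, 1, 0),
        _nifti_affine(v.spacing, v.origin),
    )
    nib.save(img, os.fspath(path))


def write_labels(lv: LabelVolume, path: str | os.PathLike) -> None:
    """Write a label volume as integer NIfTI."""
    img = nib.Nifti1Image(
        np.asarray(lv.labels, dtype=np.int16).transpose(2, 1, 0),
        _nifti_affine(lv.spacing, lv.origin),
    )
    nib.save(img, os.fspath(path))


def _read_nifti(path: Path):
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(t) for t in img.affine[:3, 3][::-1])
    return data.transpose(2, 1, 0), spacing, origin


def _read_dicom_series(path: Path):
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ""))
    if not files:
        raise FileNotFoundError(f"no DICOM slices found in {path}")
    slices = [pydicom.dcmread(os.fspath(f)) for f in files]
    slices.sort(key=lambda s: float(getattr(s, "ImagePositionPatient", [0, 0, 0])[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if dz.min() <= 0 or np.ptp(dz) > 1e-3 * abs(dz.mean()) + 1e-6:
            raise ValueError("inconsistent slice spacing in DICOM series")
        sz = float(dz.mean())
    else:
        sz = float(getattr(slices[0], "SliceThickness", 1.0))
    ps = slices[0].PixelSpacing  # (row, col) = (y, x)
    data = np.stack([s.pixel_array.astype(np.float32) for s in slices], axis=0)
    slope = float(getattr(slices[0], "RescaleSlope", 1.0))
    intercept = float(getattr(slices[0], "RescaleIntercept", 0.0))
    data = data * slope + intercept
    origin = (zs[0], float(slices[0].ImagePositionPatient[1]),
              float(slices[0].ImagePositionPatient[0]))
    return data, (sz, float(ps[0]), float(ps[1])), origin


def read_volume(path: str | os.PathLike, format: str | None = None) -> Volume:
    """Read a volume from a NIfTI file or a directory holding one DICOM series.

    Parameters
    ----------
    path
        A ``.nii``/``.nii.gz`` file, or a directory of DICOM slices.
    format
        ``"nifti"`` or ``"dicom_series"``; inferred from ``path`` if omitted.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file or directory: {p}")
    if format is None:
        format = "dicom_series" if p.is_dir() else "nifti"
    if format == "nifti":
        data, spacing, origin = _read_nifti(p)
    elif format == "dicom_series":
        data, spacing, origin = _read_dicom_series(p)
    else:
        raise ValueError(f"unknown format {format!r}")
    return Volume(np.ascontiguousarray(data, dtype=np.float32), spacing, origin)


def read_labels(path: str | os.PathLike, num_classes: int = NUM_CLASSES) -> LabelVolume:
    """Read an integer label volume from NIfTI."""
    data, spacing, origin = _read_nifti(Path(path))
    return LabelVolume(
        np.ascontiguousarray(np.rint(data).astype(np.int16)), spacing, num_classes, origin
    )


# ---------------------------------------------------------------------------
# Intensity normalization
# ---------------------------------------------------------------------------

def normalize_intensity(v: Volume, window: tuple[float, float] = DEFAULT_WINDOW) -> Volume:
    """Min-max normalize intensities within a fixed window.

    Values are clipped to ``[lo, hi]`` then mapped linearly so that
    ``lo -> 0`` and ``hi -> 1``.  The CBCT default window is (-1000, 2000):
    air maps to 0 and dense enamel saturates at 1.
    """
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError(f"degenerate window {window}: need hi > lo")
    out = (np.clip(v.data.astype(np.float32), lo, hi) - lo) / (hi - lo)
    return Volume(out, v.spacing, v.origin)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _output_shape(shape, spacing, target_spacing):
    ext = np.asarray(shape) * np.asarray(spacing)
    return tuple(int(np.ceil(e / t - 1e-9)) for e, t in zip(ext, target_spacing))


def resample_grid(
    data: np.ndarray,
    spacing: Sequence[float],
    target_spacing: Sequence[float],
    mode: str = "linear",
    output_shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Resample a 3D grid onto a new voxel lattice, sampling at voxel centers.

    Output voxel ``i`` has center ``i * target_spacing`` in the physical frame
    whose origin coincides with the center of input voxel 0; input coordinates
    outside the grid are edge-clamped.
    """
    spacing = np.asarray(spacing, dtype=float)
    target = np.asarray(target_spacing, dtype=float)
    if np.any(target <= 0):
        raise ValueError(f"target spacing must be positive, got {tuple(target)}")
    if output_shape is None:
        output_shape = _output_shape(data.shape, spacing, target)
    if tuple(output_shape) == data.shape and np.allclose(spacing, target):
        return data.copy()
    order = {"linear": 1, "nearest": 0}[mode]
    coords = np.meshgrid(
        *[np.arange(n) * t / s for n, t, s in zip(output_shape, target, spacing)],
        indexing="ij",
    )
    if order and not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    out = ndimage.map_coordinates(
        data,
        np.stack([c.ravel() for c in coords]),
        order=order,
        mode="nearest",  # edge clamp
    ).reshape(output_shape)
    return out


def resample(v: Volume, target_spacing, mode: str = "linear") -> Volume:
    """Resample a volume to a new spacing (mm); ``mode`` linear or nearest."""
    target = _as_triple(target_spacing)
    out = resample_grid(v.data, v.spacing, target, mode=mode)
    return Volume(out.astype(np.float32), target, v.origin)


def resample_labels(lv: LabelVolume, target_spacing) -> LabelVolume:
    """Nearest-neighbor resample of an integer label volume."""
    target = _as_triple(target_spacing)
    out = resample_grid(lv.labels, lv.spacing, target, mode="nearest")
    return LabelVolume(out.astype(lv.labels.dtype), target, lv.num_classes, lv.origin)
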