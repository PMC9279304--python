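import numpy as np
import pytest

from airseg.volumes import LabelVolume, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_labels(rng):
    """A small random 6-class label volume at 0.5 mm."""
    labels = rng.integers(0, 6, size=(12, 10, 14)).astype(np.int16)
    return LabelVolume(labels, spacing=(0.5, 0.5, 0.5))


def trilinear_oracle(data, spacing, target_spacing, output_shape):
    """Brute-force trilinear interpolation at output voxel centers with edge
    clamping — the independent reference for all linear resampling."""
    data = np.asarray(data, dtype=np.float64)
    out = np.zeros(output_shape, dtype=np.float64)
    shp = data.shape
    for i in range(output_shape[0]):
        for j in range(output_shape[1]):
            for k in range(output_shape[2]):
                coord = [i * target_spacing[0] / spacing[0],
                         j * target_spacing[1] / spacing[1],
                         k * target_spacing[2] / spacing[2]]
                coord = [min(max(c, 0.0), s - 1.0) for c, s in zip(coord, shp)]
                lo = [int(np.floor(c)) for c in coord]
                hi = [min(l + 1, s - 1) for l, s in zip(lo, shp)]
                f = [c - l for c, l in zip(coord, lo)]
                acc = 0.0
                for dz in (0, 1):
                    for dy in (0, 1):
                        for dx in (0, 1):
                            wz = f[0] if dz else 1 - f[0]
                            wy = f[1] if dy else 1 - f[1]
                            wx = f[2] if dx else 1 - f[2]
                            zz = hi[0] if dz else lo[0]
                            yy = hi[1] if dy else lo[1]
                            xx = hi[2] if dx else lo[2]
                            acc += wz * wy * wx * data[zz, yy, xx]
                out[i, j, k] = acc
    return out


@pytest.fixture
def tiny_volume(rng):
    return Volume(rng.normal(0, 100, (8, 9, 7)).astype(np.float32),
                  spacing=(0.5, 0.5, 0.5))
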