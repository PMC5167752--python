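import numpy as np
import pytest

from bna.preprocess import BandVolume, GridGeometry, project_montage
from bna.segmentation import Peak, Step
from bna.simulate import synthetic_head_montage


@pytest.fixture(scope="session")
def montage():
    """Projected 37-electrode spherical-cap montage."""
    return project_montage(synthetic_head_montage())


@pytest.fixture(scope="session")
def geometry():
    return GridGeometry()


@pytest.fixture
def make_volume():
    """Factory for small fully-masked band volumes."""

    def _make(data, band="theta", dt_ms=4.0, t0_ms=0.0):
        data = np.asarray(data, dtype=float)
        n_lr, n_ap, n_t = data.shape
        geom = GridGeometry(n_lr=n_lr, n_ap=n_ap,
                            mask=np.ones((n_lr, n_ap), dtype=bool))
        times = t0_ms + dt_ms * np.arange(n_t)
        return BandVolume(band=band, data=data, times_ms=times, geometry=geom)

    return _make


@pytest.fixture
def make_step():
    """Factory for hand-built STEPs on a small grid."""

    def _make(voxels, amplitudes, peak_xyz, band="theta",
              shape=(8, 8, 20), dt_ms=10.0, subject_id="s0",
              condition="Target", visit_id="V1"):
        voxels = np.asarray(voxels, dtype=np.int64)
        amplitudes = np.asarray(amplitudes, dtype=float)
        times = dt_ms * np.arange(shape[2])
        x, y, t = peak_xyz
        i = next(
            k for k, v in enumerate(voxels)
            if tuple(v) == (x, y, t)
        )
        peak = Peak(x=x, y=y, t_idx=t, t_ms=float(times[t]),
                    amplitude_uv=float(amplitudes[i]))
        return Step(
            band=band, peak=peak, voxels=voxels, amplitudes=amplitudes,
            rise_time_ms=float(times[voxels[:, 2].min()]),
            shape=shape, times_ms=times, subject_id=subject_id,
            condition=condition, visit_id=visit_id,
        )

    return _make


def gaussian_bump_volume(shape=(15, 15, 30), center=(7, 7, 15),
                         sds=(2.0, 3.0, 4.0), amplitude=10.0):
    """Separable 3-D Gaussian bump, used as an analytically known volume."""
    x = np.arange(shape[0])[:, None, None]
    y = np.arange(shape[1])[None, :, None]
    t = np.arange(shape[2])[None, None, :]
    return amplitude * np.exp(
        -0.5 * ((x - center[0]) / sds[0]) ** 2
        - 0.5 * ((y - center[1]) / sds[1]) ** 2
        - 0.5 * ((t - center[2]) / sds[2]) ** 2
    )
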