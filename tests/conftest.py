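import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

import oospindle as oo

VOXEL = (1.0, 0.25, 0.25)
VOXEL_DIAGONAL = float(np.linalg.norm(VOXEL))


@pytest.fixture(scope="session")
def scene_cache():
    """Render-on-demand cache so scenes are shared across test modules.

    Keyed by (seed, frozen overrides); values are (truth, bf, mt, spot).
    """
    cache: dict = {}

    def get(seed: int, **overrides):
        key = (seed, tuple(sorted((k, repr(v)) for k, v in overrides.items())))
        if key not in cache:
            params = oo.SceneParams(
                n_mtocs=overrides.pop("n_mtocs", 6),
                gaussian_noise_sd=overrides.pop("gaussian_noise_sd", 0.0),
                min_mtoc_separation=overrides.pop("min_mtoc_separation", 5.0),
                **overrides,
            )
            truth = oo.generate_scene(params, seed=seed)
            bf, mt, spot = oo.render_volumes(truth)
            cache[key] = (truth, bf, mt, spot)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def small_scene_params():
    """A compact scene for fast pipeline smoke tests."""
    return oo.SceneParams(
        n_mtocs=3,
        shape=(16, 64, 64),
        oocyte_radius=6.5,
        spindle_length=10.0,
        spindle_radius=2.5,
        mtoc_radius_range=(0.4, 0.6),
        min_mtoc_separation=3.5,
        gaussian_noise_sd=5.0,
    )


@pytest.fixture
def digitized_ellipsoid():
    """Ellipsoid with semi-axes (16, 8, 8) µm, long axis along y, on the
    default anisotropic grid. Feret length 32 µm, central width 16 µm."""
    nz, ny, nx = 40, 192, 192
    vz, vy, vx = VOXEL
    z = (np.arange(nz) + 0.5) * vz
    y = (np.arange(ny) + 0.5) * vy
    x = (np.arange(nx) + 0.5) * vx
    cz, cy, cx = nz * vz / 2, ny * vy / 2, nx * vx / 2
    zz, yy, xx = z[:, None, None], y[None, :, None], x[None, None, :]
    mask = ((yy - cy) / 16.0) ** 2 + ((zz - cz) / 8.0) ** 2 + ((xx - cx) / 8.0) ** 2 <= 1.0
    return mask
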