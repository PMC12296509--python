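import numpy as np
import pytest

import tomomorph as tm


@pytest.fixture(scope="session")
def small_scene() -> tm.SyntheticScene:
    """Ten digitized vesicles at study defaults (45.4 nm, 15.84 Å/voxel)."""
    return tm.gen_vesicle_scene(10, seed=1)


@pytest.fixture(scope="session")
def small_scene_records(small_scene):
    return tm.measure_vesicles(small_scene.volume)


@pytest.fixture(scope="session")
def straight_bundle() -> tm.BundleScene:
    """Eight exactly straight, parallel filaments (wobble 0)."""
    return tm.gen_filament_bundle(
        tm.BundleSpec(n_filaments=8, seed=3, wobble_amplitude=0.0, length=300.0)
    )


def digitized_sphere(diameter_vox: float, pad: int = 3) -> np.ndarray:
    """(m, 3) voxel coords of a centered digital sphere (center-in-sphere rule)."""
    r = diameter_vox / 2.0
    n = int(np.ceil(diameter_vox)) + 2 * pad
    c = (n - 1) / 2.0
    zz, yy, xx = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
    inside = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r * r
    return np.column_stack([zz[inside], yy[inside], xx[inside]])


def sphere_volume_grid(diameter_vox: float, shape: tuple[int, int, int]) -> np.ndarray:
    """Binary volume with a centered digital sphere, for wedge experiments."""
    r = diameter_vox / 2.0
    c = [(s - 1) / 2.0 for s in shape]
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    return ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r * r).astype(float)
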