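import math

import numpy as np
import pytest

from onquant.grid import BinaryMask
from onquant.phantoms import PhantomSpec, rasterize_phantom

SPACING = 0.3


@pytest.fixture(scope="session")
def cylinder_spec():
    """Straight tube along y: r = 1.5 mm, length 30 mm, 0.3 mm grid."""
    return PhantomSpec(
        grid_shape=(40, 120, 40), spacing=(SPACING,) * 3, origin=(-6.0, -3.0, -6.0),
        curve_control_points=((0.0, 0.0, 0.0), (0.0, 30.0, 0.0)),
        radius_profile=((0.0, 1.5),), csf_thickness_profile=((0.0, 0.6),),
    )


@pytest.fixture(scope="session")
def cylinder(cylinder_spec):
    return rasterize_phantom(cylinder_spec)


@pytest.fixture(scope="session")
def torus_spec():
    """Quarter-circle tube, bend radius 10 mm, tube radius 1.5 mm."""
    cps = tuple((10 * math.cos(t), 10 * math.sin(t), 0.0)
                for t in np.linspace(0.0, math.pi / 2, 9))
    return PhantomSpec(
        grid_shape=(50, 50, 20), spacing=(SPACING,) * 3, origin=(-2.55, -2.55, -2.85),
        curve_control_points=cps, radius_profile=((0.0, 1.5),),
        csf_thickness_profile=((0.0, 0.0),),
    )


@pytest.fixture(scope="session")
def torus(torus_spec):
    return rasterize_phantom(torus_spec)


@pytest.fixture(scope="session")
def head_spec():
    """Two bright globes plus a short nerve, enough for eye detection."""
    return PhantomSpec(
        grid_shape=(250, 140, 100), spacing=(0.4,) * 3, origin=(-50.0, 15.0, -20.0),
        globe_centers=((-30.0, 40.0, 0.0), (30.0, 40.0, 0.0)), globe_radius=11.0,
        curve_control_points=((30.0, 32.0, 0.0), (20.0, 20.0, 0.0)),
        radius_profile=((0.0, 1.5),), csf_thickness_profile=((0.0, 0.5),),
        noise_sigma=5.0, seed=3,
    )


@pytest.fixture(scope="session")
def head(head_spec):
    return rasterize_phantom(head_spec)


def make_mask(shape, coords, spacing=1.0, origin=0.0):
    """BinaryMask with ones at the given voxel index tuples."""
    vox = np.zeros(shape, dtype=np.uint8)
    for c in coords:
        vox[tuple(c)] = 1
    return BinaryMask(vox, np.full(3, spacing), np.full(3, float(origin)))


def random_mask_pair(rng, shape=(10, 10, 10), spacing=0.3, max_voxels=200):
    """Two random small nonempty blobs on a shared grid."""
    masks = []
    for _ in range(2):
        n = rng.integers(1, max_voxels + 1)
        vox = np.zeros(shape, dtype=np.uint8)
        # random walk blob for spatial coherence
        p = rng.integers(2, np.asarray(shape) - 2)
        for _ in range(n):
            vox[tuple(p)] = 1
            p = np.clip(p + rng.integers(-1, 2, size=3), 0, np.asarray(shape) - 1)
        masks.append(BinaryMask(vox, np.full(3, spacing), np.zeros(3)))
    return masks[0], masks[1]
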