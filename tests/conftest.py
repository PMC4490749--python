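"""Shared fixtures: phantoms and simulated crosses, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from boneqtl.phantom import PhantomSpec, generate_phantom
from boneqtl.segmentation import PoreComponent, label_components, segment_phases


@pytest.fixture(scope="session")
def default_phantom():
    """Noise-free default shell phantom: 50 lacunae (5,2,2), 2 canals."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def labeled_default(default_phantom):
    seg = segment_phases(default_phantom, bone_threshold=110)
    return label_components(seg)


def digital_ellipsoid(semi_axes, orientation=None, voxel_size=1.0):
    """A solid digital ellipsoid as a PoreComponent (voxel-center test)."""
    a = max(semi_axes)
    n = int(2 * a + 6)
    zz, yy, xx = np.meshgrid(*[np.arange(n) + 0.5] * 3, indexing="ij")
    c = n / 2
    pts = np.stack([zz - c, yy - c, xx - c], axis=-1)
    if orientation is not None:
        from boneqtl.phantom import _rotation_to
        pts = pts @ _rotation_to(np.asarray(orientation, float))
    m = ((pts[..., 0] / semi_axes[0]) ** 2 + (pts[..., 1] / semi_axes[1]) ** 2
         + (pts[..., 2] / semi_axes[2]) ** 2) <= 1
    return PoreComponent(id=1, cls="lacuna", voxels=np.argwhere(m),
                         border_touching=False)


def lattice_points(spacing, n=8):
    """Regular lattice of n³ points with the given (z, y, x) spacing."""
    g = np.meshgrid(*[np.arange(n) * s for s in spacing], indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1).astype(float)
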