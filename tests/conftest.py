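"""Shared fixtures: small phantoms and reconstruction products.

Expensive reconstructions are session-scoped so several tests can share
one ART run.
"""

from __future__ import annotations

import numpy as np
import pytest

from sxtmorph import (
    art_reconstruct,
    default_tilt_angles,
    project,
    to_absorbance,
)
from sxtmorph.phantom import PhantomConfig, make_cell_phantom


def sphere_config(grid=32, radius=8.0, lac=0.45, **kw):
    """Config for a bare single-sphere phantom (no nucleus, no beads)."""
    defaults = dict(
        grid_shape=(grid,) * 3,
        voxel_size=40.0,
        n_mitochondria=1,
        axis_ratio=(1.0, 1.0, 1.0),
        axis_ratio_jitter=0.0,
        mito_radius_vox=radius,
        mito_radius_jitter=0.0,
        mito_lac=lac,
        cytoplasm_lac=0.0,
        nucleus_lac=0.0,
        nucleus_radius_frac=0.0,
        n_beads=0,
        placement_margin_vox=0.0,
        seed=11,
    )
    defaults.update(kw)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Bare sphere, radius 8 voxels on a 32³ grid, µ = 0.45 µm⁻¹."""
    return make_cell_phantom(sphere_config())


@pytest.fixture(scope="session")
def sphere_absorbance(sphere_phantom):
    """Noiseless absorbance series of the sphere over the default 140° scheme."""
    return to_absorbance(project(sphere_phantom))


@pytest.fixture(scope="session")
def sphere_recon(sphere_absorbance):
    """Default ART reconstruction (15 sweeps, relaxation 0.01) of the sphere."""
    return art_reconstruct(sphere_absorbance)


def rasterize_ellipsoid(grid, semi_axes, rotation=None):
    """Boolean mask of an axis-aligned (or rotated) ellipsoid centered on a grid."""
    c = (grid - 1) / 2.0
    zz, yy, xx = np.meshgrid(*(np.arange(grid, dtype=float),) * 3, indexing="ij")
    pts = np.stack([zz - c, yy - c, xx - c], axis=-1)
    if rotation is not None:
        pts = pts @ rotation
    u = pts / np.asarray(semi_axes, dtype=float)
    return np.einsum("...i,...i->...", u, u) <= 1.0
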