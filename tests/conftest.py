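"""Shared phantom fixtures: all test data is generated, nothing is loaded."""

import numpy as np
import pytest

import neotract as nt


@pytest.fixture(scope="session")
def scheme():
    return nt.default_scheme()


def exact_bundle_spec(n_vox=12, width=1, eigenvalues=(1.7e-3, 0.4e-3, 0.4e-3)):
    """Straight x-aligned bundle covering exactly n_vox * (2*width+1) voxels.

    The centerline runs from the center of the first bundle voxel to the
    center of the last, so the end caps add no extra voxels; the radius
    spans `width` extra voxel rows in y only.
    """
    vx = (1.6, 1.6, 2.0)
    shape = (n_vox + 6, 9, 9)
    y = (shape[1] // 2 + 0.5) * vx[1]
    z = (shape[2] // 2 + 0.5) * vx[2]
    x0 = (3 + 0.5) * vx[0]
    x1 = (3 + n_vox - 1 + 0.5) * vx[0]
    radius = (width + 0.45) * vx[1] if width else 0.45 * vx[1]
    bundle = nt.BundleSpec(centerline=("straight", (x0, y, z), (x1, y, z)),
                           radius=radius, eigenvalues=eigenvalues)
    return nt.PhantomSpec(shape=shape, voxel_size=vx, bundles=(bundle,))


@pytest.fixture(scope="session")
def straight_phantom():
    """(tensor volume, bundle mask, eigensystems, scalar maps) for a
    12-voxel-long, 3-row-wide straight bundle."""
    spec = exact_bundle_spec(n_vox=12, width=1)
    vol, masks = nt.make_tensor_phantom(spec)
    eig = nt.eigendecompose(vol)
    maps = nt.scalar_maps(eig)
    return vol, masks[0], eig, maps


@pytest.fixture(scope="session")
def single_row_phantom():
    """One-voxel-thick straight bundle of exactly 12 voxels."""
    spec = exact_bundle_spec(n_vox=12, width=0)
    vol, masks = nt.make_tensor_phantom(spec)
    eig = nt.eigendecompose(vol)
    maps = nt.scalar_maps(eig)
    assert masks[0].sum() == 12
    return vol, masks[0], eig, maps


def bend_phantom(angle_deg):
    """Polyline bundle with a single in-plane bend of `angle_deg`."""
    vx = (1.6, 1.6, 2.0)
    shape = (16, 16, 7)
    z = 3.5 * vx[2]
    y0 = 4.5 * vx[1]
    p0 = np.array([1.5 * vx[0], y0, z])
    bend = np.array([8.5 * vx[0], y0, z])
    direction = np.array([np.cos(np.deg2rad(angle_deg)),
                          np.sin(np.deg2rad(angle_deg)), 0.0])
    p2 = bend + direction * 6 * vx[0]
    # wide enough that the post-bend orientation change happens inside the
    # bundle (nearest-neighbor FACT cannot make a diagonal voxel jump)
    bundle = nt.BundleSpec(centerline=("polyline", [p0, bend, p2]),
                           radius=1.0 * vx[1])
    vol, masks = nt.make_tensor_phantom(
        nt.PhantomSpec(shape=shape, voxel_size=vx, bundles=(bundle,)))
    eig = nt.eigendecompose(vol)
    maps = nt.scalar_maps(eig)
    return vol, masks[0], eig, maps


@pytest.fixture(scope="session")
def two_bundle_phantom():
    """Two parallel straight bundles P (low rows) and Q (high rows)."""
    vx = (1.6, 1.6, 2.0)
    shape = (18, 13, 7)
    z = 3.5 * vx[2]
    mk = lambda j: nt.BundleSpec(
        centerline=("straight",
                    (2.5 * vx[0], (j + 0.5) * vx[1], z),
                    (15.5 * vx[0], (j + 0.5) * vx[1], z)),
        radius=0.45 * vx[1])
    spec = nt.PhantomSpec(shape=shape, voxel_size=vx,
                          bundles=(mk(3), mk(9)))
    vol, masks = nt.make_tensor_phantom(spec)
    eig = nt.eigendecompose(vol)
    maps = nt.scalar_maps(eig)
    return vol, masks, eig, maps
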