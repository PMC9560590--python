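import numpy as np
import pytest

from dbsaudit.leads import ElectrodeModel, LeadSpec
from dbsaudit.volumes import LabelVolume, centered_affine, ellipsoid_mask


@pytest.fixture(scope="session")
def default_atlas():
    """Session-wide default synthetic atlas (deterministic)."""
    from dbsaudit.synthetic import generate_atlas

    return generate_atlas()


@pytest.fixture
def simple_spec():
    return LeadSpec("test", 4, 1.5, 2.0, 2.25)


def make_label_volume(shape=(41, 41, 41), voxel_size=1.0):
    return LabelVolume(
        np.zeros(shape, dtype=np.int16),
        centered_affine(shape, voxel_size),
        {"region": 1},
    )


def sphere_volume(radius, shape=(41, 41, 41), voxel_size=1.0, center=(0, 0, 0)):
    vol = make_label_volume(shape, voxel_size)
    vol.data[ellipsoid_mask(vol, center, (radius,) * 3)] = 1
    return vol


def random_ellipsoid_volume(rng, shape=(28, 28, 28), voxel_size=1.0):
    vol = make_label_volume(shape, voxel_size)
    center = rng.uniform(-4, 4, 3)
    semi = rng.uniform(2.5, 7.0, 3)
    vol.data[ellipsoid_mask(vol, center, semi)] = 1
    return vol


def surface_voxel_centers(vol, label=1):
    """Brute-force oracle helper: world centres of labelled voxels with at
    least one unlabelled 6-neighbour."""
    mask = vol.mask(label)
    padded = np.pad(mask, 1)
    interior = np.ones_like(mask)
    for axis in range(3):
        for shift in (-1, 1):
            interior &= np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
    surface = mask & ~interior
    return vol.voxel_to_world(np.argwhere(surface))


def random_electrode(rng, spec=None, tip_range=20.0, hemisphere="left"):
    if spec is None:
        spec = LeadSpec("test", 4, 1.5, 2.0, 2.25)
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    return ElectrodeModel(
        tip=rng.uniform(-tip_range, tip_range, 3), direction=d,
        spec=spec, hemisphere=hemisphere,
    )


def random_rigid(rng, translation_scale=5.0):
    from dbsaudit.metrics import rigid_affine

    return rigid_affine(
        rng.uniform(-translation_scale, translation_scale, 3),
        rng.uniform(-180, 180, 3),
    )
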