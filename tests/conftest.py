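import numpy as np
import pytest

from synglia.synthetic_data import (
    GliaParams,
    SceneParams,
    generate_scene,
    noiseless,
)


@pytest.fixture(scope="session")
def default_scene():
    """One default noisy scene, shared across tests."""
    return generate_scene(SceneParams(), seed=11)


@pytest.fixture(scope="session")
def noiseless_scene():
    """One noiseless scene (no PSF, no noise, no background)."""
    return generate_scene(noiseless(SceneParams()), seed=12)


@pytest.fixture(scope="session")
def enrichment_scene_params():
    """Scene tuned for the engulfment-enrichment contract: large glial
    volume and sparse puncta so relocated puncta rarely overlap."""
    glia = {
        "IBA1": GliaParams(n_somas=5, soma_radius_um=3.0, n_branches=8,
                           branch_length_um=10.0, branch_radius_um=0.8),
        "GFAP": GliaParams(n_somas=5, soma_radius_um=3.0, n_branches=10,
                           branch_length_um=10.0, branch_radius_um=0.8),
    }
    return SceneParams(
        synapse_density_per_um3=0.08,
        engulfment_fraction=0.05,
        glia=glia,
    )


def brute_force_sphere_count(shape, voxel_size, center_um, radius_um):
    """Independent oracle: count voxels whose centre lies in the sphere,
    by explicit nested loops."""
    nz, ny, nx = shape
    vz, vy, vx = voxel_size
    cz, cy, cx = center_um
    count = 0
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                dz = (iz + 0.5) * vz - cz
                dy = (iy + 0.5) * vy - cy
                dx = (ix + 0.5) * vx - cx
                if dz * dz + dy * dy + dx * dx <= radius_um * radius_um:
                    count += 1
    return count


def brute_force_percentages(mask_a, mask_b=None, mask_c=None):
    """Independent oracle: percent positive / co-positive voxels counted
    with plain Python loops (no vectorized boolean algebra)."""
    flat_a = [bool(v) for v in np.asarray(mask_a).ravel()]
    n = len(flat_a)
    if mask_b is None:
        return 100.0 * sum(flat_a) / n
    flat_b = [bool(v) for v in np.asarray(mask_b).ravel()]
    if mask_c is None:
        return 100.0 * sum(
            1 for a, b in zip(flat_a, flat_b) if a and b
        ) / n
    flat_c = [bool(v) for v in np.asarray(mask_c).ravel()]
    return 100.0 * sum(
        1 for a, b, c in zip(flat_a, flat_b, flat_c) if a and b and c
    ) / n


def voxelwise_f1(mask, truth):
    tp = np.count_nonzero(mask & truth)
    fp = np.count_nonzero(mask & ~truth)
    fn = np.count_nonzero(~mask & truth)
    if 2 * tp + fp + fn == 0:
        return 1.0
    return 2 * tp / (2 * tp + fp + fn)
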