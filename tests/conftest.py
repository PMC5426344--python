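import numpy as np
import pytest

import pcscloud as pc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2017)


@pytest.fixture(scope="session")
def random_chi():
    """A generic (non-axial) traceless susceptibility tensor, Å³."""
    r = np.random.default_rng(11)
    m = r.normal(size=(3, 3))
    chi = pc.SusceptibilityTensor(0.01 * (m + m.T))
    assert chi.frobenius > 0
    return chi


@pytest.fixture(scope="session")
def small_grid():
    return pc.Grid3D(origin=[-16.0, -16.0, -16.0], spacing=1.0, shape=(32, 32, 32))


@pytest.fixture(scope="session")
def delta_density(small_grid):
    v = np.zeros(small_grid.shape)
    v[16, 16, 16] = 1.0 / small_grid.voxel_volume
    return pc.DensityField(small_grid, v)


@pytest.fixture(scope="session")
def tiny_protein():
    return pc.toy_protein(24, seed=5)


@pytest.fixture(scope="session")
def inverse_problem():
    """A small masked inversion problem with noiseless synthetic data.

    Returns (functional, truth DensityField on the same grid, dataset, chi).
    """
    g = pc.Grid3D(origin=[-12.0, -12.0, -12.0], spacing=1.5, shape=(17, 17, 17))
    centers = g.voxel_centers()
    mask = np.linalg.norm(centers, axis=-1) <= 7.0
    blob = pc.gaussian_phantom(pc.PhantomSpec([(np.zeros(3), 1.5, 1.0)], g))
    v = np.where(mask, blob.values, 0.0)
    truth = pc.DensityField(g, v / (v.sum() * g.voxel_volume), mask)
    chi = pc.SusceptibilityTensor.from_axial_rhombic(0.02, 0.005)
    r = np.random.default_rng(4)
    # nuclei on a shell 9-11 A from the phantom, inside the grid
    n = 60
    u = r.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    pos = u * r.uniform(9.0, 10.5, size=(n, 1))
    ds = pc.make_synthetic_dataset(
        truth, chi, pos, noise_sd=0.0, seed=8,
        residues=np.arange(1, n + 1),
    )
    f = pc.Functional(g, mask, ds, chi, lam=1.0)
    return f, truth, ds, chi
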