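"""Variational core: functional terms, variations, minimiser, full protocol."""

import numpy as np
import pytest

import pcscloud as pc
from pcscloud.inversion import _laplacian


def _masked_random_field(f, seed, scale=1e-4):
    rng = np.random.default_rng(seed)
    v = rng.random(f.grid.shape) * scale
    v[~f.mask] = 0.0
    return v


class TestErrorFunctional:
    def test_zero_at_generating_density(self, inverse_problem):
        """Noiseless data evaluated at the generating density with λ = 0."""
        f, truth, ds, chi = inverse_problem
        total, err, pen = f.with_lambda(0.0).value(truth.values)
        scale = np.sum(ds.shifts ** 2)
        assert total <= 1e-12 * scale

    def test_zero_density_terms(self, inverse_problem):
        f, _, ds, _ = inverse_problem
        total, err, pen = f.value(np.zeros(f.grid.shape))
        assert err == pytest.approx(np.sum(ds.shifts ** 2), rel=1e-12)
        assert pen == 0.0

    def test_penalty_prefers_smooth_densities(self, inverse_problem):
        """A one-voxel spike is penalised more than an equal-mass Gaussian."""
        f, _, _, _ = inverse_problem
        g = f.grid
        spike = np.zeros(g.shape)
        spike[8, 8, 8] = 1.0 / g.voxel_volume
        smooth = pc.gaussian_phantom(
            pc.PhantomSpec([(g.index_to_world([8.0, 8.0, 8.0])[0], 3.0, 1.0)], g)
        ).values
        lap = lambda v: float(np.sum(_laplacian(v, g.spacing) ** 2) * g.voxel_volume)
        assert lap(spike) > lap(smooth)
        _, _, pen_spike = f.value(spike)
        _, _, pen_smooth = f.value(smooth)
        assert pen_spike > pen_smooth

    def test_grid_mismatch_rejected(self, inverse_problem):
        f, truth, _, _ = inverse_problem
        other = pc.Grid3D(origin=[0.0, 0.0, 0.0], spacing=1.0, shape=(4, 4, 4))
        rho = pc.DensityField(other, np.ones((4, 4, 4)) / 64.0)
        with pytest.raises(ValueError, match="grid"):
            pc.error_functional(rho, f)


class TestVariations:
    def test_gradient_vanishes_at_noiseless_minimum(self, inverse_problem):
        f, truth, ds, _ = inverse_problem
        g = f.with_lambda(0.0).gradient(np.where(f.mask, truth.values, 0.0))
        # data scale for the gradient: ‖2 Aᵀd‖∞
        scale = np.abs(f._backproject(2.0 * ds.shifts)).max()
        # the truth has (tiny) mass outside the mask: allow that leakage
        assert np.abs(g[f.mask]).max() <= 1e-6 * scale

    @pytest.mark.parametrize("lam", [0.0, 1.0, 1e4])
    def test_finite_difference_directional_derivative(self, inverse_problem, lam):
        f0, _, _, _ = inverse_problem
        f = f0.with_lambda(lam)
        x = _masked_random_field(f, seed=21)
        eta = _masked_random_field(f, seed=22)
        eps = 1e-5
        up = f.value(x + eps * eta)[0]
        dn = f.value(x - eps * eta)[0]
        fd = (up - dn) / (2 * eps)
        inner = float(np.sum(f.gradient(x) * eta))
        assert fd == pytest.approx(inner, rel=1e-5)

    def test_gradient_quadratic_scaling(self, inverse_problem):
        """Doubling χ and the data together scales the data-term gradient by 4."""
        f, _, ds, chi = inverse_problem
        f0 = f.with_lambda(0.0)
        x = _masked_random_field(f0, seed=23)
        g1 = f0.gradient(x)
        ds2 = pc.PCSDataset(
            ds.positions, 2.0 * ds.shifts, ds.nucleus, ds.residues, ds.atoms
        )
        f2 = pc.Functional(f.grid, f.mask, ds2, 2.0 * chi, lam=0.0)
        g2 = f2.gradient(x)
        # at matched ρ: A→2A, d→2d gives grad 2(2A)ᵀ(2Ax−2d) = 4 grad
        assert np.allclose(g2, 4.0 * g1, rtol=1e-10, atol=1e-12 * np.abs(g1).max())

    def test_hessian_symmetry(self, inverse_problem):
        f, _, _, _ = inverse_problem
        e1 = _masked_random_field(f, seed=24)
        e2 = _masked_random_field(f, seed=25)
        lhs = float(np.sum(f.hessian_action(e1) * e2))
        rhs = float(np.sum(e1 * f.hessian_action(e2)))
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_hessian_zero_probe(self, inverse_problem):
        f, _, _, _ = inverse_problem
        assert not f.hessian_action(np.zeros(f.grid.shape)).any()

    def test_pure_penalty_action_is_biharmonic_stencil(self, inverse_problem):
        """With the data term switched off the Hessian action is λ times the
        discrete biharmonic, verified against direct stencil application."""
        f, _, ds, chi = inverse_problem
        zero_ds = pc.PCSDataset(
            ds.positions, np.zeros(len(ds)), ds.nucleus, ds.residues, ds.atoms,
            weights=np.zeros(len(ds)),
        )
        lam = 3.7
        fpen = pc.Functional(f.grid, f.mask, zero_ds, chi, lam=lam)
        eta = _masked_random_field(fpen, seed=26)
        got = fpen.hessian_action(eta)
        expected = 2.0 * lam * f.grid.voxel_volume * _laplacian(
            _laplacian(eta, f.grid.spacing), f.grid.spacing
        )
        expected[~f.mask] = 0.0
        assert np.allclose(got, expected, rtol=1e-12, atol=1e-12 * np.abs(expected).max())

    def test_operator_and_matrix_paths_agree(self, inverse_problem):
        """Precomputed design rows and the on-the-fly FFT path are the same
        linear operator."""
        f, _, ds, chi = inverse_problem
        fop = pc.Functional(f.grid, f.mask, ds, chi, lam=1.0, precompute=False)
        x = _masked_random_field(f, seed=27)
        assert np.allclose(f.forward(x), fop.forward(x), rtol=1e-10, atol=1e-12)
        assert np.allclose(f.gradient(x), fop.gradient(x), rtol=1e-8, atol=1e-12)


class TestReconstructDensity:
    def test_round_trip_reproduces_observations(self, inverse_problem):
        f, truth, ds, _ = inverse_problem
        small = f.with_lambda(1e-6)
        init = pc.DensityField(
            f.grid, np.where(f.mask, 1.0, 0.0) / (f.mask.sum() * f.grid.voxel_volume),
            f.mask,
        )
        res = pc.reconstruct_density(small, init, max_iter=100, cg_iters=80)
        data_rms = float(np.sqrt(np.mean(ds.shifts ** 2)))
        assert res.residual_norm < 0.01 * data_rms
        assert res.density.is_normalised

    def test_objective_decreases_monotonically(self, inverse_problem):
        f, _, _, _ = inverse_problem
        init = pc.DensityField(
            f.grid, np.where(f.mask, 1.0, 0.0) / (f.mask.sum() * f.grid.voxel_volume),
            f.mask,
        )
        res = pc.reconstruct_density(f, init, max_iter=40)
        h = np.array(res.objective_history)
        assert np.all(np.diff(h) <= 1e-12 * h[0])

    def test_iterates_stay_nonnegative_and_masked(self, inverse_problem):
        f, _, _, _ = inverse_problem
        init = pc.DensityField(
            f.grid, np.where(f.mask, 1.0, 0.0) / (f.mask.sum() * f.grid.voxel_volume),
            f.mask,
        )
        res = pc.reconstruct_density(f.with_lambda(1e-3), init, max_iter=30)
        assert np.all(res.density.values >= 0)
        assert not res.density.values[~f.mask].any()

    def test_gaussian_phantom_centroid_recovery(self):
        """Seeded parameter-recovery: phantom centroid found within 0.5 Å."""
        protein, ds, truth, chi, centers = pc.cavity_tag_problem(
            seed=30, n_residues=140, n_nuclei=200, truth_shape=40
        )
        lo, hi = protein.bounding_box()
        grid = pc.Grid3D.centered(
            0.5 * (lo + hi), float(np.max(hi - lo) + 2 * 15.0), 32
        )
        mask = pc.accessible_mask(protein, grid, 2.0, 12.0)
        cc = grid.voxel_centers()
        mask &= np.all(np.abs(cc - centers[0]) <= 10.0, axis=-1)
        f = pc.Functional(grid, mask, ds, chi, lam=1.0)
        init = pc.DensityField(
            grid, np.where(mask, 1.0, 0.0) / (mask.sum() * grid.voxel_volume), mask
        )
        lam_c = f.with_lambda(0.0).value(init.values)[1] / f.value(init.values)[2]
        curve = pc.lambda_sweep(
            f, np.logspace(np.log10(lam_c) - 3, np.log10(lam_c) + 3, 9), init,
            max_iter=60, cg_iters=50,
        )
        lam = pc.lcurve_corner(curve)
        res = pc.reconstruct_density(f.with_lambda(lam), init, max_iter=80)
        centroid = pc.density_centroid(res.density)
        assert np.linalg.norm(centroid - centers[0]) < 0.5


class TestSelfConsistent:
    @pytest.fixture(scope="class")
    def protocol_result(self):
        # delta-like truth: a narrow (1 Å) blob in the binding cleft
        protein, ds, truth, chi, centers = pc.cavity_tag_problem(
            seed=31, n_residues=140, n_nuclei=220, truth_shape=40, sigma=1.0
        )
        cfg = pc.ReconstructionConfig(
            coarse_shape=28, fine_shape=40, max_cycles=6, restarts=3,
            lcurve_every_cycle=False, n_lambdas=9, inner_refits=4,
        )
        res = pc.self_consistent_reconstruction(ds, protein, cfg)
        return protein, ds, truth, chi, centers, res

    def test_converges_in_few_cycles(self, protocol_result):
        *_, res = protocol_result
        assert res.cycles <= 3

    def test_recovers_effective_tensor(self, protocol_result):
        _, _, _, chi, _, res = protocol_result
        rel = (res.chi + (-1.0) * chi).frobenius / chi.frobenius
        assert rel < 0.02

    def test_point_fit_lands_near_density_centroid(self, protocol_result):
        """Unimodal problems: the point-model metal position is close to the
        reconstructed density's centroid."""
        protein, ds, _, _, centers, res = protocol_result
        pf = pc.fit_point_model(ds, ds.positions.mean(axis=0), restarts=3, seed=2017)
        centroid = pc.density_centroid(res.density)
        assert np.linalg.norm(pf.metal_pos - centroid) < 1.0

    def test_restart_on_consistent_data_is_stable(self, protocol_result):
        """Data back-calculated from the pipeline's own output reproduce
        that output: χ, the density and its centroid stay put."""
        protein, ds, _, _, _, res = protocol_result
        ds2 = pc.PCSDataset(
            ds.positions, res.back_calculated, ds.nucleus, ds.residues, ds.atoms
        )
        cfg = pc.ReconstructionConfig(
            coarse_shape=28, fine_shape=40, max_cycles=6, restarts=2,
            lcurve_every_cycle=False, n_lambdas=9,
            start_chi=res.chi, start_density=res.density, start_lambda=res.lam,
        )
        res2 = pc.self_consistent_reconstruction(ds2, protein, cfg)
        rel_chi = (res2.chi + (-1.0) * res.chi).frobenius / res.chi.frobenius
        assert rel_chi < 0.01
        v1, v2 = res.density.values, res2.density.values
        assert np.linalg.norm(v2 - v1) / np.linalg.norm(v1) < 0.2
        c1 = pc.density_centroid(res.density)
        c2 = pc.density_centroid(res2.density)
        assert np.linalg.norm(c2 - c1) < 0.2

    def test_bimodal_phantom_recovers_both_modes(self):
        """Two equal Gaussians 8 Å apart are both recovered (0.5% noise)."""
        protein, ds, truth, chi, centers = pc.cavity_tag_problem(
            seed=33, n_residues=150, n_nuclei=220, truth_shape=40,
            sigma=1.3, noise_frac=0.005,
            phantom_centers=[[-4.0, 0.0, 0.0], [4.0, 0.0, 0.0]],
        )
        cfg = pc.ReconstructionConfig(
            coarse_shape=28, fine_shape=40, max_cycles=4, restarts=3,
            lcurve_every_cycle=False, n_lambdas=9,
        )
        res = pc.self_consistent_reconstruction(ds, protein, cfg)
        v = res.density.values
        cc = res.density.grid.voxel_centers()
        for cx in (-4.0, 4.0):
            half = cc[..., 0] * np.sign(cx) > 0
            m = np.where(half, v, 0.0)
            assert m.sum() > 0.2 * v.sum()  # both modes carry real mass
            cen = np.einsum("ijk,ijkc->c", m, cc) / m.sum()
            assert np.linalg.norm(cen - [cx, 0.0, 0.0]) < 1.0
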