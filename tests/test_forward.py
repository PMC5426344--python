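"""Forward model: point formula, FFT field solve, sampling, accessibility."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import pcscloud as pc
from pcscloud.forward import sample_adjoint, sample_at


def axial_rhombic_pcs(nucleus, metal, dax, drh):
    """Independent oracle: the angular form of the point PCS formula,
    σ = 10⁶/(12π r³)·[Δχ_ax (3cos²θ−1) + (3/2) Δχ_rh sin²θ cos2φ]."""
    r = np.asarray(nucleus, float) - np.asarray(metal, float)
    d = np.linalg.norm(r)
    ct = r[2] / d
    phi = np.arctan2(r[1], r[0])
    st2 = 1.0 - ct ** 2
    return (
        1e6 / (12 * np.pi * d ** 3)
        * (dax * (3 * ct ** 2 - 1) + 1.5 * drh * st2 * np.cos(2 * phi))
    )


def _rasterised_ball(grid, radius, subs=6):
    """Unit-mass uniform ball, rasterised with sub-voxel fractional coverage."""
    centers = grid.voxel_centers()
    sub = (np.arange(subs) + 0.5) / subs - 0.5
    ox, oy, oz = np.meshgrid(sub, sub, sub, indexing="ij")
    offsets = np.stack([ox, oy, oz], -1).reshape(-1, 3)
    frac = np.zeros(grid.shape)
    for o in offsets:
        frac += np.linalg.norm(centers + o * grid.spacing, axis=-1) <= radius
    frac /= len(offsets)
    return frac / (frac.sum() * grid.voxel_volume)



class TestPointPCS:
    def test_zero_tensor_gives_zero_shift(self):
        assert pc.point_pcs([5.0, 3.0, 1.0], [0, 0, 0], pc.SusceptibilityTensor.zero()) == 0.0

    def test_magic_angle_cone_vanishes(self):
        chi = pc.SusceptibilityTensor.from_axial_rhombic(0.02, 0.0)
        ct = np.sqrt(1.0 / 3.0)  # 3cos²θ − 1 = 0
        st = np.sqrt(1 - ct ** 2)
        r = 8.0
        nucleus = [r * st * np.cos(0.7), r * st * np.sin(0.7), r * ct]
        assert pc.point_pcs(nucleus, [0, 0, 0], chi) == pytest.approx(0.0, abs=1e-15)

    def test_inverse_cube_distance_scaling(self, random_chi):
        direction = np.array([0.3, -0.5, 0.81])
        near = pc.point_pcs(5.0 * direction, [0, 0, 0], random_chi)
        far = pc.point_pcs(10.0 * direction, [0, 0, 0], random_chi)
        assert near == pytest.approx(8.0 * far, rel=1e-12)

    @pytest.mark.parametrize("dax,drh", [(0.02, 0.0), (0.015, 0.006), (-0.03, 0.004)])
    def test_matches_angular_form_oracle(self, rng, dax, drh):
        chi = pc.SusceptibilityTensor.from_axial_rhombic(dax, drh)
        for _ in range(20):
            nucleus = rng.uniform(-15, 15, size=3)
            if np.linalg.norm(nucleus) < 3:
                continue
            expected = axial_rhombic_pcs(nucleus, np.zeros(3), dax, drh)
            assert pc.point_pcs(nucleus, np.zeros(3), chi) == pytest.approx(
                expected, rel=1e-10, abs=1e-14
            )

    def test_translation_invariance(self, random_chi, rng):
        nucleus, metal = rng.uniform(-10, 10, 3), rng.uniform(-3, 3, 3)
        shift = rng.uniform(-20, 20, 3)
        assert pc.point_pcs(nucleus, metal, random_chi) == pytest.approx(
            pc.point_pcs(nucleus + shift, metal + shift, random_chi), rel=1e-12
        )

    def test_rotational_covariance(self, random_chi, rng):
        nucleus, metal = rng.uniform(-10, 10, 3), rng.uniform(-3, 3, 3)
        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        assert pc.point_pcs(nucleus, metal, random_chi) == pytest.approx(
            pc.point_pcs(R @ nucleus, R @ metal, random_chi.rotated(R)), rel=1e-10
        )

    def test_zero_separation_rejected(self, random_chi):
        with pytest.raises(ValueError, match="coincides"):
            pc.point_pcs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], random_chi)


class TestFieldFFT:
    def test_delta_density_matches_point_formula(self, delta_density, random_chi):
        """A one-voxel density must reproduce the point formula at distance."""
        field = pc.pcs_field_fft(delta_density, random_chi)
        g = delta_density.grid
        center = np.zeros(3)
        idx = np.indices(g.shape).reshape(3, -1).T
        d = np.linalg.norm(idx - 16, axis=1)
        sel = d >= 6
        ref = pc.point_pcs(g.index_to_world(idx[sel]), center, random_chi)
        got = field.values.reshape(-1)[sel.nonzero()[0]]
        scale = np.abs(ref).max()
        assert np.max(np.abs(got - ref)) <= 0.01 * scale

    def test_uniform_ball_equals_point_source_outside(self, random_chi):
        """Mean-value property: spherically symmetric density looks like a
        point centre from outside its support."""
        n, sp, a = 64, 0.5, 4.0
        g = pc.Grid3D(origin=[-sp * (n - 1) / 2] * 3, spacing=sp, shape=(n, n, n))
        centers = g.voxel_centers()
        ball = pc.DensityField(g, _rasterised_ball(g, a))
        field = pc.pcs_field_fft(ball, random_chi)
        d = np.linalg.norm(centers, axis=-1)
        support_r = d[ball.values > 0].max()
        sel = (d >= support_r + 2 * sp) & (d <= sp * (n - 1) / 2 - 1)
        ref = pc.point_pcs(centers.reshape(-1, 3)[sel.ravel()], np.zeros(3), random_chi)
        got = field.values[sel]
        assert np.max(np.abs(got - ref)) <= 0.005 * np.abs(ref).max()

    def test_linearity_in_chi_and_density(self, small_grid, random_chi, rng):
        g = small_grid
        v1 = rng.random(g.shape)
        v2 = rng.random(g.shape)
        f = lambda v, chi: pc.PCSForwardOperator(g, chi).apply(v)
        combo = f(2.0 * v1 + 3.0 * v2, random_chi)
        parts = 2.0 * f(v1, random_chi) + 3.0 * f(v2, random_chi)
        assert np.allclose(combo, parts, rtol=0, atol=1e-10 * np.abs(combo).max())
        assert np.allclose(
            f(v1, 3.0 * random_chi), 3.0 * f(v1, random_chi), rtol=1e-12
        )

    def test_matches_direct_space_convolution(self, rng, random_chi):
        """Brute-force O(N²) direct convolution oracle on a small grid."""
        g = pc.Grid3D(origin=[-8.0, -8.0, -8.0], spacing=1.0, shape=(16, 16, 16))
        blob = pc.gaussian_phantom(pc.PhantomSpec([(np.zeros(3), 1.2, 1.0)], g))
        field = pc.pcs_field_fft(blob, random_chi)
        centers = g.voxel_centers().reshape(-1, 3)
        w = blob.values.reshape(-1) * g.voxel_volume
        src = w > 1e-14
        # check a handful of exterior voxels against the double sum
        d = np.linalg.norm(centers, axis=1)
        far = np.nonzero(d > 6.0)[0]
        ref_scale = np.abs(field.values).max()
        for i in far[:: max(1, len(far) // 25)]:
            rel = centers[i] - centers[src]
            dd = np.linalg.norm(rel, axis=1)
            ok = dd > 1e-9
            quad = np.einsum("ij,jk,ik->i", rel[ok], random_chi.matrix, rel[ok])
            direct = 1e6 * np.sum(w[src][ok] * quad / (4 * np.pi * dd[ok] ** 5))
            assert abs(field.values.reshape(-1)[i] - direct) <= 0.01 * ref_scale

    def test_delta_limit_error_decreases_with_spacing(self, random_chi):
        """Finer grids approximate the point formula better at a fixed
        off-lattice probe position (trilinear-sampled)."""
        probe = np.array([9.3, 3.4, -2.1])
        errs = []
        for spacing, n in [(1.0, 32), (0.5, 64), (0.25, 128)]:
            c = n // 2
            g = pc.Grid3D(
                origin=-spacing * np.array([c, c, c], float),
                spacing=spacing, shape=(n, n, n),
            )
            v = np.zeros(g.shape)
            v[c, c, c] = 1.0 / g.voxel_volume
            field = pc.pcs_field_fft(pc.DensityField(g, v), random_chi)
            got = pc.sample_field(field, probe)[0]
            ref = pc.point_pcs(probe, np.zeros(3), random_chi)
            errs.append(abs(got - ref) / abs(ref))
        from pcscloud.forward import clear_kernel_cache

        clear_kernel_cache()  # the 256-cubed padded kernels are large
        assert errs[0] > errs[1] > errs[2]

    def test_zero_density_gives_zero_field(self, small_grid, random_chi):
        zero = np.zeros(small_grid.shape)
        assert not pc.PCSForwardOperator(small_grid, random_chi).apply(zero).any()

    def test_nonfinite_density_rejected(self, small_grid, random_chi):
        bad = np.zeros(small_grid.shape)
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            pc.PCSForwardOperator(small_grid, random_chi).apply(bad)

    def test_rotational_covariance_of_sampled_shifts(self, rng):
        """Rotating density, nuclei and χ together by a lattice symmetry
        (90° about z) leaves the sampled PCS invariant to near roundoff."""
        n, sp = 25, 1.0
        g = pc.Grid3D(origin=[-sp * (n - 1) / 2] * 3, spacing=sp, shape=(n, n, n))
        chi = pc.SusceptibilityTensor(0.01 * np.array(
            [[0.3, 0.7, -0.2], [0.7, -0.8, 0.4], [-0.2, 0.4, 0.5]]
        ))
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        blob = pc.gaussian_phantom(pc.PhantomSpec([([2.0, -1.0, 1.5], 1.3, 1.0)], g))
        # exact lattice rotation of the voxel values: ρ'(r) = ρ(R⁻¹ r)
        vrot = np.rot90(blob.values, k=1, axes=(0, 1))
        blob_rot = pc.DensityField(g, vrot)
        pos = rng.normal(size=(20, 3))
        pos = pos / np.linalg.norm(pos, axis=1)[:, None] * 7.0 + np.array([2.0, -1.0, 1.5])
        s1 = pc.sample_field(pc.pcs_field_fft(blob, chi), pos)
        s2 = pc.sample_field(pc.pcs_field_fft(blob_rot, chi.rotated(R)), (R @ pos.T).T)
        assert np.allclose(s1, s2, rtol=0, atol=1e-6 * np.abs(s1).max())


class TestSampling:
    def test_voxel_center_is_exact(self, small_grid, rng):
        v = rng.normal(size=small_grid.shape)
        p = small_grid.index_to_world(np.array([5.0, 7.0, 9.0]))
        assert sample_at(v, small_grid, p)[0] == pytest.approx(v[5, 7, 9], rel=1e-14)

    def test_linear_field_reproduced_exactly(self, small_grid, rng):
        x = small_grid.voxel_centers()[..., 0]
        pts = rng.uniform(-10, 10, size=(30, 3))
        got = sample_at(0.7 * x, small_grid, pts)
        assert np.allclose(got, 0.7 * pts[:, 0], rtol=1e-12, atol=1e-12)

    def test_adjoint_identity(self, small_grid, rng):
        field = rng.normal(size=small_grid.shape)
        pts = rng.uniform(-12, 12, size=(40, 3))
        w = rng.normal(size=40)
        lhs = np.dot(sample_at(field, small_grid, pts), w)
        rhs = np.sum(field * sample_adjoint(small_grid, pts, w))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_outside_position_names_offender(self, small_grid, rng):
        pts = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            sample_at(np.zeros(small_grid.shape), small_grid, pts)


class TestAccessibleMask:
    def test_single_atom_shell(self):
        protein = pc.ProteinStructure(
            ["C"], ["CA"], [1], ["ALA"], ["A"], [[0.0, 0.0, 0.0]]
        )
        g = pc.Grid3D(origin=[-15.0] * 3, spacing=1.0, shape=(31, 31, 31))
        mask = pc.accessible_mask(protein, g, 2.0, 12.0)
        centers = g.voxel_centers()
        d = np.linalg.norm(centers, axis=-1)
        assert np.array_equal(mask, (d >= 2.0) & (d <= 12.0))
        assert mask[15, 15, 20]       # (0,0,5)
        assert not mask[15, 15, 16]   # (0,0,1)
        assert not mask[15, 15, 28]   # (0,0,13)

    def test_degenerate_bounds_accept_everything(self, tiny_protein):
        g = pc.Grid3D(origin=[-40.0] * 3, spacing=4.0, shape=(20, 20, 20))
        assert pc.accessible_mask(tiny_protein, g, 0.0, np.inf).all()

    def test_two_atom_union_matches_brute_force(self):
        protein = pc.ProteinStructure(
            ["C", "C"], ["CA", "CA"], [1, 2], ["ALA", "ALA"], ["A", "A"],
            [[-15.0, 0, 0], [15.0, 0, 0]],
        )
        g = pc.Grid3D(origin=[-30.0] * 3, spacing=2.0, shape=(31, 31, 31))
        mask = pc.accessible_mask(protein, g, 2.0, 12.0)
        centers = g.voxel_centers()
        d = np.minimum(
            np.linalg.norm(centers - np.array([-15.0, 0, 0]), axis=-1),
            np.linalg.norm(centers - np.array([15.0, 0, 0]), axis=-1),
        )
        assert np.array_equal(mask, (d >= 2.0) & (d <= 12.0))

    def test_empty_mask_advises_bigger_grid(self, tiny_protein):
        g = pc.Grid3D(origin=[200.0, 200.0, 200.0], spacing=1.0, shape=(4, 4, 4))
        with pytest.raises(ValueError, match="enlarge the grid"):
            pc.accessible_mask(tiny_protein, g)
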