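"""Tikhonov-regularised reconstruction of the paramagnetic-centre density.

The unknown ρ ≥ 0 lives on the masked voxels of a grid. The objective is

    F[ρ] = Σᵢ wᵢ (P_N[σ_ρ](rᵢ) − σᵢ_obs)²  +  λ ‖∇²ρ‖²,

with σ_ρ the FFT-solved PCS field, P_N trilinear sampling at the nuclei, and
the penalty the squared 7-point discrete Laplacian norm (zero-Dirichlet
outside the mask), which favours smooth densities. The data map is linear in
ρ, so F is a convex quadratic; its exact gradient and Hessian action are the
first and second variations used by the bound-constrained projected
Newton–CG minimiser in :func:`reconstruct_density`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chitensor import SusceptibilityTensor
from .data import PCSDataset, ProteinStructure
from .forward import PCSForwardOperator, accessible_mask, sample_adjoint, sample_at
from .grid import DensityField, Grid3D

__all__ = [
    "Functional",
    "ReconstructionResult",
    "ReconstructionConfig",
    "error_functional",
    "functional_gradient",
    "hessian_action",
    "reconstruct_density",
    "self_consistent_reconstruction",
]

log = logging.getLogger(__name__)

# dense precomputed design rows are used below this element count
_PRECOMPUTE_BUDGET = 2.0e8


def _laplacian(x: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """7-point Laplacian with zero-Dirichlet values outside the array."""
    p = np.pad(x, 1)
    out = np.zeros_like(x)
    out += (p[2:, 1:-1, 1:-1] + p[:-2, 1:-1, 1:-1] - 2 * x) / spacing[0] ** 2
    out += (p[1:-1, 2:, 1:-1] + p[1:-1, :-2, 1:-1] - 2 * x) / spacing[1] ** 2
    out += (p[1:-1, 1:-1, 2:] + p[1:-1, 1:-1, :-2] - 2 * x) / spacing[2] ** 2
    return out


class Functional:
    """The regularised least-squares objective for a fixed χ, grid and mask.

    ``value``, ``gradient`` and ``hessian_action`` are mutually consistent
    (finite-difference and symmetry checked in the test suite). The per-datum
    design rows can be precomputed by adjoint-FFT backprojection, which makes
    repeated evaluations (λ sweeps, Newton iterations) dense-algebra fast
    without changing the operator.
    """

    def __init__(
        self,
        grid: Grid3D,
        mask: np.ndarray,
        dataset: PCSDataset,
        chi: SusceptibilityTensor,
        lam: float,
        pad: int = 2,
        precompute: bool | None = None,
    ):
        if lam < 0:
            raise ValueError("regularisation parameter must be >= 0")
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise ValueError("mask shape does not match grid shape")
        if not np.all(grid.contains(dataset.positions)):
            raise ValueError("all nuclei must lie inside the grid")
        self.grid = grid
        self.mask = mask
        self.dataset = dataset
        self.chi = chi
        self.lam = float(lam)
        self.pad = pad
        self.op = PCSForwardOperator(grid, chi, pad=pad)
        self._w = dataset.weights
        self._vol = grid.voxel_volume
        self._A = None
        n_el = len(dataset) * int(mask.sum())
        if precompute is None:
            precompute = n_el <= _PRECOMPUTE_BUDGET
        if precompute:
            self._A = self._build_design()

    # -- operators ----------------------------------------------------------
    def _build_design(self) -> np.ndarray:
        """N × n_mask design rows aᵢ = (Conv ∘ P_Nᵀ) eᵢ restricted to the mask."""
        n = len(self.dataset)
        rows = np.empty((n, int(self.mask.sum())))
        e = np.zeros(n)
        for i in range(n):
            e[i] = 1.0
            rows[i] = self.op.apply(
                sample_adjoint(self.grid, self.dataset.positions, e)
            )[self.mask]
            e[i] = 0.0
        return rows

    def forward(self, rho_values: np.ndarray) -> np.ndarray:
        """Back-calculated shifts (ppm) at the nuclei for voxel values ρ."""
        if self._A is not None:
            return self._A @ rho_values[self.mask]
        return sample_at(self.op.apply(rho_values), self.grid, self.dataset.positions)

    def _backproject(self, r: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`forward` applied to per-datum values."""
        if self._A is not None:
            out = np.zeros(self.grid.shape)
            out[self.mask] = self._A.T @ r
            return out
        return self.op.apply(sample_adjoint(self.grid, self.dataset.positions, r))

    # -- functional, variations --------------------------------------------
    def value(self, rho_values: np.ndarray):
        """(total, error_term, penalty_term) at the given voxel values."""
        if rho_values.shape != self.grid.shape:
            raise ValueError("density values do not match the functional's grid")
        resid = self.forward(rho_values) - self.dataset.shifts
        err = float(np.sum(self._w * resid ** 2))
        lap = _laplacian(rho_values, self.grid.spacing)
        pen = float(np.sum(lap ** 2) * self._vol)
        return err + self.lam * pen, err, pen

    def gradient(self, rho_values: np.ndarray) -> np.ndarray:
        resid = self.forward(rho_values) - self.dataset.shifts
        g = 2.0 * self._backproject(self._w * resid)
        lap = _laplacian(rho_values, self.grid.spacing)
        g += 2.0 * self.lam * self._vol * _laplacian(lap, self.grid.spacing)
        g[~self.mask] = 0.0
        return g

    def hessian_action(self, eta: np.ndarray) -> np.ndarray:
        """Action of the (Gauss–Newton = exact) Hessian on a probe field η."""
        eta = np.where(self.mask, eta, 0.0)
        h = 2.0 * self._backproject(self._w * self.forward(eta))
        h += 2.0 * self.lam * self._vol * _laplacian(
            _laplacian(eta, self.grid.spacing), self.grid.spacing
        )
        h[~self.mask] = 0.0
        return h

    def with_lambda(self, lam: float) -> "Functional":
        """Shallow clone with a different λ, sharing the cached operators."""
        f = object.__new__(Functional)
        f.__dict__.update(self.__dict__)
        f.lam = float(lam)
        return f


# -- spec-surface wrappers --------------------------------------------------

def error_functional(rho: DensityField, f: Functional):
    if not rho.grid.same_geometry(f.grid):
        raise ValueError("density grid does not match the functional's grid")
    return f.value(rho.values)


def functional_gradient(rho: DensityField, f: Functional) -> np.ndarray:
    if not rho.grid.same_geometry(f.grid):
        raise ValueError("density grid does not match the functional's grid")
    return f.gradient(rho.values)


def hessian_action(rho: DensityField, eta: np.ndarray, f: Functional) -> np.ndarray:
    return f.hessian_action(eta)


# -- bound-constrained minimiser --------------------------------------------

@dataclass
class ReconstructionResult:
    density: DensityField
    chi: SusceptibilityTensor
    lam: float
    residual_norm: float
    penalty_norm: float
    iterations: int
    converged: bool
    back_calculated: np.ndarray
    mass_scale: float = 1.0
    objective_history: list = field(default_factory=list)
    raw_values: np.ndarray = None
    cycles: int = 0
    lcurve: object = None


def reconstruct_density(
    f: Functional,
    init: DensityField,
    max_iter: int = 80,
    gtol: float | None = None,
    cg_iters: int = 60,
) -> ReconstructionResult:
    """Minimise F[ρ] subject to ρ ≥ 0 on the mask.

    Projected Newton–CG: at each outer iteration the active set (voxels pinned
    at zero with outward gradient) is frozen, a truncated CG solve of the
    Newton system on the free voxels gives the step, and a projected
    backtracking line search enforces sufficient decrease. Terminates when the
    projected-gradient infinity norm drops below ``gtol`` (default 1e-6 × its
    initial value). The returned density is renormalised to unit mass with the
    applied scale reported in ``mass_scale``.
    """
    if not init.grid.same_geometry(f.grid):
        raise ValueError("initial density grid does not match the functional")
    x = np.where(f.mask, np.clip(init.values, 0.0, None), 0.0)
    fx, err, pen = f.value(x)
    if not np.isfinite(fx):
        raise ValueError("objective is not finite at the initial point")
    g = f.gradient(x)
    pg = np.where((x <= 0.0) & (g > 0.0), 0.0, g)
    pg0 = np.abs(pg).max()
    if gtol is None:
        gtol = 1e-6 * max(pg0, 1e-300)
    history = [fx]
    converged = pg0 <= gtol
    it = 0
    while not converged and it < max_iter:
        it += 1
        free = f.mask & ((x > 0.0) | (g < 0.0))
        d = _truncated_cg(f, g, free, cg_iters)
        gd = float(np.sum(g * d))
        if gd >= 0.0:
            d = -pg
            gd = float(np.sum(g * d))
            if gd >= 0.0:
                break
        alpha, fn, xn = 1.0, None, None
        for _ in range(50):
            xn = np.clip(x + alpha * d, 0.0, None)
            xn[~f.mask] = 0.0
            fn = f.value(xn)[0]
            if not np.isfinite(fn):
                raise RuntimeError("objective became non-finite during line search")
            gstep = float(np.sum(g * (xn - x)))
            if fn <= fx + 1e-4 * gstep or gstep >= 0.0:
                break
            alpha *= 0.5
        if fn >= fx * (1.0 - 1e-14) and fn >= fx - 1e-14 * (abs(fx) + 1.0):
            # stagnation: the objective can no longer decrease at FP
            # resolution, which is the practical optimum of the quadratic
            x = np.where(fn < fx, xn, x)
            history.append(min(fn, fx))
            converged = True
            break
        x, fx = xn, fn
        history.append(fx)
        g = f.gradient(x)
        pg = np.where((x <= 0.0) & (g > 0.0), 0.0, g)
        converged = np.abs(pg).max() <= gtol
    if not converged and it >= max_iter:
        log.info("reconstruction stopped at max_iter=%d (pg=%.3e)", max_iter, np.abs(pg).max())
    _, err, pen = f.value(x)
    back = f.forward(x)
    resid_rms = float(np.sqrt(np.mean((back - f.dataset.shifts) ** 2)))
    mass = float(x.sum() * f.grid.voxel_volume)
    if mass <= 0.0:
        raise RuntimeError(
            "reconstruction collapsed to a zero-mass density; "
            "check the mask, the initial guess and the data scale"
        )
    density = DensityField(f.grid, x / mass, f.mask.copy())
    return ReconstructionResult(
        density=density,
        chi=f.chi,
        lam=f.lam,
        residual_norm=resid_rms,
        penalty_norm=float(np.sqrt(pen)),
        iterations=it,
        converged=bool(converged),
        back_calculated=back,
        mass_scale=1.0 / mass,
        objective_history=history,
        raw_values=x,
    )


def _truncated_cg(f: Functional, g: np.ndarray, free: np.ndarray, max_cg: int) -> np.ndarray:
    """Truncated CG on the free set for H d = −g; returns a full-grid step."""
    b = np.where(free, -g, 0.0)
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = float(np.sum(r * r))
    if rs == 0.0:
        return x
    tol2 = (0.05 ** 2) * rs
    for _ in range(max_cg):
        hp = f.hessian_action(p)
        hp[~free] = 0.0
        php = float(np.sum(p * hp))
        if php <= 1e-300:
            break
        alpha = rs / php
        x += alpha * p
        r -= alpha * hp
        rs_new = float(np.sum(r * r))
        if rs_new <= tol2:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


# -- the full protocol -------------------------------------------------------

@dataclass
class ReconstructionConfig:
    """Protocol parameters for the two-stage, self-consistent reconstruction.

    Grid shapes default to desk-scale 64³ (localisation) and 96³ (refinement);
    the accessibility shell is 2–12 Å from the protein, and the refinement
    mask is a 20 Å cube around the coarse centroid.
    """

    coarse_shape: int = 64
    fine_shape: int = 96
    r_min: float = 2.0
    r_max: float = 12.0
    crop_side: float = 20.0
    grid_margin: float = 3.0
    n_lambdas: int = 15
    lambda_decades: float = 6.0
    lcurve_every_cycle: bool = True
    max_cycles: int = 20
    inner_refits: int = 3
    tol_chi: float = 1e-3
    tol_rho: float = 1e-3
    seed: int = 2017
    restarts: int = 8
    max_iter: int = 80
    cg_iters: int = 60
    gtol_rel: float = 1e-6
    pad: int = 2
    start_pos: tuple | None = None
    start_chi: SusceptibilityTensor | None = None
    start_density: "DensityField | None" = None
    start_lambda: float | None = None


def _uniform_on_mask(grid: Grid3D, mask: np.ndarray) -> DensityField:
    v = np.where(mask, 1.0, 0.0)
    v /= v.sum() * grid.voxel_volume
    return DensityField(grid, v, mask)


def _protocol_grid(protein: ProteinStructure, dataset: PCSDataset, cfg, shape: int) -> Grid3D:
    lo, hi = protein.bounding_box()
    lo = np.minimum(lo, dataset.positions.min(axis=0))
    hi = np.maximum(hi, dataset.positions.max(axis=0))
    margin = cfg.r_max + cfg.grid_margin
    extent = float(np.max(hi - lo) + 2 * margin)
    center = 0.5 * (lo + hi)
    return Grid3D.centered(center, extent, shape)


def _morozov_guess(f: Functional, init: DensityField) -> float:
    """Balance point of the two terms at the initial guess — the centre of the λ grid."""
    _, err, pen = f.value(init.values)
    if pen <= 0:
        return 1.0
    return max(err / pen, 1e-30)


def self_consistent_reconstruction(
    dataset: PCSDataset,
    protein: ProteinStructure,
    config: ReconstructionConfig | None = None,
) -> ReconstructionResult:
    """Full protocol: point fit → coarse localisation → cropped refinement with
    per-cycle L-curve λ selection and effective-χ re-fit, iterated to
    self-consistency between χ and ρ."""
    from .lcurve import lambda_sweep, lcurve_corner
    from .pointfit import fit_point_model, refit_chi_given_density

    cfg = config or ReconstructionConfig()

    from .postprocess import density_centroid

    # (1) point-model fit seeds χ (unless a starting tensor is supplied)
    if cfg.start_chi is not None:
        chi = cfg.start_chi
    else:
        start = (
            np.asarray(cfg.start_pos, dtype=float)
            if cfg.start_pos is not None
            else dataset.positions.mean(axis=0)
        )
        pf = fit_point_model(dataset, start, restarts=cfg.restarts, seed=cfg.seed)
        chi = pf.chi
        log.info(
            "point fit: pos=%s rms=%.4g ppm", np.round(pf.metal_pos, 2), pf.rms_residual
        )

    # (2) coarse localisation on the full accessibility shell (skipped when a
    # starting density already provides the crop centre)
    if cfg.start_density is not None:
        center = density_centroid(cfg.start_density)
    else:
        cgrid = _protocol_grid(protein, dataset, cfg, cfg.coarse_shape)
        cmask = accessible_mask(protein, cgrid, cfg.r_min, cfg.r_max)
        cinit = _uniform_on_mask(cgrid, cmask)
        f0 = Functional(cgrid, cmask, dataset, chi, lam=0.0, pad=cfg.pad)
        f0 = f0.with_lambda(_morozov_guess(f0, cinit))
        coarse = reconstruct_density(
            f0, cinit, max_iter=cfg.max_iter, cg_iters=cfg.cg_iters
        )
        center = density_centroid(coarse.density)
    log.info("coarse centroid: %s", np.round(center, 2))

    # (3) refinement mask: accessibility ∩ crop cube around the coarse centroid
    fgrid = _protocol_grid(protein, dataset, cfg, cfg.fine_shape)
    fmask = accessible_mask(protein, fgrid, cfg.r_min, cfg.r_max)
    centers = fgrid.voxel_centers()
    cube = np.all(np.abs(centers - center) <= cfg.crop_side / 2.0, axis=-1)
    fmask &= cube
    if not fmask.any():
        raise RuntimeError(
            "refinement mask is empty: the coarse stage produced a centroid "
            "outside the accessible volume"
        )

    # (4) self-consistency cycles
    rho_prev = None
    result = None
    if cfg.start_density is not None and cfg.start_density.grid.same_geometry(fgrid):
        v = np.where(fmask, cfg.start_density.values, 0.0)
        if v.sum() > 0:
            init = DensityField(fgrid, v / (v.sum() * fgrid.voxel_volume), fmask)
            rho_prev = init.values
        else:
            init = _uniform_on_mask(fgrid, fmask)
    else:
        init = _uniform_on_mask(fgrid, fmask)
    lam = cfg.start_lambda
    curve = None
    for cycle in range(1, cfg.max_cycles + 1):
        f = Functional(fgrid, fmask, dataset, chi, lam=1.0, pad=cfg.pad)
        if cfg.lcurve_every_cycle or lam is None:
            lam_c = _morozov_guess(f.with_lambda(0.0), init)
            half = cfg.lambda_decades / 2.0
            lambdas = np.logspace(
                np.log10(lam_c) - half, np.log10(lam_c) + half, cfg.n_lambdas
            )
            curve = lambda_sweep(
                f, lambdas, init, max_iter=cfg.max_iter, cg_iters=cfg.cg_iters
            )
            lam = lcurve_corner(curve)
        result = reconstruct_density(
            f.with_lambda(lam), init, max_iter=cfg.max_iter, cg_iters=cfg.cg_iters
        )
        chi_new = refit_chi_given_density(result.density, dataset, pad=cfg.pad)
        # inner χ/ρ alternations sharpen the fixed point within the cycle
        for _ in range(max(cfg.inner_refits - 1, 0)):
            f_in = Functional(fgrid, fmask, dataset, chi_new, lam=lam, pad=cfg.pad)
            result = reconstruct_density(
                f_in, result.density, max_iter=cfg.max_iter, cg_iters=cfg.cg_iters
            )
            chi_new = refit_chi_given_density(result.density, dataset, pad=cfg.pad)
        dchi = (chi_new + (-1.0) * chi).frobenius / max(chi_new.frobenius, 1e-300)
        rho = result.density.values
        if rho_prev is None:
            drho = np.inf
        else:
            drho = float(
                np.linalg.norm(rho - rho_prev) / max(np.linalg.norm(rho), 1e-300)
            )
        log.info(
            "cycle %d: lambda=%.3g resid=%.4g dchi=%.3g drho=%.3g",
            cycle, lam, result.residual_norm, dchi, drho,
        )
        chi = chi_new
        rho_prev = rho
        init = result.density
        result.cycles = cycle
        result.lcurve = curve
        if dchi < cfg.tol_chi and drho < cfg.tol_rho:
            break
    else:
        warnings.warn("self-consistency loop hit the cycle limit", stacklevel=2)

    # report with the final χ
    f_final = Functional(fgrid, fmask, dataset, chi, lam=lam, pad=cfg.pad)
    back = f_final.forward(result.density.values)
    result.chi = chi
    result.back_calculated = back
    result.residual_norm = float(np.sqrt(np.mean((back - dataset.shifts) ** 2)))
    return result
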