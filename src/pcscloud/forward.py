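"""Forward PCS model.

The pseudocontact shift of a nucleus at position r relative to a point
paramagnetic centre with traceless susceptibility tensor χ (Å³) is

    σ(r) = 10⁶ · (rᵀ χ r) / (4π |r|⁵)   [ppm],

equivalently σ = 10⁶/(12π r³) · [Δχ_ax (3cos²θ − 1) + (3/2) Δχ_rh sin²θ cos2φ]
in the principal frame. For a centre distributed with probability density
ρ(r) the observed field is the convolution of ρ with this kernel; it obeys an
elliptic PDE whose solution is computed here by FFT: the kernel is tabulated
on a zero-padded grid (≥2× each axis, so periodic images never overlap the
physical box) and the convolution is carried out in Fourier space. The
singular r = 0 voxel carries zero kernel weight, consistent with the zero
angular mean of the point formula.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .chitensor import CHI_BASIS, SusceptibilityTensor
from .data import ProteinStructure
from .grid import DensityField, Grid3D, ScalarField

__all__ = [
    "point_pcs",
    "pcs_field_fft",
    "PCSForwardOperator",
    "sample_field",
    "sample_at",
    "sample_adjoint",
    "accessible_mask",
    "clear_kernel_cache",
]

PPM = 1.0e6  # dimensionless shift -> ppm


def point_pcs(nucleus_pos, metal_pos, chi: SusceptibilityTensor) -> float:
    """Point-centre PCS (ppm) at ``nucleus_pos`` for a metal at ``metal_pos``.

    ``nucleus_pos`` may be a single 3-vector or an (N, 3) array.
    Raises ``ValueError`` on zero metal–nucleus separation (the formula is
    singular there).
    """
    r = np.atleast_2d(np.asarray(nucleus_pos, dtype=float)) - np.asarray(
        metal_pos, dtype=float
    )
    d2 = np.einsum("ij,ij->i", r, r)
    if np.any(d2 == 0.0):
        raise ValueError("nucleus coincides with the paramagnetic centre")
    m = chi.matrix if isinstance(chi, SusceptibilityTensor) else np.asarray(chi)
    quad = np.einsum("ij,jk,ik->i", r, m, r)
    out = PPM * quad / (4.0 * np.pi * d2 ** 2.5)
    return float(out[0]) if np.ndim(nucleus_pos) == 1 else out


def _design_point(nucleus_pos, metal_pos) -> np.ndarray:
    """N×5 matrix of point-PCS values for the five χ basis tensors."""
    cols = [point_pcs(nucleus_pos, metal_pos, SusceptibilityTensor(B)) for B in CHI_BASIS]
    return np.column_stack(cols)


# --------------------------------------------------------------------------
# FFT convolution on the grid
# --------------------------------------------------------------------------

_KERNEL_CACHE: dict = {}


def clear_kernel_cache() -> None:
    _KERNEL_CACHE.clear()


_NEARFIELD_RADIUS = 6  # voxels within which the kernel is box-averaged
_NEARFIELD_SUB = 5  # sub-samples per axis for the box average


def _quad_over_r5(rel: np.ndarray, B: np.ndarray) -> np.ndarray:
    """(rᵀ B r) / (4π r⁵) with the singular r = 0 entries zeroed."""
    r2 = np.einsum("...i,...i->...", rel, rel)
    quad = np.einsum("...i,ij,...j->...", rel, B, rel)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = quad / (4.0 * np.pi * r2 ** 2.5)
    return np.where(r2 == 0.0, 0.0, out)


def _basis_kernel_ffts(padded_shape: tuple, spacing: tuple) -> list:
    """rFFTs of the five χ-basis kernels on the padded circular grid.

    The kernel is the point formula evaluated at voxel-centre offsets; at
    offsets within a few voxels of the origin, where it varies steeply, it is
    replaced by its box average over the voxel — the exact interaction for a
    piecewise-constant density. The central voxel's box integral vanishes by
    cube symmetry for a traceless tensor.
    """
    key = (padded_shape, spacing)
    if key in _KERNEL_CACHE:
        return _KERNEL_CACHE[key]
    N = padded_shape
    sp = np.asarray(spacing)
    ax = [np.fft.fftfreq(N[a]) * N[a] * sp[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    rel = np.stack([X, Y, Z], axis=-1)
    # near-origin voxels (in circular-offset coordinates)
    idx = [np.abs(np.fft.fftfreq(N[a]) * N[a]) <= _NEARFIELD_RADIUS for a in range(3)]
    near = np.logical_and.outer(np.logical_and.outer(idx[0], idx[1]), idx[2])
    near &= ~((X == 0) & (Y == 0) & (Z == 0))
    sub = (np.arange(_NEARFIELD_SUB) + 0.5) / _NEARFIELD_SUB - 0.5
    ox, oy, oz = np.meshgrid(sub * sp[0], sub * sp[1], sub * sp[2], indexing="ij")
    offsets = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)
    near_rel = rel[near]
    ffts = []
    for B in CHI_BASIS:
        ker = _quad_over_r5(rel, B)
        avg = np.zeros(len(near_rel))
        for o in offsets:
            avg += _quad_over_r5(near_rel + o, B)
        ker[near] = avg / len(offsets)
        ffts.append(np.fft.rfftn(ker))
    if len(_KERNEL_CACHE) > 6:
        _KERNEL_CACHE.clear()
    _KERNEL_CACHE[key] = ffts
    return ffts


class PCSForwardOperator:
    """Linear map ρ(voxel values, Å⁻³) → σ(voxel values, ppm) on a fixed grid.

    The operator is symmetric on the grid (even kernel), which the inversion
    relies on: the adjoint of the field solve is the field solve itself.
    """

    def __init__(self, grid: Grid3D, chi: SusceptibilityTensor, pad: int = 2):
        if pad < 2:
            raise ValueError("padding factor must be >= 2 to suppress wrap-around")
        self.grid = grid
        self.chi = chi
        self.pad = pad
        self.padded_shape = tuple(pad * s for s in grid.shape)
        basis = _basis_kernel_ffts(self.padded_shape, tuple(grid.spacing))
        p = chi.params
        mult = p[0] * basis[0]
        for c in range(1, 5):
            if p[c] != 0.0:
                mult = mult + p[c] * basis[c]
        # voxel mass = value * voxel_volume; PPM converts to ppm
        self._mult = mult * (grid.voxel_volume * PPM)

    def apply(self, rho_values: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(rho_values)):
            raise ValueError("density values must be finite")
        n = self.grid.shape
        padded = np.zeros(self.padded_shape)
        padded[: n[0], : n[1], : n[2]] = rho_values
        out = np.fft.irfftn(
            np.fft.rfftn(padded) * self._mult, s=self.padded_shape, axes=(0, 1, 2)
        )
        return out[: n[0], : n[1], : n[2]]


def pcs_field_fft(
    density: DensityField, chi: SusceptibilityTensor, pad: int = 2
) -> ScalarField:
    """Solve for the PCS field σ(r) (ppm) of a distributed centre by FFT."""
    op = PCSForwardOperator(density.grid, chi, pad=pad)
    return ScalarField(density.grid, op.apply(density.values))


# --------------------------------------------------------------------------
# Sampling operator P_N and its adjoint
# --------------------------------------------------------------------------

def _trilinear_weights(grid: Grid3D, positions: np.ndarray):
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    f = grid.world_to_index(pos)
    inside = np.all((f >= 0) & (f <= np.array(grid.shape) - 1), axis=1)
    if not np.all(inside):
        bad = np.nonzero(~inside)[0]
        raise ValueError(
            f"positions outside the interpolatable grid region at rows {bad[:10].tolist()}"
        )
    i0 = np.minimum(np.floor(f).astype(int), np.array(grid.shape) - 2)
    i0 = np.maximum(i0, 0)
    t = f - i0
    return i0, t


def sample_at(field_values: np.ndarray, grid: Grid3D, positions: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of grid values at world positions (the P_N operator)."""
    i0, t = _trilinear_weights(grid, positions)
    out = np.zeros(len(i0))
    for dx in (0, 1):
        wx = t[:, 0] if dx else 1 - t[:, 0]
        for dy in (0, 1):
            wy = t[:, 1] if dy else 1 - t[:, 1]
            for dz in (0, 1):
                wz = t[:, 2] if dz else 1 - t[:, 2]
                out += (
                    wx * wy * wz
                    * field_values[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
                )
    return out


def sample_field(field: ScalarField, positions: np.ndarray) -> np.ndarray:
    return sample_at(field.values, field.grid, positions)


def sample_adjoint(grid: Grid3D, positions: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Adjoint of ``sample_at``: scatter weights onto the grid with the same
    trilinear stencils, so ⟨P f, w⟩ = ⟨f, Pᵀ w⟩ exactly."""
    i0, t = _trilinear_weights(grid, positions)
    w = np.asarray(weights, dtype=float).reshape(len(i0))
    out = np.zeros(grid.shape)
    for dx in (0, 1):
        wx = t[:, 0] if dx else 1 - t[:, 0]
        for dy in (0, 1):
            wy = t[:, 1] if dy else 1 - t[:, 1]
            for dz in (0, 1):
                wz = t[:, 2] if dz else 1 - t[:, 2]
                np.add.at(
                    out,
                    (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz),
                    w * wx * wy * wz,
                )
    return out


# --------------------------------------------------------------------------
# Accessible volume
# --------------------------------------------------------------------------

def accessible_mask(
    protein: ProteinStructure,
    grid: Grid3D,
    r_min: float = 2.0,
    r_max: float = 12.0,
) -> np.ndarray:
    """Boolean mask of voxels whose centre lies between ``r_min`` and ``r_max``
    Å from the nearest protein atom — the volume realistically accessible to a
    surface-attached tag."""
    if len(protein) == 0:
        raise ValueError("protein structure is empty")
    tree = cKDTree(protein.positions)
    centers = grid.voxel_centers().reshape(-1, 3)
    d, _ = tree.query(centers, k=1)
    mask = ((d >= r_min) & (d <= r_max)).reshape(grid.shape)
    if not mask.any():
        raise ValueError(
            "accessible mask is empty; enlarge the grid so it covers the "
            f"protein plus the {r_max} Å outer radius"
        )
    return mask
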