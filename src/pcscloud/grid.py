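"""Regular Cartesian grids and the scalar/density fields that live on them.

All coordinates are in Å, right-handed, voxel-centre convention: the centre of
voxel (i, j, k) sits at ``origin + (i, j, k) * spacing`` with 0-based indices
and axis order (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid3D", "ScalarField", "DensityField"]


@dataclass(frozen=True)
class Grid3D:
    """A regular Cartesian grid.

    Parameters
    ----------
    origin : (3,) array-like
        Position of the centre of voxel (0, 0, 0), in Å.
    spacing : (3,) array-like or scalar
        Voxel edge lengths per axis, in Å; strictly positive.
    shape : (3,) ints
        Number of voxels per axis.
    """

    origin: np.ndarray
    spacing: np.ndarray
    shape: tuple

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        shape = tuple(int(s) for s in np.atleast_1d(self.shape).reshape(-1))
        if len(shape) != 3:
            raise ValueError("shape must have three components")
        if any(s <= 0 for s in shape):
            raise ValueError("shape components must be positive")
        if not np.all(spacing > 0):
            raise ValueError("spacing components must be strictly positive")
        if not np.all(np.isfinite(origin)):
            raise ValueError("origin must be finite")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "shape", shape)

    # -- geometry -----------------------------------------------------------
    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> np.ndarray:
        """Physical edge lengths (Å) spanned by the voxel array."""
        return np.array(self.shape) * self.spacing

    def axes(self):
        """Per-axis voxel-centre coordinates (three 1-D arrays)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def voxel_centers(self) -> np.ndarray:
        """All voxel-centre positions, shape ``(*shape, 3)``."""
        ax = self.axes()
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)

    def world_to_index(self, positions: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world positions (Å)."""
        p = np.atleast_2d(np.asarray(positions, dtype=float))
        return (p - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return self.origin + idx * self.spacing

    def contains(self, positions: np.ndarray, margin_voxels: float = 0.0) -> np.ndarray:
        """True where a position lies inside the trilinear-interpolatable region."""
        f = self.world_to_index(positions)
        lo = margin_voxels
        hi = np.array(self.shape) - 1 - margin_voxels
        return np.all((f >= lo) & (f <= hi), axis=-1)

    def same_geometry(self, other: "Grid3D", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, rtol=rtol, atol=1e-9)
            and np.allclose(self.spacing, other.spacing, rtol=rtol, atol=1e-12)
        )

    @classmethod
    def centered(cls, center, extent, shape) -> "Grid3D":
        """Grid of a given physical extent centred on ``center``."""
        center = np.asarray(center, dtype=float)
        shape = np.broadcast_to(np.atleast_1d(shape), (3,))
        shape = tuple(int(s) for s in shape)
        extent = np.broadcast_to(np.asarray(extent, dtype=float), (3,))
        spacing = extent / np.array(shape)
        origin = center - spacing * (np.array(shape) - 1) / 2.0
        return cls(origin=origin, spacing=spacing, shape=shape)


@dataclass
class ScalarField:
    """A real scalar field (e.g. a PCS field in ppm) sampled at voxel centres."""

    grid: Grid3D
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar field contains non-finite values")


@dataclass
class DensityField:
    """A non-negative probability density ρ(r) on a grid, in Å⁻³.

    ``mask`` marks the variational support: values are zero wherever the mask
    is False. A normalised field integrates to one
    (``values.sum() * voxel_volume == 1``).
    """

    grid: Grid3D
    values: np.ndarray
    mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape does not match grid shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density contains non-finite values")
        if np.any(self.values < -1e-12 * max(self.values.max(initial=0.0), 1.0)):
            raise ValueError("density contains negative values")
        self.values = np.clip(self.values, 0.0, None)
        self.values[~self.mask] = 0.0

    @property
    def total_mass(self) -> float:
        return float(self.values.sum() * self.grid.voxel_volume)

    @property
    def is_normalised(self) -> bool:
        return abs(self.total_mass - 1.0) <= 1e-8

    def normalised(self) -> tuple["DensityField", float]:
        """Unit-mass copy; returns ``(field, scale)`` with ``scale`` the applied factor."""
        m = self.total_mass
        if m <= 0:
            raise ValueError("cannot normalise a zero-mass density")
        return DensityField(self.grid, self.values / m, self.mask.copy()), 1.0 / m

    def copy(self) -> "DensityField":
        return DensityField(self.grid, self.values.copy(), self.mask.copy())
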