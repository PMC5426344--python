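"""Rotamer library construction for a flexible lanthanide tag.

A tag attached through a flexible linker explores a set of conformers
("rotamers") defined by its dihedral angles. The library is built by
Monte-Carlo sampling of the dihedrals, Boltzmann weighting with a pluggable
energy function, UPGMA (average-linkage) agglomerative clustering under a
periodic dihedral-space metric, and per-cluster Boltzmann averaging. For the
DOTA-M8 linker the per-dihedral energy-minimum multiplicities
(2, 2, 2, 3, 3, 3, 3, 3) multiply to 1944 — the target cluster count.

The dihedral-space distance between two angle sets is the Euclidean norm of
the per-angle circular differences (each wrapped into [−180°, 180°]), so
359° and 1° differ by 2°, not 358°.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .forward import sample_adjoint
from .grid import DensityField, Grid3D

__all__ = [
    "DihedralSpec",
    "RotamerEnsemble",
    "RotamerLibrary",
    "dihedral_distance",
    "sample_ensemble",
    "upgma_cluster",
    "metal_cloud",
    "dihedral_chain_geometry",
    "soft_lennard_jones_energy",
    "DOTA_M8_MULTIPLICITIES",
]

#: Energy-minimum multiplicities of the DOTA-M8 linker dihedrals.
DOTA_M8_MULTIPLICITIES = (2, 2, 2, 3, 3, 3, 3, 3)


@dataclass
class DihedralSpec:
    """Description of the tag's rotatable dihedrals.

    ``energy_fn`` maps an angle vector (degrees) to an energy in kT units
    (temperature scaling belongs inside the callable); ``None`` means a flat
    energy landscape.
    """

    n_angles: int
    minima_multiplicities: tuple
    energy_fn: object = None

    def __post_init__(self):
        self.minima_multiplicities = tuple(int(m) for m in self.minima_multiplicities)
        if len(self.minima_multiplicities) != self.n_angles:
            raise ValueError("one multiplicity per dihedral angle is required")
        if any(m < 1 for m in self.minima_multiplicities):
            raise ValueError("multiplicities must be >= 1")

    @property
    def target_clusters(self) -> int:
        """Product of the per-dihedral minima counts — the cluster target."""
        return int(np.prod(self.minima_multiplicities))


@dataclass
class RotamerEnsemble:
    samples: np.ndarray  # (M, n_angles), degrees in [0, 360)
    boltzmann_weights: np.ndarray  # (M,), normalised

    def __post_init__(self):
        self.samples = np.mod(np.asarray(self.samples, dtype=float), 360.0)
        self.boltzmann_weights = np.asarray(self.boltzmann_weights, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (M, n_angles) array")
        if len(self.boltzmann_weights) != len(self.samples):
            raise ValueError("one weight per sample is required")
        s = self.boltzmann_weights.sum()
        if s <= 0:
            raise ValueError("weights must have positive total")
        self.boltzmann_weights = self.boltzmann_weights / s


@dataclass
class RotamerLibrary:
    rotamers: np.ndarray  # (K, n_angles) Boltzmann-circular-mean angles
    populations: np.ndarray  # (K,), sums to 1
    members: np.ndarray  # (M,) cluster id per ensemble sample
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.populations = np.asarray(self.populations, dtype=float)
        if abs(self.populations.sum() - 1.0) > 1e-10:
            raise ValueError("rotamer populations must sum to 1")


def _circular_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.mod(np.asarray(a, float) - np.asarray(b, float) + 180.0, 360.0) - 180.0
    return d


def dihedral_distance(a, b) -> float:
    """Periodic dihedral-space distance (degrees) between two angle vectors."""
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise ValueError("angle vectors must have equal length")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("angles must be finite")
    return float(np.sqrt(np.sum(_circular_diff(a, b) ** 2)))


def _pairwise_condensed(samples: np.ndarray) -> np.ndarray:
    """Condensed pairwise dihedral distances (for the UPGMA tree)."""
    # embed on the torus: the chordal distance per angle is monotone in the
    # circular difference, but UPGMA needs the metric itself, so compute it
    m = len(samples)
    out = np.empty(m * (m - 1) // 2)
    k = 0
    for i in range(m - 1):
        d = _circular_diff(samples[i + 1 :], samples[i])
        out[k : k + m - 1 - i] = np.sqrt(np.sum(d * d, axis=1))
        k += m - 1 - i
    return out


def sample_ensemble(spec: DihedralSpec, M: int, seed: int) -> RotamerEnsemble:
    """Seeded Monte-Carlo draw of M dihedral vectors with Boltzmann weights.

    Proposals are independent uniform draws per angle; importance weights
    carry the Boltzmann factor exp(−E/kT). Samples where the energy is
    non-finite get zero weight; more than 50% such samples is an error.
    """
    if M < 10 * spec.target_clusters:
        warnings.warn(
            f"M={M} is below the recommended 10 × {spec.target_clusters} samples",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    samples = rng.uniform(0.0, 360.0, size=(M, spec.n_angles))
    if spec.energy_fn is None:
        weights = np.full(M, 1.0 / M)
    else:
        energies = np.array([float(spec.energy_fn(s)) for s in samples])
        bad = ~np.isfinite(energies)
        if bad.mean() > 0.5:
            raise ValueError(
                f"energy function returned non-finite values on "
                f"{100 * bad.mean():.0f}% of samples"
            )
        e = np.where(bad, np.inf, energies)
        e = e - e[np.isfinite(e)].min()
        weights = np.exp(-e)
        weights[bad] = 0.0
        weights /= weights.sum()
    return RotamerEnsemble(samples, weights)


def _weighted_circular_mean(angles: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-angle weighted mean direction, in degrees [0, 360)."""
    rad = np.deg2rad(angles)
    s = np.sum(weights[:, None] * np.sin(rad), axis=0)
    c = np.sum(weights[:, None] * np.cos(rad), axis=0)
    return np.mod(np.rad2deg(np.arctan2(s, c)), 360.0)


def upgma_cluster(ensemble: RotamerEnsemble, K: int) -> RotamerLibrary:
    """Cut the UPGMA (average-linkage) tree at K clusters.

    Rotamer angles are per-cluster Boltzmann-weighted circular means;
    populations are per-cluster sums of the sample weights.
    """
    M = len(ensemble.samples)
    if K > M:
        raise ValueError(f"cannot form K={K} clusters from {M} samples")
    n_distinct = len(np.unique(ensemble.samples, axis=0))
    if K > n_distinct:
        raise ValueError(f"only {n_distinct} distinct samples for K={K} clusters")
    if K == M:
        labels = np.arange(M)
    else:
        cond = _pairwise_condensed(ensemble.samples)
        Z = linkage(cond, method="average")
        labels = fcluster(Z, t=K, criterion="maxclust") - 1
    ids = np.unique(labels)
    if len(ids) != K:
        raise RuntimeError(f"tree cut produced {len(ids)} clusters, requested {K}")
    rot = np.empty((K, ensemble.samples.shape[1]))
    pop = np.empty(K)
    for j, cid in enumerate(ids):
        sel = labels == cid
        w = ensemble.boltzmann_weights[sel]
        pop[j] = w.sum()
        rot[j] = _weighted_circular_mean(
            ensemble.samples[sel], w / w.sum() if w.sum() > 0 else np.full(sel.sum(), 1.0 / sel.sum())
        )
    order = np.argsort(-pop)
    relabel = np.empty(K, dtype=int)
    relabel[order] = np.arange(K)
    members = relabel[np.searchsorted(ids, labels)]
    return RotamerLibrary(
        rotamers=rot[order],
        populations=pop[order] / pop.sum(),
        members=members,
        meta={"K": K},
    )


def metal_cloud(library: RotamerLibrary, geometry_fn, grid: Grid3D) -> DensityField:
    """Deposit each rotamer's population at its metal position (trilinear
    splat) and return the normalised density — directly comparable to a
    PCS reconstruction on the same grid."""
    positions = np.array([geometry_fn(r) for r in library.rotamers], dtype=float)
    inside = grid.contains(positions)
    if not np.all(inside):
        bad = np.nonzero(~inside)[0]
        raise ValueError(f"rotamers map outside the grid: indices {bad.tolist()[:10]}")
    values = sample_adjoint(grid, positions, library.populations)
    values /= values.sum() * grid.voxel_volume
    return DensityField(grid, values)


# -- helpers for building geometries and energies ---------------------------

def dihedral_chain_geometry(bond_lengths, bond_angles_deg):
    """Forward kinematics of a serial chain with fixed bond lengths/angles.

    Returns a callable mapping a dihedral vector (degrees, one per bond after
    the third atom) to the position of the chain's terminal atom, with the
    chain rooted at the origin along x. ``bond_lengths`` has n+2 entries and
    ``bond_angles_deg`` n+1 for n dihedrals (standard internal coordinates).
    """
    bl = np.asarray(bond_lengths, dtype=float)
    ba = np.deg2rad(np.asarray(bond_angles_deg, dtype=float))
    if len(bl) != len(ba) + 1:
        raise ValueError("need one more bond length than bond angles")

    def place(dihedrals_deg):
        tor = np.deg2rad(np.asarray(dihedrals_deg, dtype=float).reshape(-1))
        if len(tor) != len(ba) - 1:
            raise ValueError(
                f"expected {len(ba) - 1} dihedrals, got {len(tor)}"
            )
        a = np.array([0.0, 0.0, 0.0])
        b = np.array([bl[0], 0.0, 0.0])
        c = b + bl[1] * np.array([np.cos(np.pi - ba[0]), np.sin(np.pi - ba[0]), 0.0])
        atoms = [a, b, c]
        for i, phi in enumerate(tor):
            r, theta = bl[i + 2], ba[i + 1]
            b1 = atoms[-1] - atoms[-2]
            b1 /= np.linalg.norm(b1)
            b0 = atoms[-2] - atoms[-3]
            n = np.cross(b0, b1)
            n /= np.linalg.norm(n)
            m = np.cross(n, b1)
            d = (
                -r * np.cos(theta) * b1
                + r * np.sin(theta) * (np.cos(phi) * m + np.sin(phi) * n)
            )
            atoms.append(atoms[-1] + d)
        return atoms[-1]

    return place


def soft_lennard_jones_energy(
    positions_fn, environment: np.ndarray, r_eq: float = 3.5,
    scale: float = 1.0, epsilon: float = 1.0,
):
    """Softened Lennard-Jones clash score against fixed environment atoms.

    ``positions_fn`` maps an angle vector to the tag atom coordinates
    (M, 3); equilibrium distances are scaled by ``scale`` (< 1 softens the
    potential to mimic librational averaging in the protein). Returns a
    callable suitable for :class:`DihedralSpec.energy_fn` (energy in kT).
    """
    env = np.asarray(environment, dtype=float).reshape(-1, 3)
    r0 = r_eq * scale

    def energy(angles):
        xyz = np.atleast_2d(positions_fn(angles))
        d = np.linalg.norm(xyz[:, None, :] - env[None, :, :], axis=-1)
        d = np.maximum(d, 0.3 * r0)  # soften the core singularity
        s6 = (r0 / d) ** 6
        # repulsive-only clash score: zero beyond r0, quadratic core
        return float(epsilon * np.sum(np.clip(s6 - 1.0, 0.0, None) ** 2))

    return energy
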