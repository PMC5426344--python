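"""Synthetic inputs for testing and demonstration.

Generates the three ingredients of a reconstruction problem without any
external data: phantom densities (Gaussian mixtures standing in for the true
tag distribution), a toy protein (an idealised self-avoiding backbone that
stands in for a real structure such as carbonic anhydrase), and noisy PCS
tables with the statistical structure the inversion assumes — hundreds of
¹H/¹⁵N shifts at backbone amide positions with Gaussian noise at the
0.01–0.05 ppm level typical of careful HSQC-based measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chitensor import SusceptibilityTensor
from .data import PCSDataset, ProteinStructure
from .forward import pcs_field_fft, sample_field
from .grid import DensityField, Grid3D

__all__ = [
    "PhantomSpec",
    "gaussian_phantom",
    "toy_protein",
    "amide_nuclei",
    "make_synthetic_dataset",
    "cavity_tag_problem",
]


def amide_nuclei(protein: ProteinStructure):
    """Backbone amide ¹H and ¹⁵N nuclei of a protein, as
    ``(positions, labels, residues, atoms)`` ready for a PCS table."""
    pairs = protein.amide_pairs()
    idx = [i for pair in pairs for i in pair]  # N then H per residue
    positions = protein.positions[idx]
    labels = np.array(
        ["N" if protein.names[i] == "N" else "H" for i in idx], dtype=object
    )
    residues = protein.residues[idx]
    atoms = np.array([protein.names[i] for i in idx], dtype=object)
    return positions, labels, residues, atoms


@dataclass
class PhantomSpec:
    """Axis-aligned Gaussian mixture: (center Å, widths Å, weight) components."""

    components: list
    grid: Grid3D

    def __post_init__(self):
        if not self.components:
            raise ValueError("phantom needs at least one component")
        w = np.array([c[2] for c in self.components], dtype=float)
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must be positive and sum to 1")
        for center, widths, _ in self.components:
            widths = np.broadcast_to(np.asarray(widths, dtype=float), (3,))
            if np.any(widths <= 0):
                raise ValueError("component widths must be positive")


def gaussian_phantom(spec: PhantomSpec) -> DensityField:
    """Rasterise the mixture at voxel centres and normalise to unit mass.

    Every component's ±4σ box must fit inside the grid (otherwise mass is
    lost off the edges and the phantom is rejected)."""
    grid = spec.grid
    lo = grid.origin
    hi = grid.origin + (np.array(grid.shape) - 1) * grid.spacing
    values = np.zeros(grid.shape)
    centers = grid.voxel_centers()
    for center, widths, weight in spec.components:
        center = np.asarray(center, dtype=float)
        widths = np.broadcast_to(np.asarray(widths, dtype=float), (3,))
        if np.any(center - 4 * widths < lo) or np.any(center + 4 * widths > hi):
            raise ValueError(
                f"phantom component at {center} (±4σ) escapes the grid"
            )
        z2 = np.sum(((centers - center) / widths) ** 2, axis=-1)
        values += weight * np.exp(-0.5 * z2) / (
            (2 * np.pi) ** 1.5 * float(np.prod(widths))
        )
    values /= values.sum() * grid.voxel_volume
    return DensityField(grid, values)


_HELIX_STEP = 3.8  # Å, CA-CA distance


def toy_protein(
    n_residues: int,
    seed: int = 2017,
    compactness: float = 1.0,
    cavity_radius: float = 0.0,
) -> ProteinStructure:
    """Idealised test protein: a seeded, self-avoiding CA random walk with
    N, H, CA, C, O atoms per residue.

    Local geometry is idealised (amide H–N bond exactly 1.02 Å); the
    N-terminal residue carries no amide H, so the amide selectors return
    ``n_residues − 1`` (N, H) pairs. Deterministic for a given seed.
    ``cavity_radius > 0`` keeps the backbone outside a central spherical
    cavity, modelling a deep binding cleft or channel whose interior a tag
    or metal ion can occupy surrounded by protein."""
    if n_residues < 10:
        raise ValueError("toy protein needs at least 10 residues")
    rng = np.random.default_rng(seed)
    confine = (
        cavity_radius ** 3 + (compactness * 3.4 * n_residues ** (1.0 / 3.0)) ** 3
    ) ** (1.0 / 3.0)
    for _attempt in range(200):
        ca = _self_avoiding_walk(n_residues, rng, confine, cavity_radius)
        if ca is not None:
            break
    else:
        raise RuntimeError("self-avoiding backbone walk failed after 200 retries")

    elements, names, residues, resnames, chains, positions = [], [], [], [], [], []

    def add(el, nm, res, pos):
        elements.append(el)
        names.append(nm)
        residues.append(res)
        resnames.append("ALA")
        chains.append("A")
        positions.append(pos)

    for i in range(n_residues):
        c = ca[i]
        fwd = ca[min(i + 1, n_residues - 1)] - ca[max(i - 1, 0)]
        fwd = fwd / np.linalg.norm(fwd)
        up = np.cross(fwd, [0.0, 0.0, 1.0])
        if np.linalg.norm(up) < 1e-6:
            up = np.cross(fwd, [0.0, 1.0, 0.0])
        up /= np.linalg.norm(up)
        side = np.cross(fwd, up)
        n_pos = c - 1.46 * fwd + 0.3 * up
        c_pos = c + 1.52 * fwd + 0.3 * up
        o_pos = c_pos + 1.23 * (0.55 * up + 0.835 * side) / np.linalg.norm(
            0.55 * up + 0.835 * side
        )
        h_dir = (0.6 * up - 0.8 * fwd)
        h_dir /= np.linalg.norm(h_dir)
        add("N", "N", i + 1, n_pos)
        if i > 0:  # the N-terminus has no amide proton
            add("H", "H", i + 1, n_pos + 1.02 * h_dir)
        add("C", "CA", i + 1, c)
        add("C", "C", i + 1, c_pos)
        add("O", "O", i + 1, o_pos)
    return ProteinStructure(
        np.array(elements, dtype=object),
        np.array(names, dtype=object),
        np.array(residues),
        np.array(resnames, dtype=object),
        np.array(chains, dtype=object),
        np.array(positions),
    )


def _self_avoiding_walk(
    n: int, rng: np.random.Generator, confine: float, cavity: float = 0.0
):
    start = np.array([cavity + 2.0, 0.0, 0.0]) if cavity > 0 else np.zeros(3)
    pts = [start]
    direction = np.array([0.0, 1.0, 0.0]) if cavity > 0 else np.array([1.0, 0.0, 0.0])
    for _ in range(n - 1):
        for _try in range(60):
            step = direction + 0.9 * rng.normal(size=3)
            step = step / np.linalg.norm(step) * _HELIX_STEP
            cand = pts[-1] + step
            r = np.linalg.norm(cand)
            if r > confine or r < cavity:
                continue
            if len(pts) > 2 and np.min(
                np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1)
            ) < 0.95 * _HELIX_STEP:
                continue
            pts.append(cand)
            direction = step / _HELIX_STEP
            break
        else:
            return None
    arr = np.asarray(pts)
    if cavity > 0:
        return arr  # keep the cavity centred on the origin
    return arr - arr.mean(axis=0)


def make_synthetic_dataset(
    truth: DensityField,
    chi: SusceptibilityTensor,
    nuclei: np.ndarray,
    noise_sd: float,
    seed: int,
    nucleus_labels=None,
    residues=None,
    atoms=None,
) -> PCSDataset:
    """PCS table generated by the forward model from a known density + χ.

    Shifts are the FFT-solved field sampled at the nuclei plus seeded
    Gaussian noise of standard deviation ``noise_sd`` (ppm). Nuclei must sit
    at least two voxel spacings away from the truth density's support (the
    tag lives outside the protein where the shifts are measured)."""
    nuclei = np.atleast_2d(np.asarray(nuclei, dtype=float))
    n = len(nuclei)
    # effective support: voxels above 1% of the peak (~3σ for a Gaussian)
    support = truth.values > 1e-2 * truth.values.max()
    sup_pos = truth.grid.voxel_centers()[support]
    from scipy.spatial import cKDTree

    d, _ = cKDTree(sup_pos).query(nuclei, k=1)
    min_clear = 2.0 * float(np.max(truth.grid.spacing))
    if np.any(d < min_clear):
        bad = np.nonzero(d < min_clear)[0]
        raise ValueError(
            f"nuclei inside or touching the density support at rows {bad[:10].tolist()}"
        )
    clean = sample_field(pcs_field_fft(truth, chi), nuclei)
    rng = np.random.default_rng(seed)
    shifts = clean + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else clean.copy()
    if nucleus_labels is None:
        nucleus_labels = np.array(["H"] * n, dtype=object)
    if residues is None:
        residues = np.arange(1, n + 1)
    if atoms is None:
        atoms = np.asarray(nucleus_labels, dtype=object).copy()
    return PCSDataset(
        positions=nuclei,
        shifts=shifts,
        nucleus=nucleus_labels,
        residues=residues,
        atoms=atoms,
        meta={
            "clean_shifts": clean,
            "noise_sd": float(noise_sd),
            "seed": int(seed),
            "provenance": "synthetic forward model",
        },
    )


def cavity_tag_problem(
    seed: int,
    n_residues: int = 170,
    cavity_radius: float = 10.0,
    sigma: float = 2.0,
    n_nuclei: int = 300,
    noise_frac: float = 0.01,
    dchi_ax: float = 0.02,
    dchi_rh: float = 0.005,
    phantom_centers=None,
    truth_shape: int = 48,
):
    """The package's standard synthetic reconstruction problem.

    A paramagnetic centre (σ = ``sigma`` Å Gaussian, Tm³⁺-like χ with
    Δχ_ax = 0.02 Å³ and Δχ_rh = 0.005 Å³, i.e. 2.0 and 0.5 × 10⁻³² m³) sits
    in a deep binding cleft of a toy protein, surrounded by backbone amides.
    ``n_nuclei`` ¹H/¹⁵N shifts are generated by the forward model with
    homoscedastic Gaussian noise of ``noise_frac`` × max |PCS| (1% by
    default, i.e. ~0.01 ppm). Nuclei closer to the tag than the generator's
    clearance are discarded, as their resonances would be bleached by
    paramagnetic relaxation in a real experiment.

    Returns ``(protein, dataset, truth, chi, centers)`` where ``centers`` is
    the list of phantom component centres (Å).
    """
    protein = toy_protein(n_residues, seed=seed, cavity_radius=cavity_radius)
    pos, labels, residues, atoms = amide_nuclei(protein)
    lo, hi = protein.bounding_box()
    tgrid = Grid3D.centered(
        0.5 * (lo + hi), float(np.max(hi - lo) + 40.0), truth_shape
    )
    if phantom_centers is None:
        phantom_centers = [np.zeros(3)]
    phantom_centers = [np.asarray(c, dtype=float) for c in phantom_centers]
    w = 1.0 / len(phantom_centers)
    truth = gaussian_phantom(
        PhantomSpec([(c, sigma, w) for c in phantom_centers], tgrid)
    )
    chi = SusceptibilityTensor.from_axial_rhombic(dchi_ax, dchi_rh)
    clearance = 3.0 * sigma + 2.0 * float(tgrid.spacing.max())
    dmin = np.min(
        [np.linalg.norm(pos - c, axis=1) for c in phantom_centers], axis=0
    )
    keep = dmin >= clearance
    pos, labels, residues, atoms = pos[keep], labels[keep], residues[keep], atoms[keep]
    if len(pos) < n_nuclei:
        raise ValueError(
            f"only {len(pos)} usable nuclei for the requested {n_nuclei}; "
            "increase n_residues"
        )
    rng = np.random.default_rng(seed)
    sel = np.sort(rng.choice(len(pos), size=n_nuclei, replace=False))
    pos, labels, residues, atoms = pos[sel], labels[sel], residues[sel], atoms[sel]
    clean = sample_field(pcs_field_fft(truth, chi), pos)
    noise_sd = noise_frac * float(np.abs(clean).max())
    dataset = make_synthetic_dataset(
        truth, chi, pos, noise_sd, seed,
        nucleus_labels=labels, residues=residues, atoms=atoms,
    )
    return protein, dataset, truth, chi, phantom_centers
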