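"""Readers and writers for the on-disk formats.

PDB files are read through gemmi (first model, altloc '' or 'A'); density
maps are exchanged as CCP4/MRC mode-2 maps (gemmi) or Gaussian cube text;
PCS tables and distance distributions are plain text with '#' comments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields

import gemmi
import numpy as np
import pandas as pd

from .data import PCSDataset, ProteinStructure
from .grid import DensityField, Grid3D
from .postprocess import DistanceDistribution

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_pcs_table",
    "write_pcs_table",
    "attach_positions",
    "write_density_map",
    "read_density_map",
    "read_distance_distribution",
    "write_distance_distribution",
    "RunConfig",
    "read_config",
    "write_config",
    "write_report",
]

log = logging.getLogger(__name__)

BOHR_PER_A = 1.0 / 0.529177210903


# -- PDB --------------------------------------------------------------------

def read_pdb(path) -> ProteinStructure:
    """Atom coordinates (Å) from a PDB file: ATOM and HETATM records of the
    first model; altloc '' preferred, then 'A'."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    model = st[0]
    elements, names, residues, resnames, chains, positions = [], [], [], [], [], []
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.altloc not in ("", "A", "\x00"):
                    continue
                elements.append(atom.element.name)
                names.append(atom.name)
                residues.append(res.seqid.num)
                resnames.append(res.name)
                chains.append(chain.name)
                positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not positions:
        raise ValueError(f"{path}: no atoms in the first model")
    return ProteinStructure(
        np.array(elements, dtype=object),
        np.array(names, dtype=object),
        np.array(residues),
        np.array(resnames, dtype=object),
        np.array(chains, dtype=object),
        np.array(positions),
    )


def write_pdb(protein: ProteinStructure, path) -> None:
    st = gemmi.Structure()
    st.name = "pcscloud"
    model = gemmi.Model("1")
    chain_map = {}
    for i in range(len(protein)):
        cname = str(protein.chains[i])
        if cname not in chain_map:
            chain_map[cname] = gemmi.Chain(cname)
        chain = chain_map[cname]
        resnum = int(protein.residues[i])
        if len(chain) == 0 or chain[-1].seqid.num != resnum:
            res = gemmi.Residue()
            res.name = str(protein.resnames[i])
            res.seqid = gemmi.SeqId(resnum, " ")
            chain.add_residue(res)
        atom = gemmi.Atom()
        atom.name = str(protein.names[i])
        atom.element = gemmi.Element(str(protein.elements[i]))
        atom.pos = gemmi.Position(*protein.positions[i])
        chain[-1].add_atom(atom)
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# -- PCS tables -------------------------------------------------------------

_PCS_COLUMNS = ["chain", "residue", "atom", "shift"]


def read_pcs_table(path) -> PCSDataset:
    """PCS table: whitespace/comma-delimited columns chain, residue, atom,
    shift (ppm), optional weight; '#' starts a comment. Nuclear positions are
    attached later by matching against a structure (see
    :func:`attach_positions`)."""
    df = _read_table(path)
    ncol = df.shape[1]
    if ncol not in (4, 5, 7, 8):
        raise ValueError(
            f"{path}: expected 4-5 columns (chain residue atom shift [weight]) "
            f"or 7-8 with x y z positions, got {ncol}"
        )
    chains = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
    residues = df.iloc[:, 1].astype(int).to_numpy()
    atoms = df.iloc[:, 2].astype(str).to_numpy(dtype=object)
    try:
        shifts = df.iloc[:, 3].astype(float).to_numpy()
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric shift value ({e})") from None
    weights = None
    positions = np.zeros((len(df), 3))
    if ncol >= 7:
        positions = df.iloc[:, 4:7].astype(float).to_numpy()
        if ncol == 8:
            weights = df.iloc[:, 7].astype(float).to_numpy()
    elif ncol == 5:
        weights = df.iloc[:, 4].astype(float).to_numpy()
    nucleus = np.array([a[0] for a in atoms], dtype=object)
    return PCSDataset(
        positions=positions,
        shifts=shifts,
        nucleus=nucleus,
        residues=residues,
        atoms=atoms,
        chains=chains,
        weights=weights,
        meta={"path": str(path), "has_positions": ncol >= 7},
    )


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=r"[,\s]+", comment="#", header=None, engine="python")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty PCS table") from None
    return df


def write_pcs_table(dataset: PCSDataset, path, include_positions: bool = True) -> None:
    with open(path, "w") as fh:
        cols = "chain residue atom shift_ppm"
        if include_positions:
            cols += " x y z"
        fh.write(f"# {cols}\n")
        for i in range(len(dataset)):
            line = (
                f"{dataset.chains[i]} {int(dataset.residues[i])} {dataset.atoms[i]} "
                f"{dataset.shifts[i]:.6f}"
            )
            if include_positions:
                x, y, z = dataset.positions[i]
                line += f" {x:.4f} {y:.4f} {z:.4f}"
            fh.write(line + "\n")


def attach_positions(dataset: PCSDataset, protein: ProteinStructure) -> PCSDataset:
    """Fill nuclear positions by matching (chain, residue, atom) against a
    structure; raises on records with no matching atom."""
    index = {
        (str(protein.chains[i]), int(protein.residues[i]), str(protein.names[i])): i
        for i in range(len(protein))
    }
    pos = np.zeros((len(dataset), 3))
    missing = []
    for i in range(len(dataset)):
        key = (str(dataset.chains[i]), int(dataset.residues[i]), str(dataset.atoms[i]))
        if key not in index:
            missing.append(key)
            continue
        pos[i] = protein.positions[index[key]]
    if missing:
        raise ValueError(f"no matching atoms for PCS records: {missing[:5]}")
    out = dataset.subset(np.arange(len(dataset)))
    out.positions = pos
    out.meta["has_positions"] = True
    return out


# -- density maps -----------------------------------------------------------

def write_density_map(density: DensityField, path, format: str = "mrc") -> None:
    """Write a density as CCP4/MRC (mode 2, voxel-centre origin in the ORIGIN
    header words) or Gaussian cube (Bohr units, as viewers expect)."""
    if format in ("mrc", "ccp4"):
        _write_ccp4(density, path)
    elif format == "cube":
        _write_cube(density, path)
    else:
        raise ValueError(f"unknown map format {format!r}")


def _write_ccp4(density: DensityField, path) -> None:
    grid = density.grid
    fg = gemmi.FloatGrid(*grid.shape)
    fg.set_unit_cell(gemmi.UnitCell(*(np.array(grid.shape) * grid.spacing), 90, 90, 90))
    np.array(fg, copy=False)[...] = density.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = fg
    m.update_ccp4_header(2, True)
    for w, v in zip((50, 51, 52), grid.origin):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(str(path))


def _write_cube(density: DensityField, path) -> None:
    grid = density.grid
    with open(path, "w") as fh:
        fh.write("pcscloud probability density\nvalues in A^-3; axes in Bohr\n")
        ox, oy, oz = grid.origin * BOHR_PER_A
        fh.write(f"{0:5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}\n")
        for a in range(3):
            step = np.zeros(3)
            step[a] = grid.spacing[a] * BOHR_PER_A
            fh.write(
                f"{grid.shape[a]:5d} {step[0]:12.6f} {step[1]:12.6f} {step[2]:12.6f}\n"
            )
        flat = density.values.reshape(grid.shape[0] * grid.shape[1], grid.shape[2])
        for row in flat:
            for k in range(0, len(row), 6):
                fh.write(" ".join(f"{v:13.5e}" for v in row[k : k + 6]) + "\n")


def read_density_map(path, format: str | None = None) -> DensityField:
    path = str(path)
    if format is None:
        format = "cube" if path.endswith(".cube") else "mrc"
    if format == "cube":
        return _read_cube(path)
    m = gemmi.read_ccp4_map(path)
    values = np.array(m.grid, copy=True).astype(float)
    cell = m.grid.unit_cell
    spacing = np.array([cell.a, cell.b, cell.c]) / np.array(values.shape)
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=float)
    grid = Grid3D(origin=origin, spacing=spacing, shape=values.shape)
    return DensityField(grid, np.clip(values, 0.0, None))


def _read_cube(path) -> DensityField:
    with open(path) as fh:
        fh.readline()
        fh.readline()
        parts = fh.readline().split()
        natoms = int(parts[0])
        origin = np.array(parts[1:4], dtype=float) / BOHR_PER_A
        shape, spacing = [], []
        for a in range(3):
            parts = fh.readline().split()
            shape.append(int(parts[0]))
            step = np.array(parts[1:4], dtype=float)
            spacing.append(np.linalg.norm(step) / BOHR_PER_A)
        for _ in range(abs(natoms)):
            fh.readline()
        data = np.array(fh.read().split(), dtype=float)
    values = data.reshape(shape)
    grid = Grid3D(origin=origin, spacing=np.array(spacing), shape=tuple(shape))
    return DensityField(grid, np.clip(values, 0.0, None))


# -- distance distributions -------------------------------------------------

def read_distance_distribution(path, label: str = "") -> DistanceDistribution:
    """Two-column (r, p) text; '#' comments. Radii given in nm (e.g. DEER
    output) are detected by magnitude — max(r) < 15 — and converted to Å."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (r, p)")
    r, p = data[:, 0].astype(float), data[:, 1].astype(float)
    if r.max() < 15.0:
        log.info("%s: radii look like nm (max %.2f); converting to Å", path, r.max())
        r = r * 10.0
    p = np.clip(p, 0.0, None)
    dist = DistanceDistribution(r, p, label=label or str(path))
    return dist.normalised()


def write_distance_distribution(dist: DistanceDistribution, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# r_angstrom p_per_angstrom  ({dist.label})\n")
        for r, p in zip(dist.r_centers, dist.p):
            fh.write(f"{r:.4f} {p:.8e}\n")


# -- run configuration and reports ------------------------------------------

@dataclass
class RunConfig:
    """Flat key-value run configuration; unknown keys are rejected on load."""

    protein: str = ""
    pcs_table: str = ""
    output_dir: str = "."
    coarse_shape: int = 64
    fine_shape: int = 96
    r_min: float = 2.0
    r_max: float = 12.0
    crop_side: float = 20.0
    n_lambdas: int = 15
    lambda_decades: float = 6.0
    max_cycles: int = 20
    seed: int = 2017
    restarts: int = 8
    stage: str = "full"  # point | coarse | full


def read_config(path) -> RunConfig:
    known = {f.name: f.type for f in fields(RunConfig)}
    kwargs = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{ln}: unknown configuration key {key!r}")
            default = getattr(RunConfig(), key)
            kwargs[key] = type(default)(val)
    return RunConfig(**kwargs)


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        for key, val in asdict(cfg).items():
            fh.write(f"{key} = {val}\n")


def write_report(report: dict, path) -> None:
    """Deterministic JSON report (sorted keys, fixed float formatting)."""

    def convert(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        raise TypeError(f"not JSON-serialisable: {type(x)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=convert)
        fh.write("\n")
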