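"""Containers for measured PCS data and protein coordinates."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PCSDataset", "ProteinStructure"]


@dataclass
class PCSDataset:
    """Measured pseudocontact shifts at known nuclear positions.

    positions are in Å (protein frame), shifts in ppm. ``nucleus`` holds
    element labels ("H", "N", ...); (chain, residue, atom) triples identify
    each datum and must be unique.
    """

    positions: np.ndarray
    shifts: np.ndarray
    nucleus: np.ndarray
    residues: np.ndarray
    atoms: np.ndarray
    chains: np.ndarray = None
    weights: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.shifts = np.asarray(self.shifts, dtype=float).reshape(n)
        self.nucleus = np.asarray(self.nucleus, dtype=object).reshape(n)
        self.residues = np.asarray(self.residues).reshape(n)
        self.atoms = np.asarray(self.atoms, dtype=object).reshape(n)
        if self.chains is None:
            self.chains = np.array(["A"] * n, dtype=object)
        else:
            self.chains = np.asarray(self.chains, dtype=object).reshape(n)
        if self.weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.asarray(self.weights, dtype=float).reshape(n)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("nuclear positions must be finite")
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("shifts must be finite")
        keys = list(zip(self.chains, self.residues, self.atoms))
        if len(set(keys)) != n:
            seen, dups = set(), []
            for k in keys:
                if k in seen:
                    dups.append(k)
                seen.add(k)
            raise ValueError(f"duplicate (chain, residue, atom) records: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.positions)

    def subset(self, idx) -> "PCSDataset":
        idx = np.asarray(idx)
        return PCSDataset(
            self.positions[idx],
            self.shifts[idx],
            self.nucleus[idx],
            self.residues[idx],
            self.atoms[idx],
            self.chains[idx],
            self.weights[idx],
            dict(self.meta),
        )


@dataclass
class ProteinStructure:
    """Heavy-atom (plus amide H) coordinates of the protein, in Å."""

    elements: np.ndarray
    names: np.ndarray
    residues: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        if n == 0:
            raise ValueError("protein structure must contain at least one atom")
        for attr in ("elements", "names", "resnames", "chains"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=object).reshape(n))
        self.residues = np.asarray(self.residues).reshape(n).astype(int)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("atom positions must be finite")

    def __len__(self) -> int:
        return len(self.positions)

    def select(self, name: str) -> np.ndarray:
        """Indices of atoms with the given atom name."""
        return np.nonzero(self.names == name)[0]

    def amide_pairs(self) -> list[tuple[int, int]]:
        """(N index, H index) per residue that has both backbone amide atoms.

        The two selections are disjoint by construction (distinct atom names).
        """
        pairs = []
        for chain in np.unique(self.chains):
            csel = self.chains == chain
            for res in np.unique(self.residues[csel]):
                sel = csel & (self.residues == res)
                n_idx = np.nonzero(sel & (self.names == "N"))[0]
                h_idx = np.nonzero(sel & (self.names == "H"))[0]
                if len(n_idx) == 1 and len(h_idx) == 1:
                    pairs.append((int(n_idx[0]), int(h_idx[0])))
        return pairs

    def amide_nitrogens(self) -> np.ndarray:
        return np.array([n for n, _ in self.amide_pairs()], dtype=int)

    def amide_hydrogens(self) -> np.ndarray:
        return np.array([h for _, h in self.amide_pairs()], dtype=int)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.positions.min(axis=0), self.positions.max(axis=0)
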