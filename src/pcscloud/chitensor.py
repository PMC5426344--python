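"""The anisotropic magnetic susceptibility tensor.

Only the traceless (anisotropic) part of χ generates pseudocontact shifts, so
the tensor is stored traceless-symmetric and exposes exactly five independent
degrees of freedom, parameterised as (χxx, χyy, χxy, χxz, χyz) with
χzz = −χxx − χyy.

Internal unit is Å³. PCS work commonly quotes Δχ in 10⁻³² m³;
1 × 10⁻³² m³ = 0.01 Å³ (`A3_PER_1E32_M3`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SusceptibilityTensor", "A3_PER_1E32_M3", "CHI_BASIS"]

#: Å³ per 1e-32 m³ (the conventional unit of Δχ in paramagnetic NMR).
A3_PER_1E32_M3 = 0.01

#: Basis matrices for the 5-parameter vector (χxx, χyy, χxy, χxz, χyz).
CHI_BASIS = np.array(
    [
        [[1.0, 0, 0], [0, 0, 0], [0, 0, -1.0]],
        [[0, 0, 0], [0, 1.0, 0], [0, 0, -1.0]],
        [[0, 1.0, 0], [1.0, 0, 0], [0, 0, 0]],
        [[0, 0, 1.0], [0, 0, 0], [1.0, 0, 0]],
        [[0, 0, 0], [0, 0, 1.0], [0, 1.0, 0]],
    ]
)


@dataclass(frozen=True)
class SusceptibilityTensor:
    """Traceless symmetric 3×3 susceptibility tensor (Å³).

    Construction symmetrises and removes the trace by projection, so the
    invariants (symmetry to machine precision, |trace| ≤ 1e-10 × ‖χ‖_F)
    hold for any finite input matrix.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("susceptibility tensor must be 3x3")
        if not np.all(np.isfinite(m)):
            raise ValueError("susceptibility tensor must be finite")
        m = 0.5 * (m + m.T)
        m = m - np.eye(3) * (np.trace(m) / 3.0)
        object.__setattr__(self, "matrix", m)

    # -- parameter vector ---------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        """The five independent elements (χxx, χyy, χxy, χxz, χyz)."""
        m = self.matrix
        return np.array([m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2]])

    @classmethod
    def from_params(cls, params) -> "SusceptibilityTensor":
        p = np.asarray(params, dtype=float).reshape(5)
        return cls(np.tensordot(p, CHI_BASIS, axes=(0, 0)))

    @classmethod
    def zero(cls) -> "SusceptibilityTensor":
        return cls(np.zeros((3, 3)))

    @classmethod
    def from_axial_rhombic(
        cls, dchi_ax: float, dchi_rh: float = 0.0, rotation=None
    ) -> "SusceptibilityTensor":
        """Build from axial/rhombic anisotropies (Å³) in a principal frame.

        Δχ_ax = χzz − (χxx + χyy)/2 and Δχ_rh = χxx − χyy; ``rotation`` is an
        optional 3×3 matrix taking the principal frame into the lab frame.
        """
        chi = np.diag(
            [
                -dchi_ax / 3.0 + dchi_rh / 2.0,
                -dchi_ax / 3.0 - dchi_rh / 2.0,
                2.0 * dchi_ax / 3.0,
            ]
        )
        if rotation is not None:
            R = np.asarray(rotation, dtype=float)
            chi = R @ chi @ R.T
        return cls(chi)

    # -- derived quantities -------------------------------------------------
    @property
    def frobenius(self) -> float:
        return float(np.linalg.norm(self.matrix))

    def axial_rhombic(self) -> tuple[float, float, np.ndarray]:
        """(Δχ_ax, Δχ_rh, rotation) of the principal-axis decomposition.

        Eigenvalues are ordered by the |χzz| ≥ |χyy| ≥ |χxx| convention.
        """
        w, v = np.linalg.eigh(self.matrix)
        order = np.argsort(np.abs(w))
        w = w[order]
        v = v[:, order]
        dax = w[2] - 0.5 * (w[0] + w[1])
        drh = w[0] - w[1]
        return float(dax), float(drh), v

    def rotated(self, rotation) -> "SusceptibilityTensor":
        R = np.asarray(rotation, dtype=float)
        return SusceptibilityTensor(R @ self.matrix @ R.T)

    def __mul__(self, scalar: float) -> "SusceptibilityTensor":
        return SusceptibilityTensor(self.matrix * float(scalar))

    __rmul__ = __mul__

    def __add__(self, other: "SusceptibilityTensor") -> "SusceptibilityTensor":
        return SusceptibilityTensor(self.matrix + other.matrix)
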