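"""Classical point-model fit: metal position + chi tensor from PCS data.

Generates noisy synthetic shifts from a known point centre and recovers the
eight parameters by nested linear/nonlinear least squares with multi-starts.
"""

import numpy as np

import pcscloud as pc

rng = np.random.default_rng(3)
chi_true = pc.SusceptibilityTensor.from_axial_rhombic(0.02, 0.006)
metal_true = np.array([4.0, -2.0, 1.0])

u = rng.normal(size=(250, 3))
u /= np.linalg.norm(u, axis=1)[:, None]
pos = metal_true + u * rng.uniform(9.0, 28.0, size=(250, 1))
shifts = pc.point_pcs(pos, metal_true, chi_true)
shifts += rng.normal(0.0, 0.01 * np.abs(shifts).max(), len(shifts))
ds = pc.PCSDataset(pos, shifts, ["H"] * 250, np.arange(1, 251), ["H"] * 250)

fit = pc.fit_point_model(ds, start_pos=pos.mean(axis=0), restarts=6, seed=11)
print("true metal position :", metal_true)
print("fitted metal position:", np.round(fit.metal_pos, 3))
print("position error (A)  :", round(float(np.linalg.norm(fit.metal_pos - metal_true)), 4))
print("rms residual (ppm)  :", round(fit.rms_residual, 5))
dax, drh, _ = fit.chi.axial_rhombic()
print(f"fitted dchi_ax, dchi_rh (A^3): {dax:.5f}, {drh:.5f}  (true: 0.02, 0.006)")
print(
    "\nWith 250 shifts and 1% noise the point model pins the metal to a few "
    "hundredths of an Angstrom - this fit seeds the density reconstruction."
)
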