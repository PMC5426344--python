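"""Forward model: point-centre PCS and the FFT field of a distributed centre.

Builds a Tm3+-like susceptibility tensor, evaluates the point formula at a
few nuclei, then spreads the centre into a 2 A Gaussian cloud and shows how
delocalisation attenuates the near-field shifts while the far field stays
point-like (the harmonic mean-value property).
"""

import numpy as np

import pcscloud as pc

# Tm3+ DOTA-M8-like anisotropy: dchi_ax = 2.0, dchi_rh = 0.5 (x 1e-32 m3)
chi = pc.SusceptibilityTensor.from_axial_rhombic(
    2.0 * pc.A3_PER_1E32_M3, 0.5 * pc.A3_PER_1E32_M3
)
print("chi tensor (A^3):")
print(np.round(chi.matrix, 5))

nuclei = np.array([[0.0, 0.0, 8.0], [8.0, 0.0, 0.0], [6.0, 6.0, 6.0], [0.0, 15.0, 0.0]])
point = pc.point_pcs(nuclei, np.zeros(3), chi)

grid = pc.Grid3D.centered([0.0, 0.0, 0.0], 40.0, 48)
cloud = pc.gaussian_phantom(pc.PhantomSpec([(np.zeros(3), 2.0, 1.0)], grid))
field = pc.pcs_field_fft(cloud, chi)
distributed = pc.sample_field(field, nuclei)

print(f"\n{'nucleus':>22} {'point PCS (ppm)':>16} {'2A-cloud PCS (ppm)':>19}")
for pos, p, d in zip(nuclei, point, distributed):
    print(f"{str(pos.tolist()):>22} {p:16.4f} {d:19.4f}")
print(
    "\nAlong the z axis (8 A) the shift is positive and largest; on the "
    "equator it flips sign (the 3cos^2-1 pattern; the rhombic term breaks "
    "the pure -1/2 axial ratio). "
    "Delocalising the centre barely changes the 15 A shift but "
    "visibly softens the 8 A ones - exactly the information the density "
    "reconstruction exploits."
)
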