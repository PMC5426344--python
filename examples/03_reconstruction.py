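"""Full self-consistent density reconstruction on a synthetic problem.

A 2 A Gaussian 'tag' sits in a deep binding cleft of a toy protein; ~200
noisy amide 1H/15N shifts are inverted for the 3D probability density with
L-curve-selected Tikhonov regularisation and an effective-chi refit loop.
Takes a minute or two on one CPU at the reduced grid sizes used here.
"""

import numpy as np

import pcscloud as pc

protein, dataset, truth, chi_true, centers = pc.cavity_tag_problem(
    seed=8, n_residues=140, n_nuclei=200
)
print(f"{len(dataset)} shifts, noise sd {dataset.meta['noise_sd']:.4f} ppm")

cfg = pc.ReconstructionConfig(
    coarse_shape=28, fine_shape=36, max_cycles=6, restarts=3,
    lcurve_every_cycle=False, n_lambdas=9,
)
result = pc.self_consistent_reconstruction(dataset, protein, cfg)

centroid = pc.density_centroid(result.density)
level = pc.probability_isolevel(result.density, 0.5)
print(f"converged in {result.cycles} cycles at lambda = {result.lam:.3g}")
print(f"residual rms: {result.residual_norm:.4f} ppm")
print(f"centroid: {np.round(centroid, 2).tolist()}  (truth {centers[0].tolist()})")
print(f"centroid error: {np.linalg.norm(centroid - centers[0]):.3f} A")
chi_err = (result.chi + (-1.0) * chi_true).frobenius / chi_true.frobenius
print(f"effective chi error: {100 * chi_err:.2f} %")
print(f"50%-probability isolevel: {level:.3e} A^-3")
print(
    "\nThe centroid lands within a fraction of a voxel of the true tag "
    "position and the effective chi within a few percent; the isolevel "
    "defines the 50%-probability surface for rendering in a map viewer "
    "(write it with pcscloud.io.write_density_map)."
)
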