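"""The Tikhonov trade-off and L-curve corner selection.

Sweeps the regularisation parameter on a small synthetic problem and prints
the residual/penalty table with the curvature-based corner choice.
"""

import numpy as np

import pcscloud as pc

protein, ds, truth, chi, centers = pc.cavity_tag_problem(
    seed=5, n_residues=130, n_nuclei=150, truth_shape=40
)
lo, hi = protein.bounding_box()
grid = pc.Grid3D.centered(0.5 * (lo + hi), float(np.max(hi - lo) + 30.0), 32)
mask = pc.accessible_mask(protein, grid, 2.0, 12.0)
mask &= np.all(np.abs(grid.voxel_centers() - centers[0]) <= 10.0, axis=-1)

f = pc.Functional(grid, mask, ds, chi, lam=1.0)
v = np.where(mask, 1.0, 0.0)
init = pc.DensityField(grid, v / (v.sum() * grid.voxel_volume), mask)
balance = f.with_lambda(0.0).value(init.values)[1] / f.value(init.values)[2]
lambdas = np.logspace(np.log10(balance) - 3, np.log10(balance) + 3, 13)

curve = pc.lambda_sweep(f, lambdas, init, max_iter=60, cg_iters=50)
chosen = pc.lcurve_corner(curve)

print(f"{'lambda':>12} {'residual rms':>13} {'penalty norm':>13} {'curvature':>10}")
for lam, r, p, k in curve.as_table():
    mark = "  <-- corner" if lam == chosen else ""
    print(f"{lam:12.3g} {r:13.5f} {p:13.5f} {k:10.3f}{mark}")
print(
    f"\nResidual grows and penalty falls monotonically with lambda; the "
    f"corner at lambda = {chosen:.3g} balances data fit against smoothness "
    f"(injected noise sd: {ds.meta['noise_sd']:.4f} ppm)."
)
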