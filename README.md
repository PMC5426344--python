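# pcscloud

**Spin-label position distributions from pseudocontact shift data.**

Lanthanide tags attached to proteins — and lanthanide ions bound in native
metal sites — are not points: linker flexibility spreads the paramagnetic
centre over a cloud of positions. `pcscloud` reconstructs that cloud as a 3D
probability density ρ(r) directly from pseudocontact shifts (PCS) measured
at known nuclear positions, with no conformational model in between. It is
aimed at paramagnetic NMR practitioners who have a table of ¹H/¹⁵N PCS
assignments and a structure, and want a density map they can overlay on the
protein, compare with rotamer-library predictions, or turn into inter-tag
distance distributions comparable with DEER.

## The model

A point centre with traceless magnetic susceptibility tensor **χ** (5
independent elements) shifts a nucleus at r (relative to the metal) by

    σ(r) = (1 / 4π) · rᵀχr / r⁵        (reported in ppm)

equivalently, in the principal frame,
σ = [Δχ_ax (3cos²θ − 1) + 3⁄2 Δχ_rh sin²θ cos2φ] / 12πr³.
For a centre distributed with density ρ(r), the observed field σ(r) is the
convolution of ρ with this kernel, computed here exactly by FFT on a
zero-padded grid. Recovering ρ from N point measurements is an ill-posed
linear inverse problem, solved by minimising

    F[ρ] = Σᵢ (P_N[σ_ρ](rᵢ) − σᵢ_obs)² + λ ‖∇²ρ‖²,   ρ ≥ 0,

where P_N is trilinear sampling at the nuclei, the squared-Laplacian
(Tikhonov) penalty favours smooth densities, and λ is chosen at the maximum
curvature corner of the L-curve. A projected Newton–CG minimiser handles the
non-negativity bound using the exact gradient and Hessian action of F. The
full protocol alternates density reconstruction with linear re-fits of the
effective **χ** until the two are self-consistent, starting from a classical
point-model fit and a coarse localisation pass over the 2–12 Å
accessible-volume shell around the protein.

The package also builds discrete rotamer libraries for flexible tags
(Monte-Carlo dihedral sampling, periodic dihedral metric, UPGMA clustering,
Boltzmann populations — e.g. the 2·2·2·3·3·3·3·3 = 1944 clusters of a
DOTA-M8-type linker), and post-processes densities into probability
isolevels, centroids and pair distance distributions.

## Worked example

`examples/03_reconstruction.py` builds a complete synthetic problem — a
σ = 2 Å Gaussian tag density in a deep binding cleft of a toy protein, 200
noisy amide ¹H/¹⁵N shifts — and runs the full self-consistent protocol:

```text
200 shifts, noise sd 0.0065 ppm
converged in 4 cycles at lambda = 1.64e+03
residual rms: 0.0063 ppm
centroid: [0.04, -0.02, -0.12]  (truth [0.0, 0.0, 0.0])
centroid error: 0.124 A
effective chi error: 1.67 %
50%-probability isolevel: 4.378e-04 A^-3
```

The residual matches the injected noise floor, the density centroid lands
within a fraction of a voxel of the true tag position, and the effective χ
is recovered to a couple of percent. The remaining examples cover the
forward model, the point fit, the L-curve, distance distributions and the
rotamer pipeline — each prints what it computes and what the numbers mean.

A thin command line mirrors the library for shell use:

```bash
pcscloud simulate   --out-dir demo --residues 120 --seed 11
pcscloud fit-point  --pdb demo/protein.pdb --pcs demo/pcs.txt --out fit.json
pcscloud reconstruct --pdb demo/protein.pdb --pcs demo/pcs.txt --out-dir run/
pcscloud distances  --map1 run/density.ccp4 --map2 demo/truth.ccp4 --out dist.txt
```

Density maps are written as CCP4/MRC (mode 2, with the voxel-centre origin
in the header) or Gaussian cube, so they open directly in PyMOL/ChimeraX
over the input PDB.

## Layout

- `src/pcscloud/forward.py` — point formula, FFT field solve, sampling
  operator and adjoint, accessibility mask
- `src/pcscloud/inversion.py` — functional, variations, bound-constrained
  minimiser, two-stage self-consistent protocol
- `src/pcscloud/lcurve.py` — λ sweeps and corner selection
- `src/pcscloud/pointfit.py` — point-model fit and effective-χ re-fit
- `src/pcscloud/postprocess.py` — isolevels, centroids, distance
  distributions
- `src/pcscloud/rotamers.py` — rotamer-library construction
- `src/pcscloud/synthetic.py` — phantoms, toy proteins, generated datasets
- `src/pcscloud/io.py`, `src/pcscloud/cli.py` — formats and the CLI

See `docs/methods.md` for the numerical methods, parameter choices and
known limitations.
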