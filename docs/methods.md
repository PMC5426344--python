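# Methods

This note records the model, the numerical choices and the design decisions
behind `pcscloud`, in enough detail to reproduce or audit any computed
quantity.

## Forward model

The pseudocontact shift of a nucleus at position r relative to a point
paramagnetic centre with traceless susceptibility tensor χ is

σ(r) = 10⁶ · (rᵀχr) / (4π|r|⁵) ppm,

with positions in Å and χ in Å³ (1 × 10⁻³² m³ = 0.01 Å³; Tm³⁺-like tags
have Δχ_ax ≈ 2 × 10⁻³² m³ = 0.02 Å³). In the principal frame this is the
familiar axial/rhombic angular form, and both forms are cross-checked
against each other in the test suite. The formula is linear in χ, invariant
under joint translation, and covariant under joint rotation of geometry and
tensor; its five degrees of freedom are parameterised as
(χxx, χyy, χxy, χxz, χyz) with χzz = −χxx − χyy, avoiding any constrained
optimisation over the tensor.

**Distributed centre.** For a probability density ρ(r) the field is the
convolution σ = ρ ∗ k with the point kernel k above; equivalently σ solves
an elliptic PDE whose Fourier-space form is the multiplier −(kᵀχk)/(3k²).
We solve the convolution by FFT, but *not* by applying that multiplier
directly: the multiplier does not decay with |k|, so its band-limited
inverse transform rings at O(1) of the near-field kernel amplitude and
cannot meet a 1% far-field accuracy target on practical grids. Instead the
kernel is tabulated in real space on a grid zero-padded to twice the
physical extent per axis (so source–target offsets are represented exactly
and periodic images never contribute), and the convolution is carried out
in Fourier space. Within six voxels of the origin, where the kernel varies
steeply, the tabulated value is replaced by the kernel's box average over
the voxel (5³ midpoint subsamples) — the exact interaction for a
piecewise-constant density; the central voxel's box integral vanishes by
cube symmetry for any traceless tensor, which is the real-space counterpart
of zeroing the k = 0 mode of the inverse Laplacian. With this
discretisation a one-voxel source reproduces the point formula to ~0.01%
at ≥ 6 spacings, and a uniform ball reproduces it to ~0.3% just outside
its rasterised support (the harmonic mean-value property).

The kernel transforms for the five χ basis tensors are cached per
(padded shape, spacing); an operator for any χ is a linear combination, so
effective-χ re-fits and functional rebuilds cost no new kernel work.

**Sampling.** Fields are evaluated at nuclei by trilinear interpolation
(the P_N operator); its adjoint scatters per-datum values back onto the
grid with the same eight-corner weights, and the pair satisfies
⟨P f, w⟩ = ⟨f, Pᵀw⟩ to machine precision. Trilinear (rather than higher
order) keeps the adjoint sparse and exact, which the gradient of the
inversion functional requires.

**Accessible volume.** The variational support is the set of voxels whose
centre lies between `r_min` = 2.0 Å and `r_max` = 12 Å from the nearest
protein atom (KD-tree query), the region realistically reachable by a
surface-attached tag.

## Inversion

The objective is

F[ρ] = Σᵢ wᵢ (P_N[σ_ρ](rᵢ) − σᵢ)² + λ‖∇²ρ‖²,  ρ ≥ 0 on the mask,

with the 7-point discrete Laplacian under zero-Dirichlet conditions outside
the mask and the penalty integrated over the grid (voxel-volume weighted).
Weights default to 1 for every datum (¹H and ¹⁵N both in ppm); a per-datum
weight column is honoured when supplied. The data map is linear in ρ, so F
is a convex quadratic; the gradient is the adjoint-FFT backprojection of
the sampled residuals plus λ times the discrete biharmonic of ρ, and the
Hessian action on a probe η is the same composition applied to η. Finite
difference and symmetry checks of these variations are part of the test
suite and of `scripts/acceptance.py`.

For repeated evaluations (λ sweeps, Newton iterations) the per-datum design
rows aᵢ = (Conv ∘ P_Nᵀ)eᵢ restricted to the mask are precomputed — by the
same adjoint-FFT backprojection, so the operator is unchanged to roundoff —
whenever N × n_mask stays under 2 × 10⁸ elements; beyond that the on-the-fly
FFT path is used. The two paths are asserted equal in the tests.

**Minimiser.** A projected Newton–CG method handles the bound constraint:
voxels pinned at zero with outward gradient form the active set, truncated
CG (5% relative residual, capped iterations) solves the Newton system on
the free set, and a projected backtracking line search enforces sufficient
decrease. Convergence is declared when the projected-gradient infinity norm
falls below 10⁻⁶ of its initial value or the objective stagnates at
floating-point resolution (the practical optimum of a convex quadratic).
Ill-posedness makes the landscape extremely flat along near-invisible
density modes; the tolerance is chosen so that all reported quantities
(residual, penalty, centroid, effective χ) are converged well past their
physical precision. The returned density is renormalised to unit mass with
the applied scale reported.

**Mass and scale.** ρ is not constrained to unit mass during optimisation —
the objective has no mass term, and the overall scale of ρ trades off
exactly against ‖χ‖. Mass is normalised after convergence and the scale is
absorbed into the effective χ at the next linear re-fit, keeping the
ρ/χ scale ambiguity in one place.

**Regularisation selection.** λ is swept over 15 logarithmically spaced
values spanning 6 decades centred on a balance guess
λ_c = E[ρ_init]/T[ρ_init] (the point where the two terms match at the
initial density). The sweep runs from large λ down, warm-starting each run
from the previous solution, which cuts its cost several-fold. Residual and
penalty norms are monotone in λ (asserted on every synthetic problem). The
corner is found by fitting smoothing splines to (log₁₀ residual,
log₁₀ penalty) against log₁₀ λ and maximising the *signed* curvature of the
parametric curve: the true corner's orientation (residual rising, penalty
slope flattening) makes its curvature positive, which rejects the spurious
bend where the residual hits its overfitting floor. Across the synthetic
conditions tested, the corner lands within one decade of the
discrepancy-principle λ and the corner-λ reconstruction fits within a
factor 3 of the injected noise floor.

**Self-consistent protocol.** (1) A point-model fit (nested linear χ solve
inside a Nelder–Mead position search, 8 seeded multi-starts within ±10 Å, a
soft penalty keeping the metal ≥ 1 Å from any nucleus) seeds the effective
χ. (2) A coarse reconstruction on the full accessibility shell (64³ grid by
default) localises the density; its centroid centres a 20 Å crop cube.
(3) On the refinement grid (96³ default) masked to shell ∩ cube, each cycle
selects λ (L-curve by default; a config switch reuses the first cycle's λ),
reconstructs ρ, and linearly re-fits the five effective χ elements from
five basis-tensor forward solves. Each cycle runs three inner
refit/re-minimise alternations — the χ/ρ fixed-point map contracts by
roughly 0.6 per alternation, so the inner loop is what lets simple problems
reach self-consistency in ≤ 3 outer cycles. The loop stops when the
relative changes of χ (Frobenius) and ρ (L2) both fall below 10⁻³, with a
20-cycle cap. All stochastic elements (multi-starts, synthetic noise) take
explicit seeds; the default seed is 2017.

Grid sizes are configurable; the documented defaults (64³/96³) suit
workstation runs, and the test suite and acceptance script run the same
protocol at 28³–40³, where the recovery quantities are already converged
far inside their tolerances.

## Synthetic data

The generator produces everything the tests need with no external data:

- **Phantoms**: axis-aligned Gaussian mixtures rasterised at voxel centres,
  rejected if any ±4σ box leaves the grid, normalised to unit mass.
- **Toy proteins**: seeded self-avoiding Cα walks (3.8 Å steps) decorated
  with idealised N, H, CA, C, O atoms; the amide H–N bond is exactly
  1.02 Å and the N-terminal residue carries no amide H. An optional central
  cavity keeps the backbone outside a sphere, modelling a deep binding
  cleft or channel.
- **Datasets**: shifts are the FFT-solved field of a truth density sampled
  at the nuclei plus seeded homoscedastic Gaussian noise in ppm (the same
  noise model for ¹H and ¹⁵N). Nuclei must clear the density's effective
  support (voxels above 1% of the peak, ~3σ for a Gaussian) by two voxel
  spacings; in the standard problem builder, closer nuclei are discarded —
  mirroring the paramagnetic bleaching that removes near-tag assignments
  from real spectra.

**Standard study conditions** (`cavity_tag_problem`): a σ = 2 Å Gaussian
centre in a 10 Å-radius cleft of a 170-residue toy protein, 300 amide
¹H/¹⁵N shifts, noise 1% of the strongest shift (≈ 0.01 ppm), Δχ_ax = 2.0
and Δχ_rh = 0.5 × 10⁻³² m³. The cleft geometry gives the nuclei full
solid-angle coverage of the centre, which pins the density's first moment;
under these conditions the full protocol recovers the centroid to well
under 0.5 Å and the effective χ to a few percent, and the point-fit
position lands within 1 Å of the density centroid.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real side-chain packing and the anisotropic
accessible volumes it creates; residual anisotropic chemical shifts
(assumed negligible, as appropriate for Tm³⁺ on a flexible linker);
heteroscedastic or systematic assignment errors; nuclear-position
uncertainty in the structure (which broadens real reconstructions by a few
tenths of an Å); and any orientation dependence of χ across the tag cloud
(a single effective tensor is assumed throughout, consistent with current
evidence that it is a good approximation).

## Post-processing

- **Probability isolevels**: the level c with ∫_{ρ≥c} ρ = m, by sorting
  voxel values and interpolating between the bracketing levels; for an
  isotropic Gaussian the m = 0.5 region is a ball of radius
  √(χ²₃-median)·σ ≈ 1.5382σ, reproduced within a voxel.
- **Centroids**: mass-weighted voxel-centre means.
- **Distance distributions**: |x₁ − x₂| with x₁ ~ ρ₁, x₂ ~ ρ₂ independent,
  by seeded Monte-Carlo with uniform sub-voxel jitter (which removes
  grid-comb artefacts at bin widths below the voxel size); an exact O(V²)
  voxel-pair sum serves as the oracle on small grids. Defaults: 10⁶
  samples, 0.2 Å-scale bins. Two-column DEER distributions are ingested
  as finished (r, p) text; radii with max(r) < 15 are taken to be nm and
  converted to Å.
- **Comparison metrics**: mean-distance difference, width ratio, and the
  histogram overlap coefficient ∫min(p_a, p_b)dr after rebinning.

## Rotamer libraries

Dihedral vectors are drawn uniformly (independent per angle) and weighted
by exp(−E/kT) with a pluggable energy callable; the default supplied here
is a softened, repulsive-only Lennard-Jones clash score against fixed
environment atoms with a scale factor on the equilibrium distances
(quantum-chemical or full force-field energies are intentionally out of
scope — the interface accepts any callable). The dihedral-space metric is
the Euclidean norm of per-angle circular differences (359° and 1° differ by
2°); it satisfies the triangle inequality, which average-linkage clustering
assumes. The UPGMA tree (scipy, average linkage) is cut at the target
cluster count — the product of per-dihedral energy-minimum multiplicities,
1944 for a DOTA-M8-type linker. Rotamer angles are per-cluster
Boltzmann-weighted *circular* means (vector averaging resolves the
ambiguity of averaging periodic variables); populations are per-cluster
weight sums. Metal clouds deposit each rotamer's population at its metal
position by trilinear splat, giving a density directly comparable with PCS
reconstructions. A serial-chain forward-kinematics helper
(`dihedral_chain_geometry`) builds metal-position callables from internal
coordinates.

## Known limitations

- **Surface-tag ambiguity.** When all measured nuclei lie on one side of
  the density (the classic surface-attached tag with data only from the
  protein interior), the inverse problem admits non-negative
  "downward-continued" equivalent layers: densities smeared toward the
  protein that fit the data exactly *and* have lower smoothness penalty.
  The reconstruction is then systematically biased toward the protein by
  ~1–2 Å at every λ — a property of the continuous problem, not of the
  solver (verified with independent solvers to tight tolerance). Centroids
  from one-sided geometries should be interpreted with this bias in mind;
  geometries with good solid-angle coverage (buried sites, clefts,
  multi-domain data) do not suffer from it. Effective-χ estimates are
  robust in both regimes.
- The λ corner on smooth L-curves can sit up to about a decade from the
  discrepancy-principle choice; both are inside the flat region of the
  recovery quantities in the conditions tested.
- The penalty is the squared Laplacian norm; no maximum-entropy or other
  contrast functional is provided.
- A strict fixed point of the self-consistency loop does not exist at
  λ > 0 (re-feeding back-calculated data yields a slightly smoother
  density each generation); the loop is stable in the quantities that
  matter (χ to < 1%, centroid to < 0.2 Å on restart).
- Grids are cubic-voxel Cartesian; anisotropic spacings are supported but
  untested beyond I/O round-trips.
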