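# Methods

This note documents the models implemented by `mreit`, the numerical
choices behind them, and what the synthetic experiments do and do not
establish about real data.

## Physical model and scope

A conducting slice Ω_z carries two injected currents (j = 1, 2) through
electrode pairs on its boundary. The package solves the *simplified 2D*
forward problem

∇_{xy}·(σ∇u_j) = 0 in Ω_z, u_j = ±1 on ℰ_j±, zero Neumann flux elsewhere,

rather than the full 3D Neumann problem: the reconstruction below is run
one pass (initial guess σ⁰ ≡ 1, no iteration), which yields a *scaled*
conductivity image — contrast up to a global factor — and for that scope
the 2D Dirichlet surrogate is sufficient. Iterative refinement toward
absolute conductivity would require 3D segmentation, meshing and forward
solves and is out of scope.

The magnetic flux density is the Biot-Savart integral of the current
density. The slice current is modeled as **z-invariant** near the imaging
plane (the conductivity extruded along z), giving the closed-form kernel

B_z(x) = (μ₀/4π) ∫ [J_x Δy − J_y Δx] · k(ρ) dA,   k(ρ) = 2/ρ²

in the infinite-extrusion limit (default). This is the regime in which the
in-plane identity ∇²_{xy}B_z = −μ₀(∂ₓJ_y − ∂_yJ_x), the backbone of the
harmonic B_z algorithm, holds; a thin extruded slab (`extrusion_slices`
slabs of thickness dz) is available for studying the finite-thickness
error, where the 2D Laplacian misses a large ∂²/∂z² contribution. The
singular self-pixel of the kernel is integrated by a 4×4 sub-pixel
midpoint rule (which vanishes by parity for pixel-constant currents); all
other source pixels use the midpoint value. The integral is evaluated as
an FFT convolution.

A harmonic background field (electrodes, leads) may be added to B_z; it is
annihilated by the Laplacian and verified to leave the reconstruction
unchanged to 1e-10.

## Reconstruction

With σ⁰ ≡ 1 potentials, the transverse-current matrix
𝔸 = [[−J_{y,1}, J_{x,1}], [−J_{y,2}, J_{x,2}]] is formed per pixel and
F = 𝔸⁻¹[∇²B_{z,1}, ∇²B_{z,2}]ᵀ/μ₀ feeds the Poisson problem
∇² ln σ₁ = ∇·F with ln σ₁ = 0 on the region boundary (a natural-flux
Neumann variant with pinned mean is available behind `boundary="neumann"`).
The solve is **weak-form**: F is sampled at element centroids and
integrated against P1 test-function gradients, so the (twice-
differentiated, possibly noisy) right-hand side is never differentiated a
third time. Conjugate gradients with Jacobi preconditioning solve the
reduced SPD system; Dirichlet rows are eliminated symmetrically.

Numerical reliability masks:

* pixels where |det 𝔸| falls below `det_threshold` (default 1e-3) times
  its median are excluded from F (near-parallel currents, e.g. the
  boundary diagonals between electrodes, carry no invertible information);
* the B_z evaluation mask is eroded by `boundary_margin` pixels
  (default 4): the physical surface-current sheet at ∂Ω_z makes B_z kink
  across the boundary, and the reconstruction identity does not hold
  across that sheet;
* defected pixels (below) and stencil-incomplete pixels are excluded.

Excluded right-hand-side points enter as 0 and are counted in the result.

The **local** variant meshes a user polygon D and runs the identical solve
with ln σ₁ = 0 on ∂D. Because the Poisson problem couples the whole
domain, corruption anywhere contaminates the global solve everywhere; the
local solve is provably blind to data outside D. The A/B experiment in the
acceptance script quantifies this (local/global RMSE ratio ≈ 0.4 on a
corrupted low-contrast phantom).

## Phase processing

B_z is extracted as arg(ℳ⁺·conj(ℳ⁻))/(2γT_c) with γ = 26.75×10⁷ rad/T·s
(hydrogen). The systematic phase δ cancels exactly in the product. The
wrapped phase is unwrapped by Goldstein's branch-cut algorithm: residues
are the non-closing 2×2 wrapped-gradient loops; they are paired greedily
with the nearest opposite charge (or grounded to the mask border when that
is nearer, ties by scan order), cuts are rasterized onto pixels, and a BFS
flood fill integrates wrapped differences without crossing cuts; cut
pixels are filled last from unwrapped neighbors. The algorithm is
deterministic and needs no seed. The remaining per-slice 2πk offset is
fixed by snapping the median unwrapped phase on the mask's boundary ring
to the multiple of 2π nearest zero — physically B_z is near zero far from
the current paths, and any residual constant is invisible to ∇²B_z. A
residue density above 10% of the mask aborts with advice to denoise first.

The z-continuity check compares each adjacent slice pair: the median
absolute inter-slice difference divided by the median in-plane gradient
step must stay below a threshold (default 5, a package choice exposed in
config); any failing pair forces the 2D Laplacian, since an inter-slice
2π jump would otherwise be injected as a spurious ∂²/∂z² term.

## Ramp-preserving denoising

Conductivity edges appear in B_z as *ramps* — slope changes — and the
reconstruction reads their second derivatives, so denoising must not round
them off. The structure tensor U = Σᵢ ∇wᵢ∇wᵢᵀ with (w₁,w₂) = ∇B_z is
built from gradients *of the gradient*, so constants and linear ramps
carry zero tensor energy while ramp edges produce a large eigenvalue
transverse to the edge. B_z evolves under ∂ₜB = ∇·(g(U)∇B) with
g(U) = (1+Λ)⁻¹v_Λv_Λᵀ + (1+λ)⁻¹v_λv_λᵀ and no-flux boundary on the valid
region; U itself is first regularized for time T₂ = 2 by the analogous
diffusion of its components with Gaussian-smoothed coefficients (std s = 1
pixel, truncated at 4s). T₂ and s are robust and fixed; the only user
parameter is the total time T₁ (default 1, larger for noisier data).

Two choices the governing equations leave open:

* **Tensor refresh.** Whether the tensor is frozen at t = 0 (linear PDE)
  or recomputed from the evolving field is ambiguous in the usual
  notation; both are implemented (`refresh_tensor`), default refreshed.
* **Tensor normalization.** The eigenvalues of U carry units
  (field/length²)², so the dimensionful response 1/(1+Λ) is meaningless on
  Tesla-scale data (Λ ~ 1e-16 → no anisotropy). The tensor is therefore
  normalized once by a robust noise-floor estimate — the median trace of
  the initial tensor over the mask, falling back to 1e-4 of the mean trace
  when the median vanishes (nearly noiseless, strongly structured data).
  Noise then sits at Λ ≈ 1 (g ≈ 1/2, diffuses) and coherent ramp edges far
  above it (g ≈ 0, preserved). `contrast` overrides the estimate.

Discretization: explicit conservative finite-volume steps on the pixel
grid, dt = 0.2 (pixel units; the stability bound is 0.25 since every
eigenvalue of g is ≤ 1). Fluxes are antisymmetric across faces, so the
total of B_z over the mask is conserved to roundoff and the centered L2
norm contracts. Verified properties: a clean piecewise ramp changes by
< 1% of range at T₁ = 1; on a 128×128 simulated Shepp-Logan B_z with 5%
noise, the RMSE of B_z improves ≈ 5× and of ∇²B_z ≈ 30×.

## Signal voids and harmonic inpainting

Where MR magnitude is near zero the phase is meaningless noise amplified
by the division. Pixels below 10% of the in-domain maximum magnitude are
flagged automatically (per slice by default), removed from the unwrapping
and denoising masks, and repaired after denoising: B_z on the defect is
replaced by the discrete-harmonic extension of the surrounding valid rim
(5-point Laplace, CG at 1e-12 with direct fallback) — justified by the
homogeneous-conductivity assumption ∇²B_z = 0 inside the void — followed
by a short isotropic diffusion (duration 2, matching T₂'s magnitude; the
sources give no number) on the one-ring-dilated defect to smooth the
seam. The repair is a pure function of (M, B_z, fraction): no interactive
input, hence no user-dependence. Enclosed defect islands are solved
jointly with their surrounding defect. The inpaint obeys the discrete
maximum principle, is idempotent, and leaves pixels outside the dilated
defect bit-identical.

## Geometry and meshing

The imaging domain is segmented from the magnitude image by thresholding
(10% of maximum, same convention as defect detection), largest connected
component (ties broken by centroid row then column), marching-squares
contouring and polygon simplification to 0.5 pixel. This replaces the
level-set segmentation used interactively in practice with a deterministic
equivalent adequate for phantom-shaped supports; electrode arcs are
specified in configuration (anchor angle about the centroid plus arc
length) rather than detected from the image.

Triangulation is done in-package: ear clipping of the simple polygon,
Lawson edge flips toward the constrained Delaunay triangulation, then
Rivara longest-edge bisection of oversize elements (with conformity
closure) until every area is below `max_area` — default half a pixel, so
elements are sub-pixel — and a final area-capped flip pass for quality.
Exactly collinear boundary runs (electrode endpoints inserted on straight
contour segments) are handled as null ears re-attached by splitting the
neighboring triangle. The construction is deterministic; every boundary
mesh edge lies on an original polygon segment, so electrode markers
propagate exactly.

Current densities are taken from element-wise constant P1 gradients,
area-weighted averaged to vertices (recovering one order of accuracy), and
rasterized by pixel-averaging a 2×2 midpoint rule per pixel — plain
center sampling aliases element-scale error into ∇²B_z and visibly
degrades the homogeneous-phantom recovery.

## Synthetic data: what it emulates, and what not

The generator reproduces the measurement chain: magnitude image with
optional void disks, affine systematic phase δ, current-induced phase
γB_zT_c (wrapping included — the default 30 ms pulse at 1 mA produces
phases beyond ±π), i.i.d. circular complex Gaussian noise in image space
(equivalent to k-space noise under the unitary-up-to-scale DFT), and
DC-centered k-space with an unnormalized forward / 1/(n_x n_y) inverse
convention recorded in the container metadata. Every random draw comes
from one seeded generator; identical seeds give bit-identical containers.

Not emulated: pulse-sequence physics beyond the phase model, RF/coil
inhomogeneity, chemical shift, eddy currents, electrode contact impedance,
and 3D conductivity variation (slices are replicated along z). Passing
phantom tests therefore shows correctness of the computational chain under
the stated physics, not robustness to scanner systematics.

## Problem sizes and measured behavior

Unit and property tests run at 16–64 pixels; recovery experiments at
128×128 with ≈ 38k sub-pixel elements (the acceptance script finishes in
about a minute on one CPU). At these sizes, noiseless recovery yields
max |σ₁ − 1| ≈ 0.016 on the homogeneous disk, Pearson r ≈ 0.97 between
reconstructed and true log-conductivity on the σ ∈ {0.8, 1, 1.2} phantom,
and the magnetostatic identity holds with r ≈ 0.994 (relative L2 ≈ 0.11,
dominated by the one-sided stencils at anomaly edges). The homogeneous
deviation decreases monotonically under mesh refinement.

## Known limitations

* One-pass scaled reconstruction only; no absolute conductivity.
* The 2D forward surrogate ignores out-of-plane current spreading; real
  electrodes of finite height violate the z-invariance assumption near
  their edges.
* Goldstein cuts are rasterized to pixels (the classic practical variant);
  pathological residue constellations may unwrap along suboptimal paths.
* Denoising is 2D slice-by-slice by construction; it is inconsistent with
  the 3D Laplacian mode (which is only recommended when the z-continuity
  check passes on undenoised data).
* Ear-clipping + bisection meshes have lower minimum angles than a true
  Delaunay refinement; sub-pixel element sizes keep the induced FEM error
  below the data-discretization error at the tested sizes.
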