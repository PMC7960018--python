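# Methods

## Acquisition model

An acquired stack is an ordered set of parallel 2D slices. Slice `j` is
modeled as a PSF-weighted sampling of the underlying volume under an unknown
per-slice rigid motion, multiplied by a smooth bias field and a global scale,
with additive noise and (in the sparse setting) a random subset of pixels
removed:

    raw_j = exp(+B_j)/S′_j · PSF{X ∘ T_j} + ε,   corrected_j = S′_j · exp(−B_j) · raw_j

Bias and scale are treated as *known simulation parameters*: the forward
simulator draws them and stores them on the slice, and reconstruction applies
the correction before use. Estimating them blind is out of scope (defaults:
scale 1, bias 0 for real data).

Geometry convention: pixel/voxel centers sit at 0-based integer indices,
`world_mm = affine @ [i, j, k, 1]ᵀ`, and the full chain from pixel to
reconstruction voxel is `p_r = W_r⁻¹ · T_global · T_local · W_s · p_s`.
Euler angles are intrinsic Z-Y-X; nearest-voxel rounding breaks ties away
from zero.

## PSF scatter/gather

The slice profile is a separable Gaussian with FWHM equal to the slice
thickness through-plane and to the pixel spacing in-plane
(`σ = FWHM / (2√(2 ln 2))`). Two statements about the through-plane width
conflict in the source model family ("σ_z equals the thickness" vs "FWHM
equals the thickness"); the FWHM reading is used because it is the cited
physical calibration. The kernel is truncated at 2σ per axis (<2 % tail
mass). Scatter accumulates `PSF-weight × pixel-weight × intensity` and the
matching weights; gather divides by the accumulated weights. The raw additive
update without normalization grows unboundedly over iterations, so the
weighted-mean reading is used throughout.

The truncation is deliberately *not* widened for reconstruction: with
in-plane FWHM equal to the pixel spacing, 2σ ≈ 0.85 voxel, so a sparsely
sampled acquisition genuinely leaves empty voxels — that sparsity is the
problem the steering regression addresses. The slice-*registration* metric,
however, floors the footprint reach at 1.1 voxels (`PsfSpec.min_reach`),
because with sub-voxel reach the simulated slice is piecewise constant under
sub-voxel pose changes and the NCC metric loses its gradient.

## Motion surrogate

`δ_r` is computed from the singular values of the slice data matrix (invalid
pixels enter as zeros so the matrix shape is independent of the removal
ratio; vec is column-major — only singular values matter). `μ = δ_{r*}·r*`
with threshold `β = 0.1` by default; `δ_k = 0` exactly, so `r*` always
exists. At desk-scale slice counts (k ≈ 12–32) the surrogate is noisy when
`δ` has a cliff just below `β`, but the ranking of still versus moving stacks
is stable in simulation.

## Registration

NCC is used because it is invariant to the per-slice scale factor of the
acquisition model; the optimizer is Powell (derivative-free) over
`[rotations (deg), translations (mm)]`, coarse-to-fine over a 3-level
Gaussian pyramid for volume-volume registration. Out-of-field samples are
excluded from the metric rather than zero-filled; solutions are never
accepted if they worsen the metric relative to the initialization. Slices
with fewer than 32 valid pixels are skipped. All slices are re-registered
every outer iteration — including currently excluded ones, so a slice whose
pose estimate recovers can re-enter the volume update.

## EM robust statistics

Residual model `P(e) = c·N_σ(e) + (1−c)·U` with `U` fixed at the reciprocal
of the observed residual range (the only range available). Initialization
σ = sample std, c = 0.9; convergence at relative Δσ and absolute Δc below
1e-4, cap 50 iterations; refits across outer iterations warm-start from the
previous state. Slice score `p_slice = Σ p_ij²/N_j` with exclusion threshold
0.5. Note that residuals contain not only motion/misregistration error but
also model mismatch (the double-PSF blur of simulate-after-reconstruct), so
on noise-free synthetic data the EM happily labels sharp-edge pixels as
outliers; with realistic noise the classification is dominated by the noise
scale, which is the intended regime.

## Steering kernel regression

Order-2 Taylor design `[1, d, vech(ddᵀ)]` in voxel units; weighted least
squares solved via the normal equations with an eigenvalue-based condition
check (limit 1e10), falling back to the weighted mean (order 0) for
deficient neighborhoods. Two safeguards matter in practice:

- **Local-range guard.** Under strongly anisotropic weights the order-2
  polynomial can extrapolate wildly; estimates escaping the known-neighbor
  value range by more than half its width fall back to the weighted mean.
  Without this the per-voxel error distribution has rare 10–100× range
  outliers that dominate RMSE.
- **Carry-forward.** Voxels whose steering weights all underflow keep their
  previous (classical or prior-iteration) estimate.

The steering covariance is the window sum of gradient outer products,
eigendecomposed (`s₁ ≥ s₂ ≥ s₃`) and rebuilt as `C = γ · U diag(a) Uᵀ` with
elongation `a_k = (s_k + λ)/(√(∏_{j≠k} s_j) + λ)` and footprint scale
`γ = (√(∏(s_k+λ))/L)^α` over the `w³` analysis window (`L = w³`). In a flat
region this reduces to the isotropic kernel `(λ³)^{α/2}/L^α · I`. The kernel
uses the *sample's* covariance `C_i`, and its printed `2πh²` normalizer is
kept verbatim — any global kernel scale cancels in the weighted
least-squares solve (tested).

**Scale regime of α and λ.** γ compares unnormalized window gradient energy
against λ. With the reference λ = 2.0 the "larger α ⇒ more smoothing"
behavior holds when typical window gradient energies are of order λ, i.e.
order-unity image contrast; at 0–255 contrast the same α *sharpens* (γ > 1
almost everywhere). The package keeps the construction exactly as specified
and documents the regime; the α-behavior fixture uses contrast ≈ 2.

Defaults: `k_c = 5, h_c = 2.0, k_s = 7, h_s = 0.5, w = 3, λ = 2.0, α = 0.4`,
3 steering iterations. The data vector stays the original known samples
across iterations; gradients and covariances update. Field-level evaluation
runs the bulk weight arithmetic in float32 (normal equations solved in
float64); the per-voxel reference path is full precision, and the two agree
to float32 accumulation accuracy.

## Pipeline

Per outer iteration (default 3): robust-weighted PSF scatter/gather →
simulate slices, fit EM, classify outliers → steering-KR update (estimated
voxels become "known" for subsequent simulation) → refresh residuals →
residual correction update (scatter of `PSF × p_slice × p_ij × e*`,
normalized, added to the volume) → slice-to-volume registration. The
reconstruction grid is isotropic at the template stack's in-plane spacing,
covering the template's bounding box (or a caller-supplied grid for
voxel-aligned evaluation). Divergence guard: aborts when the iterate-to-
iterate RMSE grows 3× on two consecutive iterations.

## Synthetic data

The phantom is a deterministic nested-ellipsoid object (background, bright
shell, interior with two lobes, low-amplitude smooth texture) in [0, 255] —
smooth regions and sharp boundaries exercise both the footprint scaling and
the edge elongation of the steering kernels. The simulator draws per-slice
motion uniformly within ± the configured amplitudes, one low-order-2D-
polynomial bias field per slice scaled to the configured maximum, one scale
per slice, adds Gaussian noise, clips at zero (magnitude images), and
removes exactly `round(p·m)` pixels per slice without replacement,
independently across slices.

What it does not emulate: T2 decay and k-space sampling, spin history,
through-plane motion within one slice, scanner-specific intensity
distributions, and anatomy-like texture spectra. Passing tests therefore
demonstrate the mechanics and the relative orderings (steering vs PSF-only,
motion scoring, robust weighting) at desk scale, not clinical image quality.

## Problem sizes

The benchmark protocol reconstructs a 64³ phantom from three orthogonal
stacks (thickness 2 mm, spacing 1 mm, noise σ = 2, bias amplitude 0.1,
scale 0.95–1.05, zero motion) at 50/70/90 % removal, with one outer
iteration and registration disabled (the scenario injects no motion), with
and without the steering update. Unit and property tests use 16³–32³
phantoms. Slice-registration behavior is tested separately on small
motion-corrupted datasets.

## Known limitations

- Bias/scale estimation from data is not implemented (simulated forward,
  assumed known or identity at reconstruction).
- The EM slice classification uses a fixed threshold on `p_slice`, not a
  second slice-level mixture fit.
- The steering covariance construction is scale-sensitive (see above);
  λ would need rescaling for data far from the reference contrast regime.
- Recon grids are isotropic; anisotropic target grids are out of scope.
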