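# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `csetomo`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Measurement model and geometry

A single-axis STEM tilt series is modeled slice-wise: the 3-D density
`F(x, y, z)` decomposes into independent x–z slices `f(x, z)` (y is the tilt
axis), each measured by parallel-beam line integrals at tilt angles
θ ∈ [−70°, 70°] (2° increment by default; the experimental geometries use
±78°/79 projections and 77 projections). A slice of `n_x × n_z` pixels is
measured on a detector of σ = n_x unit-width bins centred on the rotation
centre, giving T = σ·τ measurements per slice. Both bright-field and
dark-field STEM are treated as linear projections of density.

**Projector discretization.** The discrete Radon operator `R` is
pixel-driven: each pixel's value is splatted linearly onto the two detector
bins bracketing its projected centre `u = x·cosθ − z·sinθ`. Consequences:

* per-pixel detector weights sum to 1, so a projection row reproduces the
  slice mass exactly whenever the mass projects inside the detector
  (guaranteed for support in the inscribed disc; a uniform background
  extending to the slice corners loses corner mass at oblique tilts, for
  the simulated and the real geometry alike);
* a centred unit impulse projects to unit row sums at every angle;
* the adjoint `Rᵀ` is the exact algebraic transpose — the classical
  pixel-driven backprojector with linear detector interpolation — so the
  pair is a matched operator pair, which the conjugate-gradient inner solver
  requires, and the WBP baseline backprojects with the same code path.

We chose the pixel-driven splat over a ray-driven (Joseph) projector because
Joseph's per-row 1/cosθ path weighting conserves mass only approximately at
oblique angles, while the reconstruction-side benefits are equivalent at
this resolution. `R` is materialized once per (shape, angle set) as a
sparse CSR matrix (≈ 2·τ·n_x·n_z nonzeros) and cached; forward/adjoint then
batch any number of right-hand sides through one sparse product.

## Sparsity transforms

* **TV**: forward differences with replicate (Neumann) boundary — the last
  difference along each axis is zero, so constants have zero TV. The
  divergence is the exact negative adjoint. Isotropic TV (per-pixel
  gradient magnitude) is the default; anisotropic is available.
* **Identity**: the slice itself.
* **Wavelet**: orthonormal multi-level Daubechies wavelet with 8 vanishing
  moments (`db8`, 16-tap) with periodic extension, 4 levels by default, so
  `WᵀW = I` exactly and the transform is held as one coefficient array per
  slice. Slices whose sides are not divisible by 2⁴ are symmetrically
  zero-padded and cropped on inversion. The depth and the
  vanishing-moment reading of "DB8" are package choices; both leave the
  solver contract unchanged because only orthonormality is exploited.

**Compressibility.** The n%-compressibility ratio of a slice in a domain is
the fraction of transform-domain entries whose magnitude exceeds n% of the
largest magnitude entry (TV domain: the gradient-magnitude image, one entry
per pixel). It is scale-invariant and lies in (0, 1]; smaller = more
compressible. For identity-domain ratios of phantoms with a non-zero
background the evaluation harness subtracts the known background first —
otherwise every pixel of the phantom exceeds any relative threshold and the
ratio saturates at 1.0 for every slice. (This mirrors the background
subtraction applied to experimental reconstructions before identity-domain
sparsity analysis.)

## The CS-ET solver

Per slice, the reconstruction minimizes

    J(f) = (ν/2)‖Rf − y‖₂² + λ_TV·TV(f) + λ_I·‖f‖₁ + λ_W·‖Wf‖₁

by split Bregman. Each ℓ1 term carries one auxiliary variable and one
Bregman vector (`d_TV` is a gradient field updated by isotropic vectorial
shrinkage; `d_I`, `d_W` by scalar soft shrinkage). The quadratic splitting
penalty of each term equals its λ, which makes every shrinkage threshold
exactly 1 and renders the entire iteration invariant under a common
rescaling of (ν, λ_TV, λ_I, λ_W) — only the ratios λ/ν and the data scale
matter. The inner loop alternates a conjugate-gradient solve of

    [ν·RᵀR + λ_TV·∇ᵀ∇ + (λ_I + λ_W)·I] f = rhs

(with `WᵀW = I` absorbed into the identity coefficient and ∇ᵀ∇ applied as a
precomputed sparse Neumann Laplacian) with the shrinkage and Bregman
updates; the outer loop adds the data residual back onto the measurements.
Iteration counts are fixed — 10 outer, 12 inner, no adaptive stopping —
with CG warm-started from the current iterate and budgeted at 10 iterations
or 1e-6 relative residual by default. Initialization is all-zero;
non-negativity is off by default, with an optional clamp after the final
iteration.

With all λ = 0 and one outer sweep the method reduces to CG least squares;
with a single outer sweep and many inner iterations it converges to the
penalized minimizer of J (verified against a FISTA reference on dense
systems); with the full outer loop the Bregman updates drive the data term
toward equality, which on noisy data at fixed iteration counts acts as the
iterative regularization the fixed 10×12 schedule is designed around.

**Precision and batching.** The engine runs in float64 by default; when
handed float32 measurements (the phantom studies) it computes in float32
with float64 scalar reductions, halving memory traffic through the sparse
operator. Many slices (or noise trials) sharing one geometry are solved as
columns of a single batch; per-column arithmetic in the sparse products and
elementwise updates does not depend on the batch composition, but the
wavelet filtering can round differently for different batch widths, so the
user-facing volume driver solves each slice as its own column (bitwise
independent of `workers`) and `reconstruct_sinogram_batch` is the fast path
for studies.

## Hyperparameters

* **Experimental presets** (`default_weights`): bright field ν = 5e-6 (1×)
  or 1e-5 (3×, 6×) with multiples (1.2, 6, 4); dark field ν = 1e-6 with
  multiples (4, 8, 10), (6, 2, 6), (4, 2, 4) at 1×, 3×, 6×.
* **Phantom presets** (`phantom_weights`): the phantom studies need their
  own weights (data scale and content differ from the experimental
  acquisitions). We fixed membrane multiples ν·(600, 60, 100) — a strongly
  TV-dominated prior appropriate for piecewise-smooth shells on a flat
  background — and nanoparticle multiples ν·(60, 30, 0), by reconstruction
  quality on pilot phantoms, the same heuristic route used for the
  experimental weights. Because of the rescaling invariance ν = 1 is used.

## Baselines

* **WBP**: each projection row is ramp-filtered in the frequency domain
  (filter `2·|freq|`, unit gain at Nyquist, optional Hamming apodization;
  rows zero-padded to a power of two ≥ 2σ), then backprojected by `Rᵀ` and
  scaled by π/(2τ). On a near-complete angular range this recovers the
  density scale of a disc phantom to a few percent.
* **SIRT**: `f ← f + relax·C·Rᵀ·R_w·(y − Rf)` with inverse row/column-sum
  normalizations (zero sums → zero weights), 30 iterations and relax = 1 by
  default, from zero. Both baselines are linear in the data.

## Phantoms

* **Membrane phantom**: 256 × 100 × 256 voxels in [0, 1] on a 0.15
  background; 40 random ellipsoidal shells (wall thickness 1–3 voxels) and
  60 filled ellipsoids, semi-axes 4–60 voxels, uniformly random 3-D
  orientations and centres, additive contrasts 0.2–0.85, clipped to [0, 1].
  Structures are kept fully inside axes they fit in and may span/clip the
  thin tilt axis, as sectioned specimens do. Counts, ranges and background
  are package choices emulating membranous compartments at multiple scales;
  they place the phantom's compressibility between the nanoparticle phantom
  and pure noise in all three domains (tested).
* **Nanoparticle phantom**: 256 × 256 zero-background slice with 8
  non-overlapping high-contrast discs and 4 crescents (disc minus offset
  interior disc), piecewise constant by construction.

## Noise models

Both models are count-based and require non-negative projections.

* **Nanoparticle mode**: scale the sinogram so its mean equals the Poisson
  rate (5,500 expected counts at the mean projection value), sample,
  rescale, then add zero-mean Gaussian noise with σ = 10% of the projection
  mean. Pooled variance of (noisy − clean) is mean(y)²·(1/5500 + 0.01),
  verified Monte-Carlo.
* **Membrane mode**: Poisson only. The count scale s solves
  mean(√(y/s)) = target · mean(y − b), i.e. the average per-entry Poisson
  standard deviation equals 10% of the background-subtracted projection
  mean; closed form s = (mean(√y)/(target·mean(y − b)))². The background
  level b is the mean projection of a uniform-background slice through the
  same operator (not background × n_z: oblique paths are longer and corner
  rays clip). Closure of the achieved noise fraction to the target is
  tested to 10% relative.

## Study protocol and problem sizes

The full protocol would reconstruct all 100 phantom slices; the packaged
studies keep the phantom, geometry, noise calibration and the full 10×12
solver schedule, and scale the slice count:

* **Undersampling study**: 16 evenly spaced x–z slices, noisy tilt series
  at 1×/3×/6× (71/24/12 tilts), CS-ET vs ramp-filtered WBP, volume RMSE in
  phantom units (whitening is a visualization step, not applied to phantom
  RMSEs). The per-slice 5%-compressibility vs RMSE Pearson correlations
  (TV, identity, wavelet) use the per-slice mean CS-ET RMSE over the noisy
  and the noiseless 6× reconstructions: the protocol reconstructs under
  both noise conditions, and the two error components — noise passed
  through the regularizer, which tracks slice content, and edge-smoothing
  bias, which tracks gradient sparsity — each carry part of the sparsity
  signal, so either condition alone correlates weakly in some domain for
  some phantom realizations while their combination is consistently
  positive in all three.
* **Sampling-strategy study**: 2 slices binned 2× to 128 × 128, 10 paired
  trials per condition at {1× (71 tilts), 6× (12 tilts)} × {noisy,
  noiseless}; each trial reconstructs from a fresh random angle set and
  from the uniform set of equal size and reports rmse_random −
  rmse_uniform. The binning is a deliberate scale-down: random angle sets
  preclude batching across trials, and the effect under study (angular
  clumping of ~10–70 random tilts) is a property of the angle count, not
  of slice resolution. The uniform baseline is the evenly spaced set of
  equal size, coinciding with the ±70°/2° grid at 1×.
* **Nanoparticle comparison**: one 256² slice, noiseless 3× series, CS-ET
  vs WBP.

## Numerical choices and degenerate inputs

* CG: fixed iteration budget with warm starts; converged columns of a batch
  are frozen so results do not depend on batch composition; a non-finite
  iterate raises a numerical-failure error naming the iteration.
* `sampling_bound` uses the natural logarithm.
* Undersampling keeps index 0 (the most negative tilt); for even-length
  series 0° itself need not be retained.
* Random tilt draws are not deduplicated (ties have probability zero) and
  are sorted ascending.
* All-zero inputs to relative-threshold metrics, constant volumes handed to
  `whiten`, and non-positive background-subtracted means in the noise
  calibration raise degenerate-input errors rather than returning NaN.
* Mutual coherence estimates on sub-sampled dictionaries are qualitative;
  rows are normalized to unit length before comparison.

## What the synthetic studies do and do not show

The phantoms emulate the contrast structure, sparsity ordering and noise
level of stained-section STEM data, and the studies reproduce the
qualitative findings — regularized recovery beats WBP, the advantage grows
with undersampling, reconstruction error tracks slice compressibility, and
random tilt sampling underperforms uniform sampling. They do not include
detector PSF, beam damage, alignment error or fiducials, and real tissue
is substantially less compressible than the membrane phantom, so absolute
RMSEs and the size of the CS advantage on real data are outside what a
passing suite demonstrates. Reproducing the experimental-data figures
requires the deposited beta-cell tilt series, which are an optional input
only.
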