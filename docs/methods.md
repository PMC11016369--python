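# Methods

## Problem and model

Two cryo-EM density maps of the same particle, reconstructed independently,
differ by an unknown rigid transform: a rotation `R ∈ SO(3)`, a translation
`t ∈ R³`, and possibly a reflection (handedness flip). `wemdalign` estimates
this transform from the voxel data alone.

The translation is removed first. For maps with a well-defined molecule, the
center of mass of the thresholded density is equivariant under rotation, so
moving each map's center of mass to the grid center (sub-voxel Fourier
shifting, the shift recorded) reduces the problem to a pure rotation search

    min over R of  d(f1, f2 ∘ Rᵀ)

where `f ∘ Rᵀ` denotes the map resampled on the grid rotated by `R` about the
grid center, i.e. `f_R(x) = f(Rᵀ x)`.

### The loss

The default distance `d` is the wavelet approximation of the 1-Wasserstein
(earth mover's) distance. Writing `Wf` for the 3D separable discrete wavelet
transform of the voxel array (sym3, zero-extension boundary), the signature
weights every coefficient at scale `j` by `2^(−j(1+d/2))`, `d = 3`, with
`j = 0` at the coarsest band (approximation band included, weight 1) and `j`
increasing toward fine scales; the distance is the L1 norm of the difference
of weighted signatures. Coarse scales carry geometrically larger weights
because transporting mass across a coarse scale moves it further — this is
what makes the metric grow linearly with mass displacement, like the true
transport distance, rather than saturating the way pointwise (L2) distances
do once two maps stop overlapping. The approximation also extends to maps
with negative voxel values, which exact transport does not.

The decomposition depth defaults to the maximum useful level
(`pywt.dwt_max_level`; 3 levels for a 64³ grid with sym3). Deeper levels are
dominated by boundary handling and by the shift-variance of the critically
sampled transform; empirically they loosen the linear-in-shift behaviour
(proportionality coefficient-of-variation 2.3% at the maximum useful level
versus 8.8% at depth 6 on a 64³ Gaussian blob).

An L2 loss and arbitrary user callables `d(f, g)` are supported behind the
same interface; the optimizer only ever evaluates the loss.

### The search

The loss is minimized with a Gaussian-process surrogate loop:

1. Model the loss as a zero-mean GP on SO(3) with squared-exponential
   covariance in the Frobenius embedding,
   `k(R1, R2) = σ² exp(−‖R1 − R2‖²_F / 2ℓ²)` — positive definite because it
   is the Euclidean kernel restricted to the embedded manifold.
2. Start the candidate list with the identity and its loss.
3. Each iteration, fit the kriging mean `m(R) = k(R)ᵀ (K + εI)⁻¹ y` to the
   evaluated candidates and minimize it over SO(3) by Riemannian steepest
   descent from a Haar-random start: project the analytic Euclidean gradient
   `∇m(R) = Σᵢ wᵢ k(R, Rᵢ)(Rᵢ − R)/ℓ²` to the tangent space, take an
   Armijo-backtracked step, retract by QR. Descent stops early once both the
   Riemannian gradient norm and the step size drop below 0.1.
4. Evaluate the true loss at the proposal and append; after N evaluations
   return the candidate with the smallest observed loss (first occurrence on
   ties).

The surrogate mean is pure exploitation (no variance/UCB term); exploration
comes from the loose early-stopped inner solves and the random starts —
starts that land in the kernel's exponentially flat far field descend
nowhere and act as fresh random probes, while starts near evaluated
candidates are pulled into the surrogate's current basins.

An optional local polish then runs Nelder–Mead over a 3-parameter axis-angle
perturbation `δ ↦ ‖f1 − f2 ∘ (exp(δ) R̂)ᵀ‖₂` from `δ = 0`, on the L2 loss:
near the optimum L2 is narrow but better conditioned, and Nelder–Mead keeps
the evaluation-only interface. The initial simplex spans ±3° per axis; the
best vertex is returned, so the polish never increases the loss.

Handedness, when requested, is resolved by running the whole procedure on
the mirrored moving map as well and keeping the branch with the smaller
final loss — equivalent in practice to searching over all orthogonal
matrices, at twice the cost.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| iterations N | 200 | loss evaluations | budget at which rotation recovery saturates on the stock volume |
| downsample m | 32 | voxels/edge | Fourier cropping; removes fine detail, smooths the landscape, cuts cost |
| lengthscale ℓ | 0.75 (WEMD), 1.0 (L2) | Frobenius units | ‖R1−R2‖_F = 2√2 sin(θ/2), so ℓ = 0.75 correlates candidates within ~30° |
| marginal variance σ² | 1 (fixed) | loss² | the kriging mean is scale-free in σ²; not a knob |
| nugget ε | 1e-4 | loss² | guards the Cholesky factorization near duplicate candidates |
| early-stop thresholds | 0.1 / 0.1 | gradient norm / step | loose inner solves double as exploration |
| wavelet / depth | sym3 / max useful level | — | see above |
| refine downsample | 32 | voxels/edge | polish level, independent of the search level |
| rotation oversample | 1 in the loop, 2 one-shot | — | see numerical notes |

The gradient early-stop threshold is interpreted on the scale of the
observed losses (multiplied by `max|y|`): surrogate gradients scale linearly
with the observations, so a fixed absolute threshold would silently disable
the inner descent for maps with small intensity units and over-tighten it
for large ones.

## Rotation of voxel grids

`rotate_map` evaluates the map's zero-centered DFT at the rotated
frequencies `Rᵀk` (the spectrum of `f ∘ Rᵀ`) with cubic splines and
inverse-transforms. Frequencies are evaluated inside the Nyquist ball — the
isotropic, rotation-invariant band — and the spectrum's spline coefficients
are cached per map, so repeated rotations of the same map (the optimizer's
hot path) cost one interpolation pass plus one inverse FFT. A real-space
trilinear backend provides the same contract for cross-checking (the two
agree within 2% relative L2 on smooth maps).

With two-fold real-space zero-padding (`oversample=2`) the spectral
resampling is accurate to ~0.1% relative L2 on smooth 32³ maps (composition
error `rotate(rotate(f,R1),R2)` vs `rotate(f,R2R1)` ≈ 0.03%). Inside the
optimization loop the package uses `oversample=1` (~1% accuracy, several
times faster): the loop only compares losses across candidate rotations of
the same map, where a small common resampling error is immaterial. One-shot
`rotate_map` calls default to `oversample=2`.

All grid operations place the rotation/shift origin at voxel index `n//2`
per axis, matching the zero-frequency-centered FFT conventions, so the same
center is exact for even and odd `n`. Periodic wrap-around is accepted;
inputs are assumed compact in the box (the synthetic generator enforces
this, and `make_pair` raises if a transform would push more than 2% of the
mass outside the box, measured on a zero-padded copy).

## Synthetic data

`gaussian_mixture_map` evaluates anisotropic Gaussian lobes
(mass-normalized, so total mass = sum of lobe weights) on the grid. The
stock four-lobe volume has lobe centers inside the central half-box (any
rotation keeps support in-grid), anisotropic covariances and all pairwise
lobe distances distinct, so it has no rotational symmetry and the alignment
loss a unique global basin. `make_pair` produces
`f2 = shift(rotate(f1, R), t) + noise` with i.i.d. Gaussian voxel noise of
variance `mean(f1²)/SNR` added to the transformed copy only; SNR is defined
as mean squared signal over noise variance. Shifts default to uniform draws
over `[−5, 5]³` voxels.

What the generator does *not* emulate: CTF envelopes, B-factor decay,
reconstruction masks, or conformational heterogeneity. Passing tests on
these fixtures show the estimator recovers rigid transforms of smooth,
compact, asymmetric densities at the stated noise levels — not robustness to
cryo-EM-specific artifacts.

The landscape diagnostic uses a separate fixture, an elongated asymmetric
three-lobe filament: the basin-width contrast between WEMD and L2 requires
fine transverse structure (a single smooth Gaussian never decorrelates the
L2 loss), and asymmetry along the filament keeps the quarter-turn
self-alignment curve strictly increasing — for a symmetric rod, 90° is a
stationary point of the true transport curve, where the decimated
transform's residual oscillation (~0.1%) would show as micro-dips.

## Numerical choices

- Haar sampling by normalized 4D Gaussian quaternions; exact and
  seed-reproducible.
- `arccos` arguments clamped to [−1, 1]; relative angles are float-accurate
  to ~1e-4 degrees near 0° and 180°.
- Rotation-vector logarithm uses the canonical branch (angle ≤ π); at
  exactly π the sign is the quaternion convention's, and exp∘log is still
  exact.
- Projection to SO(3) by SVD polar decomposition with determinant-sign
  correction; used as the final cleanup of every optimizer output and as
  the fallback when a QR retraction lands on the wrong component.
- Kernel systems are solved by Cholesky; duplicate proposals are nudged by a
  1° random rotation before evaluation (the nugget alone already keeps the
  factorization finite).
- Interpolated observations are used raw (no centering/standardization),
  matching the zero-mean prior.
- Full re-factorization each iteration: at ≤ a few hundred candidates the
  O(m³) solve is negligible next to one loss evaluation.
- Fourier downsampling rescales by `(m/n)³` so the mean voxel value is
  preserved, and keeps the physical box size (voxel size grows by `n/m`).
- Centering iterates threshold → center-of-mass → sub-voxel shift up to
  three times (interpolation ringing can bias a single pass), applying the
  shift to the unthresholded map. Default contour: the user-supplied level,
  else the 80th percentile of positive voxel values.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full protocol at desk
scale: the 32³ four-lobe volume with 20 trials × 200 evaluations for
rotation recovery (clean), 16³ with 10 trials for the
surrogate-vs-random-search comparison, 64³ blobs for shift-linearity and
SNR statistics. These sizes reproduce the method's qualitative and
quantitative behaviour while keeping a full run in minutes on one core;
deposited maps (e.g. EMD-3683 at downsample 64, 50 trials) run the same
code path and are exercised by the deposited-map protocol test when the map
file is available.

## Known limitations

- Rotation recovery assumes both maps are centered by thresholded center of
  mass; maps whose center of mass is ill-defined (symmetric ring artifacts,
  heavy background) need an explicit contour level.
- The WEMD loss degrades gracefully but measurably under heavy noise; the
  noise-free loss landscape guarantees do not transfer to SNR ≪ 1.
- Translation is estimated once, at centering time, and never re-estimated
  after the rotation search; a joint rotation × translation search is out
  of scope.
- The periodic Fourier operators assume compact support; maps filling the
  box to the boundary alias.
- Conformational heterogeneity breaks the single-rigid-transform model; the
  pluggable loss hook exists for distances designed for that regime, but no
  such distance ships with the package.
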