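# Methods

## Problem setting

During a VMAT delivery the EPID records megavoltage transmission images
while the gantry rotates.  Reconstructing a CT volume from these images
("VMAT-CT") faces three compounded difficulties: the arc is limited (down
to ~205° for single-arc lung plans), every view is truncated to the MLC
aperture around the target, and only the neighborhood of the planning
target volume is of interest.  The package reconstructs a volume of
interest from such data with an iterative two-phase algorithm and
provides an analytic lambda-tomography baseline for comparison.

## Geometry and projectors

Circular cone-beam geometry: source at distance SAD from the isocenter
(default 1000 mm, a conventional linac value — the detector distance
SDD = 1600 mm is a clinical EPID value, the SAD is not similarly pinned
and is configurable), flat panel at SDD, isotropic voxel grid centered on
the isocenter.  Desk-scale defaults are a 64³ volume of 2 mm voxels and a
96×96 panel of 2.5 mm pixels; the clinical-scale grid (270³ mm at 1 mm,
0.8 mm pixels) is supported but not default.

The forward projector is ray-driven: each source→pixel ray is sampled at
a fixed step of half a voxel with trilinear interpolation, and the back
projector scatters with the identical weights, so the pair is the exact
matrix transpose of one discrete linear operator.  This matched-pair
property is what the SART normalization and the adjoint unit tests
assume; it is verified in the tests against a densely materialized system
matrix to 1e−5 (observed: machine precision).

Gantry angles are in degrees with the source above the isocenter at 0°
and positive rotation toward +x viewed from the couch, so arc ranges like
[−175°, 175°] map unambiguously.

## Local (lambda) filtering

Because the projections are truncated, raw line integrals of a
VOI-supported volume cannot match the measurements.  Both the measured
and the simulated projections are therefore convolved row-wise along the
transverse detector axis u with a compact zero-sum kernel `e_R`; the
default is the negated second difference `[−1, 2, −1]`, the canonical
local lambda filter, with symmetric-reflection boundaries.  The exact
taps used by the original lambda-tomography formulation are not
reproduced here; the kernel is a config option so alternative taps can be
substituted.  Detector masks are eroded by the kernel half-width along u
so that no update uses a pixel whose filtered value mixes in- and
out-of-aperture signal.  Rescaling the kernel rescales the filtered data
of both fidelity sides linearly; note that the SART update below is
*not* invariant under this rescaling (its gain scales with the kernel),
which is one reason the kernel normalization is fixed at 1 by default.

## Modified SART

One sweep visits all views in ascending gantry angle and applies, per
view θ,

    x ← x + I · λ V⁻¹ Rᵀ W (p_L − (R x)_L) |_{M_θ}

with W the reciprocal in-mask ray sums (rays weighted by how much VOI
they cross) and V the per-voxel coverage by active rays.  λ defaults to
1.0, the classical SART relaxation.  Negatives are clipped once per
sweep.  Numerical guards:

* rays whose in-VOI path is shorter than half a voxel are inactive — a
  grazing ray carries no reliable VOI information while its reciprocal
  weight would be enormous;
* voxels with no active-ray coverage at a view are skipped, not errors —
  truncated apertures guarantee they exist.

On an untruncated, noiseless, full-arc scene with the identity kernel
and an all-volume mask, ten sweeps recover a 32³ chest phantom to < 10%
relative RMSE (the parameter-recovery anchor in the test suite).  With a
VOI mask smaller than the body the identity-kernel fidelity is
*inconsistent* (no VOI-supported volume reproduces full line integrals);
the lambda filter is what makes the masked problem well-posed.

## Split-Bregman TV + BM3D denoising

After each sweep the volume is denoised by ten inner loops of the split
Bregman iteration for

    min ‖∇x f‖₁+‖∇y f‖₁+‖∇z f‖₁ + μ‖f − f_j‖² + δ‖BM3D(f)‖₁.

Loop ordering follows the algorithm's stated box: the auxiliary
variables D and multipliers b are updated from the *current* volume
(shrinkage thresholds 1/α and 1/β), then the quadratic f-subproblem

    (μ + α ∇ᵀ∇ + β) f = μ f_j + α Σ_a ∇_aᵀ(D_a − b_a) + β (D_w − b_w)

is solved exactly in the Fourier domain.  Two deliberate readings:

* the subproblem is diagonalized with a **3D** FFT and the 3D periodic
  Laplacian spectrum (a 2D transform would leave the z-gradient terms
  undiagonalized; the 3D reading makes the dense-solve oracle
  equivalence exact, verified to 1e−6 in the tests);
* the BM3D constraint enters the quadratic solve through an
  identity-operator approximation (the `+β` in the denominator); the
  BM3D operator itself acts only in the D_w / b_w updates, evaluated
  once per loop.

δ is exposed but fixed at 1 by default; the shrinkage threshold of the
BM3D channel is 1/β verbatim (with δ≠1 a δ/β threshold would be the
consistent generalization).

Gradients use periodic boundaries (required for exact FFT
diagonalization); the reconstruction mask keeps anatomy away from the
volume faces, so wrap-around effects are negligible in practice.

The defaults μ=2, δ=1, α=1, β=0.3 are *absolute* weights: the shrinkage
thresholds 1/α and 1/β are intensity quantities.  They presuppose
clinical image magnitudes well above 1 — with soft tissue at O(1) the
BM3D channel degenerates (D_w shrinks to zero every loop and its
multiplier grows without bound).  The synthetic phantom therefore uses
an HU-like intensity scale (soft tissue = 100); CNR and SSIM are
invariant to this choice of units.

### BM3D operator

Self-contained slice-wise hard-thresholding BM3D over the axial planes:
8×8 reference blocks on a step-4 grid, block matching by mean squared
difference within a ±16 pixel search window (raster-order tie-break for
determinism), stacks of up to 16 similar blocks, separable orthonormal
3D transform (2D DCT per block, 1D DCT along the stack), hard threshold
at 2.7 σ with the group DC coefficient exempt (so constant regions are
reproduced exactly), inverse transform, and aggregation with per-group
weights 1/n_retained.  σ defaults to a per-slice robust estimate (median
absolute Haar diagonal detail / 0.6745) and can be fixed.  The Wiener
second stage of canonical BM3D is intentionally omitted: the operator
serves as a regularization prior inside the outer iteration, not as a
stand-alone denoiser.

## Outer loop and stopping

From a blank volume, each outer iteration runs one SART sweep (the
measured projections are filtered and masked once up front and cached —
they never change) and one denoising step, then evaluates
`r_j = ‖f_{j+1} − f_j‖_F / ‖f₁‖_F` with f₁ the first iterate.  The loop
stops when `r_j < 0.005` or after 20 iterations.  Degenerate all-zero
data are declared converged at j=1 with a warning (the ratio is 0/0).
The returned volume is clipped non-negative.  On noiseless consistent
data the default configuration reaches the threshold within the
iteration cap; on the noisy truncated standard scene it typically runs
to the cap with r_j ≈ 0.03.

## FDK / lambda-tomography baseline

The comparison arm is a filtered-backprojection pass with the local
kernel substituted for the ramp filter: cosine pre-weighting, per-row
convolution along u, smooth short-scan (Parker-style over-scan) angular
weights whenever the arc is shorter than a full turn — the redundancy
handling is this package's own choice — and voxel-driven backprojection
with the
standard (SAD/l)² cone-beam distance weight.  The output is an
edge-enhancing, non-quantitative lambda image; it is evaluated with the
same masked SSIM and |CNR| as the iterative reconstruction.

## Image-quality metrics

* **CNR** = (mean_VOI − mean_ref) / sd_ref with population sd, ~1 cm³
  boxes (5³ voxels at 2 mm).  The air-cavity VOI makes the numerator
  negative in attenuation units while the success threshold is positive,
  so success (CNR strictly > 2) is applied to the magnitude; the signed
  value is also exposed.
* **SSIM** is computed from local means and standard deviations
  (per-axial-slice Gaussian window, σ=1.5, 11×11 support;
  C1=(0.01 L)², C2=(0.03 L)² with L the reference dynamic range — the
  conventional choices) and averaged over the evaluation mask.  The
  formula compares means and standard deviations only (no
  cross-covariance term), so it is a luminance·contrast similarity; it
  equals 1 iff the local statistics agree everywhere.

## Synthetic scene

The generator emulates the data regime of a single-arc chest delivery:

* chest phantom (64³, 2 mm): soft-tissue body ellipsoid (100), two lungs
  (25), spine cylinder (200), target sphere (120, radius 17 mm)
  containing a concentric air cavity (0, radius 12 mm) large enough that
  the 1 cm³ VOI box clears the cavity wall; rasterized without
  anti-aliasing so the clean phantom has exactly the declared levels;
* arc [−175°, 175°], 120 uniformly spaced views (a desk-scale stand-in
  for the few-hundred EPID frames of a clinical arc); one arc, not the
  clinical two — a second arc adds data but no new geometry;
* per-view rectangular aperture tracking the target's projected
  centroid with a 10 mm margin — a deliberate simplification of MLC leaf
  sequences;
* Gaussian noise of σ = 2 (2% of the soft-tissue intensity) added to the
  in-aperture projections; Poisson noise optional.  All randomness flows
  from one seed.

The evaluation boxes are placed for validity: the reference box lies in
soft tissue *fully inside the aperture-covered region* (a box straddling
never-measured voxels would measure the blank initialization, not the
reconstruction), and the reconstruction-mask margin equals the aperture
margin so the VOI mask matches the measured region.

What the generator does **not** model: megavoltage spectra, scatter and
detector glare, MLC leaf shapes and motion blur, gantry flex, or real
EPID preprocessing (the pipeline exposes a no-op preprocessing hook).
Passing tests therefore demonstrate the algorithmic contracts —
convergence, masked recovery, direction of effect versus the analytic
baseline — not clinical image quality on real portal images.

## Problem sizes and numerical choices

Tests and the acceptance script run the standard scene at 64³ / 120
views (minutes on one CPU) and the oracle equivalences at 8³–16³, where
the operators can be densely materialized.  Tolerances: adjoint and
dense-oracle equivalences at 1e−5–1e−6 relative (observed far tighter);
BM3D zero-threshold round-trip at 1e−6 relative.  Ties in block matching
break in raster order; the SART view order is ascending angle; all
stochastic tests fix their seeds.

## Known limitations

* The reconstruction is non-quantitative: the lambda-filtered fidelity
  leaves a smooth null space, so absolute attenuation levels compress
  toward the initialization (contrast ratios, CNR and SSIM remain
  meaningful).  No HU calibration is attempted.
* BM3D operates per axial slice; no inter-slice grouping.
* The split-Bregman inner loop is run a fixed 10 times, not to
  convergence; its surrogate objective decreases over the first loops
  but is not guaranteed monotone.
* CPU-only; the per-view projectors dominate the runtime.
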