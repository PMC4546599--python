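# Methods

## Physical model

The forward model treats analyzer-based (dark-field) phase-contrast
imaging in its geometric-refraction regime.  A specimen is described by
two registered 2-D maps on a centered square grid: the refractive-index
decrement δ(x, y) (dimensionless, ~10⁻⁷ for soft tissue at ~31–35 keV)
and the linear attenuation coefficient μ(x, y) (mm⁻¹).  For a parallel
beam at view angle θ,

* the absorption image at the rocking-curve plateau (point B) is
  Beer–Lambert: I_abs = I₀·exp(−∫μ dl), with I₀ = 1;
* the refraction angle is the transverse derivative of the phase
  projection, θ_r(ξ, θ) = ∂/∂ξ (ℜ_θ δ), in radians;
* the refraction-modulated image at the flank working point A is
  I_refr = I_abs · T(A + θ_r), where T is the analyzer transmissivity.

T is parametric: a flat plateau of half-width 0.15 × FWHM joined to
Gaussian flanks, with the FWHM defaulting to 2×10⁻⁶ rad and peak
transmissivity 0.8.  Point A defaults to the half-maximum point of the
negative flank (−FWHM/2); the extraction step treats ±5×10⁻⁷ rad around
A as the one-to-one measurable range.  The true dynamical-diffraction
curve of a Si(440) Laue analyzer is not modeled; only the features the
method uses — a flat absorption point, a monotonic flank, the stated
FWHM — are reproduced.  One consequence of the symmetric parametric
curve: deflections several times beyond the positive range can alias
across the plateau into the measurable intensity window, so the
per-pixel saturation flag detects a subset of the truly degenerate rays.
The suppression algorithm is unaffected, because it derives its
missing-data region from the absorption tomogram, not from the flag.

`extract_refraction` divides the refraction-modulated image by the
absorption image and inverts the flank; ratios outside the one-to-one
window are clamped to the range edge and flagged.  The asymmetry factor
of the monochromator-collimator, b = sin(θ_B − α)/sin(θ_B + α), is
implemented for provenance and its two reference configurations
(12.0°/11.1° → 0.04 and 10.6°/10.2° → 0.02) serve as exact worked
examples; beam expansion itself is not simulated.

## Phantoms

Two presets emulate the study scenarios on a ~1 cm field (256² pixels at
39 μm; tests and the suppression benchmarks use the same physical field
at 128²/78 μm):

* **artery** — a smooth elliptical tissue dome (δ = 2×10⁻⁷,
  μ = 0.03 mm⁻¹), a vessel-wall annulus (Δδ = 4×10⁻⁸, wide raised-cosine
  tapers), and one hard-edged calcification-like blob (δ = 10⁻⁶,
  μ = 0.5 mm⁻¹, radius 420 μm) whose position jitters with the seed;
* **rat_foot** — the dome plus two bone-like blobs (δ ≈ 1.2–1.5×10⁻⁶,
  μ ≈ 0.7–0.8 mm⁻¹) and a soft joint-tissue blob.

Soft structures deliberately use wide, smooth radial profiles.  The
transverse derivative of a projected structure of radius r and edge
width w scales like δ·√(2r/w): a hard-edged "soft" disk would deflect
the beam just as far out of the measurable range as a calcification
does, which is physically wrong for tissue-scale δ gradients.  The
dome/taper widths were chosen (and verified against the forward model at
design time) so that soft-only phantoms peak at ≈4.4×10⁻⁷ rad — inside
the ±5×10⁻⁷ rad range — while dense-blob edges deflect by ~5×10⁻⁶ rad
and saturate hard.  Dense blobs keep hard edges by default; an
`edge_blur` parameter exists for sensitivity studies.

Acquisition noise defaults to Poisson counting at 10⁶ photons per
detector bin (~0.1% relative).  This models a well-exposed, averaged
synchrotron projection.  Note a genuine sensitivity of the method: the
flank inversion is convex, so intensity noise produces a small *bias* in
the extracted angle that grows as 1/photons; at ~10⁵ photons the bias
breaks the per-angle zero-sum property of the measured data badly enough
that the reconstruction loop cannot reach its convergence tolerance.
Real systems with shallower noise or steeper analyzer slopes shift this
threshold; the generator makes it explorable.

What the generator does **not** emulate: anatomical texture, partial
volume at tissue interfaces, detector point-spread, beam hardening,
alignment errors between the two acquisitions.  Passing tests therefore
demonstrate the algorithmic behavior (corruption localized to dense-ray
sinogram entries, recoverability from the zero-sum constraint), not
performance on real specimens.

## Tomographic primitives

The projector is pixel-driven: each pixel center splats onto nearby
detector bins (spaced at the pixel pitch) with a linear hat convolved
with a normalized Gaussian anti-aliasing kernel (σ = 1 bin, truncated at
±3).  The kernel matters: with a bare hat footprint, the quasi-random
pixel-to-bin phases put a pixel-frequency ripple on smooth projections
that ξ-differentiation amplifies above the analyzer's linear range even
for soft-only phantoms.  Because the kernel is symmetric the
forward/backprojection pair is an exact transpose (verified to machine
precision), and because it sums to one, column mass is conserved, making
the per-angle zero-sum of differentiated compact projections hold to
machine precision.  The trade-off is conditioning: single-pixel
checkerboard modes are nearly invisible to the smoothed system
(σ_min/σ_max ~ 2×10⁻³ on an 8×8 test system), so algebraic inversion of
those modes is slow — the pseudoinverse oracle test compensates with an
aggressive relaxation and a large sweep count, cheap at that size.

ξ-differentiation uses central differences (one-sided at detector
edges); for compactly supported data the column sum telescopes to zero
exactly.  FBP uses a plain ramp filter (|ω| up to Nyquist, zero-padded
FFT) and the adjoint as backprojector, scaled by πΔθ; it is cross-checked
against scikit-image's `iradon` in the tests.  ART is implemented as
angle-block simultaneous updates with SART weighting (residuals divided
by row sums, updates by column sums — the per-view column sum is exactly
the pixel pitch because footprints are normalized), visiting views in a
fixed bit-reversed (multilevel) order; relaxation defaults to 0.25 with
3 sweeps per outer iteration.  The SART weighting was chosen over raw
row-norm Kaczmarz blocks because the wide footprints of adjacent rays
overlap, which destabilizes the unweighted simultaneous update at
relaxations above ~0.3.

Signum integration is computed by the prefix-sum identity
½(Σ_{j<i} − Σ_{j>i}) p_j Δξ, equal to the literal O(n²) signum
convolution (kept as a test oracle), and inverts ξ-differentiation on
compact projections to <1%.  Phase reconstruction = signum integration →
FBP warm start → ART sweeps.

## Segmentation

Dense mask D: Otsu threshold on the absorption tomogram, accepted only
when the upper class has real dense-object contrast (mean ≥ 3× the bulk
of the positive lower class) — otherwise Otsu would hallucinate a dense
class on soft-only specimens; small components (<4 px) removed.  An
explicit threshold bypasses the gate.  Missing region R: forward
projection of D, thresholded at 1/20 pixel of dense path, dilated by 2
detector bins (the artefact extends beyond the geometric shadow).
Support S: 10% of the robust (99.5th-percentile) maximum of the initial
phase tomogram, morphological closing (3 px disk), hole filling, largest
component, then union with D.  With the anti-aliased projector the
support overshoots a hard object boundary by ~1.5 px; this is
deliberate generosity — S only constrains where tissue may live, and a
slightly dilated support never deletes real structure.

## The suppression loop

The loop follows the seven-step structure described in the README.  Two
numerical safeguards, both package design choices, stabilize the
per-angle rescale factor k = −∫_R̄ p(0) / ∫_R p(n):

* **Ridge regularization toward 1.**  The denominator is a small
  difference of large values (a dense inclusion's differential content
  nearly cancels over its own shadow), so the raw ratio can reach ±10³
  early in the iteration and feed amplified copies of the estimate back
  into the reconstruction.  With d = ∫_R p(n), m = ∫_R̄ p(0) and
  ε = 0.2 × the L1 mass of p(n) inside R, the factor used is
  k = (−m·d + ε²)/(d² + ε²), clipped to [0, 3]: exact when |d| ≫ ε,
  smoothly → 1 as the denominator degenerates (a vanishing denominator
  gives exactly k = 1).  Hard fallbacks (discrete switching between the
  exact k and k = 1) were tried first and left the loop in
  branch-switching limit cycles under realistic noise.  Whatever k is
  used, the small residual needed to zero each angle's total sum is
  spread uniformly over R_θ, so the zero-sum identity holds exactly for
  every angle at every iteration, and measured data outside R is never
  touched.
* **Krasnoselskii–Mann relaxation.**  The outer update is damped,
  f ← f + β(Φ(f) − f) with β = 0.5, which removes the oscillatory
  (period-2) modes the sinogram↔tomogram alternation can excite; β = 1
  recovers the undamped iteration.

The TV weight λ (default 0.05) is dimensionless: the loop multiplies it
by the robust amplitude of the iterate (99.5th percentile, frozen after
the first pass so the penalty is a true constant multiplier) and divides
by the pixel pitch before calling the denoiser.  Convergence uses the
plain relative change ‖f(n+1) − f(n)‖/‖f(n)‖ against a default tolerance
of 10⁻³ with at most 30 iterations; non-convergence returns the result
flagged, never an exception.  Dense-interior pixel values are whatever
the loop produces; all evaluation metrics exclude them.

On the artery benchmark (128², 180 views, 10⁶ photons) the loop
converges in ~11–23 iterations across seeds with k settling in
[0.95, 1.07] and reduces near-inclusion band RMSE by ~85–95%.  The
rat-foot preset, with ~32% of the sinogram missing (two large bones), is
a documented harder case: the improvement is positive but smaller and
convergence can exceed the default iteration budget.

## TV denoising

`tv_denoise` solves min_{f ≥ 0} ‖f − g‖²_F + λ·TV(f) with the isotropic,
forward-difference, pitch-scaled TV of `tv_value`, using a
Chambolle-style primal-dual scheme (dual variable projected onto the
λ-ball, primal prox handling data term and nonnegativity; steps
τ = σ = 1/√8, 50 iterations default, 10⁻⁵ relative-objective stop).  A
best-iterate safeguard makes the reported objective non-increasing.
λ = 0 returns the input unchanged.  The solver is validated against an
independent long-run L-BFGS-B reference on a smoothed objective (within
0.5%) and against scikit-image's Chambolle solver where the constraint
is inactive.

## Evaluation metrics

`band_rmse` measures RMSE over pixels within 10 px of the dense mask,
excluding the dense pixels and a 2 px guard ring at their boundary: any
band-limited reconstruction mis-renders the hard inclusion edge itself,
and without the guard that irreducible edge error dominates the
soft-tissue restoration the metric is meant to quantify.
`high_freq_artefact_index` is the L2 norm, inside the support, of the
Gaussian high-pass (σ = 2 px) of the reconstruction error — the scale of
the "minute" iteration-noise artefacts the TV step exists to remove.

## Problem sizes

The suite runs the artefact-reproduction check at the acquisition scale
(256², 360 views at 0.5°) and the suppression benchmarks at 128² with
180 views on the same 1 cm field — the package's standard benchmark
size, at which a full suppression run takes ~10 s.

## Known limitations

* Slice-by-slice 2-D only; no 3-D regularization across slices.
* The parametric rocking curve cannot represent Pendellösung structure
  or asymmetric flanks; saturation detection inherits the aliasing
  ambiguity noted above.
* Per-angle k is a single scalar even when R_θ has several disjoint
  intervals (several inclusions); large missing fractions slow
  convergence.
* The noise-bias sensitivity of the flank inversion at low exposure is
  inherent to the extraction, not corrected by the loop.
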