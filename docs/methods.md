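# Methods

`respimoco` is a desk-scale, fully synthetic implementation of a
surrogate-driven respiratory motion-correction pipeline for simultaneous
PET/MR. Every stage of the clinical chain is present — phantom,
acquisition, respiratory signal, motion model, motion-compensated
reconstruction, quantification — and every stage can be validated against
the simulator's hidden ground truth.

## The problem

Respiration moves the diaphragm by roughly 20 mm per cycle. Over a
multi-minute PET acquisition this blurs lesions in the thorax and upper
abdomen (apparent size up, apparent uptake down), mislocates lesions near
the lung–liver boundary, and — because the attenuation map (μ-map) is a
breath-hold snapshot — creates emission/attenuation mismatch artifacts such
as the curved low-intensity band at the liver dome.

The correction modelled here uses no external hardware: the respiratory
surrogate is derived from the PET data themselves, a short free-breathing
dynamic MR acquisition supplies the deformation information, and a
continuous motion model ties the two together so that 100% of the PET data
can be corrected and the μ-map can be mapped between respiratory states,
including states never visited during the model-building minute.

## Phantom and ground-truth motion (`phantom`, `waveform`)

The default phantom is a single coronal slab, 128 × 128 voxels at 3 mm
(axis 0 superior → inferior): a body ellipse, two lungs
(μ = 0.03 cm⁻¹, activity 0.3 kBq/mL), soft tissue (0.096 cm⁻¹, 1.0 kBq/mL),
a liver (0.096 cm⁻¹, 2.5 kBq/mL) whose upper edge forms the diaphragm dome,
and spherical lesions (default one 10-mm, 12 kBq/mL lesion at the liver
dome — the site most affected clinically). A 3D switch extrudes the same
layout; the reconstruction operates on the 2D slab, which keeps the whole
pipeline at interactive runtimes without changing any algorithmic content
(the method is dimension-agnostic).

Ground-truth motion is generated in the same functional form the model
later fits: per-voxel displacement `d(x) = g1(x)·s + g2(x)·ṡ`, pull-back
convention, with

* `g1`: superior–inferior displacement with peak 20 mm at the diaphragm,
  decaying as a Gaussian envelope (σ = 70 mm) away from it, plus a small
  (10%) lateral expansion component;
* `g2`: the hysteresis term (default 2 mm·s at the diaphragm) — at equal
  amplitude, tissue sits at different positions during inspiration and
  expiration, which is precisely what motivates the gradient surrogate;
* an optional quadratic-in-`s` mismatch term for misspecification studies.

Because generator and model share the linear form, coefficient recovery can
be tested exactly; the mismatch mode breaks that alignment on purpose.

The breathing waveform is `s(t) = a_c · sin^{2k}(π t / T_c)` per cycle
(k = 2 default): the 2k-th-order flat bottom reproduces the long end-exhale
dwell of quiet breathing. Per-cycle amplitude (CV 15%) and period
(mean 4 s, CV 10%) are drawn independently; an optional linear drift models
baseline creep. These are conventional values for quiet adult breathing —
chosen once as the study conditions, with the clinical protocol supplying
the fixed timing facts (4-min PET window; 1-min dynamic MR at 0.3 s/image
cycling 9 slice positions).

## Acquisition simulation (`acquisition`, `projector`)

PET: the 4-min window is cut into 0.5-s frames (a list-mode stand-in that
resolves a 4-s cycle). Each frame's expected sinogram is the attenuated
parallel-beam projection of the phantom warped to the frame-midpoint state;
Poisson noise is optional, with the calibration set so the noise-free trues
total 3 × 10⁶ counts over the window — enough for per-gate images at desk
scale while keeping realistic frame-level sparsity. Scatter and randoms are
emulated as a *known* uniform additive background (10% of trues,
apportioned to frames by live time — a constant rate); it is passed to the
reconstruction as the additive term, and its estimation (a standard,
separate problem) is out of scope. The true `(s, ṡ)` at each frame midpoint
is stored as hidden truth for validation; the correction path never reads
it.

The projector is parallel-beam with an *exactly matched adjoint*: rotation
is an explicit sparse bilinear-resampling matrix, the forward projection is
a column sum of the rotated image, and back-projection is the transpose of
that composition. The matched pair is what preserves the EM update's
behaviour; the implementation agrees with an independent radon transform to
machine precision on odd grids (even grids differ by the rotation-centre
half-pixel convention). 126 angles over [0, π) (21 subsets × 6 angles).
Attenuation enters as per-line factors exp(−∫μ dl) from the same line
integrals. An optional 4.5-mm FWHM radial blur emulates system resolution
(off by default).

Dynamic MR: snapshots of a per-organ contrast map (lung dark, liver bright)
warped to the instantaneous state, 0.3 s per image, cycling 9 slice
positions for 1 min, with mild Gaussian noise (σ = 0.02 of the unit
intensity scale). In the 2D slab the 9 "positions" are acquisition-
interleave labels viewing the same plane — the timing structure is
preserved exactly, the geometry collapses; in 3D they select sagittal
planes. MR timestamps are written on a separate clock
(`t_mr = rate · t_pet + τ`) to model real hardware clock offset and drift.

μ-map: the attenuation map is "acquired" at an arbitrary breath-hold state,
possibly outside the free-breathing range (deep exhale/inhale). Alongside
it the simulator emits a short breath-hold PET segment; the pipeline later
measures the map's surrogate value by projecting those frames through the
fitted surrogate transform — the same route the clinical method uses — so
no hidden truth enters the correction.

## PET-derived surrogate and clock alignment (`surrogate`)

The surrogate is the first principal-component score of the mean-centred
frame sinograms (computed via the frame-space Gram matrix), after 4 × 4
coarse rebinning for per-bin statistics; a centre-of-mass alternative is
provided. The sign is fixed against the axial centre of mass (deterministic
across runs), a Savitzky–Golay filter (≈1.5-s window, order 2) suppresses
the Poisson noise of the per-frame score *before* normalisation — without
it, surrogate noise attenuates every downstream regression on `s`
(errors-in-variables) — and min–max normalisation to [0, 1] is frozen over
the 4-min window (per-window, not per-cycle; new frames projected through
the frozen transform can legitimately land outside [0, 1] — that is the
extrapolation case). `ṡ` is the central-difference derivative of the
smoothed, normalised `s`. The extractor also estimates the per-frame score
noise from the 0.8–1.0 Hz spectral floor (clear of quiet-breathing
harmonics) and carries a *reliability* factor
`1 − noise variance / var(s)`: the model is fitted against the noisy
surrogate and its slopes are therefore diluted by exactly that factor
(classical regression attenuation), which is the consistent calibration for
gating — gates are defined by the same noisy signal — but not for a query
state measured nearly noise-free. The μ-map's breath-hold state (an average
over many frames at a held position) is such a state, and is rescaled about
the series mean by the reliability before the model is queried.

Clock alignment maximises the correlation between the PET surrogate
(interpolated) and a per-image diaphragm-edge trace from the MR series
(subpixel edge localisation in a lateral column band, standardised per
slice position), over a τ grid (±10 s, 0.1-s step) with parabolic
refinement; the clock-rate factor can be co-estimated on a small grid. A
pure sinusoid would leave τ ambiguous modulo one breathing period — the
cycle-to-cycle variability of real (and simulated) breathing is what makes
the optimum unique.

## Motion model (`registration`, `motionmodel`)

Per slice position, the reference image is the one whose aligned surrogate
value is closest to the end-exhale histogram mode; every other image is
registered to it with multi-resolution (shrink 4/2/1) fast symmetric-forces
demons (SimpleITK), smoothed update and displacement fields, after mild
pre-smoothing. An intensity-difference threshold (0.05 of the unit
intensity scale, ≈2σ of the image noise) zeroes the demons force where the
image difference is below the noise floor; without it the force term
random-walks in flat regions, and two identical noisy images come back with
spuriously non-zero fields. Images whose post-warp residual is grossly out
of line (5 × median, floor 0.08) are flagged outliers and excluded, not
fatal. No sliding-motion model is used.

The model itself is per-voxel, per-component robust linear regression of
displacement on `(1, s, ṡ)` — Huber IRLS, tuning constant 1.345σ with a MAD
scale — vectorised across all voxels. `MotionModel.fit()` returns a
`MotionModelResult` with coefficient maps (c0, c1, c2), R², robust weight
sums, the frozen fit ranges, `predict_field(s, ṡ)` (exactly linear;
extrapolation permitted and flagged in the field's metadata) and a
`summary()` table. A degenerate design (constant or collinear surrogate)
raises an error naming the offending regressor; a degenerate *signal*
(motionless, noiseless data) makes the pipeline fall back to the explicit
null model — no detectable breathing means the correct correction is none,
and the motion-corrected reconstruction then equals the uncorrected one to
float precision. Cubic through-plane interpolation of coefficient maps
across slice positions is provided for the 3D case (trivial in the 2D
slab).

The fit is two-stage (register, then fit) with robustness supplied by the
Huber weights and the outlier flags; a joint registration–model
optimisation would be an alternative formulation of the same requirement.

## Reconstruction (`recon`)

OSEM with 21 subsets, 3 iterations, 4-mm Gaussian postfilter (applied to
the final image only); additive background in the denominator of the
multiplicative update; bit-reversed subset processing order; interleaved
(near-equal, with a warning, when the subset count does not divide the
angle count) angle allocation; zero-sensitivity voxels excluded rather than
divided by. With one subset the algorithm is algebraically MLEM.

Uncorrected mode pools all frames and uses the static μ-map as acquired.

Motion-corrected mode is MCIR: gates are equal-count amplitude bins of `s`
(8 by default; an amplitude × breathing-direction scheme is available),
each gate's representative state is the count-weighted mean `(s, ṡ)`, and
the per-gate warp (sparse matrix, exact adjoint — the adjoint, not the
inverse, appears in the back-projection) sits inside the system model, so
one image estimate at the reference state absorbs every gate's data: count
conservation over gates is asserted on every run, and an empty gate is a
hard error unless explicitly allowed. The μ-map is first mapped from its
measured surrogate state to the reference (fixed-point inversion of the
predicted field), then warped to each gate's state for that gate's
attenuation factors. Reconstruct-transform-average (RTA) is provided as a
config alternative; MCIR is the default because a single-image output with
per-gate warped μ-maps matches the clinical description most directly.

## Quantification and reader statistics (`quantify`)

SUV = concentration × weight / dose (70 kg, 350 MBq defaults).
SUV_peak is the maximum, over sphere centres inside the lesion ROI, of the
mean SUV in a 12-mm-diameter sphere discretised by voxel-centre inclusion
(6-mm radius; the sphere may extend outside the ROI; at the grid edge only
in-grid voxels contribute); SUV_max is the maximum ROI voxel. Both equal
exhaustive brute-force sweeps exactly. Δ% uses the uncorrected value as
denominator (undefined and flagged when U ≤ 0); a change is "considerable"
when both metrics move by more than 5% in the same direction.

Reader marks are matched to reference lesions one-to-one, greedily by
distance within 15 mm (the readers' visual matching has no stated
tolerance; 15 mm is a package default). Matched marks are TP, unmatched
marks FP, unmarked reference lesions false negatives scored χ = 0 on the
1–4 confidence scale. Δχ per reader and the across-reader sum Δχ₁₊₂ feed
the summary, together with per-reader/pooled TP rates, FP counts per mode
and the both-readers-agree subsets.

Wilcoxon signed rank: zeros dropped by default (Pratt handling available),
average ranks for ties; exact two-sided p by dynamic-programming
enumeration of all 2^m sign assignments for m ≤ 12 non-zero pairs;
otherwise a normal approximation with tie correction, continuity
correction, and an Edgeworth fourth-cumulant refinement (the null is
symmetric but platykurtic; the refinement brings the m = 12 worst-case
discrepancy from ~0.014 to ~0.001). Paired t is the classical two-sided
test. Two-sided throughout.

## What the synthetic data do and do not show

The simulator reproduces the *mechanisms*: cycle-variable hysteretic
motion, count-limited short frames, interleaved MR timing on a skewed
clock, breath-hold μ-maps at arbitrary states, lesion blur and
emission/attenuation mismatch. It does not attempt anatomical realism
(no cardiac or bowel motion, no sliding interfaces, piecewise-constant
organs, no MR physics, ideal detector), and the clinical effect sizes
(e.g. the reported mean SUV changes of a patient cohort) are properties of
patient data that a phantom cannot and should not reproduce. Passing tests
therefore demonstrate correctness of the machinery and the direction and
mechanism of the clinical effect, not its clinical magnitude.

## Numerical choices and problem sizes

* Grid 128 × 128 at 3 mm, 126 angles, 480 × 0.5-s frames, 200 MR images —
  every validation experiment runs on the full default geometry.
* Warp boundary: linear interpolation, zero fill, partial interpolation at
  the grid edge (`grid-constant`), identical between the dense warp and the
  sparse warp matrices.
* Field inversion: fixed-point iteration (≤30 iterations, 10⁻³ mm
  tolerance).
* OSEM denominators floored at 10⁻³⁰; bins with zero measured counts
  contribute zero ratio.
* The motion-correction effect study uses the generator's own model and
  surrogate ("true model given" mode) to isolate the reconstruction
  machinery, and compares against the noise-free motion-free
  reconstruction — a deterministic reference, so per-seed deviations
  measure the corrected image alone. The μ-map artifact study, in
  contrast, runs the *fully fitted* pipeline end to end, including the
  breath-hold surrogate measurement and model extrapolation.
* Model parameter recovery is asserted on mean/median relative error: with
  0.5-mm noise on 200 images the per-voxel standard error is ≈0.12 mm
  (the information bound), so a max-over-voxels criterion at 5% of a 2-mm
  coefficient would be unattainable by any estimator.

## Known limitations

* The 2D slab collapses sagittal slice geometry to interleave labels;
  through-plane model interpolation is therefore exercised only on
  synthetic coefficient planes.
* The demons registration has no sliding-motion model; errors concentrate
  at the chest wall in realistic anatomy.
* The PET-derived surrogate responds mildly nonlinearly to very large
  deformations, which biases extrapolated states (deep inhale) toward the
  fitted range; the μ-map artifact experiment quantifies the residual.
* PSF modelling in reconstruction uses the same radial blur as the
  simulator but composed with attenuation in a different order; with the
  default (no PSF) the forward models match exactly.
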