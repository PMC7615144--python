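# Methods

`mocosim` is a self-contained, fully synthetic re-creation of a
retrospective rigid-body motion-correction study for 3-D brain MRI: a
digital head phantom is "scanned" by a segmented Cartesian MPRAGE-like
sequence while following prescribed motion scripts, the corrupted
k-space is corrected retrospectively from emulated motion estimates
(high-rate tracker stream, or per-TR fat-navigator registration with and
without a neck mask), and the outcome is quantified with the motion
score and with FSIM / NGS image-quality metrics.  This note records the
models, the parameter choices, and what the synthetic setting does and
does not demonstrate.

## Coordinate frame and pose convention

One scanner frame is used everywhere: `x` runs right-to-left (left
positive), `y` down-to-up (up positive), `z` foot-to-head (head
positive).  Poses are six parameters — rotations in degrees, translations
in mm — and a pose materialises as `R = Rz(θz) · Ry(θy) · Rx(θx)` about
the fixed axes, translation applied after.  The composition order is a
deliberate choice: the closed-form combined-rotation angle used by the
motion score,

    |θ| = arccos(½(−1 + cosθx·cosθy + cosθx·cosθz + cosθy·cosθz
                     + sinθx·sinθy·sinθz)),

is *exact* for this order (we verified agreement with
`arccos((trace(R)−1)/2)` to ~3·10⁻¹¹ degrees over ±170°), whereas for
`Rx·Ry·Rz` the sign of the sin-product term is wrong and the formula
deviates by up to 0.35° at 6° amplitudes.  Both the closed form and the
matrix-trace route are exposed (`combined_rotation_angle`,
`rotation_angle_from_matrix`).

The rotation origin sits at the cranio-cervical junction of the phantom
(the anatomical pivot of nodding), not at the head centre.  This matters
for the neck-confound experiments below.

## Motion score

Per frame-to-frame pose increment: the largest displacement of any point
on a 64 mm-radius sphere under the net rotation, `ΔR = 2r·sin(|θ|/2) =
r·√((1−cos|θ|)² + sin²|θ|)`, plus the Euclidean norm of the translation.
The mean motion score averages this over consecutive samples of a trace;
it is invariant to rebasing (re-expressing all poses relative to a
chosen zero-motion time) because it only sees differentials.

Predicted head rotations follow the small-angle viewing-geometry ratio
`d/L` in radians (dot displacement `d` on a screen at `L` = 76 cm),
which reproduces all the protocol's printed predictions (1.9°, 2.6°,
3.8°, 5.7°) at one decimal; `arctan(d/L)` would round 7.5 cm to 5.6°.

## Head phantom

A sum of signed-intensity ellipsoids: a bright thin scalp-fat shell
(outer minus inner ellipsoid), a brain with six internal contrast
features (ventricles, deep-gray nuclei, cortical foci — enough edges for
the quality metrics to score), and a small, dim neck-fat pad
inferior-posterior to the head, clear of the scalp shell.  Each
ellipsoid is smoothed by an isotropic Gaussian (σ = 2 mm): image-space
rasterisation uses an erf profile along the local surface normal, and
k-space uses the closed-form uniform-ellipsoid spectrum
`ρV·3(sin u − u·cos u)/u³` (with `u = 2π|A·Rᵀk|`) multiplied by the
matching Gaussian factor, so the image and spectral views are mutually
consistent (inverse FFT of the analytic spectrum matches the
rasterisation to ~1% relative RMSE at 64³).

The neck is *non-rigidly coupled*: it translates with the head but
follows only a fraction `neck_coupling` (default 0.3, a free modelling
choice) of the head rotation, applied about the scanner origin.  Its
size and intensity (semi-axes 16/20/14 mm, 0.18 of the scalp intensity)
were chosen so that unmasked navigator registration shows a clear
pitch-estimation bias while the contamination of the other five
parameters stays below the 0.05°/0.05 mm level — the qualitative
signature reported for neck-masked versus unmasked navigator
registration, where only the x-rotation deviates noticeably.  Placing
the rotation origin at the neck attachment keeps the translation leak of
the confound small, as it does physically.

## Motion scenarios

Scripted at full length (338 s scan, TR 2.41 s per readout train) and
scaled *in time* by `scan_duration/338` for desk-scale runs so each
motion phase corrupts the same fraction of k-space:

* **stepwise** — targets up, down, right, left, then the four diagonals,
  35 s per dwell starting at 20 s, returning to centre between targets
  (the centre-return is an assumption; the protocol does not state it);
  2.5 cm (1.9°) or 7.5 cm (5.7°).
* **circular** — constant-deflection cone precession `(θx, θy) =
  A(sin ωt, cos ωt)`, A = 1.9°, at 4 or 6 cycles/min, three 1-min bouts
  (on/off) from 10 s, with 2 s amplitude ramps at bout edges.
* **pitch-wise** — nodding: dip to −A in 2 s, return in 15 s, rest 35 s
  (a 52 s cycle, i.e. 17 s of motion per cycle); A = 1.9/3.8/5.7°.
* **slow diagonal** — 90 s linear ramp along the ±45° diagonal from
  120 s, then hold; 3.5 cm → 2.6°.

Prescribed traces have zero translation (the instruction is a pure
re-orientation); peak rotation is measured as the Euclidean norm of the
angle triple, which equals the prescribed deflection exactly for these
one- and two-axis poses (the composed-rotation angle differs only at
third order).

## Acquisition and forward model

Segmented Cartesian sampling: readout along x, one pe1 (y) line per
train with all pe2 (z) lines, linear or centric pe1 ordering, pose
constant within a train and timestamped at train end.  The k-space value
at Cartesian location `k` for pose `(R, t)` is `e^{−i2πk·t}·F(Rᵀk)`
evaluated with the analytic phantom spectrum (the neck evaluated at its
coupled pose), so forward simulation is exact for any pose — no
interpolation enters until reconstruction.  The signal model is
steady-state single-contrast: inversion/readout relaxation evolution is
not modelled, since the artifact mechanisms under study are purely the
phase/rotation inconsistencies of k-space.

## Retrospective correction and NUFFT

Correction rebases the motion estimate to the acquisition time of the
k-space centre (the standard zero-motion convention), multiplies each
sample by the conjugate phase ramp `e^{+i2πk·t}` and assigns the
effective coordinate `Rᵀk`.  Translation-only motion is therefore
corrected exactly (measured: relative RMSE ~10⁻¹⁶); rotations move
samples off the grid and are reconstructed with a type-1 NUFFT.

The gridder uses a Kaiser–Bessel kernel of width 4 on a 2× oversampled
grid with the Beatty shape parameter; deapodization divides by the DFT
of the integer-sampled kernel, which makes the Cartesian degeneration
exact (measured NUFFT-vs-FFT relative RMSE ~10⁻⁴, asserted < 10⁻³).
Density compensation is a single-pass kernel-convolution estimate
(gridding ones, sampling back, inverting), adequate for the
near-Cartesian sampling produced by small rotations.  An optional
conjugate-gradient least-squares mode solves the forward model's normal
equations in physical units; it noticeably reduces the residual
artifacts of the circular scenario (round-trip FSIM 0.92 → 0.996 at
64³), consistent with the expectation that iterative reconstruction can
compensate local Nyquist violations that single-step gridding cannot.
The *default* arm is the single-step adjoint, matching the
reconstruction style whose limitations the study characterises.

The fraction of corrected coordinates leaving the Nyquist cube (the
"pie-slice" bookkeeping) is reported per correction and grows
monotonically with rotation amplitude.

## Tracking emulation

* **Tracker stream** (~30 Hz): the true trace linearly interpolated to
  the device rate plus white noise (σ = 0.05°/0.05 mm), band-limited
  5–10 Hz rotational jitter (σ = 0.1°) and optional slow sinusoidal
  drift; magnitudes are free parameters of the noise model.  Estimates
  are low-pass filtered at 1 Hz with a zero-phase 4th-order Butterworth
  (applied forward-backward) before use; the filter family is a free
  choice, the cutoff is the study's.
* **Navigators**: one low-resolution fat-only volume per TR (scalp shell
  at the head pose, neck at its coupled pose), rasterised analytically
  at the transformed pose — no resampling chain, so registration tests
  are free of simulation-side interpolation artifacts.  The rendered
  edge width is floored at 0.7 navigator voxels; sharper edges alias on
  the coarse grid and measurably bias sub-voxel registration (this floor
  reduced a rigid-recovery bias from ~1° to ~0.01°).

## Navigator registration

Weighted-MSE rigid registration over a two-level multi-resolution
schedule: Gaussian pre-smoothing (FWHM 1 voxel), trilinear resampling at
the coarse level and cubic spline at the fine level, optimised by
trust-region least squares with fixed-step (0.01°/0.01 mm) forward
differences.  Three numerical details proved load-bearing and are part
of the design: volumes are zero-padded by 4 voxels so boundary handling
cannot inject cost discontinuities; finite-difference steps are absolute
(relative steps degenerate near zero parameters); and near-zero warm
starts are snapped to exactly zero because the optimiser sizes its
initial trust region by |x₀|.  Convergence: relative tolerance 10⁻⁶ or
100 iterations; non-convergence is flagged, not raised.  Series
estimation registers every navigator to the first, warm-starting from
the previous frame.

The geometric neck mask keeps the scalp-fat support dilated by one
voxel, zeroes the neck support dilated by ~6 mm (covering where the
non-rigidly moving neck can appear) and everything below an axial cut
just under the scalp shell, with a smooth one-voxel transition.  It is
constructed directly in phantom space; propagating a manually drawn
standard-space mask through inter-subject registration would only
exercise third-party tooling on synthetic data.

## Image quality assessment

All volume scores are means of per-slice 2-D metrics over the 30 central
axial slices; each slice is min-max normalised to [0, 1] and, for FSIM,
rescaled to [0, 255].  FSIM combines phase-congruency similarity
(stability constant T1 = 0.85) and gradient-magnitude similarity
(T2 = 160, Scharr operator by default), weighted by the maximum phase
congruency.  Phase congruency is the standard multi-scale log-Gabor
construction (4 scales from wavelength 6 px, multiplier 2, σ_onf = 0.55;
4 orientations), with Rayleigh-statistics noise-floor subtraction and a
frequency-spread weighting; images are affinely pre-normalised so the
contrast invariance of the construction is exact.  No numeric equality
with any external FSIM implementation is claimed — identity, symmetry,
boundedness and degradation monotonicity are the guaranteed properties,
and cross-condition comparisons are directional.

NGS (normalized gradient squared) is `Σ_p (g_p/Σ_q g_q)²` per normalised
slice (0 for a constant slice).  Background analysis: per-slice
foreground = the 2-px-dilated convex hull of pixels above 10% of the
slice maximum; background power = Σ background²/Σ total² over the
central slices; background-masked scores zero the background of both
images before scoring.

**Pose-matched still reference.** Rebasing places a corrected
reconstruction at the pose held when the k-space centre was acquired.
Each arm is therefore scored against the FFT reconstruction of a
motion-free acquisition simulated at that arm's reference pose: the
comparison then measures artifact content, not the arbitrary global
transform implied by the rebasing convention (a 1.9° global offset alone
costs ~0.02 FSIM at 64³), and it keeps reconstruction blur common to
both images.  This also makes the scores invariant (within 0.005 FSIM)
to the choice of rebasing time, as the rebasing argument predicts.

## Statistics

Wilcoxon signed-rank (two-sided) for paired quality comparisons: zero
differences discarded, average ranks for ties, `W = min(T+, T−)`; the
null is enumerated exactly over all 2ⁿ sign patterns for n ≤ 15 (the
enumeration, unlike library exact modes, also handles rank ties) and
normally approximated above.  The test refuses fewer than six pairs, the
study's own minimum.  Pearson correlation uses the two-sided t-test with
n − 2 degrees of freedom.

## Problem sizes and defaults

Desk-scale experiments use a 64³ matrix over a 200 mm field of view, 64
readout trains of TR 2.41 s (154 s scan; scenario timings scaled by
154.24/338), navigators at 40³ (5 mm, near the 4 mm navigator resolution
of practice), and the single-step adjoint NUFFT.  Cohort analyses run 48³
across eight seeds.  These sizes keep a full experiment to a few minutes
while preserving every mechanism under study: rotation amplitudes are at
protocol scale, and the fraction of k-space each motion phase corrupts
matches the full-length design.

## What the synthetic study does and does not show

The generator reproduces the *mechanisms* — phase/rotation k-space
inconsistency, sampling-density violations under rotation, the non-rigid
neck confound, tracker noise — but not scanner physics: no coil
sensitivities or parallel-imaging reconstruction, no relaxation-weighted
contrast evolution, no B0/chemical-shift effects, no point-cloud-level
tracker geometry, and rigid single-body brain motion only.  Passing
tests therefore demonstrate the correctness and the qualitative
behaviour of the correction and evaluation pipeline (direction and
ordering of effects: correction helps; circular motion is hardest;
masking fixes pitch; background ghosts depress FSIM), not quantitative
agreement with any particular in-vivo dataset.  Figure-level per-subject
metric values from real scans are out of reach by construction and are
not matched numerically.
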