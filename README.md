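# mocosim

A fully synthetic study of **retrospective rigid-body motion correction
for 3-D brain MRI**.  The package simulates segmented Cartesian
MPRAGE-like k-space acquisition of a digital head phantom while the
"subject" performs scripted head motion (stepwise re-orientations,
circular dot-following, nodding, slow diagonal drift), corrects the
corrupted data retrospectively from emulated motion estimates — a noisy
~30 Hz markerless tracker stream and per-TR fat-navigator registration,
with and without a neck-exclusion mask — and quantifies the outcome with
a motion score and FSIM / NGS image-quality metrics.

It is aimed at people developing or evaluating motion-correction and
image-quality-assessment pipelines who want a controlled, ground-truthed
testbed: every stage that matters in the real problem is present
(Fourier shift/rotation correction, NUFFT reconstruction of rotated
sampling, rigid registration with spatial weighting, per-slice metric
protocols, paired nonparametric statistics), but the data are generated
by code, so every estimate can be compared against the exact truth.

## The models in brief

**Motion score.** For a frame-to-frame pose increment with rotations
(θx, θy, θz) and translations (Δx, Δy, Δz),

    score = ΔR + sqrt(Δx² + Δy² + Δz²),   ΔR = 64·sqrt((1−cos|θ|)² + sin²|θ|)

where |θ| = arccos(½(−1 + cosθx·cosθy + cosθx·cosθz + cosθy·cosθz +
sinθx·sinθy·sinθz)) is the combined rotation angle and 64 mm is the
radius of the scoring sphere.  Poses compose as `R = Rz·Ry·Rx` about
fixed scanner axes, the order for which this closed form is exact.

**Forward model and correction.**  With the head at pose (R, t) during a
readout train, the sampled value at Cartesian k-space location k is
`exp(−i2πk·t)·F(Rᵀk)`, with F the phantom's closed-form ellipsoid
spectrum.  Retrospective correction rebases the motion estimate to the
k-space-centre acquisition time, applies the conjugate phase ramp, and
re-grids the rotated coordinates with a Kaiser–Bessel NUFFT (adjoint
with density compensation, or CG least squares).

**Quality metrics.**  FSIM (phase-congruency × gradient similarity,
in [0, 1], 1 iff identical) and NGS (normalized gradient squared
sharpness), both computed per axial slice after min–max normalisation
and averaged over the 30 central slices, plus background ghost power
from dilated-convex-hull masks, Wilcoxon signed-rank and Pearson
statistics.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```python
from mocosim.pipeline import ExperimentConfig, run_experiment

cfg = ExperimentConfig(scenario="stepwise-small",
                       arms=("moco_off", "true_trace", "tcl"), seed=0)
manifest = run_experiment(cfg, "results/experiments/stepwise-small")
for arm, rep in manifest.reports["arms"].items():
    print(arm, round(rep["fsim"], 4))
```

prints

```
moco_off 0.9353
true_trace 0.9841
tcl 0.9839
```

The uncorrected reconstruction of the small-stepwise scan (±1.9° head
re-orientations every scaled 16 s dwell) scores FSIM 0.935 against the
motion-free reference; correcting with the true motion restores 0.984,
and correcting with the 1 Hz-filtered noisy tracker estimate performs
essentially as well (0.984).  Running the same experiment across the
scenario panel (`analysis/03_correction_arms.py`) reproduces the study's
qualitative hierarchy: large-stepwise motion is corrected from 0.800 to
0.964, the slow diagonal from 0.992 to 0.996, while circular motion
barely improves (0.902 → 0.905) — the continuously rotating sampling
leaves local Nyquist violations that the single-step NUFFT cannot
compensate.

The numbered scripts under `analysis/` walk through the full study:

1. `01_motion_scenarios.py` — scenario traces, predicted deflections and
   expected motion scores;
2. `02_tracking_and_masking.py` — tracker filtering RMSE and the
   navigator neck-masking benefit (pitch error 0.058° → 0.007° RMSE with
   all other parameters unchanged);
3. `03_correction_arms.py` — FSIM/NGS across scenarios and arms;
4. `04_background_ghosting.py` — background ghost power vs. the FSIM
   gain from background masking (r = 0.94 in the default sweep);
5. `05_cohort_statistics.py` — eight-seed cohorts with exact Wilcoxon
   signed-rank tests.

Each writes its tables under `results/`.

## Command line

A thin CLI mirrors the library stages:

```bash
mocosim synthgen --scenario stepwise-small --out out/
mocosim acquire --scenario circular-6 --out out/kspace.npz
mocosim recon --input out/kspace.npz --trace out/kspace.trace.csv \
              --method moco-nufft --out out/corrected.nii.gz
mocosim score --test out/corrected.nii.gz --ref out/reference.nii.gz --out out/report.json
mocosim run --scenario pitch-large --arms moco_off,true_trace --out out/run
mocosim cohort --scenario stepwise-small --out out/cohort
```
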