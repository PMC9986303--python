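# Methods

This note records the models, conventions and design choices behind
`ovigait`, in the spirit of a statistical-methods appendix: what each stage
assumes, which knobs matter, and what the synthetic data do and do not
establish about real recordings.

## Coordinates, units and data model

All marker data live in the capture volume's global coordinate system:
z vertical (up), y progression (forward), x lateral with positive x to the
animal's right. The convention is stored once per `Trial`
(`AxesConvention`) and read from there everywhere downstream. Marker
positions are millimetres internally; derived outcomes are converted to
reporting units (s, cm, m/s, degrees) only when written into the long-format
`StudyTable` (one row per animal x session x limb x measure, units
attached). Frames are 0-based; time = frame / sample rate (200 Hz default).

The 42-landmark set comprises 4 axial markers (HEAD, T1, T13, L7,
unsuffixed) and per-limb chains tagged `_FL_`/`_HL_` plus `_L`/`_R`
(e.g. `DPHAL_FL_L`, the left fore hoof). The native file format is a
human-diffable TSV (header `frame time <LABEL>_x ...`, blank = occluded);
C3D is available behind an optional dependency.

## Trajectory conditioning

Occlusion gaps up to `max_gap` (default 20 frames = 0.1 s; longer gaps are
reported and the trial flagged) are filled by cubic-spline interpolation
through the flanking visible frames, or — for periodic limb markers — by a
"cyclic" fill: the displacement pattern of the same gait-cycle phase one
period away (period from autocorrelation, or a donor marker), linearly
offset-matched at the gap edges so the fill joins the flanking samples
exactly. The cyclic rule is our own concrete definition of a procedure
that commercial pipelines implement opaquely; it is exact on periodic
signals by construction and is tested against analytic sinusoids.

Low-pass filtering is a 4th-order Butterworth at 10 Hz applied
forward-backward (zero net phase). The quoted cutoff is the single-pass
−3 dB point, matching common biomechanics practice; the combined response
is its square, i.e. `|H(f)|^2 = 1/(1 + (f/10)^8)`, which passes 1 Hz within
10⁻⁸ and attenuates 50 Hz to ~2.6 × 10⁻⁶. Endpoints use odd (anti-symmetric)
reflection of length 3 x order, the reflective variant that preserves the
dominant linear walking trend at trial edges. Velocities are central
differences (one-sided at the ends), reported in m/s.

## Gait events and cycle extraction

Following the velocity-threshold school of event detection, stance is the
set of frames where the hoof (distal phalange) marker's sagittal-plane
speed is below 0.05 m/s — the threshold originally proposed for this
method — and swing is the complement. The lateral component is excluded on
purpose: only vertical and progression motion distinguish loading from
advance. Runs shorter than `min_phase_duration` (default 0.1 s) are merged
into the longer adjacent phase to suppress threshold chatter. A cycle runs
foot-strike to next foot-strike (stance first), and one cycle per limb per
trial is analysed: the one whose mid-cycle hoof position is nearest the
capture-volume centre, where lens distortion and edge effects are smallest
(ties go to the earlier cycle).

## Kinematic outcomes

Global measures are whole-trial means: T1 progression velocity and the
vertical (and, for the head, lateral) offsets HEAD−T1, T1−T13, T13−L7.

Joint angles are planar: both defining vectors are projected onto the
sagittal plane; the angle is the signed rotation from proximal to distal
vector, 0° when the limb is straight and negative in flexion (the
convention that makes the stifle walk in the −80…−35° range, matching how
these joints are reported). Four-marker joints use the first→second marker
pair as the proximal vector and third→fourth as the distal. Frames where a
projected vector is shorter than 1 mm are flagged missing and excluded from
summaries. Per-cycle limb measures are: stance/swing/stride durations and
their ratios (frame arithmetic, so stance/stride + swing/stride = 1
exactly); stride length (hoof progression displacement strike to strike);
hoof height range and lateral deviation over swing; mean absolute
progression and vertical hoof velocity over swing; mean ground-plane
distance between the limb pair's hooves during double stance; and
min/max/range of each joint angle restricted to stance and to swing.
Where the underlying protocol names a measure without defining it, the
definitions above are fixed choices: lateral deviation is swing-only, swing
velocities are means (not peaks; both are computable from the angle and
velocity series). Session-level values are means over a session's trials.

## Neurological score

The rubric is encoded criterion by criterion: demeanour (0–3), five
behaviour criteria (food debris, torticollis, limb flexion, ataxia 0–3,
circling 0–2), three postural-reaction criteria scored per body side
(hemi-standing 0–4 per side with 0.25 knuckling modifiers per limb;
forelimb hopping 0–2 per side with one knuckling slot; lateral dragging
0–2 *per limb* with partial-correction and drag modifiers), and
wheelbarrowing (0–2). Lateral dragging is read as per-limb because that is
the only reading consistent with a per-side postural subscore substantially
above the other criteria's maxima. The maximum total is computed from the
rubric — 36.5 — while the source protocol's prose quotes 36; the
half-point discrepancy is deliberately surfaced
(`rubric_max_total()`) rather than resolved by fiat, and no code or test
hard-codes 36. Score sheets are tidy CSV rows
(`animal,session,criterion,component,value`) so base scores and modifiers
stay separable; validation rejects off-grid (non-0.25-step), out-of-range
and missing entries with per-field messages.

## Statistics

**Percentiles.** Medians and IQRs use the convention of the study field's
dominant statistics package: with h = n·p/100, the average of order
statistics h and h+1 when h is integral, else order statistic ⌈h⌉. A
linear-interpolation variant is provided for comparison. The bundled
20-animal reference table reproduces its published infarct-volume summary
(2.7, IQR 1.4–11.9 cm³) under this convention exactly.

**ICC.** Repeatability across the three baseline sessions is ICC(A,k):
absolute agreement of the mean of k = 3 ratings in a two-way model,
computed from the ANOVA mean squares,
`(MSR − MSE) / (MSR + (MSC − MSE)/n)`. Parametric CIs use the F-based
single-rating bounds with Satterthwaite degrees of freedom, stepped up by
Spearman–Brown; bootstrap CIs resample subjects with replacement
(percentile method, 2000 resamples by default, seed required). The
implementation is tested for exact agreement with a brute-force
sums-of-squares oracle and against an independent implementation.

**Velocity adjustment.** A measure is adjusted by regressing it on the
trial-global walking velocity (one slope across all cells in the analysis
set) and keeping residual + grand mean. Constant velocity leaves the
measure unadjusted with a warning.

**Pre/post mixed models.** The pre value is the mean of the baseline
sessions per animal and limb. The model is value ~ time + side +
time x side (+ velocity), with a random intercept per animal, fit by REML
(statsmodels MixedLM). p-values and CIs use the normal approximation — a
single documented choice; with 24 animals the difference from
degrees-of-freedom corrections is small. Per-limb post-minus-pre contrasts
are linear combinations of the fixed effects. A group variant replaces the
time term with a two-level between-animal factor (sex, infarct-size class)
on the collapsed data. Singular fits report zero animal variance with a
warning rather than failing.

**PCA.** Variables first lose one member of every pair with |r| > 0.85
(the member with the larger mean absolute correlation to the others; ties
drop the later column; all removals logged). KMO sampling adequacy is then
screened iteratively: drop the worst variable below 0.5, recompute, repeat
(each step logged). Bartlett's test is
χ² = −(n − 1 − (2p+5)/6)·ln det R with p(p−1)/2 degrees of freedom. The
PCA itself is an eigendecomposition of the correlation matrix; loadings are
unit-norm eigenvectors with PC1's sign anchored so a designated variable
(total neuroscore by default) loads positively; percent variance is
eigenvalue/p × 100 and components with eigenvalue > 1 are retained. KMO of
an identity correlation matrix is defined as 0 (no common variance). No
factor rotation is applied, and no multiple-testing correction is applied
anywhere, matching the analysis the package reimplements.

## Synthetic data: what it emulates and what it does not

The generator produces walking passes of an idealized quadruped: trunk
markers advance at the designed velocity with a small two-per-cycle
vertical oscillation; each hoof is *exactly* stationary in stance and
advances one stride per cycle in swing; limb chains are built
distal-to-proximal from designed per-joint angle waveforms (per-phase
min/max with smooth easing); limb phasing is a lateral-sequence walk
(LH 0, LF 0.25, RH 0.5, RF 0.75). Defaults encode the healthy study
baseline: 1.28 m/s, 0.77 s cycles, 0.41 s forelimb / 0.43 s hindlimb
stance (stride ≈ 0.99 m), head ~3 cm right of T1, stifle −69/−45° in
stance and −81/−35° in swing. A named post-stroke preset injects the day-3
deficit point estimates (velocity −0.28 m/s, head −8.21 cm, stance
+0.13/+0.14/+0.13/+0.12 s for left/right fore/hind, swing +0.02/+0.03 s,
fetlock swing range −3.9/−3.31/−8.34/−8.19°). Limbs must share one cycle
duration to stay phase-locked, so per-limb duration deltas are folded into
per-limb duty factors around the mean cycle.

Two constructions make the generator's ground truth *exact through the
conditioning filter* rather than merely approximate:

1. **Contact speed.** The swing velocity profile is
   v_b + (V − v_b)·sin²(πτ): a small instantaneous lift-off/touch-down
   speed v_b (default 0.10 m/s, twice the detection threshold) plus a
   band-limited advance. A zero-phase filter halves a velocity step at the
   step instant, so the filtered sagittal speed crosses the 0.05 m/s
   threshold at the true phase boundary, and detected stance/stride match
   the design to within one frame.
2. **Filter-calibrated chains.** Joint waveforms are band-limited to the
   harmonics the filter passes; each chain level's angle series is then
   pre-distorted against the filter's exact periodic response, and the
   band-limited designs are nudged (Gaussian bumps at the extreme
   locations) until the *realized* filtered joint-angle extremes equal the
   designed values. This converges below 0.05° for any waveform whose
   phase-boundary value lies within both phases' ranges — true of
   physiological joints — up to roughly 90° per-phase excursions; a 10 Hz
   filter cannot, even in principle, transmit arbitrarily fast excursions,
   which bounds the contract's validity domain.

Noise models white marker jitter, sinusoidal skin-motion artifact, and
geometric occlusion gaps; identical seeds give bit-identical trials.
Cohorts draw per-animal random effects once (shared across that animal's
sessions) and simulate at two levels: a fast measure-level mode (designed
parameters plus between-animal and trial-residual dispersion, averaged to
session level exactly as the pipeline averages reconstructed trials) used
for the statistics-layer studies, and a full marker-level mode rendering
every trial. Between-animal dispersion defaults are free parameters of the
simulator — the source study does not decompose its inter-trial
variability — and are set to plausible values for a habituated flock.
Neuroscore sheets are generated against the rubric (near-zero baselines
with occasional postural quarter-points; a left-dominant post-stroke
deficit totalling ~7 points above baseline); infarct volumes are
log-normal around a 2.7 cm³ median.

What passing tests on these data show: the pipeline's event detection,
angle computation and statistics recover known truth under the stated
capture conditions, including injected deficits and asymmetries. What they
do not show: robustness to real-world soft-tissue artifact spectra,
label swaps, non-straight walking, camera dropouts longer than the gap
limit, or behavioural variability — none of which the generator attempts
to model faithfully.

## Numerical and procedural choices

- Cycle extraction ties break toward the earlier cycle; debouncing absorbs
  the shorter run into the longer neighbour.
- Trials whose T1 lateral range exceeds 0.5 m (half the run width) are
  excluded by the pipeline's straight-line-walking guard (logged,
  configurable).
- `filtfilt` padding: odd reflection, padlen = 3·order.
- The ICC bootstrap enforces CI ⊇ point estimate (percentile CIs on small
  n can otherwise exclude it by a hair).
- Mixed-model fits swallow convergence warnings and report singular
  random-effect fits as zero variance with a warning.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); study runs are deterministic given their
  config, and every output file carries the config hash.
- Problem sizes in the test suite and acceptance script (6-cycle trials,
  24-animal cohorts, 20 replicates, 200 ICC simulations) were chosen as
  the smallest sizes at which the checked statistical properties are
  stable.

## Known limitations

- 2D planar angles only; no anatomical-frame 3D rotations.
- The generator's chains are kinematic, not dynamic: no forces, no mass.
- The bundled 20-animal reference table is printed to 2 decimal places;
  analyses computed from it inherit that rounding, and its PCA summary
  differs from the one computable from the printed values for the fetlock
  variable (a documented labelling ambiguity in the source tables —
  "minimum fetlock in swing" in the data table versus "minimum fetlock
  stance" in the loadings table). The package reports what the printed
  data yield.
- C3D support requires the optional `ezc3d` dependency.
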