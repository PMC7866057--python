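# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `tugkit`, in the order the pipeline runs them.

## Kalman velocity estimation

Range-only tracking uses the standard discrete constant-acceleration
model: state `x = (p, v, a)`, transition `p += v·Ts + ½a·Ts²`,
`v += a·Ts`, `a` persistent, with a scalar position measurement.
Defaults: update interval `Ts = 0.2 s` (a 5 Hz radar frame rate),
measurement variance `R = 0.04 m²` (≈ 0.2 m ranging noise, conservative
for a radar specified at ±10 cm), process noise
`Q = diag(0.04, 0.01, 0.01)` held constant.  The filter is initialised at
the first measurement with zero velocity/acceleration and covariance
`P0 = Q + R·I`.  The `R·I` floor matters in the degenerate `Q = 0` limit:
with `P0 = Q = 0` the gain is identically zero and the filter can never
leave its initial state, whereas with the floor it behaves like recursive
least squares and converges to an exactly linear input, which is the
behaviour a zero-process-noise filter should have.  The covariance update
uses the Joseph form plus explicit re-symmetrisation so it stays symmetric
positive semi-definite over arbitrarily long runs.

No accelerometer-bias state is modelled: the radar measures range
directly, and a bias term would be unidentifiable from range alone.

## Radar segmentation

Walking onset is the first sample at which the filtered `|v|` reaches
`V_thres = 0.4 m/s` — a threshold low enough to catch slow, impaired
gait but above postural-sway velocities.  At least 3 s of data
(`onset_window_s`) must exist before any verdict; if the threshold is
never reached within `quasi_static_timeout_s = 30 s` the trace is
declared quasi-static.  The onset window is a buffering requirement, not
an exclusion: motion inside the first 3 s still counts once the buffer is
full.

The transition points are range-threshold crossings evaluated on the
measured range (the Kalman filter serves velocity estimation only —
thresholding the filtered position would add detector lag of roughly one
frame per crossing):

* `T0`: first point with `D > D_pos` inside the 3 s look-back from onset;
* `T1`: first point at/after `T0` with `D ≥ D_pos + d_qs`;
* `T2`: first point with `D ≥ D_pos + walk_distance`;
* `T3`: last point of the turn plateau, i.e. of the contiguous run with
  `D ≥ D_pos + walk_distance − ε`, `ε = 0.1 m` (one range cell);
* `T4`: first point after `T3` with `D ≤ D_pos + d_qs`;
* `T5`: first point after `T4` with `D ≤ D_pos` — the exact mirror of the
  `T0` rule.  A sustained-low-velocity rule for `T5` was considered and
  rejected: stand-to-sit range rates (`d_qs` over ~1.5 s ≈ 0.2–0.3 m/s)
  sit *below* the walking threshold, so a velocity clock would collapse
  `T5` onto `T4`.

Two robustness devices, both inert on noise-free data:

* **Majority debouncing.** A crossing qualifies only if its sample and at
  least `n−1` of the next `n` samples (default `n = 2`, i.e. 2-of-3)
  satisfy the threshold.  A single-sample noise spike can never trigger a
  transition, but an isolated dropout inside a genuine crossing does not
  postpone detection the way a strict consecutive-run test would.
* **Half-cell slack at T2/T4.**  At those two points the subject reaches
  the threshold range and then hovers at it (turn plateau, pause at the
  chair), so "becomes equal to" is tested with `ε/2 = 0.05 m` of slack;
  `T0`, `T1` and `T5` are transversal crossings and stay exact.

`d_qs` (default 0.3 m) is treated as a known geometric constant of the
test layout, not estimated from data.  Degenerate inputs raise typed
errors: a trace that never reaches `D_pos + walk_distance − ε/2` is an
incomplete trial; a quasi-static trace has no events.

Resampling between the radar and insole clocks uses a cubic spline and
refuses extrapolation; transition points are always located on the
original samples, never on interpolated ones.

## Insole stride detection

Preprocessing: the y-axis (anteroposterior) acceleration is z-scored with
the population SD (divide by N — fixed convention so results are exactly
reproducible), then median filtered (5 samples, kills single-sample
spikes) and low-pass filtered with a zero-phase 4th-order Butterworth.
The cutoff default is **6 Hz**: stride rates near 0.9 Hz put the
heel-strike transient's energy around 3–6 Hz, and a lower cutoff (3 Hz
was tried) attenuates the heel-strike peaks four- to five-fold relative
to the broad mid-stride bump, destroying both peak amplitude ordering and
peak timing.  Zero-phase filtering (`filtfilt`) preserves event times.

The locking period `lockP` is the mean interval between consecutive
sign changes of the filtered signal.  With two zero crossings per step
(four per stride) this averages a quarter of the stride time; it serves
as the flank-search window size and as the minimum admissible inter-peak
gap.  Exact zeros inherit the preceding sign so flat samples cannot
manufacture crossings.

Peak validation runs on all local maxima:

1. **Flank drops.**  Within a `lockP`-sized window centred on each
   candidate, `PL` = peak minus the minimum before (toe-off side) and
   `PR` = peak minus the minimum after (heel-strike side).
2. **Shape similarity.**  A candidate is kept only if
   `min(PL, PR) ≥ 0.35 × max over candidates of min(PL, PR)`.  This is a
   relative criterion — no absolute amplitude threshold — and separates
   heel-strike peaks (flank ratios near 1, turn strides near 0.6) from
   contralateral-step bumps and noise maxima (ratios ≤ ~0.25).  An
   optional absolute gate (`peak_threshold_frac`, fraction of the signal
   maximum) exists but is off by default.
3. **Gap rule.**  Scanning left to right over the surviving peaks, a peak
   closer than `lockP` to the previously retained one is invalidated (the
   *later* of the pair is dropped, which keeps a lone leading peak
   meaningful); a gap beyond `Max_time = 2.5 s` marks a new walking bout
   and the peak is retained as its first stride boundary.

Strides = valid peaks − 1; stride `i` spans valid peak `i` to `i+1`.
Validation is idempotent: every retained gap already respects the rule,
so re-screening changes nothing.

Force-side checks use the summed FSR channels scaled to unit maximum
(channel subsets support the 4→3→2 sensor-reduction configurations).
Stance/swing cycles are counted with hysteresis (high 0.6 / low 0.2 of
the normalized maximum — the gap prevents chatter); one completed
stance→swing→stance cycle corresponds to one stride of the instrumented
foot.  Sit-to-stand is the first loading ramp from the initial low-force
plateau to first attainment of the standing level and stand-to-sit the
final unloading ramp, located at the 5%/95% levels of the
plateau-to-standing span on a 0.3 s moving-average smoothed signal; the
stand-to-sit search runs from the end of the recording backwards so the
per-stride swing dips can never masquerade as sitting down.  `stance_onsets`
returns the swing→stance transition times, giving a force-only stride-time
series for cross-checking the acceleration-based one.

Cadence is reported in steps/min as `60 × steps-per-stride / ST` with two
steps per stride by default (configurable for pathological gait).

## Stride length and calibration

The three estimators read the **raw** acceleration window (the z-scored
copy would destroy the amplitude information they need).  `K1 = 0.98` is
fixed; `K2 = K` and `K3 = 2K` are linked to the single calibration
coefficient `K` (default 0.9763).  `calibrate_k` is the mean ratio of
estimated to reference distances; `refine_constants` divides the current
`K` by that ratio so the calibrated Weinberg estimates are unbiased on
the calibration set.  Estimation is per stride window (not per walking
bout).  The Scarlett estimator raises on a constant window (zero
amplitude range); its output is otherwise confined to `(0, K3)`.

## ROFA scoring

Baselines pool all strides of all baseline trials per parameter, with the
sample SD (ddof = 1 — baseline stride counts are small).  A parameter
with zero pooled variance is flagged with a warning and excluded rather
than producing infinite ratios.  Scoring is per stride by default: each
stride's deviation score is computed and stride scores are averaged per
parameter before the equal-weight combination; a `per_stride=False`
switch scores the trial-mean parameter instead.  `S_k` is clamped at 0 so
the composite stays in `[0, 100]` for arbitrary deviations.  Band edges
are half-open at 25/50/75 with 100 as a singleton "very low" — a
continuous score between the printed integer ranges has to land
somewhere, and the ceiling is reserved for gait exactly at baseline.
The default scored set is {stride length, stride time, cadence, stride
speed} with equal weights; custom weights are accepted but must be convex.

## Paired comparison

The Wilcoxon signed-rank implementation discards zero differences
(classical two-sided default), mid-ranks ties, enumerates all `2^n` sign
assignments of the realized ranks for `n ≤ 15` (so tied ranks are handled
exactly), and otherwise uses the normal approximation with continuity and
tie corrections.  The two-sided p sums both tails at the observed rank
sums.  Significance is reported at 0.05 but never gates any computation.

## The synthetic-data generator

The generator emulates the 3 m TUG layout with the radar 0.5 m behind the
chair and defaults chosen for a healthy adult at comfortable pace:
1.3 ± 0.05 m strides of 1.1 ± 0.04 s (≈ 1.2 m/s), 1.5 s chair transfers,
a 2 s turn, a 0.7 s standing pause before sitting down, 5 Hz radar and
100 Hz insole.  Noise defaults: 0.03 m radar jitter (white plus a
band-limited body-sway component at half that amplitude), 0.05 g
accelerometer noise, 0.02 force noise.  The seated range sits 0.1 m
behind `D_pos` (the torso is behind the chair's reference plane), and the
subject steps a few cm past the walkway end while turning, so the turn
plateau stays at or beyond `D_pos + 3 m`.

Within a stride the radar range advances as
`u − β·sin(2πu)/2π` (`β = 0.7`), i.e. forward speed oscillates between
0.3× and 1.7× its mean without ever stopping; per-stride radar
displacement equals the stride length exactly.  Stride lengths are drawn
per direction and rescaled to sum exactly to
`walk_distance − d_qs`.

The acceleration waveform is a per-stride monotone-spline (PCHIP)
template with a dominant heel-strike peak at each stride boundary,
a toe-off minimum after it, a deeper pre-heel-strike minimum before the
next peak (so `PL ≠ PR` generically), and a small positive
contralateral-step bump mid-stride — four sign changes per stride, two
per step.  Template amplitude scales as `(SL/1.3)^4` for walking strides,
which makes the Weinberg estimator exact at the reference calibration;
the turn stride is decoupled (0.6× amplitude) because turning mechanics
do not follow the straight-walking amplitude law.  A slow turn stride
keeps walking-timescale transients — it is modelled as a pause between
near-normal steps, not a uniformly stretched gait cycle.  Gait initiation
and termination transients give the first and last heel-strike peaks the
same local context as interior ones, so filtering shifts every peak
identically and stride times are unbiased at the boundaries.

The force profile is piecewise linear: 0.25 of maximum while seated
(feet partially loaded), a linear loading ramp during sit-to-stand,
stance at 1.0 / swing at 0.05 during walking with the loading ramp
centred exactly on each heel strike (so force-derived and
acceleration-derived stride times measure the same events), and a linear
unloading ramp during stand-to-sit.  The total splits 0.45/0.25/0.30
across heel-medial, heel-lateral and metatarsal channels.

Ground-truth `t0…t5` are the *analytic threshold-crossing times* of the
noise-free trajectory under the segmenter's own geometric definitions —
the honest reference for an event detector defined by those thresholds —
while the motion-phase start/end times are stored separately in
`motion_phases`.

**What passing tests do and do not show.**  The generator reproduces the
geometry, event structure, quasi-periodicity and noise scales of the
paired recordings, so tests demonstrate that the algorithms recover what
the signal model encodes.  It does not model: radar multipath or body-part
ambiguity (the range is a clean line-of-sight scalar), soft-tissue and
footwear artefacts in the accelerometer, inter-subject waveform
variability, FSR drift and saturation, or pathological gait beyond a
slow-gait parameter knob.  Performance numbers on simulated trials
therefore bound what clean data allow; they do not certify clinical
accuracy.

## Problem sizes

The test suite and acceptance checks run on: 100-seed noise-free and
100-seed noisy (σ_radar = 0.05 m, a_y noise 15% of the heel-strike
amplitude) segmentation sweeps; 50-trial sensor-reduction comparison
(per-trial mean stride times; "agreement" means within one insole sample,
10 ms); 10 + 10 trials for calibration/held-out recovery; 100 seeds × 100
samples for the filter-vs-finite-difference benchmark; full `2^n` sign
enumeration up to `n = 10` against the Wilcoxon oracle.  A single trial
is ~17 s of simulated wall time (~85 radar and ~1700 insole samples), so
the whole suite runs in well under a minute.

## Known limitations

* `T0` depends on a look-back from the velocity onset; a subject who
  creeps forward at just under `V_thres` before walking would shift it.
* The radar-side stride metrics use insole-derived stride intervals;
  there is no radar-only stride detector.
* The exact Wilcoxon enumeration is `O(2^n)` and capped at `n = 15`;
  beyond that the corrected normal approximation is used.
* Turn-stride "length" is ill-defined for a rotation in place; the radar
  and insole deliberately disagree there, which callers must keep in mind
  when aggregating stride lengths across the whole trial.
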