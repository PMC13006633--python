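# Methods notes

This document records the modeling assumptions, parameter choices and
numerical conventions behind `gazebeta`, and what the synthetic-data
validation does and does not establish.

## Stimulus kinematics

Target motion is ideal projectile motion in screen centimetres:
`x(t) = x₀ + v cosθ·t`, `y(t) = y₀ + v sinθ·t − ½gt²`, with
g = 9.81 cm/s², no drag. The three conditions' speed/angle pairs
(23.28 cm/s @ 75.96°, 23.33 @ 75.45°, 23.39 @ 74.93°) all give a 4.60 s
flight back to launch height and landing offsets of 26.0 / 27.0 / 28.0 cm.
Speeds are interpreted as **cm/s**: only under that reading do the apex and
landing coordinates follow from the printed angles with g in cm/s². The
closed form is cross-checked in tests against an explicit-Euler integrator
at dt = 1e-5 s (agreement < 1e-3 cm).

The occlusion boundary t = 2.3 s belongs to the *visible* phase (strict
inequality), so the visible-phase analysis window [0, 2.3 s] is closed and
matches the 0–2300 ms EEG window.

Pixel↔degree conversion is linear per axis using the full-screen angular
extents (35.66°/1280 px horizontally, 28.86°/1024 px vertically). The two
factors differ by ~1%, so conversions are never collapsed to a shared
scalar. A per-pixel tangent mapping would differ only far below measurement
noise at these eccentricities. The cm↔pixel mapping hangs off a configurable
*anchor* — the pixel position of the launch point, default (165, 900) —
which places the occlusion-onset crossing near x ≈ 612 px and the landing
points around x ≈ 1030–1090 px on the 1280×1024 display; the display y axis
points down.

## Behavioral metrics

* Gaze at the button press is the **latest sample at or before** the press
  time, not an interpolation: at 50 Hz, sub-sample interpolation against an
  asynchronous button press would be spurious precision.
* PE converts the per-axis pixel offsets to degrees first, then takes the
  Euclidean norm.
* The 20-ms PE/X/Y series run over 0.00–4.60 s (231 bins) and are truncated
  at each trial's press; post-press bins are missing, not padded, and the
  per-bin trial/participant counts propagate into the statistics.
* Trial exclusion is stepwise: gaze losses (any invalid sample between
  motion onset and the press) first, then EEG artifact flags on the
  remaining trials; the two reasons partition the excluded set, so the QC
  report's blink + artifact counts always sum to the total excluded.
* Group statistics operate on participant means (participants are the
  exchangeable units), giving df = 15 for a 6 + 11 pooled comparison.

## Group statistics

The Welch fallback rule is: run mean-centered Levene; use Welch whenever
levene_p < 0.10, pooled otherwise. (The reference procedure names the
0.05 ≤ p < 0.10 "trend" band explicitly and is silent below 0.05; extending
Welch to all p < 0.10 is strictly more conservative and contains that
band.) Cohen's d always uses the pooled SD so it is comparable across
variants. Series tests apply BH-FDR per measure (PE, X, Y are separate
families; only bins with ≥2 participants per group enter the family), and
the significance mask is keyed to the *raw* p-values with the adjusted set
reported alongside.

`welch_from_summary` is algebraically identical to the raw-sample Welch
test for any samples matching the (n, mean, SEM) summaries — tested to
1e-9 via affine-constructed samples. On the printed PE summaries
(6, 2.00, 0.11) vs (11, 3.04, 0.45) it gives t(11.15) = 2.25, d = 0.85,
95% CI [0.02, 2.06].

## EEG pipeline

All filters are zero-phase forward–backward Butterworth cascades (order 4,
i.e. 8th-order band-passes after the transform). Because filtfilt applies
the magnitude response twice, a textbook −3 dB-at-corner design would
retain only 50% at the nominal edges; the low-beta filter's corners are
instead solved numerically (≈11.80 and 16.27 Hz) so the **net** two-pass
gain at 12 and 16 Hz is exactly 1/√2 ≈ 70.7%, with ~100% at 14 Hz and
<0.1% at 30 Hz. This matches the stated "~70% amplitude retention at the
cutoffs" convention and preserves the 13–15 Hz band of interest.

Processing order: 1–40 Hz broadband filter → common average reference over
the 19 scalp channels → −200..+2300 ms epochs (2500 samples at 1 kHz) →
artifact rejection (default: any sample |x| > 100 µV after preprocessing;
a peak-to-peak reading of the same threshold is available as a config
switch, since the criterion is stated both ways in the field) → 12–16 Hz
band-pass → Hilbert analytic signal → natural-log envelope (log base is a
convention choice; ε = 1e-12 µV floors the magnitude before the log).
Envelopes are log-transformed per trial and then averaged within
participant ("log-then-average"). No ICA or EOG regression is applied — an
intentional choice for small trial counts with task-locked eye movements,
where component misclassification risks distorting the band of interest.

Filter transients: the narrowband filter rings past each epoch edge; the
envelope settles to ~3% by roughly 500 ms in. A 200 ms edge margin is
flagged as untrusted metadata, and the steady-state tests assert in the
0.5–1.8 s core. Conclusions about the first ~0.3 s of an epoch ride partly
on filter settling and should be treated accordingly.

## Cluster permutation inference

Participants — never trials — are the exchangeable units: group labels are
permuted over the 17 participant-mean envelope maps, which is what the
between-group design and unequal trial counts require. One set of label
permutations drives everything: the pointwise p map, the cluster-formation
threshold, and the max-cluster-mass null, so observed and permuted data are
treated identically. Pointwise p at each (electrode, ms) is
(1 + #{|t_perm| ≥ |t_obs|})/(1 + n_perm) with a pooled two-sample t; for
≤8-participant cohorts an exact mode enumerates all label assignments
(tested against brute-force enumeration).

Cluster formation: points with pointwise p < 0.05 and common t sign are
connected along consecutive 1-ms samples on one electrode and across
neighboring electrodes at the same sample (so temporally overlapping
supra-threshold runs on adjacent electrodes merge). At 1 kHz each sample
counts as 1 ms of extent, so a k-sample run is k ms and the >10 ms
persistence criterion keeps runs of ≥11 samples on some single electrode.
Cluster mass is the sum of member t values; the null records, per
permutation, the maximum |mass| over clusters of both signs (two-sided
family-wise control); cluster p = (1 + #{null max ≥ |mass|})/(1 + n_perm).

The 19-site electrode neighborhood (10–20 with 10–10 extensions; CPz is the
reference, AFz ground) is shipped as an explicit table with the absent
C-row bridged to the nearest present sites (e.g. CP5–{FC5, CP1, P7, P3});
it is overridable from CSV. Representative windows merge same-direction
significant clusters whose intervals overlap or sit within 15 ms — a
reporting convenience only; inference never depends on it.

One subtlety: a permutation's pointwise count includes the permutation
itself, while the observed map is not part of the permutation sample; the
null cluster-formation cut is therefore shifted one order statistic down so
permuted datasets form clusters exactly as easily as the observed one.
Measured family-wise error on effect-free synthetic cohorts is ≈ 0.04–0.11
across independent 100–200-dataset estimates (pooled ≈ 0.06), inside the
Monte-Carlo acceptance band [0.01, 0.10] at 200 datasets.

## Synthetic cohort generator

The generator reproduces the *statistical structure* the analysis assumes,
with known ground truth:

* **Design**: two groups (6 "anticipatory" vs 11 "late-shift"
  participants), 180 trials each (6 blocks × 30) over the three randomized
  trajectory conditions.
* **Gaze**: hold a pre-fixation point (group A: launch center; group B:
  +16 px forward, 35 px up), then an instantaneous shift at a drawn latency
  (A: 0.5 ± 0.08 s; B: 1.2 ± 0.15 s) to the true landing point plus
  endpoint scatter drawn in degrees. Endpoint SDs are calibrated so mean PE
  ≈ 2.0° (A) and ≈ 3.0° (B) (Rayleigh mean = σ√(π/2)); a per-participant
  scale factor (CV 0.15/0.20) gives groups a realistic between-participant
  spread — without it, group tests would have degenerate ~100% power and
  nothing useful would be validated. Button presses are 4.6 s + N(0,
  0.69 s), making E|press − 4.6| ≈ 0.55 s in both groups. Saccade transit
  is instantaneous between 20-ms samples (50 Hz cannot resolve transit).
* **Blinks**: Poisson counts per trial (rates 0.32/0.56 for A/B), uniform
  onset, Gaussian duration (0.25 ± 0.10 s, floored at 40 ms), marking
  samples invalid — which yields mean exclusions per participant on the
  scale of ~49 (A) and ~77 (B) of 180 trials.
* **EEG**: per channel, 1/f pink-noise background (rms 12 µV), a
  random-phase 10 Hz alpha component (4 µV), and group/channel/window
  specific low-beta bursts: Hann-windowed sinusoids at a per-trial random
  frequency in 12.5–15.5 Hz (avoiding filter-edge dependence). The default
  injection pattern mirrors the group contrast the analysis is meant to
  detect (a mid-latency parietal–premotor window 0.554–0.619 s for group A,
  early parietal and occipital windows for group B). Because these windows
  are shorter than one low-beta cycle, the narrowband filter passes only a
  small fraction of the burst; the default pre-filter amplitude (40 µV) is
  calibrated once so the post-filter envelope effect is recovered reliably
  (≥80% of cohorts) at the validation cohort sizes. Artifacts are large
  slow excursions (220 µV Gaussian bumps) at a 9% trial rate.

What the generator does **not** emulate: volume conduction (channels are
independent noise — no spatially correlated background, so real-data
cluster geometry will differ), oculomotor physiology (no main sequence,
pupil, or microsaccades), EEG nonstationarity, and any coupling between
gaze behavior and EEG. Passing validation therefore demonstrates that the
*pipeline* is correct and calibrated under its own assumptions, not that
those assumptions hold for any particular recording.

## Problem sizes and numerics

Monte-Carlo validation uses deliberately scaled-down cohorts — 8–12 trials
per participant and 200 permutations per test for the EEG studies, 30
trials per participant for the behavioral power study — sizes at which the
statistical properties under test (exchangeability, calibration, recovery,
power) are already well expressed. Heavy array paths run in float32
(the permutation t matrices, synthetic EEG, envelopes); t statistics agree
with float64 references to ~1e-7, far below any tolerance used. Exact ties
in the permutation count are kept with a 1e-6 relative slack so the
label-swap tie survives float32 rounding. All randomness flows from
explicit seeds (numpy Generator streams, spawned per participant), and the
full pipeline is byte-reproducible: identical config + seeds give
byte-identical report bundles (HDF5 written without timestamps).

## Known limitations

* Pointwise series tests ignore temporal autocorrelation in gaze signals;
  contiguous significant intervals mean sustained differences, not sharply
  localized effects.
* Electrode→Brodmann annotations (O2→BA18, P3/P4/CP2→BA7, CP5→BA40,
  FC1→BA6, with Talairach coordinates and SDs) are static report metadata;
  scalp EEG does not localize sources.
* EDF input is read-only (via `mne`) and subject to the format's 16-bit
  quantization; the native container is HDF5.
* The band-edge "70% retention" convention is implemented exactly for the
  default order-4 design; overriding the band or order re-solves the
  corners for the same net convention.
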