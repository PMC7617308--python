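# Methods

## Scope and data model

The package models a two-channel physiological recording setup — fingertip
photoplethysmography (PPG) and a chest respiration belt, both sampled at
75 Hz — around a heart-rate biofeedback game. Five containers carry the
pipeline: `SignalTrace` (one uniformly sampled channel), `BeatSeries`
(pulse-peak times, interbeat intervals and per-IBI audit flags),
`HRVSummary` (mean HR, mean IBI, SDNN, cvSDNN plus a QC report),
`StressTimeline` (the engine's per-beat output) and `ParticipantRecord`
(all sessions of one participant plus group assignment).

## Virtual-participant generator

### Interbeat intervals

Beats are generated sequentially from a beat at t = 0:

    IBI_i = 60000 / HR_base + g_eff(t_i) · w(φ_i) + ε_i     [ms]

`w` is the breathing waveform at the beat's breathing phase, mean-centred
per cycle and scaled to unit amplitude; `ε` is i.i.d. Gaussian noise.
`g_eff = rsa_gain · min(1, T_cycle / 15 s)` attenuates the respiratory
sinus arrhythmia (RSA) gain for breathing faster than the 4/min paced
reference. A purely phase-additive model with constant gain cannot make
slow pacing raise SDNN (equal amplitude at all rates); the roll-off is the
simplest mechanism consistent with the vagal low-pass character of RSA,
and its normalisation (factor 1 at or below 4/min) keeps the calibration
case exact: a sinusoidal pattern at 4/min with gain g yields IBIs sampled
from a sinusoid of amplitude exactly g (SD g/√2). The modulation term is
tabulated at 16 Hz and linearly interpolated inside the beat loop; at
breathing frequencies ≤ 0.25 Hz the interpolation error is below 1e-4 of
the amplitude. IBIs are floored at 300 ms (200 bpm).

### Breathing patterns

Patterns are cycle sequences with one of three shapes: the paced
ramp-hold-ramp (5 s inhale, 5 s hold, 5 s exhale by default), a raised
sinusoid for spontaneous breathing (cycle lengths jittered with CV 0.08),
and flat (apnoea/zero amplitude). Imperfect adherence to training is a
per-cycle Bernoulli mixture: each cycle is paced with probability equal to
the participant's adherence, otherwise one spontaneous cycle. Belt traces
are the pattern's [0, 1] amplitude plus a slow sinusoidal drift (0.005 Hz,
amplitude 0.02) and optional white noise.

### PPG rendering and artifacts

One stereotyped asymmetric pulse template (100 ms half-cosine rise, 200 ms
decay, peak aligned to the beat sample) per beat, plus baseline wander
(0.05 Hz, amplitude 0.1) and measurement noise. No morphology claims are
made — the template exists to be found by peak detection. Artifacts are
drawn as a Poisson process (default 0.4/min) over four kinds mirroring the
correction taxonomy: `missed` (template suppressed), `ectopic` (extra
early template), `long` (template displaced late by 0.6 of the median
IBI) and `noise_burst` (2 s of high-variance noise). Beat-level injection
(`apply_ibi_artifacts`) sizes artifacts against the median interval: a
"long beat" is +0.6 median, an ectopic advance is −0.3 median. Sizing
against the local interval instead would make the injected class itself
ill-defined — a long beat scaled from a momentarily short interval is not
long at all, and one scaled from a long interval is effectively a missed
beat.

### Cohort defaults

Chosen once as the study conditions the generator emulates, then left
alone: baseline HR ~ N(78.49, 11.00) bpm clipped to [50, 110]; spontaneous
respiration ~ N(13.02, 4.92) breaths/min clipped to [6, 24]; stressor HR
elevation ~ N(6.57, 4.0) bpm (6.57 = 85.06 − 78.49); adherence ~
N(0.85, 0.10) clipped to [0.3, 1]; RSA gain 150 ms (half the
peak-to-trough IBI swing under deep slow pacing — large, as slow-breathing
RSA is); IBI noise 50 ms. With these, baseline cvSDNN lands near 8 and a
well-adhering participant's paced-stressor cvSDNN near 13–16, bracketing
the magnitudes such studies report. The intruder condition adds 4 bpm and
speeds breathing by 15%; control participants slow breathing by 1.5/min in
the stressor. Stress onset is a step at session start (the within-session
trajectory is unconstrained by the emulated design; a step is the simplest
choice and only between-condition means enter the analysis). Study-2
control/trained pairs share demographics draws, mirroring matched
recruitment.

## Cardiac pipeline

Peak detection band-passes 0.5–8 Hz (3rd-order Butterworth, zero phase),
finds local maxima with ≥250 ms separation and prominence ≥ 0.3 × the
2.5–97.5 percentile half-range, rejects edge transients weaker than half
the median peak amplitude, and refines each peak to the raw-signal local
maximum (sample-exact on clean traces). A truncated pulse exactly at a
trace edge is not recoverable. Flat or degenerate traces return zero
peaks with a QC exclusion rather than an exception. Unreliable time is the
sum of inter-peak gaps exceeding max(2 s, 2.5 × median IBI), including the
recording's ends.

Correction classifies intervals against a centred rolling median of 21
beats — deliberately wider than one breathing cycle, so the local baseline
does not ride the RSA phase. Alternating short–long (or long–short) pairs
whose sum is near twice the local median are ectopic displacements, both
intervals replaced by their mean; intervals above 1.75 × median are missed
beats, split in two; intervals above 1.5 × median are long beats, replaced
by the local median. All repairs are flagged; a series needing correction
of more than half its intervals is excluded. Replacement operates on the
interval sequence (peak times are rebuilt from the corrected IBIs), so
corrected series trade wall-clock fidelity for statistical fidelity, which
is what SDNN consumes.

The missed/long discrimination has an intrinsic floor: with resting IBI
variability near 9% of the mean, a +0.6-median long beat (ratio 1.6) and a
merged missed-beat interval (ratio 2.0) overlap, and no magnitude-only
classifier separates them perfectly. Inject-and-recover suites under the
default cohort conditions restore exact beat counts in roughly 92–96% of
recordings, with both error modes (long split as missed, missed repaired
as long) represented; aggregate beat-count error always falls.

Excision mirrors manual removal of noisy periods: spans come from a
signal-quality index (rolling RMS of the >15 Hz residual against its own
median) and only spans covering more than 3 beats are removable; IBIs with
either endpoint inside an applied span are dropped, never concatenated.
Exclusion applies the rule: >60 s unreliable or >3 excised regions.
Detection order is detect → excise → correct.

SDNN uses the sample (n−1) standard deviation over retained IBIs;
cvSDNN = 100·SDNN/mean IBI from the same segment — computing both from one
`BeatSeries` is what enforces the per-condition heart-rate adjustment.
PPG-derived variability is strictly pulse-rate variability; the package
reports it as cvSDNN without claiming ECG equivalence.

## Respiration pipeline

The low-pass is a 10th-order Butterworth applied forward–backward (zero
phase, so breath peaks do not shift; the effective magnitude response is
squared). The 0.1 cutoff is interpreted in the normalized half-sample
convention (0.1 × Nyquist = 3.75 Hz at 75 Hz) — the convention of the
tooling this pipeline mirrors; an absolute-Hz dialect is a config switch.
An absolute 0.1 Hz cutoff would sit below the 13/min spontaneous
fundamental (0.22 Hz) and could not have supported resting-rate detection.

Breaths are local maxima with prominence ≥ 0.25 × the trace interquartile
range and ≥ 2 s separation; when the filtering step supplies a noise floor
(SD of the raw-minus-filtered residual), peaks must additionally clear 3
noise SDs, which is what rejects pure-noise traces. A trace with no peak
for more than 60 s anywhere is unusable. Adherence is 4 − breaths/min,
kept signed (the absolute value is derivable downstream; the sign
distinguishes slower- from faster-than-trained breathing). Manual peak
editing is replaced by an `override_peak_times` argument for
reproducibility.

## Biofeedback engine

C = 2·ln(3)·(RefBPM − BPM)/RangeBPM and StressScore = 1/(e^C + 1); the
2·ln 3 constant is what pins the printed anchors (score 0.9 at Ref+Range,
0.1 at Ref−Range — any other parsing fails them). RangeBPM is restricted
to the experimenter UI's {5, 10, …, 100}. Light thresholds compare with ≥
("reaching" a value escalates). Note the amber threshold 0.41 lies below
the score at BPM = RefBPM (0.5): a participant at their training heart
rate already shows amber. This is reproduced faithfully, not corrected.
The rolling BPM uses an expanding window until 30 IBIs accumulate (the
engine's warm-up is otherwise unconstrained). Death checks find the beat
nearest each of the five death times (default 100–500 s evenly spaced, a
configuration choice); the timeline updates per beat, not per display
frame. Boat speed: `HR + 50` as shipped; the reconstructed intended
mapping mirrors HR around 2·RefBPM before adding the constant (the
original inverse design was never specified; this reconstruction preserves
the 1 unit/bpm slope and the value at RefBPM).

## Study pipeline

Baseline normalisation is metric(condition) − metric(baseline) per
participant; segments failing QC drop the record from that test with a
logged reason, and per-test accounting conserves n (input = analysed +
excluded). Paired and independent t tests and the Pearson correlation run
through scipy.stats behind the module surface (textbook-formula oracles
cross-check them in the tests); all tests are two-sided and uncorrected
for multiplicity, matching the emulated reporting style. The 2×2
mixed-design ANOVA (between = group, within = time) is computed directly
from sums of squares — the between effect tested against
subjects-within-groups, the within and interaction effects against the
subject × time residual, dfs (1, 2(n−1)) — and is cross-checked against
pingouin's `mixed_anova` in the tests. Unbalanced groups are refused; the
runner equalises by seeded random exclusion first and logs the dropped
record. Between-group contrasts use independent-samples t tests (the
two-group contrasts this mirrors were ambiguously labelled as paired; a
config-free independent test matches their dfs).

## Problem sizes and what passing shows

Replicated direction-of-effect checks run 100 seeded study-2 cohorts of 26
per group at ground-truth level (metrics computed from the generator's
beat and breath times, skipping the waveform round trip) — the full
render → detect → correct → summarise route is exercised end-to-end on
smaller cohorts and single recordings. Session lengths are the emulated
design's: 5 min baseline/intruder, 3.5–5 min training, 10 min stressor.

The generator produces what the analysis assumes — RSA-coupled IBIs,
template pulses, belt-shaped breathing — not real physiology: no
baroreflex dynamics, blood-pressure coupling, motion artifacts, sensor
drift beyond a toy wander, or PPG morphology. Passing tests therefore
demonstrates that the pipelines recover what was simulated under the
stated noise and artifact model and that the statistics behave as
documented; they do not validate the pipelines against real recordings.

## Numerical choices

Zero-phase filtering throughout (sosfiltfilt; stable at order 10).
Degenerate inputs: zero-variance difference vectors flag the paired t as
degenerate (t = 0, p = 1) rather than dividing by zero; all-equal ANOVA
cells report F = 0; flat traces yield QC exclusions, not exceptions.
Threshold ties in the light classifier escalate. All randomness flows
from explicit `numpy.random.Generator` objects or a single seed via
`SeedSequence.spawn`; identical seeds give bit-identical cohorts and
byte-identical CLI outputs (manifests carry a config hash and no
timestamps).
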