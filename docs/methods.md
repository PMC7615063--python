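# Methods

This note documents the generative model behind the simulator, the decoding
and analysis pipeline, the defaults and why they were chosen, and what the
simulation can and cannot establish about real recordings.

## Stimulus model

Each tagged patch is a luminance modulation `L(t) = 0.5 + 0.5·depth·m(t)`
sampled at the 1440 Hz frame clock, with `m` either a sinusoid (default) or
a square wave at the tagging frequency (56 Hz left, 60 Hz right). The
waveform of the physical flicker is a free design choice here; the sinusoid
is preferred because its spectrum is a single line. 56 Hz does not divide
1440 (25.71 frames per cycle), so the sinusoid is sampled at frame times
rather than forced to integer cycles; the resulting leakage is negligible
over 1-s analysis windows. Patch edges carry a linear transparency ramp
over 10 % of the patch extent (fully transparent at the border, fully
opaque inside), which in the real display hides the patch outline against a
static grainy background texture; the texture is static and therefore
spectrally inert.

## Synthetic MEG

Seven gradiometer-like channels at 1000 Hz are modelled as

```
x_c(t) = Σ_f g_c(f)·A_f·m_f(t)·sin(2πft + φ_c,f)  +  σ·n_c(t)  +  α_c(t)
```

* **Steady-state responses** — pure sinusoids at 56 and 60 Hz with random
  phase (per trial per channel in training; fixed per session in the live
  stream). No response-waveform realism beyond narrowband power is
  attempted, which is all the decoder and the analyses consume.
* **Topography** — per-channel gain pairs `g_c(56), g_c(60)`: three
  left-hemisphere channels weight 60 Hz (right hemifield) more, three
  right-hemisphere channels weight 56 Hz more, one midline channel is
  balanced. The values are configuration defaults describing a lateralized
  occipital pattern, not measurements.
* **Attention** — covert attention to one side multiplies the amplitude of
  that side's frequency by `attention_gain` (power gain = gain²). In the
  live stream attention follows the requested policy with a 300 ms neural
  lag (configurable); the lag makes closed-loop control non-trivial because
  the decoder's 1-s window straddles attention switches.
* **Noise** — 1/f background (measured log-log slope ≈ −1 over 1–80 Hz)
  produced by streaming white noise through a pinking IIR filter whose
  state persists across 100-ms blocks, so streamed sessions are seamless;
  plus a 10 Hz alpha rhythm with a slow deterministic envelope. Neither
  intrudes on the 54–62 Hz bins that matter for decoding, which is why the
  alpha amplitude is uncritical.
* **Trial-to-trial variability** — in training, each trial's response
  amplitude is jittered lognormally (σ = 0.25) per frequency.

Everything is driven by `numpy.random.default_rng(profile.seed)`: the same
seed reproduces a session bit-for-bit.

### Gaze and blinks

Gaze is smooth fixational jitter (8 Hz lowpass-filtered white noise, sd
0.35°) plus brief excursions (Poisson arrivals ≈ 10/min, ~150 ms, offsets
1.2–2.8°). These two components jointly reproduce the targeted containment
statistics: ≈ 97 % of samples within 1° of fixation and ≈ 1 % beyond 2°.
Blinks arrive as a Poisson process (default 8/min, ~250 ms) and blank the
gaze channels with NaN sentinels; the online path flags any contiguous gap
≥ 50 ms as a blink (a standard pupil-loss criterion — the tracking hardware
this emulates reports lost pupils, not eyelid kinematics). Optional MEG
blink artifacts are off by default.

### SNR calibration

The response amplitudes are not free parameters: they are set by bisection
so that the measured spectral SNR — power at the tag over the mean power
±2 Hz away, with power averaged over 7 sensors and ≥ 100 non-overlapping
1-s windows of continuous tagging *before* taking the ratio — matches the
targets 3.1 (56 Hz) and 2.0 (60 Hz). Averaging power before the ratio
matters: single-window ratios are heavy-tailed (the denominator is a
two-bin chi-square) and their mean is ≈ 2 even for pure noise, whereas the
ratio of averaged powers tends to 1 on a flat spectrum, is 1 exactly at
zero amplitude, and increases monotonically with amplitude. The bisection
objective averages three fixed measurement seeds (200 windows each) so a
single unlucky noise realization cannot bias the calibrated amplitude; the
frozen defaults `amp_56 = 0.130`, `amp_60 = 0.0894` (noise scale 1) are the
output of this procedure and verify to within ±0.1–0.15 on fresh seeds.

`attention_gain = 1.35` is the one remaining behavioural dial; it was set
once so that, at the calibrated SNRs, decoding accuracy falls in the
60–75 % band — the regime of interest for a two-class covert-attention BCI
— and is not adjusted per subject.

## Streaming and decoding

The acquisition path delivers 100-ms blocks (MEG + gaze + trigger) into a
1-s FIFO ring buffer; window queries are refused until ten blocks have
arrived, and during that warm-up the game bar holds its initial (left)
position. The simulation clock is the block tick — no wall-clock coupling,
so runs are deterministic and fast.

The online power estimate is a single rectangular-window DFT bin with no
taper and no normalization (`P(f) = |DFT bin f·n/srate|²`); the Hanning
taper belongs only to the offline time-frequency analysis, and the two
paths are kept deliberately distinct. Features are the 14 powers
(7 sensors × 2 frequencies, ordered sensor-major), z-scored with training
statistics — raw DFT powers span orders of magnitude, and a linear SVM on
unstandardized power would be dominated by the strongest sensor. The SVM
uses a linear kernel, C = 1, no class weighting (the design is balanced
40/40), stratified 4-fold CV for the reported accuracy, and a final refit
on all trials. The decision score is the signed distance to the hyperplane;
its sign selects the side, and a score of exactly zero keeps the previous
side (hysteresis) rather than chattering. The trained model serializes to
versioned JSON; loading it against a recording with a different channel
order is an error.

## Game

The world is the unit square. The ball starts at a random position in the
top quarter, falls at 0.30 screen/s (halved for the first second after any
reset — an orientation period), drifts horizontally at 0.04–0.10 screen/s
with wall bounces, and meets the bar line at y = 0.90 after ≈ 3 s. If the
bar shares the ball's side the trial is a hit: the ball deflects 90° into a
horizontal trajectory toward the nearer wall, bounces briefly, and a new
trial starts from the top. On a miss the ball falls through and resets
directly. Every completed trial therefore ends in a reset (resets = hits +
misses + 1 including the initial placement), which keeps the slow-start
orientation period attached to every trial; continuous rallies after a hit
would be the main alternative, and this choice favours well-defined trial
boundaries over them. Geometry
and speeds are configuration; the defaults yield ~80 trials per 5-minute
game. Trials with a blink in the last second before the collision are
flagged invalid: they still appear in the on-screen score but never enter
the accuracy.

## Offline analysis

* **Preprocessing** — zero-phase 4th-order Butterworth band-pass 1–80 Hz
  plus a 2 Hz-wide 50 Hz notch. The notch is a 2001-tap linear-phase FIR
  band-stop rather than a biquad because the biquad's two-pass skirt would
  shave several percent off 56 Hz; with the FIR the tags pass with < 5 %
  amplitude change while 50 Hz is suppressed by far more than 20 dB. No
  baseline correction or artifact rejection — recordings are kept as raw as
  the online path sees them.
* **Epochs** — training: [−1, +3] s around tagging onset; game: [−3, +1] s
  around collisions. Out-of-bounds trials are dropped and counted.
* **TFR** — Hanning-tapered sliding window of 20 cycles per frequency,
  40–70 Hz in 1 Hz steps, 25 ms time steps, power normalized so a unit
  sinusoid reads ~1 and averaged over trials. Time points whose window runs
  past the epoch edge are NaN and flagged unavailable, never zero-filled.
* **Sliding power** — the trailing 1-s DFT-bin power at every sample
  (computed by complex convolution, identical to the online definition at
  every point), decimated to 100 Hz. The trailing (causal) window mirrors
  the online ring buffer; its last point equals the online feature exactly.
* **ITR** — Wolpaw's convention with the error term divided by N−1. A
  published variant divides by N, which yields negative rates at chance for
  N = 2; it is available as `printed_formula=True` for comparison but is
  not the default.
* **Cluster permutation** — per-timepoint paired t, cluster-forming
  threshold two-tailed p < 0.05 (the field default; the forming threshold
  is otherwise a free choice), clusters are maximal same-sign
  supra-threshold runs, and the null is the maximum cluster |t-sum| over
  within-subject condition swaps (max-statistic, family-wise control),
  1000 permutations by default with the +1-corrected p. For small n an
  exhaustive mode enumerates all 2ⁿ sign patterns. Empirical family-wise
  type-I error at nominal 0.05 measures ≤ 0.07 over 500 null simulations.
* **Eye confound** — containment fractions within 1° and 2°, and the
  40-bin eye-position/power histogram over ±2°. The accompanying test uses
  the sample-level rank correlation rather than a bin-level one: outer bins
  hold only a few excursion episodes whose 1-s-smoothed power is shared
  between neighbouring bins, so a bin-level test has far fewer effective
  degrees of freedom than bins.

## Problem sizes

The test suite and the acceptance script use eight simulated subjects
(80-trial training sessions and full 5-minute games), 200–400 one-second
windows per SNR measurement, 200 label shuffles for the chance control, and
500 simulated datasets for the permutation-test calibration. These sizes
keep every estimate's sampling error comfortably inside the tolerances
asserted against it.

## What passing tests do and do not show

The generator reproduces the *statistical contract* the decoder relies on —
narrowband tagged power, attention modulation, 1/f + alpha background,
realistic gaze containment, blink gaps — under which the pipeline reaches
its target operating points. It does not emulate head movement,
sensor noise correlations, forward-model topography beyond a gain pattern,
microsaccades, or non-stationary attention, so passing here demonstrates
the correctness and internal consistency of the pipeline, not its
performance on any particular human dataset.

## Known limitations

* The neural response is a fixed-phase sinusoid per trial; real SSVEFs show
  phase jitter and harmonics.
* Attention acts as an instantaneous multiplicative gain after a fixed lag;
  real attentional modulation waxes over hundreds of milliseconds.
* The 7-channel topography is a stylized gain pattern; no leadfields.
* Game geometry (speeds, collision height, reflection angles) is
  configuration, chosen only to give plausible trial rates.
* One calibration serves both training and game sessions; whether their
  SNRs differ in real use is an open question the simulator does not probe.
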