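# Methods

## Stimulus model

A looming (crescendo) stimulus is a broadband-noise burst whose **level rises
linearly in dB SPL** — not in pressure — from a background of 20 dB SPL to a
peak (default 70 dB SPL) over a rise time (default 0.4 s), returns to
background within a fast 5-ms transition, and holds at background for an
inter-ramp interval (default 0.6 s). The default train repeats this ten
times.

Conventions fixed here:

* The 5-ms return transition is folded into the hold interval, so one repeat
  period is exactly `rise + hold` (1 s by default) and the default train is
  exactly 10 s with ramp windows `[k, k+0.4)`. The transition is rendered as
  a linear dB ramp inside the hold.
* Window intervals are half-open `[onset, offset)`; the envelope is sampled
  at 1 kHz by default (sufficient for 5-ms features) and the peak is attained
  to within one envelope sample for arbitrary rise times.
* The optional waveform is a **single continuous** white Gaussian noise
  stream at 96 kHz (covering a 1–60 kHz calibrated band), amplitude-modulated
  by `10^((level − background)/20)`. Whether a real deployment would re-draw
  noise per presentation is unknowable from level traces; continuous
  modulation is the simpler choice and makes the waveform reproducible from
  `(spec, seed)` alone. The exact spectral shape of the noise within the
  calibrated band is likewise unspecified; we use flat (white) noise.
* Decrescendo trains come in a low-background variant (5-ms step up, linear
  fall peak→background, hold at background) and a high-background variant
  (continuous peak-level background with per-repeat falls); the falls are the
  analysis windows.
* The single slow stimulus used for comparing repeated vs. single
  presentation is just `n_repeats=1, rise_time_s=5.0` — no special casing.

## Behavioral scoring

Input is a tracked centroid trajectory (time, x, y in cm; 20 or 14 frames/s)
in a 48 × 48 cm arena with a corner nest. Speed is the finite-difference
displacement rate at frame-interval midpoints, smoothed with a 0.15-s moving
average; the smoothing absorbs single-frame tracker jitter.

* **Freezing**: maximal runs of (smoothed) speed below 2 cm/s lasting
  ≥ 1 s, starting at or after stimulus onset. The criterion is strict
  per-sample: a single supra-threshold sample splits an episode. This is a
  declared reading of "consistently below" on a lightly filtered trace; it is
  validated against a brute-force run-length oracle and is not silently
  changeable.
* **Escape**: the first post-onset movement run that (i) terminates inside
  the nest disc or a corner zone, (ii) contains no sub-threshold interruption
  of ≥ 0.5 s ("without stopping"; 0.5 s sits between frame noise and the
  freezing minimum), and (iii) peaks at ≥ 1.1 × the top speed of the 5 s
  before stimulus onset. The published escape onset is a head-turn video
  frame, which centroid data cannot provide; we use the **last sub-threshold
  sample before the qualifying run** as a surrogate and label it as such in
  the event record. On synthetic data the surrogate sits within ~1.5 frames
  of the true motor-program onset.
* **Normalized top speed**: peak speed during the stimulus train over the
  peak in the 5-s pre-stimulus window. An immobile pre-stimulus baseline
  (peak 0) is an error, not a silent infinity.
* **Nest time**: dwell in nest-or-corner during the 15 s following stimulus
  offset. Corner zones are 8-cm squares at each arena corner (the source
  criterion names "corner or nest" without geometry). Dwell time is additive
  over any window split.
* **Outcomes**: freezing-escape (freezing precedes escape), escape-only,
  freezing-only, none. An escape onset strictly inside a freezing episode
  (beyond the one-frame surrogate boundary) is a contradiction and raises.
* Cohort summaries report mean ± s.e.m. over non-missing values with counts
  (matching the reporting convention in which escape latency has n = 31 of
  32 animals), and outcome probabilities to the nearest percent.

## Spike-train analysis

* **PSTH**: counts per bin across alignment events divided by
  `bin × n_events` (10-ms bins for trains, 5-ms for tones, configurable);
  total spike count is conserved exactly.
* **Evoked rate**: raw in-window rate per stimulus window averaged over
  trials; the baseline-subtracted variant is stored alongside and available
  behind a flag (whether published per-stimulus rates are baseline-subtracted
  is not stated; raw is the default reading of "analyzed for the duration of
  each individual stimulus"). Baseline for trains is the 1 s before train
  onset; for tones, 50 ms before tone onset.
* **Onset latency**: first post-onset PSTH bin whose rate exceeds baseline
  mean + 3 SD. The SD is floored at the Poisson counting noise
  `sqrt(mean/(bin × n_trials))` so a silent or perfectly flat baseline cannot
  yield a zero criterion.
* **Response typing** (On / Sustained / Off) has no published numeric
  criteria; the operationalization here is: significant elevation requires
  two consecutive bins above the 3-SD criterion (one-bin excursions at
  2-Hz-range spontaneous rates are common); On responses are confined to the
  first 100 ms and return to ≤ baseline + 1 SD before stimulus offset;
  Sustained responses persist with late-half mean ≥ early-half mean (the
  rising-ramp signature); Off responses show no stimulus-locked elevation but
  a significant one within 300 ms of offset. When both stimulus and offset
  windows are formally significant, latency-guarded mean excess rates
  arbitrate. These thresholds are validated against the labeled synthetic
  archetype bank (≥ 90% required), not against recorded-cell proportions.
* **TRF metrics**: threshold = lowest intensity with a significant pixel
  (same 3-SD rule), best frequency = peak-response frequency at threshold,
  bandwidth = octave span of significant pixels at threshold + 20 dB, one
  0.2-octave step counting as 0.2 octaves.
* **RS/IB**: median one spike per best-frequency tone → regular spiking;
  median ≥ 2 with intra-burst ISIs < 10 ms in at least half the trials →
  intrinsic bursting; anything else (including zero-spike medians) is left
  unclassified.

## Synthetic-data generator

The generator is first-class, tested code; its defaults **are** the study
conditions, and all round-trip tests run against them.

**Behavior.** Baseline exploration is a correlated random walk:
Ornstein–Uhlenbeck speed modulation (mean 8 cm/s, SD 4 cm/s, 1-s time
constant — producing 5-s top speeds in the 15–20 cm/s range typical of
open-field mice), heading diffusion, reflecting walls. The animal is steered
into the central trigger zone to define stimulus onset, then executes its
assigned outcome program:

* Outcome classes are allocated by largest remainder from the configured
  probabilities (27:4:1:0 out of 32).
* Freeze durations, escape-only latencies and escape speed gains are drawn
  as **stratified (midpoint-quantile) samples** of the configured lognormal
  distributions, randomly permuted across animals. Stratification preserves
  the marginal distribution and its spread while making any finite cohort
  representative of the configured means, so round-trip recovery probes the
  scoring pipeline rather than Monte-Carlo luck.
* In freezing-escape trials the escape latency is structural: a freeze-onset
  delay (mean derived as `latency_mean − freeze_mean` = 0.5 s) plus the
  freeze duration, since escape begins when freezing ends. Freeze duration:
  lognormal mean 3.0 s, SD 1.7 s (cohort s.e.m. ≈ 0.3 at n = 32), floored at
  1.2 s so every programmed freeze is detectable under the 1-s criterion.
  Escape-only trials draw their latency from the configured lognormal
  (mean 3.5 s, SD 2.2 s) and insert a 0.75-s head-turn pause before the run —
  long enough to separate the run from prior walking, short enough never to
  count as freezing.
* The escape run is a straight, lightly jittered dash to the nest at
  `gain ×` the animal's own smoothed 5-s baseline top speed. The gain is a
  shifted lognormal with mean 1.6 and SD 0.55 supported above 1.15: a
  symmetric distribution with the implied cohort SD would put ~19% of animals
  below the 1.1× detection margin, inconsistent with near-universal escape
  detection, so the support floor is the self-consistent calibration.
* Tracking noise is stationary AR(1) jitter, SD 0.2 cm, per-frame
  correlation 0.99. Real centroid jitter is strongly temporally correlated;
  an i.i.d. jitter of this amplitude would alias into apparent speeds of
  5–7 cm/s and make the 2-cm/s freezing criterion undetectable on any
  usable tracker output.

**Ephys.** Spike trains are inhomogeneous Poisson:
`rate(t) = spontaneous + drive × adaptation^k × profile(t − latency)` for
stimulus index k. Profiles: a ramp with a 25% onset step for
TS/SC/cortical-sustained archetypes (sustained units show a clear response at
latency, then firing grows with the dB ramp), a 15-ms-decay onset kernel for
On, a 20-ms-decay post-offset kernel for Off. Per-unit drive is calibrated
numerically (by integrating the unit's normalized profile) so the expected
raw evoked rate over the first two response windows equals the unit's target;
unit targets are stratified Gamma draws with population means 34.5 Hz (TS,
n = 55) and 16.3 Hz (SC, n = 46) and across-unit SDs equal to the reported
s.e.m. × √n (26.0 and 15.6 Hz). Adaptation factors: 0.45/stimulus (TS,
fast-adapting), 0.97 (SC, slow), 0.85 (cortical sustained), 1.0 (On/Off).
Intensity tuning: an inverted-U gain peaking at 70 dB SPL for TS-like units
and a monotone sigmoid rising to 90 dB for SC-like units, normalized to 1 at
70 dB. A deterministic mode (time-rescaled regular spiking) gives exact
expected counts for tests.

**Coupling.** For the linking analysis, escape timing can be generated from
the neural side: each animal carries a release threshold θ ~ U(0, 1) and
escapes at the first stimulus-window midpoint where the normalized TS drive
has fallen below θ. Under this mechanism the escape-latency CDF is (up to
sampling) an affine function of the adaptation profile, so their Pearson
correlation approaches −1; the suite requires r ≤ −0.9.

**What the generator does not emulate.** Real pose dynamics (rearing,
grooming, thigmotaxis), head direction, lossy or discontinuous tracking,
non-Poisson spiking (bursting, refractoriness), electrode drift, or
behavioral state changes. Passing round trips therefore demonstrate the
correctness and calibration of the scoring and analysis chain under the
stated statistical structure — not robustness to every artifact of real
video or electrophysiology data.

## Linking statistics

Correlations between a 10-point adaptation profile and a continuous
behavioral time course pair the profile with the behavior **sampled at the
10 stimulus-window midpoints** (0.2, 1.2, …, 9.2 s); the pairing convention
is declared, not inferred. Non-escaping animals are excluded from the
latency ECDF with their count reported. Fisher's exact test is two-sided by
the point-probability rule (the sum of hypergeometric probabilities of all
tables with the observed margins whose probability does not exceed the
observed table's); mid-p and twice-one-sided conventions differ and are not
provided. Two-sample t tests are Welch by default (no equal-variance
assumption). Polynomial fits are compared by R² with ties going to the
lowest degree.

## Problem sizes and determinism

Default round trips use the study-scale sizes throughout: 32 behavioral
trials, 55 + 46 simulated units at 5 train presentations each, 150 units for
the classifier bank. Every generator consumes an explicit seed
(`numpy.random.SeedSequence` spawning per trial/unit), and identical
configuration + seed reproduces byte-identical pipeline summaries.

## Known limitations

* The escape-onset surrogate is speed-based; latencies carry a one-frame to
  one-smoothing-window (≤ 0.15 s) systematic offset relative to a
  head-turn-based annotation.
* The freezing criterion's strict per-sample reading means heavy tracker
  noise shortens or splits episodes; the smoothing window is the only
  mitigation, by design.
* Response typing thresholds are operational definitions tuned for the
  archetype bank's noise regime (2-Hz spontaneous, ≥ 20 trials); very sparse
  baselines rely on the Poisson SD floor.
* `trf_metrics` reports no bandwidth when threshold + 20 dB was not mapped,
  rather than extrapolating.
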