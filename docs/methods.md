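# Methods note

This note documents the models implemented in `mrcpspeller`, the default
parameters with their rationale, the numerical choices that matter, and the
known limits of the synthetic generator. All defaults live in
`mrcpspeller.config.StudyConfig` and its nested dataclasses; everything below
is configurable.

## 1. Speller paradigm and session plan

A 6×6 grid holds A–Z, 0–8 and space, row-major. Selection is two-stage
scanning: a bar sweeps the six columns left→right; when the user confirms a
column, the bar sweeps the six rows of that column bottom→top. A *cue event*
is the bar entering the target column or row. With dwell time 2 s per
position and a 2 s pause after each confirmed selection, a 13-character
phrase yields exactly 26 cue events (one column + one row per character),
each treated as one trial.

The cued movement is modelled at the midpoint of the 2 s dwell
(`TimingSpec.midpoint_offset_s = 1.0`): the bar enters the target position at
the cue, and the user reacts within the dwell rather than instantaneously.
All validation windows are taken relative to this *expected movement time*,
not the raw cue (`movement_time_s` in `evaluate_criteria`); with
`midpoint_offset_s = 0` the two coincide.

A 5 s lead-in precedes the first cue and ~6 s of tail follow the last one so
the widest epoch window, [−4, +5) s, never leaves the recording.

Conditions: `control` spells "OOOOOOOOOOOOO", `phrase` spells
"HELLO IM FINE", `random` spells a seeded anagram of the phrase. The motor
task is identical across conditions; only the cognitive load differs.

## 2. Synthetic signal model

**MRCP template** (piecewise linear, time relative to PN, smoothed by a
0.1 s moving average to round the corners):

| segment | window (s) | default slope / value |
|---|---|---|
| NS1 | [−2.0, −0.5] | −2 µV/s |
| NS2 | [−0.5, 0] | −10 µV/s |
| PN | 0 | −8 µV |
| rebound | [0, +1.0] | +8 µV/s, clamped at baseline |

The template is built from the slopes and rescaled so its minimum equals
`pn_amplitude`; at the defaults the slopes already land exactly at −8 µV so
the scale factor is 1. This keeps the parameter set over-determined but
consistent, and makes slope recovery an exact identity in noise-free runs.

**Topography.** The template is planted at full amplitude on Cz, at 0.5 on
the surrounding ring (FC1, FC2, C3, C4, CP1, CP2), 0.25 on Fz and Pz, and 0
on FP1. Consequence used throughout the tests: the large Laplacian
Cz − mean(Fz, C3, C4, Pz) passes 1 − (0.25+0.5+0.5+0.25)/4 = 0.625 of the
planted waveform while averaging down uncorrelated noise.

**EEG background** per channel: 1/f ("pink") noise with σ = 2 µV (FFT
spectral shaping of white noise), a 2 µV 50 Hz line component with random
phase, and a slow drift (two sinusoids at 0.01 and 0.03 Hz, amplitude up to
5 µV) that the 0.05 Hz band-pass edge must remove.

**EMG.** Baseline Gaussian noise (σ = 2 µV) multiplied by a gain of 10 for
2 s from the movement onset, with 50 ms raised-cosine ramps. The burst being
multiplicative matters for the "noise-free" configuration: EEG noise and all
jitters are zeroed, but the EMG baseline stays on, because a silent baseline
would carry no burst at all.

**Trial planting.** Each trial carries an MRCP + burst with probability
`success_prob` (defaults 0.67 / 0.67 / 0.63 for control / phrase / random —
the condition-level means the analysis should recover). PN time is cue +
midpoint offset + N(0, 0.15 s); EMG onset is cue + midpoint offset +
N(0, 0.1 s). Both are snapped to the sample grid so planted and detectable
times can coincide exactly. The jitter SDs are set so that criterion 1's
±0.5 s windows are satisfiable but not guaranteed (a ±0.5 s window captures
~99.9% of a 0.15 s-SD jitter; the joint PN+EMG requirement plus slope noise
brings recovered rates a few points under the planted probability, see §6).

**Formats.** Signals travel as 16-bit EDF with 1 s records; each channel is
scaled to the digital range from its own physical min/max, so round-trip
error is at most one quantization step. Writing is implemented directly
against the EDF specification; reading goes through `mne.io.read_raw_edf`,
which doubles as an independent check of the writer in the test suite.
Events are CSV; ground truth is JSON.

## 3. Preprocessing

2nd-order Butterworth filters, applied zero-phase (`filtfilt`; the analysis
is offline, so no causality constraint): 48–52 Hz band-stop, then 0.05–3 Hz
band-pass — the MRCP is a sub-3 Hz phenomenon and the 0.05 Hz corner removes
drift without flattening the slow slopes. Epochs are [−4, +5) s around each
cue (half-open at the sample level: 10 800 samples at 1200 Hz), demeaned per
epoch. Two derivations are analysed in parallel: raw Cz and the large
Laplacian around Cz using the available next-nearest ring (Fz, C3, C4, Pz in
the 10-channel montage).

## 4. EMG onset detection

Envelope: 20 Hz high-pass → full-wave rectification → 5 Hz low-pass.
Threshold: baseline mean + 3 SD. The binary supra-threshold mask is cleaned
by morphological closing then opening (50 ms structuring element), and the
onset is the first sample of the first run of at least 1.5 s (a sustained
~2 s movement, tolerating envelope dips).

Two provisions address the *paced* nature of the paradigm, where the
previous trial's burst lies inside the current epoch:

- **Quietest-baseline threshold.** The nominal baseline window is
  [−4, −2] s before the cue, but with a 4 s inter-cue gap the previous burst
  (roughly [−3, −1] s on the current axis) intrudes into it and would inflate
  the threshold ~15-fold. The statistics are therefore taken from the
  quietest 0.5 s sub-window of the baseline, which stays on resting activity.
- **Onset search window.** Only runs *starting* within ±2 s of the expected
  movement time qualify; without this the first supra-threshold run found is
  the previous trial's burst.

Benchmark (`synth_emg_epochs`, 500 bursts at default noise): median absolute
onset error ≈ 38 ms, 90th percentile ≈ 47 ms, no missed bursts, no false
positives on 200 burst-free epochs. The residual bias is the envelope's
low-pass group delay interacting with the threshold crossing; it stays well
inside the ±0.5 s criterion window.

## 5. Trial validation

PN = most negative sample within ±2 s of the expected movement time
(earliest tie wins). A trial is a valid MRCP iff, relative to the expected
movement time *m*:

1. |PN − m| ≤ 0.5 s **and** an EMG onset exists with |EMG − m| ≤ 0.5 s;
2. NS1 < 0, NS2 < 0, rebound > 0 (slopes fitted on the PN-aligned trace);
3. the PN is a local minimum within a 50 ms neighbourhood;
4. *exclusion*: PN earlier than m − 1 s rejects the trial outright (such a
   peak cannot reflect the cued movement).

Numerical detail on (3): a band-limited trace stored at 16-bit EDF
resolution is flat to quantization at a smooth extremum, so consecutive
samples tie at the minimum. The check therefore tolerates ties *at* the
minimum but requires strictly larger values at the ±50 ms neighbourhood
edges; a plateau wider than the neighbourhood still fails. Without this the
criterion silently fails almost every trial after a disk round trip while
passing in memory — the local-minimum rule must not depend on the storage
format.

Success rate = rounded percentage of the 26 trials passing all rules. For
each subject × condition × processing cell, the successful trials are
re-windowed to [−2, +1.5] s around three references — cue, EMG onset, and
PN — giving the three aligned datasets; features and group statistics use
the PN alignment (sharpest averages; other alignments suffer phase
cancellation).

## 6. Features

Per validated, PN-aligned trial: PN amplitude (value at t = 0); NS1, NS2 and
rebound slopes as ordinary-least-squares line fits over [−2, −0.5],
[−0.5, 0] and [0, +1] s (endpoints inclusive); PP = max − min over ±2 s
clipped to the epoch. Subject × condition means feed the statistics.

Recovery at defaults: noise-free runs recover all 26 trials and the planted
slopes to machine precision, with PN timing error of 0 samples. With default
noise ~96% of planted trials are recovered and no noise-only trial passes;
the losses are dominated by criterion 2 — the NS1 window has the smallest
slope (−2 µV/s) and OLS noise on a 1.5 s window occasionally flips its sign —
plus occasional PN jitter beyond the c1 window. This ~4-point gap between
planted probability and recovered rate is a property of the validation
criteria, not a detector bug, and is visible in the worked example.

## 7. Statistics

- **Friedman** omnibus across the three conditions per descriptor and
  processing path, on complete subject × condition tables (subjects with any
  empty cell are dropped, with a log warning). Mid-ranks with the standard
  tie correction. The p-value is the *exact* permutation probability —
  enumerating all (k!)^n within-row orderings via a rank-sum-vector
  convolution — whenever (k!)^n ≤ 500 000 (n ≤ 7 at k = 3), else the χ²(k−1)
  tail. Exactness is verified against a brute-force enumeration oracle to
  1e−12 in the tests.
- **Wilcoxon signed-rank** post-hoc on each condition pair when the Friedman
  test is significant, at the Bonferroni-adjusted alpha 0.05/3 ≈ 0.0167.
  Zero differences are dropped; W is the smaller signed-rank sum. For n ≤ 25
  the two-sided p is exact, computed from the conditional distribution of the
  rank sum via a generating-function recursion over doubled ranks (so
  mid-ranks stay integral); beyond that, the normal approximation with
  tie-corrected variance. Also oracle-verified to 1e−12.
- **Grand averages**: pointwise mean ± SD of the subject-condition mean
  traces per condition.
- **1-D SPM**: pointwise one-way repeated-measures ANOVA over the PN-aligned
  time axis on the (subjects × conditions × time) array of mean traces. The
  pointwise threshold is the parametric F quantile at 1 − α; significance of
  each supra-threshold cluster is assessed by permutation — condition labels
  shuffled within subject, null distribution of the *maximum cluster mass*
  (sum of F − threshold), p = (1 + #{perm ≥ obs}) / (B + 1). This replaces
  random-field-theory correction with a distribution-free equivalent under
  within-subject exchangeability; `estimate_fwer` measures its family-wise
  error on pure-noise simulations at ≈ 0.04–0.05 for the nominal 0.05
  (acceptance requires within three Monte-Carlo SEs of 0.05 over 1000
  simulations). Post-hoc pointwise paired-t curves (Bonferroni-adjusted,
  no cluster correction — reported as descriptive runs) are produced when
  the SPM is significant.

## 8. Determinism

A single master seed drives everything. Named substreams are derived as
`sha256(f"{seed}:{label}") mod 2^31` (cohort, SPM per path, each acceptance
benchmark), and the cohort assigns per-session seeds from a
`numpy.random.SeedSequence`. All derived seeds stay below 2³¹. Two runs with
the same seed are bit-identical down to the EDF bytes on disk.

## 9. Known limits of the generator

- The MRCP template is piecewise linear with fixed shape; real MRCPs vary in
  morphology within and across subjects. Amplitude/shape variability across
  *subjects* is not modelled, so between-subject SDs of the descriptors are
  narrower than in real cohorts.
- All three conditions plant the same template: condition effects on
  descriptors are null by construction. The pipeline *measures* differences;
  the generator does not create them. (Planted success probabilities do
  differ, so success-rate contrasts are real.)
- EEG noise is stationary Gaussian-based (1/f + line + drift); no eye blinks,
  movement artifacts, or electrode drift events, hence no artifact-rejection
  stage.
- EMG is amplitude-modulated noise, not motor-unit physiology; onset shape is
  a clean ramp.
- The speller is simulated at the event level (cue times), not rendered;
  reaction-time variability beyond the PN/EMG jitters is not modelled.
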