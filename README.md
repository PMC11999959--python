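# mrcpspeller

Offline feasibility analysis of a movement-related cortical potential (MRCP)
brain–computer-interface speller, run end to end on ground-truthed synthetic
EEG/EMG.

## Background

An MRCP is a slow cortical potential that develops over motor cortex around a
voluntary movement: a shallow early negative slope (NS1) starting roughly 2 s
before the movement, a steeper late slope (NS2) in the last half second, a
peak negativity (PN) of several microvolts near movement onset, and a positive
rebound back to baseline. Because the MRCP precedes the movement it is a
candidate control signal for brain–computer interfaces operated by people with
limited motor function.

This project asks the feasibility question for a *scanning speller*: a 6×6
character grid in which a moving bar first sweeps the columns and then the
rows of the selected column. The user selects a cell by performing (or
attempting) a cued foot dorsiflexion when the bar reaches the target column or
row. Spelling a 13-character phrase therefore produces 26 cued movements — 26
chances to elicit an MRCP per session. Three conditions vary cognitive load
while keeping the motor task identical: spelling a repeated dummy character
(*control*), a meaningful phrase (*phrase*), and a seeded anagram of that
phrase (*random*).

Human sessions of this paradigm are not reproducible at desk scale, so the
package generates synthetic sessions with planted, ground-truthed MRCPs and
EMG bursts, and then runs the full offline analysis that such a study needs:

1. **Simulate** — plan the cue sequence for each condition; synthesize
   10-channel EEG (1/f noise + 50 Hz mains + drift, with the MRCP template
   planted at Cz and attenuated copies on neighbouring electrodes) and
   tibialis-anterior EMG (baseline noise with multiplicative ~2 s bursts), at
   1200 Hz, written as EDF plus CSV event tables and JSON ground truth.
2. **Preprocess** — 48–52 Hz Butterworth notch, 0.05–3 Hz band-pass
   (zero-phase), and two processing paths: raw Cz and a large Laplacian
   (Cz minus the mean of Fz, C3, C4, Pz).
3. **Validate** — detect the EMG onset (envelope threshold at baseline
   mean + 3 SD with morphological cleaning), find the PN (most negative
   sample near the cued movement), and accept a trial as a valid MRCP only if
   (1) PN and EMG onset both fall within ±0.5 s of the cued movement time,
   (2) NS1 < 0, NS2 < 0 and rebound > 0, (3) the PN is a local minimum within
   a 50 ms neighbourhood, and (4) the PN does not precede the movement time by
   more than 1 s. The success rate is the percentage of the 26 trials passing
   all rules.
4. **Features** — per validated trial: PN amplitude, NS1/NS2/rebound slopes
   (ordinary-least-squares fits over fixed windows relative to PN), and
   peak-to-peak amplitude.
5. **Statistics** — Friedman omnibus across conditions per descriptor (exact
   permutation p-value where enumerable), Wilcoxon signed-rank post-hoc with
   Bonferroni correction, PN-aligned grand averages, and a one-dimensional
   statistical parametric map: pointwise repeated-measures ANOVA over time
   with cluster-level permutation correction.

Because every recording carries its ground truth, the same pipeline doubles
as a test bench: detectors and statistics are scored against the planted
values (see `tests/` and `scripts/acceptance.py`).

## Quick start

Either the CLI:

```bash
mrcpspeller run --out results/run --seed 0
```

or the numbered analysis scripts, which run the same five stages with a
narrative summary each:

```bash
python analysis/01_simulate_cohort.py  --run-dir results/run --seed 0
python analysis/02_preprocess.py       --run-dir results/run
python analysis/03_validate_trials.py  --run-dir results/run
python analysis/04_extract_features.py --run-dir results/run
python analysis/05_statistics.py       --run-dir results/run --seed 0
```

A full default study (13 subjects × 3 conditions, both processing paths,
1000 SPM permutations) takes about one minute on one CPU and writes ~350 MB
of intermediate EDF under the run directory.

## Worked example

Output of the commands above with `--seed 0` (your numbers will match exactly;
everything is derived deterministically from the seed):

```
simulated 39 subject-condition sessions (13 subjects x 3 conditions, 1200 Hz) under results/run/data
filtered recordings (cz + laplacian) written under results/run/filtered
assessed 2028 trials (56.5% validated overall)
  mean success rate [cz] - control: 64.9%, phrase: 61.5%, random: 56.6%
  mean success rate [laplacian] - control: 55.7%, phrase: 50.6%, random: 50.0%
descriptor means for 78 subject-condition cells (pn_uv, ns1_uv_per_s, ns2_uv_per_s, rebound_uv_per_s, pp_uv)
  mean PN amplitude [cz] - control: -6.86 uV, phrase: -6.82 uV, random: -6.64 uV
  mean PN amplitude [laplacian] - control: -4.76 uV, phrase: -4.76 uV, random: -4.53 uV
[cz]
  Friedman              pn_uv: chi2 =  2.000, p = 0.3679
  Friedman       ns1_uv_per_s: chi2 =  0.462, p = 0.7939
  Friedman       ns2_uv_per_s: chi2 =  4.769, p = 0.0921
  Friedman   rebound_uv_per_s: chi2 =  7.538, p = 0.0231 *
  Friedman              pp_uv: chi2 =  1.077, p = 0.5836
  SPM: 39 mean traces, F threshold 3.40, 2 supra-threshold cluster(s)
    cluster [-1.83, -1.37] s, p = 0.021
    cluster [+0.09, +0.20] s, p = 0.491
[laplacian]
  Friedman              pn_uv: chi2 =  5.692, p = 0.0581
  Friedman       ns1_uv_per_s: chi2 =  0.462, p = 0.7939
  Friedman       ns2_uv_per_s: chi2 =  2.462, p = 0.2921
  Friedman   rebound_uv_per_s: chi2 =  3.846, p = 0.1462
  Friedman              pp_uv: chi2 =  2.000, p = 0.3679
  SPM: 39 mean traces, F threshold 3.40, 3 supra-threshold cluster(s)
    cluster [+0.13, +0.23] s, p = 0.590
    cluster [+0.30, +0.41] s, p = 0.526
    cluster [+0.67, +0.73] s, p = 0.563
```

Reading the output: the three conditions were generated with success
probabilities 0.67 / 0.67 / 0.63, and the recovered mean success rates on the
Cz path (64.9 / 61.5 / 56.6%) sit a few points below those targets — the
validation criteria discard a small fraction of genuinely planted MRCPs whose
noisy slope estimates flip sign (see `docs/methods.md`). The Laplacian path
runs lower because the derivation scales the planted signal by 0.625 while
noise is uncorrelated across electrodes. The generator plants the *same*
MRCP template in every condition, so descriptor differences between
conditions are null by construction; the one nominally significant Friedman
result above (rebound slope, p = 0.023, with only the phrase-vs-random
post-hoc surviving Bonferroni at 0.0167) and the one SPM cluster at p = 0.021
are the kind of borderline findings a 5%-level analysis produces now and then
on null data — a useful reminder of what the machinery does and does not
guarantee on a single cohort.

The run directory also contains, per processing path, the subjects ×
conditions success table with MEAN/SD rows (`success-table-*.csv`), the SPM
F-curve (`spm-curve-*.csv`), a grand-average figure (`grand-average-*.png`),
and `stats-report.json` with every test result.

## Configuration

All tunables live in one YAML-serialisable `StudyConfig` (subjects,
conditions, success probabilities, template shape, noise levels, filters, EMG
detector, slope windows, alignment, statistics options):

```bash
python - <<'EOF'
from mrcpspeller import StudyConfig
StudyConfig(n_subjects=5).to_yaml("small.yaml")
EOF
mrcpspeller run --config small.yaml --out results/small --seed 7
```

`StudyConfig().noise_free()` is the all-signal variant used by the
parameter-recovery tests.

## Project layout

```
src/mrcpspeller/   the package: speller, synth, io_formats, preprocess,
                   emg, validate, features, stats, config, pipeline, cli
analysis/          numbered narrative drivers for a full study run
scripts/           acceptance.py (recompute headline numbers as JSON)
tests/             pytest suite incl. test_acceptance.py
docs/methods.md    methods note: models, parameters, design choices, limits
```
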