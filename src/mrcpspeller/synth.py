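"""Ground-truthed synthetic EEG/EMG realising a speller session plan.

Every cued trial either carries a planted movement-related cortical
potential (MRCP) on Cz — two negative slopes, a peak negativity (PN) near
the expected movement time, then a rebound — together with a tibialis
anterior EMG burst, or it carries background noise only.  The generator
records every planted PN time and EMG onset so downstream detectors can be
scored against ground truth.

Background EEG is 1/f ("pink") noise plus 50 Hz mains and a slow drift;
EMG is broadband Gaussian noise whose amplitude is multiplied during the
burst.  The MRCP is strongest at Cz with attenuated copies on neighbouring
electrodes, so the large Laplacian shrinks but does not remove it.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io_formats import Recording, write_edf, write_events
from .speller import CONDITIONS, SessionPlan, TimingSpec, build_layout, plan_condition, simulate_session

__all__ = [
    "EEG_CHANNELS",
    "EMG_CHANNEL",
    "MRCP_SPREAD",
    "MRCPTemplateParams",
    "NoiseParams",
    "TrialTruth",
    "GroundTruth",
    "mrcp_template",
    "pink_noise",
    "synth_subject",
    "synth_emg_epochs",
    "synth_cohort",
]

EEG_CHANNELS = ("FP1", "Fz", "FC1", "FC2", "C3", "Cz", "C4", "CP1", "CP2", "Pz")
EMG_CHANNEL = "EMG_TA"

#: fraction of the Cz MRCP waveform projected onto each electrode
MRCP_SPREAD = {
    "Cz": 1.0,
    "FC1": 0.5,
    "FC2": 0.5,
    "C3": 0.5,
    "C4": 0.5,
    "CP1": 0.5,
    "CP2": 0.5,
    "Fz": 0.25,
    "Pz": 0.25,
    "FP1": 0.0,
}

#: sustained-movement duration emulated by the EMG burst, seconds
EMG_BURST_DURATION_S = 2.0
#: raised-cosine onset/offset ramp of the burst envelope, seconds
EMG_RAMP_S = 0.05


@dataclass(frozen=True)
class MRCPTemplateParams:
    """Piecewise-linear MRCP template, time relative to PN.

    Slopes are µV/s; the early shallow negativity (NS1) runs from
    ``-ns1_start_s`` to ``-ns2_start_s``, the steep late negativity (NS2)
    from ``-ns2_start_s`` to the PN at time 0, and the rebound rises at
    ``rebound_slope`` until the trace returns to baseline.  The waveform is
    rescaled so the minimum equals ``pn_amplitude`` (at the defaults the
    slopes already land there, so the scale factor is exactly 1).  Corners
    are optionally smoothed by a moving average of width ``smoothing_s``.
    """

    ns1_slope: float = -2.0
    ns2_slope: float = -10.0
    pn_amplitude: float = -8.0
    rebound_slope: float = 8.0
    ns1_start_s: float = 2.0
    ns2_start_s: float = 0.5
    smoothing_s: float = 0.1

    def __post_init__(self) -> None:
        if not (self.ns1_slope < 0 and self.ns2_slope < self.ns1_slope):
            raise ValueError("need ns2_slope < ns1_slope < 0")
        if self.rebound_slope <= 0:
            raise ValueError("rebound_slope must be positive")
        if not (self.ns1_start_s > self.ns2_start_s > 0):
            raise ValueError("need ns1_start_s > ns2_start_s > 0")
        if self.pn_amplitude >= 0:
            raise ValueError("pn_amplitude must be negative")
        if self.smoothing_s < 0:
            raise ValueError("smoothing_s must be non-negative")

    @property
    def unscaled_min(self) -> float:
        return self.ns1_slope * (self.ns1_start_s - self.ns2_start_s) + self.ns2_slope * self.ns2_start_s

    @property
    def rebound_end_s(self) -> float:
        """Time after PN at which the rebound returns to baseline."""
        return -self.pn_amplitude / self.rebound_slope


@dataclass(frozen=True)
class NoiseParams:
    """Background-activity and jitter settings (µV / seconds).

    ``emg_burst_gain`` multiplies the EMG baseline noise during a burst;
    ``pn_jitter_s`` / ``emg_onset_jitter_s`` are the SDs of the planted PN
    time and EMG onset around the expected movement time.
    """

    pink_sigma: float = 2.0
    line_amp: float = 2.0
    drift_amp: float = 5.0
    emg_baseline_sigma: float = 2.0
    emg_burst_gain: float = 10.0
    emg_onset_jitter_s: float = 0.1
    pn_jitter_s: float = 0.15

    def __post_init__(self) -> None:
        if any(v < 0 for v in asdict(self).values()):
            raise ValueError("noise parameters must be non-negative")

    @classmethod
    def noiseless(cls) -> "NoiseParams":
        """EEG noise and jitters off.

        The EMG baseline noise stays on: the burst is multiplicative on the
        baseline, so a silent baseline would carry no burst at all and
        movement confirmation would be impossible.
        """
        return cls(
            pink_sigma=0.0,
            line_amp=0.0,
            drift_amp=0.0,
            emg_onset_jitter_s=0.0,
            pn_jitter_s=0.0,
        )


@dataclass(frozen=True)
class TrialTruth:
    trial_idx: int
    cue_onset_s: float
    mrcp_present: bool
    true_pn_time_s: float | None  # absolute session time
    true_emg_onset_s: float | None


@dataclass(frozen=True)
class GroundTruth:
    subject: str
    condition: str
    success_prob: float
    seed: int
    trials: tuple[TrialTruth, ...]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "subject": self.subject,
            "condition": self.condition,
            "success_prob": self.success_prob,
            "seed": self.seed,
            "trials": [asdict(t) for t in self.trials],
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        trials = tuple(TrialTruth(**t) for t in payload.pop("trials"))
        return cls(trials=trials, **payload)


def mrcp_template(params: MRCPTemplateParams, time_axis: np.ndarray) -> np.ndarray:
    """Evaluate the MRCP template (µV) on a time axis relative to PN.

    Zero before ``-ns1_start_s``; NS1 then NS2 slopes down to the PN at
    time 0; rebound back up to baseline, flat afterwards.  A moving-average
    of width ``smoothing_s`` rounds the corners (skipped when the axis
    spacing cannot resolve it).
    """
    t = np.asarray(time_axis, dtype=float)
    if t.size < 2:
        raise ValueError("time axis too short")
    if t[0] > -params.ns1_start_s or t[-1] < params.rebound_end_s:
        raise ValueError(
            "time axis must cover the template support "
            f"[{-params.ns1_start_s}, {params.rebound_end_s}] s"
        )
    v1 = params.ns1_slope * (params.ns1_start_s - params.ns2_start_s)
    w = np.zeros_like(t)
    seg1 = (t >= -params.ns1_start_s) & (t < -params.ns2_start_s)
    w[seg1] = params.ns1_slope * (t[seg1] + params.ns1_start_s)
    seg2 = (t >= -params.ns2_start_s) & (t < 0)
    w[seg2] = v1 + params.ns2_slope * (t[seg2] + params.ns2_start_s)
    unscaled_min = params.unscaled_min
    seg3 = (t >= 0) & (t <= params.rebound_end_s * unscaled_min / params.pn_amplitude)
    w[seg3] = unscaled_min + params.rebound_slope * t[seg3]
    w[w > 0] = 0.0  # rebound clamps at baseline
    w *= params.pn_amplitude / unscaled_min

    if params.smoothing_s > 0:
        dt = float(np.median(np.diff(t)))
        n = int(round(params.smoothing_s / dt))
        if n > 1:
            kernel = np.ones(n) / n
            w = np.convolve(w, kernel, mode="same")
    return w


def pink_noise(rng: np.random.Generator, n: int, sigma: float, exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent noise of length ``n`` scaled to standard deviation ``sigma``."""
    if sigma == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spectrum * scale, n)
    std = out.std()
    return out * (sigma / std) if std > 0 else out


def _burst_envelope(n_samples: int, rate: float) -> np.ndarray:
    """Unit gain envelope of one sustained burst with raised-cosine ramps."""
    seg = np.ones(n_samples)
    n_ramp = int(round(EMG_RAMP_S * rate))
    if n_ramp > 1 and n_samples > 2 * n_ramp:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        seg[:n_ramp] = ramp
        seg[-n_ramp:] = ramp[::-1]
    return seg


def synth_emg_epochs(
    n_epochs: int,
    noise: NoiseParams | None = None,
    window: tuple[float, float] = (-4.0, 5.0),
    onset_range_s: tuple[float, float] = (0.5, 1.5),
    rate: float = 1200.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stand-alone EMG burst epochs for onset-detector benchmarking.

    Returns ``(epochs, times, true_onsets)``: each epoch is baseline noise
    with one ~2 s burst whose onset is drawn uniformly from
    ``onset_range_s`` and snapped to the sample grid, using the same burst
    model as :func:`synth_subject`.
    """
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)
    i_lo, i_hi = int(round(window[0] * rate)), int(round(window[1] * rate))
    times = np.arange(i_lo, i_hi) / rate
    n = times.size
    epochs = rng.standard_normal((n_epochs, n)) * noise.emg_baseline_sigma
    onsets = np.empty(n_epochs)
    for i in range(n_epochs):
        onset = rng.uniform(*onset_range_s)
        onset = round(onset * rate) / rate
        onsets[i] = onset
        b0 = int(round(onset * rate)) - i_lo
        b1 = min(n, b0 + int(round(EMG_BURST_DURATION_S * rate)))
        env = np.zeros(n)
        env[b0:b1] = _burst_envelope(b1 - b0, rate)
        epochs[i] *= 1.0 + (noise.emg_burst_gain - 1.0) * env
    return epochs, times, onsets


def _session_duration_s(plan: SessionPlan, epoch_tail_s: float = 6.0) -> float:
    last = plan.events[-1].onset_s if plan.events else 0.0
    return math.ceil(last + epoch_tail_s)


def synth_subject(
    plan: SessionPlan,
    tpl: MRCPTemplateParams | None = None,
    noise: NoiseParams | None = None,
    success_prob: float = 1.0,
    seed: int = 0,
    rate: float = 1200.0,
    subject: str = "S01",
) -> tuple[Recording, Recording, GroundTruth]:
    """Synthesize one subject-condition recording pair plus ground truth.

    With probability ``success_prob`` a trial receives an MRCP whose PN is
    jittered around cue + midpoint offset, and an EMG burst with a jittered
    onset; other trials get background noise only.
    """
    if not 0.0 <= success_prob <= 1.0:
        raise ValueError("success_prob must lie in [0, 1]")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    tpl = tpl or MRCPTemplateParams()
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)

    n = int(round(_session_duration_s(plan) * rate))
    times = np.arange(n) / rate
    n_eeg = len(EEG_CHANNELS)

    eeg = np.zeros((n_eeg, n))
    for c in range(n_eeg):
        eeg[c] += pink_noise(rng, n, noise.pink_sigma)
        if noise.line_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            eeg[c] += noise.line_amp * np.sin(2 * np.pi * 50.0 * times + phase)
        if noise.drift_amp > 0:
            # slow drift below 0.05 Hz: two very-low-frequency sinusoids
            for f in (0.01, 0.03):
                eeg[c] += noise.drift_amp * rng.uniform(0.3, 1.0) * np.sin(
                    2 * np.pi * f * times + rng.uniform(0, 2 * np.pi)
                )

    emg = rng.standard_normal(n) * noise.emg_baseline_sigma
    burst_env = np.zeros(n)  # extra gain envelope, 0 at baseline

    spread = np.array([MRCP_SPREAD[ch] for ch in EEG_CHANNELS])
    midpoint = plan.timing.midpoint_offset_s
    truths: list[TrialTruth] = []
    for ev in plan.events:
        present = bool(rng.random() < success_prob)
        if not present:
            truths.append(TrialTruth(ev.trial_idx, ev.onset_s, False, None, None))
            continue
        pn_time = ev.onset_s + midpoint + rng.normal(0.0, noise.pn_jitter_s)
        emg_onset = ev.onset_s + midpoint + rng.normal(0.0, noise.emg_onset_jitter_s)
        # snap to the sample grid so planted and detectable times coincide
        pn_time = round(pn_time * rate) / rate
        emg_onset = round(emg_onset * rate) / rate

        lo = max(0, int(round((pn_time - tpl.ns1_start_s) * rate)) - 1)
        hi = min(n, int(round((pn_time + tpl.rebound_end_s) * rate)) + 2)
        pad = 0
        if tpl.smoothing_s > 0:  # widen so the moving average sees the flanks
            pad = int(round(tpl.smoothing_s * rate)) + 1
            lo, hi = max(0, lo - pad), min(n, hi + pad)
        wave = mrcp_template(tpl, times[lo:hi] - pn_time) if hi > lo else np.zeros(0)
        eeg[:, lo:hi] += spread[:, None] * wave[None, :]

        b0 = int(round(emg_onset * rate))
        b1 = min(n, b0 + int(round(EMG_BURST_DURATION_S * rate)))
        if b0 < n:
            seg = _burst_envelope(b1 - b0, rate)
            burst_env[b0:b1] = np.maximum(burst_env[b0:b1], seg)
        truths.append(TrialTruth(ev.trial_idx, ev.onset_s, True, pn_time, emg_onset))

    emg *= 1.0 + (noise.emg_burst_gain - 1.0) * burst_env

    eeg_rec = Recording(eeg, rate, EEG_CHANNELS)
    emg_rec = Recording(emg[None, :], rate, (EMG_CHANNEL,))
    truth = GroundTruth(subject, plan.condition, success_prob, seed, tuple(truths))
    return eeg_rec, emg_rec, truth


def synth_cohort(
    out_dir: str | Path,
    n_subjects: int = 13,
    conditions: tuple[str, ...] = CONDITIONS,
    success_probs: dict[str, float] | None = None,
    tpl: MRCPTemplateParams | None = None,
    noise: NoiseParams | None = None,
    timing: TimingSpec | None = None,
    seed: int = 0,
    rate: float = 1200.0,
) -> list[dict]:
    """Write a full synthetic cohort to ``out_dir`` and return its manifest.

    One EEG EDF, one EMG EDF, one event CSV and one ground-truth JSON per
    subject x condition; the default success probabilities per condition are
    the study-level mean success rates (control/phrase ≈ 0.67, random 0.63).
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    success_probs = success_probs or {"control": 0.67, "phrase": 0.67, "random": 0.63}
    timing = timing or TimingSpec()
    layout = build_layout()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(n_subjects * len(conditions) + 1) % (2**31)]

    manifest: list[dict] = []
    k = 0
    for i in range(n_subjects):
        subject = f"S{i + 1:02d}"
        for cond in conditions:
            sub_seed = child_seeds[k]
            k += 1
            phrase = plan_condition(cond, seed=sub_seed)
            plan = simulate_session(phrase, layout, timing, condition=cond)
            eeg, emg, truth = synth_subject(
                plan,
                tpl=tpl,
                noise=noise,
                success_prob=success_probs.get(cond, 0.67),
                seed=sub_seed,
                rate=rate,
                subject=subject,
            )
            stem = f"{subject}_{cond}"
            entry = {
                "subject": subject,
                "condition": cond,
                "seed": sub_seed,
                "eeg": f"{stem}_eeg.edf",
                "emg": f"{stem}_emg.edf",
                "events": f"{stem}_events.csv",
                "truth": f"{stem}_truth.json",
            }
            write_edf(eeg, out_dir / entry["eeg"])
            write_edf(emg, out_dir / entry["emg"])
            write_events(plan.to_frame(), out_dir / entry["events"])
            truth.to_json(out_dir / entry["truth"])
            manifest.append(entry)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
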