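"""Filtering, epoching, demeaning and the large Laplacian spatial filter.

The processing chain mirrors an offline MRCP pipeline: 50 Hz notch
(2nd-order Butterworth band-stop), 0.05-3 Hz band-pass (2nd-order
Butterworth), epoching from 4 s before to 5 s after each cue, per-epoch
demeaning, and a large Laplacian centred on Cz.  Filters run zero-phase
(forward-backward) by default since the analysis is offline; note this
doubles the effective order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .io_formats import Recording

__all__ = [
    "FilterSpec",
    "EpochSet",
    "apply_filter",
    "segment_epochs",
    "demean_epochs",
    "large_laplacian",
    "LAPLACIAN_RING",
]

#: next-nearest neighbours of Cz available in the 10-channel montage
LAPLACIAN_RING = ("Fz", "C3", "C4", "Pz")


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter settings.

    ``band`` is (low, high) in Hz; a notch is realised as a band-stop over
    the band, a bandpass passes it.  ``zero_phase`` selects
    forward-backward application (no group delay, squared magnitude).
    """

    kind: str  # 'notch' | 'bandpass'
    band: tuple[float, float]
    order: int = 2
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("notch", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        low, high = self.band
        if not 0 < low < high:
            raise ValueError("band must satisfy 0 < low < high")

    @classmethod
    def notch(cls, band: tuple[float, float] = (48.0, 52.0), **kw) -> "FilterSpec":
        return cls("notch", band, **kw)

    @classmethod
    def bandpass(cls, band: tuple[float, float] = (0.05, 3.0), **kw) -> "FilterSpec":
        return cls("bandpass", band, **kw)


@dataclass
class EpochSet:
    """Per-trial windows of one derived channel.

    data
        ``(n_trials, n_samples)`` array, µV.
    times
        Shared time axis, seconds relative to ``reference``.
    reference
        Name of the alignment point: 'cue', 'emg' or 'pn'.
    """

    data: np.ndarray
    times: np.ndarray
    reference: str
    rate: float
    trial_ids: np.ndarray
    condition: str | None = None
    subject: str | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.data.shape[1] != self.times.size:
            raise ValueError("time axis length must match epoch length")
        if self.data.shape[0] != self.trial_ids.size:
            raise ValueError("one trial id per epoch required")
        dt = np.diff(self.times)
        if self.times.size > 1 and not np.allclose(dt, 1.0 / self.rate, rtol=1e-6, atol=1e-9):
            raise ValueError("time axis must increase at 1/rate spacing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            self.data[mask], self.times, self.reference, self.rate,
            self.trial_ids[mask], self.condition, self.subject,
        )


def _design(spec: FilterSpec, rate: float):
    nyq = rate / 2.0
    low, high = spec.band
    if high >= nyq:
        raise ValueError(f"filter band {spec.band} exceeds Nyquist ({nyq} Hz)")
    btype = "bandstop" if spec.kind == "notch" else "bandpass"
    return signal.butter(spec.order, [low / nyq, high / nyq], btype=btype)


def apply_filter(rec: Recording, spec: FilterSpec) -> Recording:
    """Filter every channel of ``rec``; zero-phase by default."""
    b, a = _design(spec, rec.rate)
    if spec.zero_phase:
        out = signal.filtfilt(b, a, rec.samples, axis=1)
    else:
        out = signal.lfilter(b, a, rec.samples, axis=1)
    return Recording(out, rec.rate, rec.labels, rec.start_time)


def segment_epochs(
    rec: Recording,
    events: pd.DataFrame,
    window: tuple[float, float] = (-4.0, 5.0),
    channel: str | None = None,
) -> EpochSet:
    """Cut one epoch per cue event from a single (or named) channel.

    Epochs use the half-open sample convention [onset + window[0],
    onset + window[1]); time 0 is the cue.  An event whose window leaves the
    recording is an error reporting the trial id.
    """
    if channel is None:
        if rec.n_channels != 1:
            raise ValueError("recording has several channels; name one")
        trace = rec.samples[0]
    else:
        trace = rec.channel(channel)
    rate = rec.rate
    i_lo = int(round(window[0] * rate))
    i_hi = int(round(window[1] * rate))
    n_samp = i_hi - i_lo
    times = np.arange(i_lo, i_hi) / rate

    rows = []
    for onset, trial in zip(events["onset_s"], events["trial_idx"]):
        center = int(round((onset - rec.start_time) * rate))
        lo, hi = center + i_lo, center + i_hi
        if lo < 0 or hi > trace.size:
            raise ValueError(
                f"trial {trial}: epoch window [{onset + window[0]:.2f}, "
                f"{onset + window[1]:.2f}] s leaves the recording"
            )
        rows.append(trace[lo:hi])
    data = np.stack(rows) if rows else np.empty((0, n_samp))
    return EpochSet(data, times, "cue", rate, np.asarray(events["trial_idx"]))


def demean_epochs(epochs: EpochSet) -> EpochSet:
    """Subtract each trial's own mean (per-epoch offset correction)."""
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return replace(epochs, data=data)


def large_laplacian(
    rec: Recording,
    center: str = "Cz",
    ring: tuple[str, ...] = LAPLACIAN_RING,
) -> Recording:
    """Large Laplacian derivation: center minus the mean of its ring.

    Sharpens activity local to the center electrode by rejecting the
    common mode shared with the surrounding ring.
    """
    center_trace = rec.channel(center)
    ring_traces = np.stack([rec.channel(ch) for ch in ring])
    out = center_trace - ring_traces.mean(axis=0)
    return Recording(out[None, :], rec.rate, (f"{center}-lap",), rec.start_time)
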