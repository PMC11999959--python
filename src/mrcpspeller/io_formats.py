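"""On-disk interchange formats: EDF for continuous signals, CSV for events.

Continuous multichannel recordings travel as plain EDF (16-bit, one-second
data records).  Writing is implemented here directly against the EDF
specification; reading goes through :func:`mne.io.read_raw_edf`, which also
serves as an independent check of the writer in the test suite.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "read_edf",
    "write_edf",
    "read_events",
    "write_events",
]

_EVENT_COLUMNS = ["onset_s", "type", "target_char", "trial_idx", "condition"]

_DIG_MIN, _DIG_MAX = -32768, 32767


@dataclass
class Recording:
    """Continuous multichannel signal in microvolts.

    samples
        ``(n_channels, n_samples)`` float array, µV.
    rate
        Sampling rate, Hz.
    labels
        Unique channel names, one per row of ``samples``.
    start_time
        Session time of the first sample, seconds.
    """

    samples: np.ndarray
    rate: float
    labels: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.labels = tuple(self.labels)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.samples.shape[0] != len(self.labels):
            raise ValueError("one label per channel row required")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording {self.labels}") from None

    def pick(self, labels: "tuple[str, ...] | list[str]") -> "Recording":
        data = np.stack([self.channel(lb) for lb in labels])
        return Recording(data, self.rate, tuple(labels), self.start_time)

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate


def _pad_ascii(value: str, width: int) -> bytes:
    raw = value.encode("ascii", errors="replace")[:width]
    return raw.ljust(width)


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write ``rec`` as plain EDF with 1-second data records.

    Each channel is scaled independently onto the 16-bit digital range from
    its own physical min/max, so the round-trip error is at most one
    quantization step per channel.  The duration must be a whole number of
    seconds and the rate an integer (EDF stores samples-per-record as an
    integer).
    """
    path = Path(path)
    rate = int(round(rec.rate))
    if abs(rate - rec.rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    if rec.n_samples % rate:
        raise ValueError(
            "EDF writer requires a whole number of seconds "
            f"({rec.n_samples} samples at {rate} Hz)"
        )
    n_records = rec.n_samples // rate
    n_ch = rec.n_channels

    phys_min = rec.samples.min(axis=1)
    phys_max = rec.samples.max(axis=1)
    # degenerate (constant) channels still need a non-zero physical span
    flat = phys_max - phys_min <= 0
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)

    gain = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.rint((rec.samples - phys_min[:, None]) * gain[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad_ascii("0", 8),  # version
            _pad_ascii("X X X X", 80),  # patient id
            _pad_ascii("Startdate 01-JAN-2000 X X X", 80),  # recording id
            _pad_ascii(now.strftime("%d.%m.%y"), 8),
            _pad_ascii(now.strftime("%H.%M.%S"), 8),
            _pad_ascii(str(256 * (n_ch + 1)), 8),  # header bytes
            _pad_ascii("", 44),  # reserved
            _pad_ascii(str(n_records), 8),
            _pad_ascii("1", 8),  # record duration, s
            _pad_ascii(str(n_ch), 4),
        ]
    )

    def per_channel(values: list[str], width: int) -> bytes:
        return b"".join(_pad_ascii(v, width) for v in values)

    header += per_channel(list(rec.labels), 16)
    header += per_channel(["Active electrode"] * n_ch, 80)
    header += per_channel(["uV"] * n_ch, 8)
    header += per_channel([f"{v:.6g}" for v in phys_min], 8)
    header += per_channel([f"{v:.6g}" for v in phys_max], 8)
    header += per_channel([str(_DIG_MIN)] * n_ch, 8)
    header += per_channel([str(_DIG_MAX)] * n_ch, 8)
    header += per_channel([""] * n_ch, 80)  # prefiltering
    header += per_channel([str(rate)] * n_ch, 8)  # samples per record
    header += per_channel([""] * n_ch, 32)  # reserved

    # records: per record, all samples of ch0, then ch1, ...
    body = (
        digital.reshape(n_ch, n_records, rate)
        .transpose(1, 0, 2)
        .tobytes()
    )
    path.write_bytes(header + body)
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (µV)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    return Recording(data, raw.info["sfreq"], tuple(raw.ch_names))


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    """Write a cue-event table as CSV (columns fixed by the plan format)."""
    missing = [c for c in _EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing columns {missing}")
    path = Path(path)
    events[_EVENT_COLUMNS].to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    """Read and validate a cue-event CSV.

    Rows are returned sorted by onset.  Trial indices must be unique: every
    cue is its own trial.
    """
    path = Path(path)
    events = pd.read_csv(path)
    missing = [c for c in _EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if events["trial_idx"].duplicated().any():
        dupes = sorted(events.loc[events["trial_idx"].duplicated(), "trial_idx"])
        raise ValueError(f"{path}: duplicate trial indices {dupes}")
    events = events.sort_values("onset_s", kind="stable").reset_index(drop=True)
    if not events["onset_s"].is_monotonic_increasing:
        raise ValueError(f"{path}: onsets are not sortable to monotone order")
    return events
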