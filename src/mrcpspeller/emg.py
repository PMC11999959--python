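"""Tibialis-anterior EMG movement-onset detection.

A baseline-relative threshold plus binary morphology: the rectified,
smoothed EMG envelope is binarised at baseline mean + k·SD, cleaned with
morphological closing then opening, and the onset is the start of the first
supra-threshold run long enough to reflect a sustained (~2 s) movement.
Because the threshold is baseline-relative the detection is invariant to
overall EMG gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

__all__ = ["EMGOnsetParams", "emg_envelope", "detect_onset"]


@dataclass(frozen=True)
class EMGOnsetParams:
    """Envelope, threshold and morphology settings.

    hp_cutoff / lp_cutoff
        Envelope chain: high-pass (Hz), full-wave rectification, low-pass.
    k_threshold
        Threshold in baseline SDs above the baseline envelope mean.
    struct_len_s
        Structuring-element length for closing/opening (bridges gaps and
        removes blips shorter than this).
    min_burst_s
        Minimum accepted supra-threshold run.
    baseline_window
        Interval relative to the cue used as baseline.
    baseline_segment_s
        Length of the quietest sub-window of the baseline actually used for
        the threshold statistics.  In a paced paradigm the previous trial's
        burst can intrude into the fixed baseline interval; taking the
        sub-window with the lowest envelope keeps the threshold on resting
        activity.
    """

    hp_cutoff: float = 20.0
    lp_cutoff: float = 5.0
    k_threshold: float = 3.0
    struct_len_s: float = 0.05
    min_burst_s: float = 1.5
    baseline_window: tuple[float, float] = (-4.0, -2.0)
    baseline_segment_s: float = 0.5

    def __post_init__(self) -> None:
        if min(self.hp_cutoff, self.lp_cutoff, self.k_threshold,
               self.struct_len_s, self.min_burst_s) <= 0:
            raise ValueError("all parameters must be positive")
        lo, hi = self.baseline_window
        if not lo < hi <= 0:
            raise ValueError("baseline window must precede the cue")


def emg_envelope(trace: np.ndarray, rate: float, params: EMGOnsetParams | None = None) -> np.ndarray:
    """Linear envelope: high-pass, full-wave rectify, low-pass."""
    params = params or EMGOnsetParams()
    nyq = rate / 2.0
    if params.hp_cutoff >= nyq or params.lp_cutoff >= nyq:
        raise ValueError("envelope cutoffs must be below Nyquist")
    trace = np.asarray(trace, dtype=float)
    if np.allclose(trace, 0.0):
        return np.zeros_like(trace)
    b, a = signal.butter(2, params.hp_cutoff / nyq, btype="highpass")
    hp = signal.filtfilt(b, a, trace)
    rect = np.abs(hp)
    b, a = signal.butter(2, params.lp_cutoff / nyq, btype="lowpass")
    env = signal.filtfilt(b, a, rect)
    return np.clip(env, 0.0, None)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, stop) index pairs."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def _baseline_stats(env: np.ndarray, base_mask: np.ndarray, rate: float,
                    segment_s: float) -> tuple[float, float]:
    """Mean and SD of the quietest ``segment_s`` stretch of the baseline."""
    base = env[base_mask]
    n_seg = min(base.size, max(2, int(round(segment_s * rate))))
    if base.size <= n_seg:
        return float(base.mean()), float(base.std())
    step = max(1, n_seg // 5)
    starts = range(0, base.size - n_seg + 1, step)
    best = min(starts, key=lambda s: base[s : s + n_seg].mean())
    seg = base[best : best + n_seg]
    return float(seg.mean()), float(seg.std())


def detect_onset(
    trace: np.ndarray,
    times: np.ndarray,
    rate: float,
    params: EMGOnsetParams | None = None,
    search_window: tuple[float, float] | None = None,
) -> float | None:
    """Movement onset (s, on the epoch's time axis) or None.

    The envelope is thresholded at baseline mean + k·SD, the binary mask is
    closed then opened with a ``struct_len_s`` element, and the onset is the
    first sample of the first run no shorter than ``min_burst_s``.  When
    ``search_window`` is given, only runs *starting* inside it qualify —
    in a paced paradigm the epoch also contains the neighbouring trials'
    bursts, which are not candidate movements for this cue.
    """
    params = params or EMGOnsetParams()
    times = np.asarray(times, dtype=float)
    lo, hi = params.baseline_window
    base_mask = (times >= lo) & (times <= hi)
    if not base_mask.any():
        raise ValueError("baseline window lies outside the epoch")

    env = emg_envelope(trace, rate, params)
    mean, sd = _baseline_stats(env, base_mask, rate, params.baseline_segment_s)
    threshold = mean + params.k_threshold * sd
    active = env > threshold

    n_struct = max(1, int(round(params.struct_len_s * rate)))
    structure = np.ones(n_struct, dtype=bool)
    active = ndimage.binary_closing(active, structure=structure)
    active = ndimage.binary_opening(active, structure=structure)

    min_len = int(round(params.min_burst_s * rate))
    for start, stop in _runs(active):
        if stop - start < min_len:
            continue
        onset = float(times[start])
        if search_window is not None and not (search_window[0] <= onset <= search_window[1]):
            continue
        return onset
    return None
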