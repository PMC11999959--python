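"""Peak-negativity detection, per-trial MRCP acceptance criteria, success
rates, and re-alignment of epochs to cue / EMG onset / PN.

A trial counts as a successful MRCP elicitation when, relative to the cued
movement time: (1) both the peak negativity (PN) and the EMG onset fall
within ±0.5 s; (2) the trace shows two negative pre-PN slopes followed by a
positive rebound slope; (3) the PN is a strict local minimum; and the trial
is rejected outright when the PN precedes the movement time by more than
1 s (it cannot then reflect the cued movement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EpochSet

__all__ = [
    "TrialAssessment",
    "SuccessSummary",
    "detect_pn",
    "evaluate_criteria",
    "success_rate",
    "realign_epochs",
]

#: half-width of the acceptance window around the movement time, s
CRITERION_WINDOW_S = 0.5
#: PN earlier than this before the movement time rejects the trial, s
EARLY_PN_LIMIT_S = 1.0
#: neighbourhood for the strict-local-minimum check, s
LOCAL_MIN_NEIGHBORHOOD_S = 0.05


@dataclass(frozen=True)
class TrialAssessment:
    """Validation verdict for one trial (times on the epoch's cue axis)."""

    trial_idx: int
    pn_time_s: float
    pn_amplitude_uv: float
    emg_onset_s: float | None
    c1: bool
    c2: bool
    c3: bool
    rejected_early_pn: bool
    success: bool


@dataclass(frozen=True)
class SuccessSummary:
    subject: str
    condition: str
    processing: str  # 'cz' | 'laplacian'
    n_success: int
    n_total: int

    @property
    def success_rate_pct(self) -> int:
        return int(round(100.0 * self.n_success / self.n_total))


def detect_pn(
    times: np.ndarray,
    trace: np.ndarray,
    window: tuple[float, float] = (-2.0, 2.0),
) -> tuple[float, float]:
    """PN = global minimum of ``trace`` within ``window``; earliest tie wins.

    Returns (pn_time_s, pn_amplitude_µV).
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError(f"PN search window {window} is empty on this epoch")
    idx = np.flatnonzero(mask)
    local = int(np.argmin(trace[idx]))  # argmin returns the first minimum
    i = idx[local]
    return float(times[i]), float(trace[i])


def _strict_local_min(
    times: np.ndarray, trace: np.ndarray, pn_time: float,
    neighborhood_s: float = LOCAL_MIN_NEIGHBORHOOD_S,
) -> bool:
    """Local-minimum check at ``neighborhood_s`` granularity.

    The PN must be no higher than any sample within the neighbourhood and
    strictly lower than the values at the neighbourhood edges.  Sample-level
    ties right at the minimum are tolerated: a band-limited trace stored at
    16-bit resolution is flat to quantization at a smooth extremum.
    """
    i = int(np.argmin(np.abs(times - pn_time)))
    dt = (times[-1] - times[0]) / (times.size - 1) if times.size > 1 else 0.0
    n = max(1, int(round(neighborhood_s / dt))) if dt else 1
    left = trace[max(0, i - n) : i]
    right = trace[i + 1 : i + 1 + n]
    if left.size == 0 or right.size == 0:
        return False
    v = trace[i]
    return bool(left[0] > v and right[-1] > v and left.min() >= v and right.min() >= v)


def evaluate_criteria(
    epoch_times: np.ndarray,
    epoch_trace: np.ndarray,
    trial_idx: int,
    pn_time_s: float,
    pn_amplitude_uv: float,
    emg_onset_s: float | None,
    ns1: float,
    ns2: float,
    rebound: float,
    movement_time_s: float = 0.0,
) -> TrialAssessment:
    """Apply the four acceptance rules to one trial.

    All times are on the epoch's own axis; ``movement_time_s`` locates the
    cued movement on that axis (0 when the epoch is already centred on the
    movement cue), and the ±0.5 s windows and the early-PN rejection are
    taken relative to it.  A missing EMG onset simply fails criterion 1.
    """
    rel_pn = pn_time_s - movement_time_s
    c1 = (
        abs(rel_pn) <= CRITERION_WINDOW_S
        and emg_onset_s is not None
        and abs(emg_onset_s - movement_time_s) <= CRITERION_WINDOW_S
    )
    c2 = ns1 < 0 and ns2 < 0 and rebound > 0
    c3 = _strict_local_min(epoch_times, epoch_trace, pn_time_s)
    rejected = rel_pn < -EARLY_PN_LIMIT_S
    return TrialAssessment(
        trial_idx=trial_idx,
        pn_time_s=pn_time_s,
        pn_amplitude_uv=pn_amplitude_uv,
        emg_onset_s=emg_onset_s,
        c1=bool(c1),
        c2=bool(c2),
        c3=bool(c3),
        rejected_early_pn=bool(rejected),
        success=bool(c1 and c2 and c3 and not rejected),
    )


def success_rate(
    assessments: list[TrialAssessment],
    subject: str = "",
    condition: str = "",
    processing: str = "cz",
) -> SuccessSummary:
    """Count successful trials and report the rounded percentage."""
    if not assessments:
        raise ValueError("no trials to summarise")
    n_success = sum(a.success for a in assessments)
    return SuccessSummary(subject, condition, processing, n_success, len(assessments))


def assessments_frame(assessments: list[TrialAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_idx": [a.trial_idx for a in assessments],
            "pn_time_s": [a.pn_time_s for a in assessments],
            "pn_amplitude_uv": [a.pn_amplitude_uv for a in assessments],
            "emg_onset_s": [a.emg_onset_s for a in assessments],
            "c1": [a.c1 for a in assessments],
            "c2": [a.c2 for a in assessments],
            "c3": [a.c3 for a in assessments],
            "rejected_early_pn": [a.rejected_early_pn for a in assessments],
            "success": [a.success for a in assessments],
        }
    )


def realign_epochs(
    epochs: EpochSet,
    ref_times: dict[int, float],
    reference: str,
    window: tuple[float, float] = (-2.0, 1.5),
    on_short: str = "drop",
) -> EpochSet:
    """Re-window each trial around its own reference time.

    ``ref_times`` maps trial id -> reference time (s, on the source epoch's
    axis); trials absent from the map are dropped.  ``reference`` names the
    alignment point ('cue', 'emg' or 'pn').  A trial whose new window falls
    outside the source epoch is dropped (``on_short='drop'``) or raises
    (``on_short='error'``).
    """
    if reference not in ("cue", "emg", "pn"):
        raise ValueError(f"unknown alignment reference {reference!r}")
    rate = epochs.rate
    i_lo = int(round(window[0] * rate))
    i_hi = int(round(window[1] * rate))
    new_times = np.arange(i_lo, i_hi) / rate

    rows, kept = [], []
    for row, trial in zip(epochs.data, epochs.trial_ids):
        t_ref = ref_times.get(int(trial))
        if t_ref is None:
            continue
        center = int(np.argmin(np.abs(epochs.times - t_ref)))
        lo, hi = center + i_lo, center + i_hi
        if lo < 0 or hi > row.size:
            if on_short == "error":
                raise ValueError(f"trial {trial}: realignment window leaves the epoch")
            continue
        rows.append(row[lo:hi])
        kept.append(trial)
    data = np.stack(rows) if rows else np.empty((0, new_times.size))
    return EpochSet(
        data, new_times, reference, rate, np.asarray(kept),
        epochs.condition, epochs.subject,
    )
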