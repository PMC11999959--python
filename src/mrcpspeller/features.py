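"""MRCP descriptor extraction from PN-aligned trials.

Five descriptors per trial: PN amplitude (value at the peak negativity),
the early and late pre-PN slopes NS1 and NS2, the post-PN rebound slope
(all ordinary-least-squares line fits over fixed windows relative to PN,
µV/s), and PP, the peak-to-peak amplitude over ±2 s around PN clipped to
the aligned epoch's extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EpochSet

__all__ = ["SlopeWindows", "FEATURE_NAMES", "extract_features", "epochs_features", "subject_condition_means"]

FEATURE_NAMES = ("pn_uv", "ns1_uv_per_s", "ns2_uv_per_s", "rebound_uv_per_s", "pp_uv")

#: peak-to-peak window around PN, s (clipped to the epoch)
PP_WINDOW_S = (-2.0, 2.0)


@dataclass(frozen=True)
class SlopeWindows:
    """Slope-fit intervals, seconds relative to PN (endpoints included)."""

    ns1: tuple[float, float] = (-2.0, -0.5)
    ns2: tuple[float, float] = (-0.5, 0.0)
    rebound: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("ns1", "ns2", "rebound"):
            a, b = getattr(self, name)
            if not a < b:
                raise ValueError(f"{name} window must be increasing")
        if not (self.ns1[1] <= self.ns2[0] <= self.ns2[1] <= self.rebound[0]):
            raise ValueError("windows must be ordered ns1 <= ns2 <= rebound")


def _ols_slope(times: np.ndarray, trace: np.ndarray, window: tuple[float, float]) -> float:
    mask = (times >= window[0]) & (times <= window[1])
    if mask.sum() < 2:
        raise ValueError(f"window {window} contains fewer than two samples")
    t, y = times[mask], trace[mask]
    tc = t - t.mean()
    return float(tc @ (y - y.mean()) / (tc @ tc))


def extract_features(
    times: np.ndarray,
    trace: np.ndarray,
    windows: SlopeWindows | None = None,
) -> dict[str, float]:
    """Descriptors of one PN-aligned trial (PN at time 0)."""
    windows = windows or SlopeWindows()
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    i0 = int(np.argmin(np.abs(times)))
    pp_mask = (times >= PP_WINDOW_S[0]) & (times <= PP_WINDOW_S[1])
    if not pp_mask.any():
        raise ValueError("peak-to-peak window is empty after clipping")
    seg = trace[pp_mask]
    return {
        "pn_uv": float(trace[i0]),
        "ns1_uv_per_s": _ols_slope(times, trace, windows.ns1),
        "ns2_uv_per_s": _ols_slope(times, trace, windows.ns2),
        "rebound_uv_per_s": _ols_slope(times, trace, windows.rebound),
        "pp_uv": float(seg.max() - seg.min()),
    }


def epochs_features(
    epochs: EpochSet,
    windows: SlopeWindows | None = None,
    processing: str = "cz",
) -> pd.DataFrame:
    """One feature row per trial of a PN-aligned epoch set."""
    if epochs.reference != "pn":
        raise ValueError("features are defined on PN-aligned epochs")
    rows = []
    for trace, trial in zip(epochs.data, epochs.trial_ids):
        feats = extract_features(epochs.times, trace, windows)
        feats.update(
            trial_idx=int(trial),
            subject=epochs.subject,
            condition=epochs.condition,
            processing=processing,
        )
        rows.append(feats)
    cols = ["subject", "condition", "processing", "trial_idx", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)


def subject_condition_means(features: pd.DataFrame) -> pd.DataFrame:
    """Mean of each descriptor per subject x condition (x processing).

    Empty cells (a subject-condition pair with no validated trial) are
    simply absent from the result; callers decide whether that is an error.
    """
    keys = [k for k in ("processing", "subject", "condition") if k in features.columns]
    out = features.groupby(keys, as_index=False)[list(FEATURE_NAMES)].mean()
    out["n_trials"] = features.groupby(keys).size().to_numpy()
    return out
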