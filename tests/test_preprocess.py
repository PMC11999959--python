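"""Filtering, epoching, demeaning and the large Laplacian."""

import numpy as np
import pandas as pd
import pytest

from mrcpspeller.io_formats import Recording
from mrcpspeller.preprocess import (
    EpochSet,
    FilterSpec,
    apply_filter,
    demean_epochs,
    large_laplacian,
    segment_epochs,
)

RATE = 1200.0


def _rec(data, labels=("Cz",)):
    return Recording(np.atleast_2d(data), RATE, labels)


def _sine(freq, duration=20.0, amp=1.0):
    t = np.arange(int(duration * RATE)) / RATE
    return amp * np.sin(2 * np.pi * freq * t)


def _steady_amplitude(x):
    """Peak amplitude of the central half (clear of filter transients)."""
    n = x.size
    return np.abs(x[n // 4 : 3 * n // 4]).max()


class TestFilters:
    def test_zero_in_zero_out(self):
        out = apply_filter(_rec(np.zeros(int(10 * RATE))), FilterSpec.notch())
        assert np.allclose(out.samples, 0.0)

    def test_notch_attenuates_50_hz_by_20_db(self):
        out = apply_filter(_rec(_sine(50.0)), FilterSpec.notch())
        assert _steady_amplitude(out.samples[0]) < 10 ** (-20 / 20)

    def test_bandpass_passes_1_hz_within_5_pct(self):
        out = apply_filter(_rec(_sine(1.0, duration=60.0)), FilterSpec.bandpass())
        assert _steady_amplitude(out.samples[0]) == pytest.approx(1.0, rel=0.05)

    def test_bandpass_rejects_out_of_band(self):
        # 30 Hz is a decade above the 3 Hz edge; the 0.05 Hz corner's long
        # transients keep some residual, but attenuation must be >= 20 dB
        out = apply_filter(_rec(_sine(30.0)), FilterSpec.bandpass())
        assert _steady_amplitude(out.samples[0]) < 0.1

    def test_linearity(self, rng):
        x, y = rng.normal(size=(2, int(5 * RATE)))
        spec = FilterSpec.bandpass()
        lhs = apply_filter(_rec(3.0 * x - 2.0 * y), spec).samples[0]
        rhs = 3.0 * apply_filter(_rec(x), spec).samples[0] - 2.0 * apply_filter(_rec(y), spec).samples[0]
        assert np.allclose(lhs, rhs, atol=1e-5)

    def test_zero_phase_preserves_pulse_position(self):
        n = int(10 * RATE)
        x = np.zeros(n)
        center = n // 2
        width = 600
        x[center - width : center + width + 1] = np.hanning(2 * width + 1)
        out = apply_filter(_rec(x), FilterSpec.bandpass()).samples[0]
        assert abs(int(np.argmax(out)) - center) <= 1

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            apply_filter(_rec(np.zeros(1200)), FilterSpec("notch", (598.0, 640.0)))

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec("bandpass", (3.0, 0.05))


def _events(onsets):
    return pd.DataFrame(
        {
            "onset_s": onsets,
            "type": "column",
            "target_char": "O",
            "trial_idx": range(len(onsets)),
            "condition": "control",
        }
    )


class TestEpoching:
    def test_epoch_length_is_9_seconds(self, rng):
        rec = _rec(rng.normal(size=int(30 * RATE)))
        epochs = segment_epochs(rec, _events([5.0, 15.0]), window=(-4.0, 5.0))
        assert epochs.data.shape == (2, 10800)
        assert epochs.times[0] == -4.0
        assert epochs.reference == "cue"

    def test_epoch_content_matches_source(self, rng):
        trace = rng.normal(size=int(30 * RATE))
        epochs = segment_epochs(_rec(trace), _events([10.0]))
        lo = int((10.0 - 4.0) * RATE)
        assert np.array_equal(epochs.data[0], trace[lo : lo + 10800])

    def test_event_near_edge_reports_trial(self, rng):
        rec = _rec(rng.normal(size=int(30 * RATE)))
        with pytest.raises(ValueError, match="trial 0"):
            segment_epochs(rec, _events([2.0]))

    def test_26_events_give_26_epochs(self, noise_free_subject, phrase_plan):
        eeg, _, _ = noise_free_subject
        epochs = segment_epochs(eeg, phrase_plan.to_frame(), channel="Cz")
        assert epochs.n_trials == 26


class TestDemean:
    def test_constant_epoch_becomes_zero(self):
        es = EpochSet(np.full((2, 1200), 3.3), np.arange(1200) / RATE, "cue", RATE, [0, 1])
        out = demean_epochs(es)
        assert np.allclose(out.data, 0.0)

    def test_zero_mean_to_numerical_precision_and_idempotent(self, rng):
        es = EpochSet(rng.normal(5, 10, size=(4, 2400)), np.arange(2400) / RATE, "cue", RATE, range(4))
        once = demean_epochs(es)
        assert np.all(np.abs(once.data.mean(axis=1)) < 1e-9)
        twice = demean_epochs(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)


class TestLaplacian:
    LABELS = ("Fz", "C3", "Cz", "C4", "Pz")

    def test_common_mode_is_rejected_exactly(self, rng):
        v = rng.normal(size=int(2 * RATE))
        rec = Recording(np.tile(v, (5, 1)), RATE, self.LABELS)
        out = large_laplacian(rec)
        assert np.allclose(out.samples, 0.0, atol=1e-12)

    def test_center_only_signal_passes_unchanged(self, rng):
        v = rng.normal(size=int(2 * RATE))
        data = np.zeros((5, v.size))
        data[2] = v
        out = large_laplacian(Recording(data, RATE, self.LABELS))
        assert np.array_equal(out.samples[0], v)

    def test_direct_formula(self):
        data = np.ones((5, 10))
        data[2] = 4.0
        out = large_laplacian(Recording(data, RATE, self.LABELS))
        assert np.allclose(out.samples, 3.0)

    def test_missing_ring_channel_raises(self, rng):
        rec = Recording(rng.normal(size=(2, 100)), RATE, ("Cz", "C3"))
        with pytest.raises(KeyError):
            large_laplacian(rec)

    def test_laplacian_commutes_with_segment_and_demean(self, rng):
        data = rng.normal(size=(5, int(30 * RATE)))
        rec = Recording(data, RATE, self.LABELS)
        events = _events([10.0, 20.0])
        # Laplacian first
        a = demean_epochs(segment_epochs(large_laplacian(rec), events))
        # segment + demean each channel first, then combine
        per_ch = {lb: demean_epochs(segment_epochs(rec.pick((lb,)), events)).data for lb in self.LABELS}
        ring_mean = np.mean([per_ch[lb] for lb in ("Fz", "C3", "C4", "Pz")], axis=0)
        b = per_ch["Cz"] - ring_mean
        assert np.allclose(a.data, b, atol=1e-9)
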