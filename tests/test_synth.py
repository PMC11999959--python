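"""Synthetic EEG/EMG generator: template shape, planting, noise content."""

import numpy as np
import pytest
from scipy import signal

from mrcpspeller.synth import (
    EEG_CHANNELS,
    GroundTruth,
    MRCPTemplateParams,
    NoiseParams,
    mrcp_template,
    pink_noise,
    synth_cohort,
    synth_emg_epochs,
    synth_subject,
)

RATE = 1200.0


def _axis(lo=-3.0, hi=2.0):
    return np.arange(int(lo * RATE), int(hi * RATE)) / RATE


class TestTemplate:
    def test_minimum_is_pn_amplitude_within_smoothing(self):
        tpl = MRCPTemplateParams()
        w = mrcp_template(tpl, _axis())
        # the moving average rounds the sharp PN corner slightly upward
        assert w.min() == pytest.approx(tpl.pn_amplitude, abs=0.5)
        assert abs(_axis()[np.argmin(w)]) <= tpl.smoothing_s

    def test_unsmoothed_kink_value_is_ns1_segment_arithmetic(self):
        tpl = MRCPTemplateParams(smoothing_s=0.0)
        t = _axis()
        w = mrcp_template(tpl, t)
        i = np.argmin(np.abs(t + tpl.ns2_start_s))
        expected = tpl.ns1_slope * (tpl.ns1_start_s - tpl.ns2_start_s)
        assert w[i] == pytest.approx(expected, abs=1e-9)

    def test_zero_before_onset_and_after_rebound(self):
        tpl = MRCPTemplateParams(smoothing_s=0.0)
        t = _axis()
        w = mrcp_template(tpl, t)
        assert np.all(w[t < -tpl.ns1_start_s] == 0)
        assert np.all(w[t > tpl.rebound_end_s + 1e-9] == 0)

    def test_rebound_rises_monotonically(self):
        tpl = MRCPTemplateParams(smoothing_s=0.0)
        t = _axis()
        w = mrcp_template(tpl, t)
        seg = w[(t >= 0) & (t <= tpl.rebound_end_s)]
        assert np.all(np.diff(seg) > 0)

    def test_short_axis_rejected(self):
        with pytest.raises(ValueError):
            mrcp_template(MRCPTemplateParams(), np.linspace(-0.5, 0.5, 100))

    @pytest.mark.parametrize(
        "kwargs",
        [{"ns1_slope": 1.0}, {"ns2_slope": -1.0}, {"rebound_slope": -2.0},
         {"ns1_start_s": 0.2}, {"pn_amplitude": 1.0}],
    )
    def test_inconsistent_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MRCPTemplateParams(**kwargs)


class TestSubject:
    def test_same_seed_is_bit_identical(self, phrase_plan):
        a = synth_subject(phrase_plan, seed=5)
        b = synth_subject(phrase_plan, seed=5)
        assert np.array_equal(a[0].samples, b[0].samples)
        assert np.array_equal(a[1].samples, b[1].samples)
        assert a[2] == b[2]

    def test_success_prob_zero_plants_nothing(self, phrase_plan):
        _, _, truth = synth_subject(phrase_plan, success_prob=0.0, seed=5)
        assert not any(t.mrcp_present for t in truth.trials)

    def test_rate_and_channel_contract(self, phrase_plan):
        eeg, emg, _ = synth_subject(phrase_plan, seed=5)
        assert eeg.rate == emg.rate == RATE
        assert eeg.labels == EEG_CHANNELS
        assert emg.labels == ("EMG_TA",)

    def test_noise_free_cz_minimum_is_pn_amplitude(self, noise_free_subject, phrase_plan, noise_free_cfg):
        eeg, _, truth = noise_free_subject
        cz = eeg.channel("Cz")
        tpl = noise_free_cfg.template
        for ev in phrase_plan.events:
            lo = int((ev.onset_s - 1.0) * RATE)
            hi = int((ev.onset_s + 3.0) * RATE)
            assert cz[lo:hi].min() == pytest.approx(tpl.pn_amplitude, abs=1e-9)

    def test_noise_free_trial_window_equals_template(self, noise_free_subject, noise_free_cfg):
        """Alignment identity: the planted Cz trace around each PN is the
        template evaluated on the same grid."""
        eeg, _, truth = noise_free_subject
        cz = eeg.channel("Cz")
        tpl = noise_free_cfg.template
        times = eeg.times()
        for trial in truth.trials[:5]:
            lo = int(round((trial.true_pn_time_s - tpl.ns1_start_s) * RATE))
            hi = int(round((trial.true_pn_time_s + tpl.rebound_end_s) * RATE))
            expected = mrcp_template(tpl, times[lo : hi + 1] - trial.true_pn_time_s)
            assert np.allclose(cz[lo : hi + 1], expected, atol=1e-9)

    def test_invalid_probability_rejected(self, phrase_plan):
        with pytest.raises(ValueError):
            synth_subject(phrase_plan, success_prob=1.5, seed=0)


class TestNoise:
    def test_pink_spectrum_falls_with_frequency(self, rng):
        x = pink_noise(rng, 2**16, sigma=1.0)
        f, p = signal.periodogram(x, fs=RATE)
        low = p[(f > 1) & (f < 10)].mean()
        high = p[(f > 100) & (f < 300)].mean()
        assert low > 10 * high

    def test_line_component_peaks_at_50_hz(self, phrase_plan):
        noise = NoiseParams(pink_sigma=0.5, line_amp=5.0, drift_amp=0.0)
        eeg, _, _ = synth_subject(phrase_plan, noise=noise, success_prob=0.0, seed=3)
        f, p = signal.periodogram(eeg.channel("Cz"), fs=RATE)
        assert abs(f[np.argmax(p)] - 50.0) < 0.5

    def test_negative_noise_parameter_rejected(self):
        with pytest.raises(ValueError):
            NoiseParams(pink_sigma=-1.0)


class TestEmgEpochs:
    def test_burst_onsets_are_recorded_and_on_grid(self):
        epochs, times, onsets = synth_emg_epochs(8, seed=2)
        assert epochs.shape == (8, times.size)
        assert np.all((onsets >= 0.5) & (onsets <= 1.5))
        assert np.allclose(onsets * RATE, np.round(onsets * RATE))

    def test_burst_region_has_higher_power(self):
        epochs, times, onsets = synth_emg_epochs(4, seed=2)
        for row, onset in zip(epochs, onsets):
            burst = row[(times > onset + 0.2) & (times < onset + 1.8)]
            base = row[times < onset - 0.5]
            assert burst.std() > 5 * base.std()


class TestCohort:
    def test_cohort_layout_on_disk(self, tmp_path):
        manifest = synth_cohort(tmp_path, n_subjects=1, conditions=("control",), seed=4)
        assert len(manifest) == 1
        entry = manifest[0]
        for key in ("eeg", "emg", "events", "truth"):
            assert (tmp_path / entry[key]).exists()
        truth = GroundTruth.from_json(tmp_path / entry["truth"])
        assert len(truth.trials) == 26
        assert truth.success_prob == pytest.approx(0.67)

    def test_truth_json_round_trip(self, phrase_plan, tmp_path):
        _, _, truth = synth_subject(phrase_plan, success_prob=0.5, seed=9)
        path = truth.to_json(tmp_path / "t.json")
        assert GroundTruth.from_json(path) == truth
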