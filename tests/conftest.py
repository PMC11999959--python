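import numpy as np
import pytest

from mrcpspeller.config import StudyConfig
from mrcpspeller.speller import PHRASE, TimingSpec, build_layout, simulate_session
from mrcpspeller.synth import synth_subject

RATE = 1200.0


@pytest.fixture(scope="session")
def layout():
    return build_layout()


@pytest.fixture(scope="session")
def timing():
    return TimingSpec()


@pytest.fixture(scope="session")
def phrase_plan(layout, timing):
    return simulate_session(PHRASE, layout, timing, condition="phrase")


@pytest.fixture(scope="session")
def noise_free_cfg():
    """All-signal study configuration: unsmoothed template, no EEG noise or
    jitter, every trial planted, filters bypassed."""
    return StudyConfig().noise_free()


@pytest.fixture(scope="session")
def noise_free_subject(phrase_plan, noise_free_cfg):
    """One noise-free subject-condition session plus its ground truth."""
    eeg, emg, truth = synth_subject(
        phrase_plan,
        tpl=noise_free_cfg.template,
        noise=noise_free_cfg.noise,
        success_prob=1.0,
        seed=11,
    )
    return eeg, emg, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
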