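import numpy as np
import pytest

from nnrf.preprocess import baseline_correct
from nnrf.synthetic import CohortConfig, make_template_waveform, simulate_epochset
from nnrf.template import Template

RATE = 500.0  # working rate used throughout the suite; keeps tests fast
               # while staying above the 250 samples/s floor for 30 Hz content


@pytest.fixture(scope="session")
def waveform():
    return make_template_waveform(RATE)


@pytest.fixture(scope="session")
def template(waveform):
    return Template.from_waveform(waveform)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: projections must recover truth exactly."""
    cfg = CohortConfig(
        n_participants=12, rate=RATE, noise_rms=0.0, seed=7,
        sites={"A": 1.3}, control_mean=0.42,
        # keep all true magnitudes positive: correlation-based alignment
        # is only sign-consistent for positive responses
        magnitude_sd=0.2, control_sd=0.1,
    )
    epochs, table = simulate_epochset(cfg)
    return cfg, baseline_correct(epochs.crop(-500.0, 1000.0)), table
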