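import numpy as np
import pytest

from seegenc.core import EnvelopeSeries
from seegenc.synth import SessionConfig, simulate_session


@pytest.fixture(scope="session")
def short_session():
    """120 s, 8 channels (4 responsive), snr 4 — the demo-scale session."""
    cfg = SessionConfig(duration=120.0, n_channels=8, responsive_fraction=0.5,
                        snr=4.0, n_events=10, seed=7)
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def noiseless_session():
    """Small noiseless session for exact self-consistency checks."""
    cfg = SessionConfig(duration=30.0, n_channels=2, responsive_fraction=0.5,
                        snr=np.inf, line_noise_amp=0.0, n_events=0, seed=5)
    return simulate_session(cfg)


@pytest.fixture()
def flat_envelope():
    return EnvelopeSeries(values=np.ones(1000), fs=100.0)


def pearson(a, b):
    return float(np.corrcoef(np.asarray(a, float), np.asarray(b, float))[0, 1])
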