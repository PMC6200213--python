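import numpy as np
import pytest

from samph.samph_core import EnvelopeSet


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def env_rate():
    return 1050.0


@pytest.fixture(scope="session")
def env_5hz(env_rate):
    """30 s envelope set modulated only at 5 Hz (plus a tiny noise floor)."""
    n = int(30 * env_rate)
    t = np.arange(n) / env_rate
    gen = np.random.default_rng(7)
    envs = np.stack([
        np.clip(1 + 0.5 * np.sin(2 * np.pi * 5 * t)
                + 0.01 * gen.standard_normal(n), 0, None)
        for _ in range(5)
    ])
    return EnvelopeSet(envelopes=envs, env_rate=env_rate)
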