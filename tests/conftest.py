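import numpy as np
import pytest

from erpspell.synthetic import NoiseModel, default_template, generate_session


@pytest.fixture(scope="session")
def small_session():
    """One 6-trial block at default settings (cheap, shared across tests)."""
    return generate_session(n_blocks=1, trials_per_block=6, seed=11)


@pytest.fixture(scope="session")
def high_snr_block():
    """One full 30-trial block at the default (high-SNR) amplitude."""
    return generate_session(n_blocks=1, trials_per_block=30, seed=3)


@pytest.fixture(scope="session")
def two_block_session():
    """Calibration + evaluation block at default settings."""
    return generate_session(n_blocks=2, trials_per_block=30, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_toy_features(rng, n_trials=2, K=2, J=2, dim=3):
    """Small labeled feature set with AMUSE-like trial structure for oracles."""
    X, stim, trial, attended = [], [], [], []
    for t in range(n_trials):
        att = int(rng.integers(1, K + 1))
        attended.append(att)
        for j in range(J):
            for s in rng.permutation(K) + 1:
                x = rng.standard_normal(dim)
                x[0] += 1.0 if s == att else -1.0
                X.append(x)
                stim.append(s)
                trial.append(t)
    return (np.array(X), np.array(stim), np.array(trial), np.array(attended))
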