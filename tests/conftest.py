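"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import ncreann as nc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_config():
    """Small training config for tests that fit the network many times."""
    return nc.NMVARConfig(order=3, n_folds=3, max_epochs=40, patience=8, seed=0)


def simulate_var(coeff_matrices, length=4000, noise_sd=1.0, seed=0):
    """Simulate a purely linear VAR ground truth."""
    m = np.asarray(coeff_matrices[0]).shape[0]
    spec = nc.GroundTruthSpec(
        n_channels=m,
        linear_coeffs=[np.asarray(a, dtype=float) for a in coeff_matrices],
        noise_sd=noise_sd,
        length=length,
        seed=seed,
    )
    return nc.simulate_nmvar(spec)


def simulate_coupled_pair(coupling=0.5, self_coeffs=(0.6, 0.6), length=4000,
                          noise_sd=1.0, seed=0):
    """Two-channel VAR(1) with a single directed edge ch0 -> ch1."""
    a1 = np.array([[self_coeffs[0], 0.0], [coupling, self_coeffs[1]]])
    return simulate_var([a1], length=length, noise_sd=noise_sd, seed=seed)


def make_hand_model(w1, b1, w2, b2, activation="tanh", p=1):
    """NMVARModel with hand-set weights and identity standardization."""
    w1 = np.atleast_2d(np.asarray(w1, dtype=float))
    w2 = np.atleast_2d(np.asarray(w2, dtype=float))
    m = w2.shape[0]
    return nc.NMVARModel(
        hidden_weights=w1,
        hidden_biases=np.atleast_1d(np.asarray(b1, dtype=float)),
        output_weights=w2,
        output_biases=np.atleast_1d(np.asarray(b2, dtype=float)),
        activation=activation,
        p=p,
        n_channels=m,
        channel_mean=np.zeros(m),
        channel_sd=np.ones(m),
        channel_labels=[f"ch{i}" for i in range(m)],
    )
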