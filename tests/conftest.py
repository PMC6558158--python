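"""Shared fixtures: synthetic sessions are expensive, so they are built
once per test session and shared read-only."""

from __future__ import annotations

import numpy as np
import pytest

import headgait as hg


@pytest.fixture(scope="session")
def noiseless_session():
    """600-s noiseless session (seed 1) with default AC targets."""
    params = hg.GaitGeneratorParams(seed=1).noiseless()
    head, trunk, truth = hg.generate_session(params, 600.0)
    return params, head, trunk, truth


@pytest.fixture(scope="session")
def noiseless_result(noiseless_session):
    _, head, trunk, _ = noiseless_session
    return hg.run_session(head, trunk, keep_aligned=True)


@pytest.fixture(scope="session")
def noisy_session():
    """600-s session with default sensor noise (seed 2)."""
    params = hg.GaitGeneratorParams(seed=2)
    head, trunk, truth = hg.generate_session(params, 600.0)
    return params, head, trunk, truth


@pytest.fixture(scope="session")
def noisy_result(noisy_session):
    _, head, trunk, _ = noisy_session
    return hg.run_session(head, trunk)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
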