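"""Shared fixtures: simulated studies are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from lignosense.preprocessing import process_bundle
from lignosense.synthetic import SimulatorParams, simulate_study


@pytest.fixture(scope="session")
def default_params() -> SimulatorParams:
    return SimulatorParams()


@pytest.fixture(scope="session")
def noisy_study():
    """Default noisy study bundle + oracle (seed 0)."""
    return simulate_study(seed=0)


@pytest.fixture(scope="session")
def noiseless_study():
    """Noiseless study bundle + oracle (seed 0)."""
    return simulate_study(params=SimulatorParams().noiseless(), seed=0)


@pytest.fixture(scope="session")
def anchor_triplets(noisy_study):
    bundle, _ = noisy_study
    return process_bundle(bundle)


@pytest.fixture(scope="session")
def noiseless_triplets(noiseless_study):
    bundle, _ = noiseless_study
    return process_bundle(bundle)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
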