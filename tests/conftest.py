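"""Shared fixtures.

Expensive sampling runs are session-scoped and reused across tests; all
fixtures are generated programmatically with fixed seeds.
"""

import numpy as np
import pytest

from evbkit import (HarmonicSurrogate, Schedule, ToySpec, build_toy_system,
                    run_protocol, surrogate_window_samples,
                    zwanzig_increments)

SURROGATE_T = 298.15


@pytest.fixture(scope="session")
def surrogate40():
    return HarmonicSurrogate.from_reorganization(40.0, dg0=0.0, h_ij=0.0)


@pytest.fixture(scope="session")
def surrogate_samples(surrogate40):
    return surrogate_window_samples(
        surrogate40, np.linspace(0.0, 1.0, 51), 2000, SURROGATE_T,
        seed=1, replicas=4)


@pytest.fixture(scope="session")
def surrogate_mapping(surrogate_samples):
    return zwanzig_increments(surrogate_samples, SURROGATE_T)


@pytest.fixture(scope="session")
def toy_system():
    return build_toy_system(ToySpec())


@pytest.fixture(scope="session")
def small_schedule():
    return Schedule(lambdas=np.linspace(0.0, 1.0, 21), replicas=3,
                    n_steps=4000, friction=5.0e-3)


@pytest.fixture(scope="session")
def toy_samples(toy_system, small_schedule):
    return run_protocol(toy_system, small_schedule, seed=99)


@pytest.fixture(scope="session")
def toy_mapping(toy_samples):
    return zwanzig_increments(toy_samples, 300.0)
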