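"""Shared fixtures: small synthetic sessions generated once per test run."""

import numpy as np
import pytest

from popsaliency import synth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_population():
    return synth.make_unit_population(
        30,
        {"suppression": 0.4, "early_enh_late_supp": 0.2, "enhancement": 0.2, "nonselective": 0.2},
        synth.GeometrySpec(d_true=5, overlap=0.5),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_session(small_population):
    """30 units, 20 trials per condition; enough for every downstream screen."""
    return synth.simulate_session(
        small_population, n_trials_per_condition=20, seed=11
    )


@pytest.fixture(scope="session")
def small_rates(small_session):
    from popsaliency import preprocess

    rates, grid = preprocess.session_rates(small_session)
    return rates, grid
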