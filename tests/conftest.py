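"""Shared fixtures: loaded scenario bundles and session-wide PSA results.

The probabilistic analyses are expensive enough to share; every consumer
uses the same master seed so results are reproducible across runs.
"""

import pytest

from chemoswitch import load_scenario, run_psa

SEED = 20260317
N_RUNS = 1000


@pytest.fixture(scope="session")
def bundle_capox():
    return load_scenario("capox")


@pytest.fixture(scope="session")
def bundle_folfox():
    return load_scenario("folfox")


@pytest.fixture(scope="session")
def bundle_cap_mono():
    return load_scenario("cap_mono")


@pytest.fixture(scope="session")
def psa_capox(bundle_capox):
    return run_psa(bundle_capox, n_runs=N_RUNS, seed=SEED)


@pytest.fixture(scope="session")
def psa_folfox(bundle_folfox):
    return run_psa(bundle_folfox, n_runs=N_RUNS, seed=SEED)


@pytest.fixture(scope="session")
def psa_cap_mono(bundle_cap_mono):
    return run_psa(bundle_cap_mono, n_runs=N_RUNS, seed=SEED)
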