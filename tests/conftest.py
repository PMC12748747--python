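import numpy as np
import pytest

import duplexrepair as dr


@pytest.fixture(scope="session")
def gag3():
    return dr.demo_substrate("gag3")


@pytest.fixture(scope="session")
def gt5():
    return dr.demo_substrate("gt5")


@pytest.fixture(scope="session")
def blunt():
    return dr.demo_substrate("blunt")


@pytest.fixture(scope="session")
def gag3_products(gag3):
    return dr.enumerate_expected_products(gag3, ["C", "TC", "CTC"])


@pytest.fixture(scope="session")
def gt5_products(gt5):
    return dr.enumerate_expected_products(gt5)


@pytest.fixture(scope="session")
def blunt_products(blunt):
    return dr.enumerate_expected_products(blunt)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_error_free_library(gt5, gt5_products):
    """300 molecules, error-free, with per-read and per-molecule truth."""
    kinetics = dr.KineticsModel(mode="parallel_independent", k_top=0.2, k_bottom=0.2)
    states = dr.simulate_repair(gt5, kinetics, 300, 10.0, seed=101)
    records, truth = dr.synthesize_reads(
        states, gt5, gt5_products,
        oversampling_mean=12.0, error_rate=0.0, seed=102,
    )
    return states, records, truth
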