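import numpy as np
import pytest

import batvoc as bv


@pytest.fixture(scope="session")
def library():
    return bv.make_call_library(seed=1)


@pytest.fixture(scope="session")
def categories(library):
    return {c.call_id: c.category for c in library}


@pytest.fixture(scope="session")
def call_protocol():
    return bv.TrialProtocol(pre_stimulus_ms=50.0, post_stimulus_ms=450.0, n_trials=20, seed=3)


@pytest.fixture(scope="session")
def dac_call_data(library, call_protocol):
    """Responses of one dAC-like unit to all 15 calls (simulated once)."""
    prof = bv.dac_template("dac_fixture")
    return {c.call_id: bv.simulate_call_response(prof, c, call_protocol) for c in library}


@pytest.fixture(scope="session")
def faf_call_data(library, call_protocol):
    prof = bv.faf_template("faf_fixture")
    return {c.call_id: bv.simulate_call_response(prof, c, call_protocol) for c in library}
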