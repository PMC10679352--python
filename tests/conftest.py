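from dataclasses import replace

import pytest

from flucea import default_italy_like


@pytest.fixture(scope="session")
def params():
    """Default Italy-like parameter set (influenza-coded approach)."""
    return default_italy_like()


@pytest.fixture(scope="session")
def cardio_params(params):
    """Same set under the cardiorespiratory (hidden-burden) approach."""
    return replace(params, scenario=replace(params.scenario,
                                            hospitalization_approach="cardiorespiratory"))
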