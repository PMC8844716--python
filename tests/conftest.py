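import logging

import pytest

import tetosc as T

# the k1-prior normalisation warning is intentional; keep test output clean
logging.getLogger("tetosc.network").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def network():
    return T.build_goodwin_network()


@pytest.fixture(scope="session")
def prior():
    return T.ParameterPrior()


@pytest.fixture(scope="session")
def mid_params(prior):
    return prior.midpoint()


def zeroed_rates(**overrides) -> T.RateParameters:
    """All eleven rates zero except the given ones (disables reactions)."""
    vals = {sym: 0.0 for sym in T.network.RATE_SYMBOLS}
    vals.update(overrides)
    return T.RateParameters(**vals)
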