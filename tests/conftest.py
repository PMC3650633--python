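import numpy as np
import pytest

from stpsim import (constant_release, make_exponential, make_rayleigh,
                    periodic_train)


@pytest.fixture(scope="session")
def exp05():
    """Exponential availability times, tau_a = 0.5 s."""
    return make_exponential(0.5)


@pytest.fixture(scope="session")
def ray05():
    """Rayleigh availability times, mean tau_a = 0.5 s."""
    return make_rayleigh(0.5)


@pytest.fixture(scope="session")
def p06():
    """Constant release probability given availability, P_r|a = 0.6."""
    return constant_release(0.6)


@pytest.fixture(scope="session")
def train_10hz_20():
    """20 periodic spikes at 10 Hz — the standard short train."""
    return periodic_train(10.0, 20)


@pytest.fixture(autouse=True)
def _silence_flawed_variant_warnings():
    """The deliberately flawed simulators warn on use; tests exercise them
    constantly, so the warning is demoted to a record-only filter."""
    import warnings
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore",
                                message=".*known-flawed algorithm.*",
                                category=UserWarning)
        yield
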