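import numpy as np
import pytest

from refblochi import SequenceParams


@pytest.fixture(scope="session")
def accuracy_protocol() -> SequenceParams:
    """Simulation protocol: TR/alpha/TI/RR/N = 5 ms/15 deg/300 ms/900 ms/33."""
    return SequenceParams(tr_ms=5.0, flip_deg=15.0, ti_ms=300.0, rr_ms=900.0,
                          n_views=33)


@pytest.fixture(scope="session")
def precision_protocol() -> SequenceParams:
    """Precision-study protocol at the longer RR of 950 ms."""
    return SequenceParams(tr_ms=5.0, flip_deg=15.0, ti_ms=300.0, rr_ms=950.0,
                          n_views=33)


@pytest.fixture(scope="session")
def swine_protocol() -> SequenceParams:
    """In-vivo multi-TI protocol: TR/alpha/N = 3.9 ms/15 deg/37, RR 1000 ms."""
    return SequenceParams(tr_ms=3.9, flip_deg=15.0, ti_ms=300.0, rr_ms=1000.0,
                          n_views=37)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
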