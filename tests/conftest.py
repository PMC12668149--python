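import numpy as np
import pytest

from feastfamine.model import CRParams, CRState


@pytest.fixture
def simple_params():
    """A plain, well-behaved parameter set for unit tests (not the shipped one)."""
    return CRParams(
        mu1=8.0, K1=1.0, mu21=2.0, K21=1.0, mu22=4.0, K22=1.0,
        Y1=1.0, Y21=1.0, Y22=0.5, p=0.05, q=0.8, d1=0.5, d2=0.3,
        D=0.1, S=10.0, dt_dilution=10.0,
    )


@pytest.fixture
def state0():
    return CRState(X1=0.05, X2=0.05, R1=10.0, R2=0.0)


def random_valid_params(rng: np.random.Generator) -> CRParams:
    """Random draw over a broad box of valid parameter values."""
    return CRParams(
        mu1=rng.uniform(1, 12), K1=rng.uniform(0.1, 2),
        mu21=rng.uniform(0, 5), K21=rng.uniform(0.1, 2),
        mu22=rng.uniform(0.5, 12), K22=rng.uniform(0.05, 2),
        Y1=rng.uniform(0.3, 2), Y21=rng.uniform(0.3, 2), Y22=rng.uniform(0.3, 2),
        p=rng.uniform(0, 0.3), q=rng.uniform(0, 1),
        d1=rng.uniform(0.05, 2), d2=rng.uniform(0.05, 2),
        D=0.1, S=10.0, dt_dilution=rng.uniform(1, 12),
    )
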