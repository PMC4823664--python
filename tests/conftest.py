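import numpy as np
import pytest

from odormix import GlobalConfig, OdorParams, builtin_parameter_sets


@pytest.fixture(scope="session")
def cfg():
    return GlobalConfig()


@pytest.fixture(scope="session")
def sets():
    return builtin_parameter_sets()


@pytest.fixture(scope="session")
def control_pair(sets):
    """The two-odor control set used throughout the figure reproductions."""
    ps = sets["fig2/control"]
    return ps.U, ps.V, ps.r


def random_params(rng, n_lo=0.3, n_hi=15.0, eta_lo=0.2, eta_hi=8.0,
                  k_lo=-4.0, k_hi=-1.0, name=None):
    """Draw one physiologically plausible odor parameter set."""
    return OdorParams(
        n=float(rng.uniform(n_lo, n_hi)),
        eta=float(rng.uniform(eta_lo, eta_hi)),
        K=float(10.0 ** rng.uniform(k_lo, k_hi)),
        name=name,
    )
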