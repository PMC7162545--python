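import numpy as np
import pytest

from dlgradient.mechanistic import MechanisticParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_mechanistic_params(rng, lo=1e-3, hi=1e3, **overrides) -> MechanisticParams:
    """Log-uniform draw of the five free rate parameters."""
    draws = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), 5)
    kw = dict(
        lambda_d=draws[0],
        lambda_dc=draws[1],
        beta_o=draws[2],
        gamma=draws[3],
        kappa=draws[4],
    )
    kw.update(overrides)
    return MechanisticParams(**kw)
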