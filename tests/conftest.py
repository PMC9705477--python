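import numpy as np
import pytest

from coacerlab import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def double_well():
    """Tabulated double-well landscape: wells at N=10 and N=35, 4 kBT barrier."""
    from oracles import double_well_beta_f

    return double_well_beta_f()


@pytest.fixture(scope="session")
def double_well_windows(double_well):
    """Umbrella windows over the double well with the standard schedule."""
    return synth.gen_umbrella_windows(
        double_well, kappa_kt=10.0, nstar_schedule="{-9..3..54}",
        n_samples=5000, seed=7,
    )
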