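import warnings

import numpy as np
import pytest

import nowiw as nw

# suppress the expected numeric-edge warnings so test output stays readable
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def battery():
    return nw.battery_lifetimes()


@pytest.fixture(scope="session")
def battery_series(battery):
    return nw.split_sample(battery)


@pytest.fixture(scope="session")
def unit_params():
    return nw.NOWIWParams(1.0, 1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def finite_mean_params():
    # zeta > 1 so all moments exist
    return nw.NOWIWParams(1.0, 2.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def param_grid():
    """12 parameter sets spanning eta, zeta in {0.5,1,2} and k, n in {0.8,1.5,2.5}."""
    etas_zetas = [(0.5, 0.5), (0.5, 2.0), (1.0, 1.0), (2.0, 0.5), (2.0, 2.0), (1.0, 2.0)]
    kns = [(0.8, 1.5), (2.5, 0.8)]
    return [nw.NOWIWParams(e, z, k, n) for (e, z) in etas_zetas for (k, n) in kns]


@pytest.fixture(scope="session")
def battery_mle(battery):
    """One shared battery MLE fit (the expensive object several tests need)."""
    return nw.fit_neutrosophic(battery, "mle", nw.FitConfig(starts=20, seed=1))
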