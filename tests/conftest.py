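import numpy as np
import pytest

from ionloop import (
    PumpParams,
    PumpState,
    load_pump_plant,
    load_smc_config,
)


@pytest.fixture
def simple_params():
    """Small hand-picked pump parameters for unit-level checks."""
    return PumpParams(D=0.02, c1=1.0, c2=1.2, cc1=0.5, cc2=0.4,
                      d1=10.0, d2=8.0, dd1=6.0, dd2=5.0, g=0.03,
                      epsilon=0.5, zeta=0.7)


@pytest.fixture
def insilico_plant():
    return load_pump_plant("insilico")


@pytest.fixture
def insilico_cfg():
    return load_smc_config("insilico")


@pytest.fixture
def invitro_cfg():
    return load_smc_config("invitro")


@pytest.fixture
def rng():
    return np.random.default_rng(20240514)


@pytest.fixture
def log_frame():
    """Minimal experiment-log DataFrame in the deposited column layout."""
    import pandas as pd

    return pd.DataFrame({
        "d": [1200.0, 1200.0, 1200.0],
        "err": [-30.0, 10.0, 5.0],
        "u": [0.5, 1.0, -0.2],
        "plot_timer": [1.0, 2.0, 3.0],
    })
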