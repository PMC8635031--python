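import numpy as np
import pytest

from trnkit import ModelParams


@pytest.fixture(scope="session")
def params():
    """Baseline analysis parameter set (gT=2.25, gKL=0.0065, k=0.01)."""
    return ModelParams()


@pytest.fixture(scope="session")
def comparison_params():
    """Parameter set of the full-vs-reduced firing-pattern protocols."""
    return ModelParams().with_(gKL=0.0152)


@pytest.fixture(scope="session")
def v_grid():
    """Dense physiological voltage grid (mV)."""
    return np.linspace(-120.0, 60.0, 721)
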