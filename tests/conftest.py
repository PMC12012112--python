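import numpy as np
import pytest
from scipy import integrate as _sint

from stableews import StableParams, sas_characteristic_function


def sas_pdf_by_inversion(x: float, params: StableParams) -> float:
    """Independent oracle: numeric Fourier inversion of the characteristic
    function, f(x) = (1/pi) * int_0^inf cos(u x) exp(-(gamma u)^alpha) du."""

    def integrand(u):
        return np.cos(u * x) * sas_characteristic_function(u, params)

    val, _ = _sint.quad(integrand, 0.0, np.inf, limit=400)
    return val / np.pi


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
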