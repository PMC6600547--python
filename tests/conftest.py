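import numpy as np
import pytest

from specbind import Titration
from specbind.synthetic import simulate_quenching_series

# Multi-temperature binding/quenching constants of the albumin-ligand system
# used as shared ground truth across the suite (M^-1 unless noted).
KSV_BY_T = {298.0: 2.67e3, 303.0: 2.10e3, 310.0: 1.63e3, 315.0: 1.27e3}
KB_BY_T = {298.0: 1.69e3, 303.0: 2.75e3, 310.0: 3.90e3, 315.0: 8.42e3}
TAU0 = 5.71e-9


@pytest.fixture(scope="session")
def ksv_by_t():
    return dict(KSV_BY_T)


@pytest.fixture(scope="session")
def kb_by_t():
    return dict(KB_BY_T)


@pytest.fixture()
def noiseless_titration() -> Titration:
    """Exact static 1:1 titration with Ksv = 2670 M^-1 on the 0-56 uM grid."""
    tits, _ = simulate_quenching_series(ksv_by_temperature={298.0: 2670.0})
    return tits[298.0]


@pytest.fixture()
def conc_grid():
    return np.linspace(0.0, 56e-6, 8)
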