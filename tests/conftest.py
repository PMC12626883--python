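import numpy as np
import pytest

from msinfo import (
    FAST_PROCESSING,
    CouplingSpec,
    SystemSpec,
    SystemTemplate,
    UnitSpec,
    realize_system,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_template():
    """A small chain that keeps every Monte-Carlo check cheap."""
    return SystemTemplate(M_I=8, M_P=4, M_O=1, g_PI=2.0, g_OP=2.0, g_OI=2.0)


@pytest.fixture
def small_fast_system(small_template):
    return realize_system(small_template, FAST_PROCESSING, 7)


@pytest.fixture
def one_dof_chain():
    """Fully hand-checkable system: every unit one-dimensional, unit weights."""
    units = {
        "I": UnitSpec("I", 1, 1.0, np.array([[1.0]])),
        "P": UnitSpec("P", 1, 1e-4, np.array([[1.0]])),
        "O": UnitSpec("O", 1, 1e-2, np.array([[1.0]])),
    }
    couplings = [
        CouplingSpec("I", "P", 1.5, np.array([[1.0]])),
        CouplingSpec("P", "O", 0.8, np.array([[1.0]])),
    ]
    return SystemSpec(units=units, couplings=couplings)
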