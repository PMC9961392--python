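import numpy as np
import pytest

from hgdiff import core, taylor
from hgdiff.binding import BindingSystem


@pytest.fixture(scope="session")
def instrument() -> taylor.TaylorInstrument:
    return taylor.default_instrument()


@pytest.fixture(scope="session")
def ions():
    return core.default_ions()


@pytest.fixture(scope="session")
def charged_system(ions):
    from hgdiff.nernst import IonicSystem
    nasal, na4etra = core.default_solutes()
    return IonicSystem(nasal, na4etra)


@pytest.fixture(scope="session")
def bcd_binding() -> BindingSystem:
    """The salicylate/β-CD 1:1 system with tabulated species diffusivities."""
    return BindingSystem(Ka=80.0, D_guest=0.918, D_host=0.436, D_complex=0.421)


from hgdiff.synthetic import random_diffusion_matrix as random_valid_matrix  # noqa: E402,F401
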