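import numpy as np
import pytest

from pnwave.config import load_preset
from pnwave.lattice import build_chain, build_hex_disc, build_hex_rect
from pnwave.simulate import ICKind, InitialCondition, integrate


@pytest.fixture(scope="session")
def fig2a():
    return load_preset("fig2a")


@pytest.fixture(scope="session")
def fig2b():
    return load_preset("fig2b")


@pytest.fixture(scope="session")
def fig3():
    return load_preset("fig3")


@pytest.fixture(scope="session")
def chain40():
    return build_chain(40)


@pytest.fixture(scope="session")
def hex_10x10():
    return build_hex_rect(10, 10)


@pytest.fixture(scope="session")
def disc5():
    return build_hex_disc(5)


@pytest.fixture(scope="session")
def integrated_1d_run(fig3):
    """A shared 1D integrated-model trajectory with a fully developed
    travelling transition zone."""
    lat = build_chain(50)
    ic = InitialCondition(kind=ICKind.LEFT_COLUMNS, n_columns=3)
    return integrate(fig3, lat, ic, t_end=45.0, dt=0.02, record_every=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(421)
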