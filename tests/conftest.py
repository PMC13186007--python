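import numpy as np
import pytest

from orrquant import geometry as G
from orrquant import synthdata as S

#: flat band thicknesses (um) used across geometry tests
FLAT_BANDS = {"GCL": 20, "IPL": 50, "INL": 30, "OPL": 20,
              "ONL": 40, "IS": 20, "OS": 20}


def make_flat_profile(bands=None, extent_um=1000.0, n=201):
    """Laterally uniform profile with the given band thicknesses."""
    bands = dict(FLAT_BANDS if bands is None else bands)
    x = np.linspace(0.0, extent_um, n)
    cum = np.cumsum([0.0] + [bands[name] for name in G.LAYER_NAMES])
    depths = np.tile(cum[:, None], (1, x.size)).astype(float)
    return G.LayerProfile(x=x, depths=depths)


@pytest.fixture
def flat_profile():
    return make_flat_profile()


@pytest.fixture(scope="session")
def treated_section():
    """One rendered treated section with heterogeneous degeneration."""
    spec = S.SectionSpec(length_um=1000.0, px_per_um=2.0,
                         condition="treated", seed=7)
    return S.generate_section(spec)


@pytest.fixture(scope="session")
def control_section():
    spec = S.SectionSpec(length_um=1000.0, px_per_um=2.0,
                         condition="control", seed=11)
    return S.generate_section(spec)
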