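import numpy as np
import pytest

from octplaq import (DEFAULT_TISSUE_PARAMS, PhantomSpec, SystemParams,
                     generate_phantom)

THREE_SECTORS = ((0.0, 120.0, 1, 1.2), (120.0, 240.0, 2, 1.2),
                 (240.0, 360.0, 3, 1.2))


@pytest.fixture(scope="session")
def sys_params():
    return SystemParams()


@pytest.fixture(scope="session")
def neutral_sys():
    """System with T ~ s ~ 1 over the imaged depth range."""
    return SystemParams(z0=0.0, zR=1e6, zC=0.0, zW=1e6)


@pytest.fixture(scope="session")
def three_sector_phantom(sys_params):
    """A speckled three-tissue phantom with a guide-wire shadow."""
    spec = PhantomSpec(tissue_sectors=THREE_SECTORS,
                       guidewire_sector=(200.0, 220.0), seed=7)
    img, labels, boundary = generate_phantom(spec, DEFAULT_TISSUE_PARAMS,
                                             sys_params)
    return spec, img, labels, boundary


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
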