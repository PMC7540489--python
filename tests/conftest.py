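import numpy as np
import pytest

from ringdye import LightHarvestingModel
from ringdye.geometry import AssemblyGeometry, ChromophoreSite, TransitionDipole


@pytest.fixture(scope="session")
def fitted():
    """Calibrated default model (lowest ring band at 810 nm, dye coupling 25 cm^-1)."""
    return LightHarvestingModel().fit()


@pytest.fixture
def lineshape(fitted):
    return fitted.lineshape()


def point_dipole_assembly(specs):
    """Ad-hoc assembly of single-transition sites for dimer/n-mer tests.

    ``specs``: iterable of (origin, direction, magnitude, energy).
    """
    sites = [
        ChromophoreSite(
            id=i,
            role="dye",
            transitions=[TransitionDipole(np.array(o, float), np.array(d, float), m, e)],
        )
        for i, (o, d, m, e) in enumerate(specs)
    ]
    return AssemblyGeometry(sites=sites, conformer="dye_only", ring_radius=0.0)
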