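import numpy as np
import pytest

from raftfilm.datatypes import Isotherm
from raftfilm.synthetic import composition_fixtures, mixture_spec_for


@pytest.fixture(scope="session")
def registry():
    """The deterministic DOPC:Chol:SM fixture registry (seed 0), built once."""
    return composition_fixtures(seed=0)


@pytest.fixture(scope="session")
def mixtures(registry):
    """MixtureSpec per ternary composition, sharing the session registry."""
    return {r: mixture_spec_for(r, registry) for r in ("2:1:1", "1:2:1", "1:1:2", "1:1:1")}


def linear_isotherm(a0=50.0, slope=2.0, a_min=30.0, a_max=48.0, n=100):
    """π = slope·(a0 − A) on a descending area grid; exact linear branch."""
    area = np.linspace(a_max, a_min, n)
    return Isotherm(area=area, pressure=slope * (a0 - area))
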