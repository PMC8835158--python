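import numpy as np
import pytest

from eegdyn.montage import default_montage
from eegdyn.microstate import canonical_templates
from eegdyn.synth import CohortSpec, make_cohort, make_prototype_maps


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def templates(montage):
    return canonical_templates(montage)


@pytest.fixture(scope="session")
def prototypes(montage):
    return make_prototype_maps(montage, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-effect cohort kept small for fast structural tests."""
    return make_cohort(CohortSpec(n_per_group=(4, 4), duration_s=20.0, seed=21))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
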