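import numpy as np
import pytest

from pilitransport.synthetic import SyntheticSpec, make_ideal_pilin, make_pathway_pilus

# Published model geometry: planted pathway distance triples (Å) and the
# scalar transport inputs of the two pilus models.
GS1_DISTANCES = (3.9, 6.1, 5.1)
GS2_DISTANCES = (5.2, 5.9, 3.9)
GS1_T_HOLE, GS1_T_ELEC = 1.56e-2, 3.25e-2
GS2_T_HOLE, GS2_T_ELEC = 1.46e-2, 2.93e-2
LAMBDA_EV = 0.37
RHO_PER_M3 = 4.00e26


@pytest.fixture(scope="session")
def ideal_pilin():
    return make_ideal_pilin(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def gs1_assembly():
    return make_pathway_pilus(SyntheticSpec(seed=0, distances=GS1_DISTANCES))


@pytest.fixture(scope="session")
def gs2_assembly():
    return make_pathway_pilus(SyntheticSpec(seed=0, distances=GS2_DISTANCES))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
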