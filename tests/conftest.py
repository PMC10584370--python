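import numpy as np
import pytest

from genodt import ionic, protocols


@pytest.fixture(scope="session")
def ge():
    return ionic.baseline_ge()


@pytest.fixture(scope="session")
def pkp2(ge):
    return ionic.make_variant(ge, "PKP2")


@pytest.fixture(scope="session")
def fibrosis(ge):
    return ionic.make_variant(ge, "FIBROSIS")


@pytest.fixture(scope="session")
def ge_rest(ge):
    return ionic.relax_to_rest(ge)


@pytest.fixture(scope="session")
def ge_steady(ge):
    """Final beat of 20-beat 1 Hz pacing, finely sampled."""
    return protocols.pace_to_steady_state(ge, bcl=1000.0, n_beats=20,
                                          sample_every=0.1)


@pytest.fixture(scope="session")
def pkp2_steady(pkp2):
    return protocols.pace_to_steady_state(pkp2, bcl=1000.0, n_beats=20,
                                          sample_every=0.1)


@pytest.fixture(scope="session")
def ge_restitution(ge):
    return protocols.s1s2_restitution(ge)


@pytest.fixture(scope="session")
def pkp2_restitution(pkp2):
    return protocols.s1s2_restitution(pkp2)
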