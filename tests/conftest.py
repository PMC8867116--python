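import numpy as np
import pytest

import polexo as px


@pytest.fixture(scope="session")
def catalogue():
    return px.fixtures()


@pytest.fixture(scope="session")
def single_mismatch_scheme():
    """Branched excision scheme for the 20 °C single-terminal-mismatch row."""
    params = px.get_fixture("excision_20C", "1").proofreading_params()
    return px.build_proofreading_scheme(params, conc_E=1.0, conc_D=0.25)


@pytest.fixture(scope="session")
def extension_n3_scheme():
    params = px.get_fixture("buried_extension_20C", "n-3").extension_params()
    return px.build_extension_scheme(params, conc_E=0.2, conc_D=0.075)


@pytest.fixture
def decay_scheme():
    """Single irreversible unimolecular decay D -> P at 2 s^-1."""
    from polexo.models import KineticScheme, Reaction, Species

    return KineticScheme(
        species=[Species("D", "free-dna"), Species("P", "absorbing-product")],
        reactions=[Reaction(("D",), ("P",), 2.0, "k")],
        initial_conditions={"D": 1.0},
        dna_moiety={"D": 1, "P": 1},
        enzyme_moiety={},
    )


def times_excision(n=20, t_max=10.0):
    return np.geomspace(1e-3, t_max, n)
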