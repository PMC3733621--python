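import pytest

from gemkin import (
    FixtureSpec,
    Metabolite,
    Network,
    Reaction,
    assemble_model,
    make_toy_network,
    make_yeast_like_fixture,
)


@pytest.fixture(scope="session")
def yeast():
    """(network, reference, phi) of the yeast-like fixture, built once."""
    return make_yeast_like_fixture()


@pytest.fixture(scope="session")
def yeast_kinetic_model(yeast):
    from gemkin import RateParameters

    net, ref, phi = yeast
    return assemble_model(net, ref, None, RateParameters(phi=phi))


@pytest.fixture(scope="session")
def chemostat_toy_model():
    from gemkin.fixtures import chemostat_toy

    return chemostat_toy()


@pytest.fixture()
def chain3():
    return make_toy_network(FixtureSpec(topology="chain", n=3, seed=7))


def two_step_chain(v: float = 2.0) -> Network:
    """E_ext -> A -> P_ext, both irreversible with product inhibition on the
    first step; admits the closed form [A] = sqrt(g1/g2), flux = v*sqrt(g1 g2)."""
    return Network(
        [
            Metabolite("E", role="boundary"),
            Metabolite("A"),
            Metabolite("P", role="boundary"),
        ],
        [
            Reaction("r1", {"E": -1.0, "A": 1.0}),
            Reaction("r2", {"A": -1.0, "P": 1.0}),
        ],
    )
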