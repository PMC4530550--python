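import pytest

from micropub import Agent, make_micropublication


def local(iri: str) -> str:
    """Last path/fragment component of an IRI, for readable assertions."""
    return iri.rsplit("#", 1)[-1].rsplit("/", 1)[-1]


def by_suffix(iris, suffix: str) -> str:
    matches = [i for i in iris if local(i) == suffix]
    assert len(matches) == 1, f"expected one {suffix!r}, got {matches}"
    return matches[0]


@pytest.fixture
def author():
    return Agent(id="http://example.org/micropub/agent/PSpilman", name="Patricia Spilman")


@pytest.fixture
def curator():
    return Agent(id="http://example.org/micropub/agent/KBCurator", name="KB Curator")


@pytest.fixture
def minimal_mp(author, curator):
    return make_micropublication(
        "rapamycin is an inhibitor of the mTOR pathway", author, curator
    )
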