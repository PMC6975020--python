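import pytest

from grnabc import DirectedGRN, Link, Sign, UndirectedGRN


@pytest.fixture
def activation_chain() -> DirectedGRN:
    """X -> Y, activation, the basic cascade motif."""
    return DirectedGRN(["X", "Y"], [Link("X", "Y", Sign.ACTIVATION)])


@pytest.fixture
def inhibition_chain() -> DirectedGRN:
    """X -| Y, inhibition."""
    return DirectedGRN(["X", "Y"], [Link("X", "Y", Sign.INHIBITION)])


@pytest.fixture
def path_abc() -> UndirectedGRN:
    """Undirected path A - B - C, both edges activating."""
    return UndirectedGRN(
        ["A", "B", "C"],
        [("A", "B", Sign.ACTIVATION), ("B", "C", Sign.ACTIVATION)],
    )


@pytest.fixture
def triangle() -> UndirectedGRN:
    """Undirected triangle A - B - C - A."""
    return UndirectedGRN(
        ["A", "B", "C"],
        [
            ("A", "B", Sign.ACTIVATION),
            ("B", "C", Sign.ACTIVATION),
            ("C", "A", Sign.ACTIVATION),
        ],
    )
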