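import pytest

from netdeduce.reference import reference_networks
from netdeduce.topology import InteractionClass

ALL_CLASSES = [
    InteractionClass("regulation", "direct"),
    InteractionClass("regulation", "one_intermediate"),
    InteractionClass("regulation", "two_intermediate"),
    InteractionClass("conversion", "two_state"),
    InteractionClass("conversion", "three_state"),
    InteractionClass("binding", "standard"),
]


@pytest.fixture(scope="session")
def refs():
    """The six minimal antagonistic networks, keyed by mechanism label."""
    return {r.label: r for r in reference_networks()}
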