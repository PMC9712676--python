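"""Enumeration, counting, and symmetry canonicalization."""

import pytest
from hypothesis import given, settings, strategies as st

from netdeduce.topology import (
    Edge,
    InteractionClass,
    NetworkTopology,
    apply_relabeling,
    canonicalize,
    class_size,
    count_networks,
    count_viable,
    edge_positions,
    enumerate_networks,
    orbit,
    swap_inputs,
    symmetry_group,
    unique_networks,
)
from conftest import ALL_CLASSES


# -- position tables -------------------------------------------------------


@pytest.mark.parametrize(
    "name,variant,n_positions",
    [
        ("regulation", "direct", 3),
        ("regulation", "one_intermediate", 6),
        ("regulation", "two_intermediate", 13),
        ("conversion", "two_state", 6),
        ("conversion", "three_state", 11),
        ("binding", "standard", 7),
    ],
)
def test_position_counts(name, variant, n_positions):
    assert len(edge_positions(InteractionClass(name, variant))) == n_positions


def test_unknown_class_rejected():
    with pytest.raises(ValueError, match="unsupported"):
        InteractionClass("regulation", "three_intermediate")
    with pytest.raises(ValueError, match="unsupported"):
        InteractionClass("binding", "two_state")


# -- published counts ------------------------------------------------------


@pytest.mark.parametrize(
    "name,variant,expected",
    [
        ("regulation", "direct", 12),
        ("regulation", "one_intermediate", 216),
        ("regulation", "two_intermediate", 472392),
        ("conversion", "two_state", 64),
        ("conversion", "three_state", 2048),
        ("binding", "standard", 128),
    ],
)
def test_class_sizes(name, variant, expected):
    assert class_size(InteractionClass(name, variant)) == expected


@pytest.mark.parametrize(
    "name,variant,n,expected",
    [
        ("regulation", "one_intermediate", 3, 8),
        ("regulation", "two_intermediate", 3, 2288),
        ("regulation", "two_intermediate", 4, 11440),
        ("regulation", "two_intermediate", 5, 41184),
        ("regulation", "two_intermediate", 6, 109824),
        ("binding", "standard", 4, 35),
        ("binding", "standard", 7, 1),
        ("conversion", "two_state", 0, 1),
        ("regulation", "one_intermediate", 2, 0),  # below mandatory minimum
        ("binding", "standard", 8, 0),  # above the position count
    ],
)
def test_stratum_counts(name, variant, n, expected):
    cls = InteractionClass(name, variant)
    assert count_networks(cls, n) == expected


@pytest.mark.parametrize("cls", ALL_CLASSES, ids=str)
def test_count_matches_enumeration_everywhere(cls):
    """count_networks is the closed form of the enumerator, every stratum."""
    heavy = cls.variant == "two_intermediate"
    for n in range(0, len(cls.spec.positions) + 1):
        expected = count_networks(cls, n)
        if heavy and n > 3:
            continue  # strata up to 2288 networks are plenty for the identity
        assert sum(1 for _ in enumerate_networks(cls, n)) == expected


@pytest.mark.parametrize("cls", ALL_CLASSES, ids=str)
def test_stratum_counts_sum_to_class_size(cls):
    """Summing configurations over strata recovers the class total.

    For signed classes each present optional edge contributes 2 states
    and absence 1, so the weighted sum telescopes to the ternary total;
    for binary classes this is the binomial theorem.
    """
    if cls.variant == "two_intermediate":
        total = sum(
            count_networks(cls, n) for n in range(len(cls.spec.positions) + 1)
        )
        assert total == 3**13  # free-position universe; class_size uses 2^3*3^10
    else:
        total = sum(
            count_networks(cls, n) for n in range(len(cls.spec.positions) + 1)
        )
        assert total == class_size(cls)


def test_viable_counts():
    """Structurally responsive candidates: both inputs wired, output wired."""
    assert count_viable(InteractionClass("conversion", "two_state"), 3) == 8
    assert count_viable(InteractionClass("binding", "standard"), 3) == 12


# -- enumeration determinism and legality ----------------------------------


def test_enumeration_is_deterministic():
    cls = InteractionClass("conversion", "three_state")
    run1 = [n.label() for n in enumerate_networks(cls, 4)]
    run2 = [n.label() for n in enumerate_networks(cls, 4)]
    assert run1 == run2
    assert len(run1) == len(set(run1))


def test_mandatory_edges_always_present():
    cls = InteractionClass("regulation", "one_intermediate")
    for net in enumerate_networks(cls, 4):
        positions = {e.position for e in net.edges}
        assert set(cls.spec.mandatory) <= positions
        assert net.edge_count == 4


def test_illegal_edges_rejected():
    cls = InteractionClass("regulation", "one_intermediate")
    with pytest.raises(ValueError, match="not a legal position"):
        NetworkTopology(
            cls,
            frozenset(
                [
                    Edge("regulation", "S1", "A", "up"),
                    Edge("regulation", "S2", "A", "up"),
                    Edge("regulation", "A", "M", "up"),
                    Edge("regulation", "S1", "M", "up"),  # inputs never hit M here
                ]
            ),
        )
    with pytest.raises(ValueError, match="sign"):
        Edge("activation", "A", "M", "up").validate()
    with pytest.raises(ValueError, match="sign"):
        Edge("regulation", "S1", "A").validate()


# -- symmetry --------------------------------------------------------------

_random_class = st.sampled_from(ALL_CLASSES)


@st.composite
def topologies(draw, cls=None):
    cls = cls or draw(_random_class)
    spec = cls.spec
    chosen = draw(
        st.sets(st.integers(0, len(spec.optional) - 1), max_size=len(spec.optional))
    )
    positions = list(spec.mandatory) + [spec.optional[i] for i in sorted(chosen)]
    edges = []
    for p in positions:
        sign = draw(st.sampled_from(("up", "down"))) if p.kind == "regulation" else None
        edges.append(Edge(*p, sign=sign))
    return NetworkTopology(cls, frozenset(edges))


@settings(derandomize=True, max_examples=80, deadline=None)
@given(topologies())
def test_canonicalize_idempotent_and_orbit_constant(net):
    canon = canonicalize(net)
    assert canonicalize(canon) == canon
    for sigma in symmetry_group(net.cls):
        relabeled = apply_relabeling(net, sigma)
        assert relabeled.cls == net.cls
        assert relabeled.edge_count == net.edge_count
        assert canonicalize(relabeled) == canon


@settings(derandomize=True, max_examples=40, deadline=None)
@given(topologies())
def test_orbit_size_divides_group_order(net):
    assert len(symmetry_group(net.cls)) % len(orbit(net)) == 0


def test_input_swap_orbit_example():
    cls = InteractionClass("regulation", "one_intermediate")
    a = NetworkTopology(
        cls,
        frozenset(
            [
                Edge("regulation", "S1", "A", "down"),
                Edge("regulation", "S2", "A", "up"),
                Edge("regulation", "A", "M", "down"),
            ]
        ),
    )
    assert canonicalize(a) == canonicalize(swap_inputs(a))
    assert canonicalize(a) != canonicalize(
        NetworkTopology(
            cls,
            frozenset(
                [
                    Edge("regulation", "S1", "A", "up"),
                    Edge("regulation", "S2", "A", "up"),
                    Edge("regulation", "A", "M", "down"),
                ]
            ),
        )
    )


def test_unique_network_counts(refs):
    one_int = InteractionClass("regulation", "one_intermediate")
    assert len(unique_networks(list(enumerate_networks(one_int, 3)))) == 6
    two_state = InteractionClass("conversion", "two_state")
    viable = [
        n
        for n in enumerate_networks(two_state, 3)
        if {"S1", "S2"} <= {e.source for e in n.edges}
        and any(e.target == "M" for e in n.edges)
    ]
    assert len(viable) == 8
    assert len(unique_networks(viable)) == 3


def test_unique_networks_edge_cases(refs):
    assert unique_networks([]) == []
    net = refs["double_repression"].topology
    assert unique_networks([net, swap_inputs(net)]) == [canonicalize(net)]
    with pytest.raises(ValueError, match="single class"):
        unique_networks([net, refs["sequestration"].topology])
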