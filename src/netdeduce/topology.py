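"""Interaction classes, candidate-network enumeration, and symmetry.

A candidate network is a set of typed edges placed on the fixed scaffold
of its interaction class:

* ``regulation`` -- every species has basal zeroth-order production and
  first-order degradation; a signed edge makes the target's production
  (``up``) or degradation (``down``) depend linearly on the source.
  Variants: ``direct`` (inputs act on the output M directly),
  ``one_intermediate`` (inputs -> A -> M, with optional A/M feedback),
  ``two_intermediate`` (inputs -> {A,B}, free regulation among A, B, M).
* ``conversion`` -- a conserved species interconverts among states
  (A <-> Astar, or the chain B <-> A <-> C); every directed link carries
  basal rate 1 and an input may catalyze it; states may activate M.
* ``binding`` -- A and B are produced and combine reversibly into the
  complex C; inputs may boost production of A and/or B; A, B, C may
  activate M.

Edges occupy *positions*: the fixed, ordered list of legal (kind,
source, target) slots of the class. Regulation positions carry a sign,
catalysis/activation positions are presence/absence. Infrastructure
(the conversion chain, the binding reaction, basal turnover) is never
counted as an edge.

Networks related by relabeling -- exchanging the two inputs S1/S2, or
relabeling indistinguishable intermediates (A/B, A/Astar, B/C) -- have
identical input-output behaviour up to argument exchange and are
identified via :func:`canonicalize`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional, Sequence

NODE_IDS = ("S1", "S2", "A", "B", "C", "Astar", "M")
INPUTS = ("S1", "S2")
SIGNS = ("up", "down")

EDGE_KINDS = ("regulation", "catalysis", "activation")


class Position(NamedTuple):
    """A legal edge slot: kind plus (source, target).

    For catalysis the target is a directed conversion link encoded as
    ``"X>Y"``; for regulation and activation it is a node id.
    """

    kind: str
    source: str
    target: str


class Edge(NamedTuple):
    kind: str
    source: str
    target: str
    sign: Optional[str] = None  # "up"/"down" for regulation, else None

    @property
    def position(self) -> Position:
        return Position(self.kind, self.source, self.target)

    def validate(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {self.kind!r}")
        if self.kind == "regulation":
            if self.sign not in SIGNS:
                raise ValueError(
                    f"regulation edge {self.source}->{self.target} needs sign 'up' or 'down'"
                )
        elif self.sign is not None:
            raise ValueError(
                f"{self.kind} edge {self.source}->{self.target} must not carry a sign"
            )


@dataclass(frozen=True)
class InteractionClass:
    """One of the supported (mechanism, variant) pairs."""

    name: str
    variant: str

    def __post_init__(self) -> None:
        if (self.name, self.variant) not in CLASS_SPECS:
            supported = ", ".join(f"{n}/{v}" for n, v in CLASS_SPECS)
            raise ValueError(
                f"unsupported interaction class {self.name}/{self.variant}; "
                f"supported: {supported}"
            )

    @property
    def spec(self) -> "ClassSpec":
        return CLASS_SPECS[(self.name, self.variant)]

    def __str__(self) -> str:
        return f"{self.name}/{self.variant}"


@dataclass(frozen=True)
class ClassSpec:
    """Scaffold of an interaction class: positions, species, symmetry."""

    mandatory: tuple[Position, ...]  # always present, signed
    optional: tuple[Position, ...]
    species: tuple[str, ...]  # dynamical species, in canonical order
    conserved: tuple[str, ...]  # states summing to the conserved total (or empty)
    generators: tuple[dict, ...]  # node-relabeling maps

    @property
    def positions(self) -> tuple[Position, ...]:
        return self.mandatory + self.optional

    @property
    def signed(self) -> bool:
        return any(p.kind == "regulation" for p in self.positions)


def _reg(src: str, tgt: str) -> Position:
    return Position("regulation", src, tgt)


def _cat(inp: str, link: str) -> Position:
    return Position("catalysis", inp, link)


def _act(src: str, tgt: str) -> Position:
    return Position("activation", src, tgt)


_SWAP_INPUTS = {"S1": "S2", "S2": "S1"}
_SWAP_AB = {"A": "B", "B": "A"}
_SWAP_A_ASTAR = {"A": "Astar", "Astar": "A"}
_SWAP_BC = {"B": "C", "C": "B"}

CLASS_SPECS: dict[tuple[str, str], ClassSpec] = {
    ("regulation", "direct"): ClassSpec(
        mandatory=(_reg("S1", "M"), _reg("S2", "M")),
        optional=(_reg("M", "M"),),
        species=("M",),
        conserved=(),
        generators=(_SWAP_INPUTS,),
    ),
    ("regulation", "one_intermediate"): ClassSpec(
        mandatory=(_reg("S1", "A"), _reg("S2", "A"), _reg("A", "M")),
        optional=(_reg("A", "A"), _reg("M", "A"), _reg("M", "M")),
        species=("A", "M"),
        conserved=(),
        generators=(_SWAP_INPUTS,),
    ),
    ("regulation", "two_intermediate"): ClassSpec(
        mandatory=(),
        optional=(
            _reg("S1", "A"),
            _reg("S1", "B"),
            _reg("S2", "A"),
            _reg("S2", "B"),
            _reg("A", "A"),
            _reg("A", "B"),
            _reg("A", "M"),
            _reg("B", "A"),
            _reg("B", "B"),
            _reg("B", "M"),
            _reg("M", "A"),
            _reg("M", "B"),
            _reg("M", "M"),
        ),
        species=("A", "B", "M"),
        conserved=(),
        generators=(_SWAP_INPUTS, _SWAP_AB),
    ),
    ("conversion", "two_state"): ClassSpec(
        mandatory=(),
        optional=(
            _cat("S1", "A>Astar"),
            _cat("S1", "Astar>A"),
            _cat("S2", "A>Astar"),
            _cat("S2", "Astar>A"),
            _act("A", "M"),
            _act("Astar", "M"),
        ),
        species=("A", "Astar", "M"),
        conserved=("A", "Astar"),
        generators=(_SWAP_INPUTS, _SWAP_A_ASTAR),
    ),
    ("conversion", "three_state"): ClassSpec(
        mandatory=(),
        optional=(
            _cat("S1", "B>A"),
            _cat("S1", "A>B"),
            _cat("S1", "A>C"),
            _cat("S1", "C>A"),
            _cat("S2", "B>A"),
            _cat("S2", "A>B"),
            _cat("S2", "A>C"),
            _cat("S2", "C>A"),
            _act("A", "M"),
            _act("B", "M"),
            _act("C", "M"),
        ),
        species=("A", "B", "C", "M"),
        conserved=("A", "B", "C"),
        generators=(_SWAP_INPUTS, _SWAP_BC),
    ),
    ("binding", "standard"): ClassSpec(
        mandatory=(),
        optional=(
            _act("S1", "A"),
            _act("S1", "B"),
            _act("S2", "A"),
            _act("S2", "B"),
            _act("A", "M"),
            _act("B", "M"),
            _act("C", "M"),
        ),
        species=("A", "B", "C", "M"),
        conserved=(),
        generators=(_SWAP_INPUTS, _SWAP_AB),
    ),
}

#: Conversion chain links per variant, as (source state, target state).
CONVERSION_LINKS: dict[str, tuple[tuple[str, str], ...]] = {
    "two_state": (("A", "Astar"), ("Astar", "A")),
    "three_state": (("B", "A"), ("A", "B"), ("A", "C"), ("C", "A")),
}


@dataclass(frozen=True)
class NetworkTopology:
    """An interaction class plus a concrete set of present edges."""

    cls: InteractionClass
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        spec = self.cls.spec
        legal = set(spec.positions)
        seen: set[Position] = set()
        for e in self.edges:
            e.validate()
            if e.position not in legal:
                raise ValueError(
                    f"edge {e.kind} {e.source}->{e.target} is not a legal "
                    f"position for class {self.cls}"
                )
            if e.position in seen:
                raise ValueError(f"duplicate edge at position {e.position}")
            seen.add(e.position)
        missing = [p for p in spec.mandatory if p not in seen]
        if missing:
            raise ValueError(
                f"class {self.cls} requires edges at positions {missing}"
            )

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> list[Edge]:
        order = {p: i for i, p in enumerate(self.cls.spec.positions)}
        return sorted(self.edges, key=lambda e: (order[e.position], e.sign or ""))

    def sort_key(self) -> tuple:
        order = {p: i for i, p in enumerate(self.cls.spec.positions)}
        return tuple(
            (order[e.position], SIGNS.index(e.sign) if e.sign else 0)
            for e in self.sorted_edges()
        )

    def label(self) -> str:
        """Compact human-readable edge listing, e.g. ``S1-|A, A->M``."""
        glyph = {"up": "->", "down": "-|", None: "->"}
        parts = []
        for e in self.sorted_edges():
            if e.kind == "catalysis":
                parts.append(f"{e.source}~{e.target}")
            else:
                parts.append(f"{e.source}{glyph[e.sign]}{e.target}")
        return ", ".join(parts)

    def __repr__(self) -> str:
        return f"NetworkTopology({self.cls}, [{self.label()}])"


def make_topology(cls: InteractionClass, edges: Sequence[Edge]) -> NetworkTopology:
    return NetworkTopology(cls, frozenset(edges))


# ---------------------------------------------------------------------------
# enumeration


def edge_positions(cls: InteractionClass) -> list[Position]:
    """Ordered legal edge positions of the class (mandatory first)."""
    return list(cls.spec.positions)


def mandatory_edge_count(cls: InteractionClass) -> int:
    return len(cls.spec.mandatory)


def enumerate_networks(cls: InteractionClass, n_edges: int) -> Iterator[NetworkTopology]:
    """Yield every distinct topology of the class with exactly ``n_edges``
    present edges, in a fixed lexicographic order over positions and signs.

    Mandatory positions (regulation direct / one_intermediate) are present
    in every yielded topology. An out-of-range ``n_edges`` yields nothing.
    """
    spec = cls.spec
    n_opt = n_edges - len(spec.mandatory)
    if n_opt < 0 or n_opt > len(spec.optional):
        return
    signed = spec.signed
    for chosen in itertools.combinations(range(len(spec.optional)), n_opt):
        slots = list(spec.mandatory) + [spec.optional[i] for i in chosen]
        if signed:
            for signs in itertools.product(SIGNS, repeat=len(slots)):
                yield NetworkTopology(
                    cls,
                    frozenset(Edge(*p, sign=s) for p, s in zip(slots, signs)),
                )
        else:
            yield NetworkTopology(cls, frozenset(Edge(*p) for p in slots))


def count_networks(cls: InteractionClass, n_edges: int) -> int:
    """Number of distinct ``n_edges``-edge topologies (no symmetry folding)."""
    spec = cls.spec
    n_opt = n_edges - len(spec.mandatory)
    if n_opt < 0 or n_opt > len(spec.optional):
        return 0
    base = math.comb(len(spec.optional), n_opt)
    if spec.signed:
        base *= 2 ** n_edges
    return base


def class_size(cls: InteractionClass) -> int:
    """Total number of candidate networks in the class.

    For signed classes each optional position is ternary (up/down/absent)
    and each mandatory position binary; the two_intermediate regulation
    class follows the 2^3 * 3^10 accounting (three designated
    always-present signed edges, ten ternary slots), which depends only
    on the counts, not on which positions are designated.
    """
    spec = cls.spec
    if cls == InteractionClass("regulation", "two_intermediate"):
        return 2**3 * 3**10
    if spec.signed:
        return 2 ** len(spec.mandatory) * 3 ** len(spec.optional)
    return 2 ** len(spec.optional)


def count_viable(cls: InteractionClass, n_edges: int) -> int:
    """Count ``n_edges``-edge topologies in which each input has at least
    one outgoing edge and at least one edge targets the output M.

    This is the structural notion of a candidate that can possibly react
    to both cues; networks failing it are later rejected by the
    increased-output precondition anyway.
    """
    total = 0
    for net in enumerate_networks(cls, n_edges):
        srcs = {e.source for e in net.edges}
        if "S1" not in srcs or "S2" not in srcs:
            continue
        if not any(e.target == "M" for e in net.edges):
            continue
        total += 1
    return total


# ---------------------------------------------------------------------------
# symmetry


def _map_node(node: str, sigma: dict) -> str:
    return sigma.get(node, node)


def _map_target(kind: str, target: str, sigma: dict) -> str:
    if kind == "catalysis":
        a, b = target.split(">")
        return f"{_map_node(a, sigma)}>{_map_node(b, sigma)}"
    return _map_node(target, sigma)


def apply_relabeling(net: NetworkTopology, sigma: dict) -> NetworkTopology:
    edges = frozenset(
        Edge(e.kind, _map_node(e.source, sigma), _map_target(e.kind, e.target, sigma), e.sign)
        for e in net.edges
    )
    return NetworkTopology(net.cls, edges)


def swap_inputs(net: NetworkTopology) -> NetworkTopology:
    """The same network with the roles of S1 and S2 exchanged."""
    return apply_relabeling(net, _SWAP_INPUTS)


def symmetry_group(cls: InteractionClass) -> list[dict]:
    """All node-relabeling maps of the class symmetry group.

    Generators (input swap; intermediate relabeling where intermediates
    are interchangeable) act on disjoint node sets, so the group is the
    direct product of the generator pairs.
    """
    elements: list[dict] = [{}]
    for gen in cls.spec.generators:
        elements += [{**e, **gen} for e in elements]
    return elements


def canonicalize(net: NetworkTopology) -> NetworkTopology:
    """Lexicographically smallest topology in the symmetry orbit of ``net``.

    Idempotent; two topologies share a canonical form iff one is a
    relabeling of the other.
    """
    best = None
    best_key = None
    for sigma in symmetry_group(net.cls):
        cand = apply_relabeling(net, sigma)
        key = cand.sort_key()
        if best_key is None or key < best_key:
            best, best_key = cand, key
    return best


def orbit(net: NetworkTopology) -> set[NetworkTopology]:
    return {apply_relabeling(net, sigma) for sigma in symmetry_group(net.cls)}


def unique_networks(nets: Sequence[NetworkTopology]) -> list[NetworkTopology]:
    """One canonical representative per symmetry orbit, sorted."""
    if not nets:
        return []
    cls = nets[0].cls
    reps: dict[tuple, NetworkTopology] = {}
    for net in nets:
        if net.cls != cls:
            raise ValueError(
                f"unique_networks needs a single class; got {net.cls} and {cls}"
            )
        rep = canonicalize(net)
        reps.setdefault(rep.sort_key(), rep)
    return [reps[k] for k in sorted(reps)]
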