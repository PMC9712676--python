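"""Topology serialization (JSON), validation, and DOT export.

Topology JSON schema::

    {
      "class": "regulation" | "conversion" | "binding",
      "variant": "<class variant>",
      "edges": [
        {"kind": "regulation", "source": "S1", "target": "A", "sign": "up"},
        {"kind": "catalysis",  "source": "S1", "target": "A>Astar"},
        {"kind": "activation", "source": "C",  "target": "M"}
      ]
    }

Node ids are drawn from {S1, S2, A, B, C, Astar, M}; catalysis targets
are directed conversion links encoded ``"X>Y"``. Regulation edges carry
a sign; catalysis/activation edges must not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .topology import EDGE_KINDS, NODE_IDS, SIGNS, Edge, InteractionClass, NetworkTopology


class TopologyValidationError(ValueError):
    """A topology document violates the JSON schema; names the field."""


def topology_to_dict(net: NetworkTopology) -> dict:
    edges = []
    for e in net.sorted_edges():
        d = {"kind": e.kind, "source": e.source, "target": e.target}
        if e.sign is not None:
            d["sign"] = e.sign
        edges.append(d)
    return {"class": net.cls.name, "variant": net.cls.variant, "edges": edges}


def _check_node(value: str, where: str) -> None:
    if value not in NODE_IDS:
        raise TopologyValidationError(
            f"{where}: unknown node id {value!r} (expected one of {NODE_IDS})"
        )


def topology_from_dict(doc: dict) -> NetworkTopology:
    if not isinstance(doc, dict):
        raise TopologyValidationError("document: expected a JSON object")
    for key in ("class", "variant", "edges"):
        if key not in doc:
            raise TopologyValidationError(f"{key}: missing required field")
    try:
        cls = InteractionClass(doc["class"], doc["variant"])
    except ValueError as exc:
        raise TopologyValidationError(f"class/variant: {exc}") from exc
    if not isinstance(doc["edges"], list):
        raise TopologyValidationError("edges: expected a list")
    edges = []
    for i, ed in enumerate(doc["edges"]):
        where = f"edges[{i}]"
        if not isinstance(ed, dict):
            raise TopologyValidationError(f"{where}: expected an object")
        kind = ed.get("kind")
        if kind not in EDGE_KINDS:
            raise TopologyValidationError(
                f"{where}.kind: {kind!r} is not one of {EDGE_KINDS}"
            )
        source = ed.get("source")
        target = ed.get("target")
        if not isinstance(source, str):
            raise TopologyValidationError(f"{where}.source: missing or not a string")
        if not isinstance(target, str):
            raise TopologyValidationError(f"{where}.target: missing or not a string")
        _check_node(source, f"{where}.source")
        if kind == "catalysis":
            parts = target.split(">")
            if len(parts) != 2:
                raise TopologyValidationError(
                    f"{where}.target: catalysis target must be a directed link 'X>Y'"
                )
            for p in parts:
                _check_node(p, f"{where}.target")
        else:
            _check_node(target, f"{where}.target")
        sign = ed.get("sign")
        if kind == "regulation":
            if sign not in SIGNS:
                raise TopologyValidationError(
                    f"{where}.sign: regulation edges need 'up' or 'down', got {sign!r}"
                )
        elif sign is not None:
            raise TopologyValidationError(
                f"{where}.sign: {kind} edges must not carry a sign"
            )
        extra = set(ed) - {"kind", "source", "target", "sign"}
        if extra:
            raise TopologyValidationError(f"{where}: unknown fields {sorted(extra)}")
        edge = Edge(kind, source, target, sign)
        if any(e.position == edge.position for e in edges):
            raise TopologyValidationError(
                f"{where}: duplicate edge position {source}->{target}"
            )
        edges.append(edge)
    try:
        return NetworkTopology(cls, frozenset(edges))
    except ValueError as exc:
        raise TopologyValidationError(f"edges: {exc}") from exc


def read_topology(path: Union[str, Path]) -> NetworkTopology:
    return topology_from_dict(json.loads(Path(path).read_text()))


def write_topology(net: NetworkTopology, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(topology_to_dict(net), indent=2) + "\n")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Sweep configuration, readable from a ``key = value`` file.

    CLI flags override file values. The grid maximum must exceed 2 —
    value antagonism of the known minimal networks only appears for
    inputs above 2 — and all tolerances must be positive.
    """

    s_max: float = 10.0
    step: float = 0.5
    eps: float = 1e-6
    h: float = 1e-3
    residual_tol: float = 1e-10
    divergence_bound: float = 1e6
    t_max: float = 1e4
    max_edges: Optional[int] = None
    sample: Optional[int] = None

    def __post_init__(self) -> None:
        if self.s_max <= 2:
            raise ValueError("s_max must exceed 2 to witness value antagonism")
        for name in ("step", "eps", "h", "residual_tol", "divergence_bound", "t_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
            field_ = cls.__dataclass_fields__[key]
            kwargs[key] = int(value) if field_.type == "Optional[int]" else float(value)
        return cls(**kwargs)

    def grid(self):
        import numpy as np

        n = int(round(self.s_max / self.step))
        return np.linspace(0.0, self.s_max, n + 1)

    def solver_options(self):
        from .dynamics import SolverOptions

        return SolverOptions(
            residual_tol=self.residual_tol,
            divergence_bound=self.divergence_bound,
            t_max=self.t_max,
        )


# ---------------------------------------------------------------------------
# DOT export


_INFRASTRUCTURE = {
    # conversion chains and the binding reaction, drawn as plain edges
    ("conversion", "two_state"): [("A", "Astar"), ("Astar", "A")],
    ("conversion", "three_state"): [("B", "A"), ("A", "B"), ("A", "C"), ("C", "A")],
    ("binding", "standard"): [("A", "C"), ("B", "C")],
}


def export_dot(net: NetworkTopology, path: Union[str, Path, None] = None) -> str:
    """Render the topology as a deterministic Graphviz digraph.

    Up-regulation/activation edges are plain arrows, down-regulation
    edges end in a tee, catalysis edges are dashed from the input to the
    midpoint label of the catalyzed link. Returns the DOT text; writes
    it to ``path`` when given.
    """
    nodes: set[str] = {"M"}
    lines = [f'digraph "{net.cls.name}_{net.cls.variant}" {{']
    body: list[str] = []
    for src, tgt in _INFRASTRUCTURE.get((net.cls.name, net.cls.variant), []):
        nodes.update((src, tgt))
        body.append(f'  "{src}" -> "{tgt}" [color=gray, arrowhead=vee];')
    for e in net.sorted_edges():
        nodes.add(e.source)
        if e.kind == "catalysis":
            a, b = e.target.split(">")
            nodes.update((a, b))
            body.append(f'  "{e.source}" -> "{a}_{b}_link" [style=dashed];')
            body.append(f'  "{a}_{b}_link" [label="{a}>{b}", shape=plaintext];')
        elif e.sign == "down":
            nodes.add(e.target)
            body.append(f'  "{e.source}" -> "{e.target}" [arrowhead=tee];')
        else:
            nodes.add(e.target)
            body.append(f'  "{e.source}" -> "{e.target}";')
    for n in sorted(nodes):
        lines.append(f'  "{n}";')
    lines.extend(body)
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
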