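"""Known minimal antagonistic networks and their closed-form responses.

Six fixtures, one per (interaction class, antagonism type) pair, each a
mechanistically named minimal network together with its exact
steady-state input-output function at unit parameters:

======================  ==========================  =========  =============
label                   mechanism                   class      criterion
======================  ==========================  =========  =============
double_repression       repression of a repressor   regulation slope
pathway_saturation      shared conversion step      conversion slope
complex_formation       limiting binding partner    binding    slope
mutual_inhibition       cross-repressing pathways   regulation value
competing_fluxes        opposing conversion drives  conversion value
sequestration           complex removes activators  binding    value
======================  ==========================  =========  =============

The ``sequestration`` fixture carries two formulas: the normative one,
``sqrt(s1^2 + s2^2 - 2 s1 s2 + 2 s1 + 2 s2 + 5)``, derived from the
compiled dynamics, and an ``as_printed`` variant with cross term
``-s1 s2`` that circulates in the literature. The printed variant agrees
on both axes (s2 = 0 or s1 = 0) but provably cannot satisfy the
value-antagonism condition anywhere: it would require s1 > s2 + 2 and
s2 > s1 + 2 simultaneously. The normative form does exhibit value
antagonism (e.g. at s1 = s2 = 3) and is what the sequestration network's
rate equations actually produce. :func:`verify_equations` surfaces the
discrepancy rather than patching it silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import sympy as sp

from .criteria import CriteriaResult, classify
from .dynamics import build_rate_system, closed_form_m, default_grid, evaluate_points
from .topology import Edge, InteractionClass, NetworkTopology, canonicalize

_S1, _S2 = sp.symbols("s1 s2", nonnegative=True)


@dataclass(frozen=True)
class ReferenceNetwork:
    label: str
    topology: NetworkTopology
    formula: sp.Expr
    criterion: str  # the antagonism type the network minimally achieves
    as_printed: Optional[sp.Expr] = None
    expected: dict = None  # criteria flags the fixture must reproduce


def _reg(s, t, sign):
    return Edge("regulation", s, t, sign)


def _cat(i, link):
    return Edge("catalysis", i, link)


def _act(s, t):
    return Edge("activation", s, t)


def _net(name, variant, edges) -> NetworkTopology:
    return canonicalize(NetworkTopology(InteractionClass(name, variant), frozenset(edges)))


def reference_networks() -> list[ReferenceNetwork]:
    """The six minimal networks with their exact response formulas."""
    slope_flags = dict(
        increased_output=True, slope_antagonism=True, value_antagonism=False, value_synergy=True
    )
    value_flags = dict(increased_output=True, slope_antagonism=True, value_antagonism=True)
    return [
        ReferenceNetwork(
            "double_repression",
            _net(
                "regulation",
                "one_intermediate",
                [_reg("S1", "A", "down"), _reg("S2", "A", "down"), _reg("A", "M", "down")],
            ),
            (_S1 + _S2 + 1) / (_S1 + _S2 + 2),
            "slope",
            expected=slope_flags,
        ),
        ReferenceNetwork(
            "pathway_saturation",
            _net(
                "conversion",
                "two_state",
                [_cat("S1", "A>Astar"), _cat("S2", "A>Astar"), _act("Astar", "M")],
            ),
            (2 * _S1 + 2 * _S2 + 3) / (_S1 + _S2 + 2),
            "slope",
            expected=slope_flags,
        ),
        ReferenceNetwork(
            "complex_formation",
            _net(
                "binding",
                "standard",
                [_act("S1", "B"), _act("S2", "B"), _act("C", "M")],
            ),
            (_S1 + _S2 + 5 - sp.sqrt((_S1 + _S2 + 1) ** 2 + 4)) / 2,
            "slope",
            expected=slope_flags,
        ),
        ReferenceNetwork(
            "mutual_inhibition",
            _net(
                "regulation",
                "two_intermediate",
                [
                    _reg("S1", "A", "up"),
                    _reg("S2", "B", "up"),
                    _reg("A", "B", "down"),
                    _reg("B", "A", "down"),
                    _reg("A", "M", "up"),
                    _reg("B", "M", "up"),
                ],
            ),
            sp.sqrt(_S1**2 - 2 * (_S2 - 1) * _S1 + (_S2 + 1) ** 2 + 4),
            "value",
            expected=value_flags,
        ),
        ReferenceNetwork(
            "competing_fluxes",
            _net(
                "conversion",
                "three_state",
                [
                    _cat("S1", "B>A"),
                    _cat("S1", "A>C"),
                    _cat("S2", "C>A"),
                    _cat("S2", "A>B"),
                    _act("B", "M"),
                    _act("C", "M"),
                ],
            ),
            (2 * _S1**2 + 2 * _S2**2 + _S1 * _S2 + 5 * _S1 + 5 * _S2 + 5)
            / (_S1**2 + _S2**2 + _S1 * _S2 + 3 * _S1 + 3 * _S2 + 3),
            "value",
            expected=value_flags,
        ),
        ReferenceNetwork(
            "sequestration",
            _net(
                "binding",
                "standard",
                [_act("S1", "A"), _act("S2", "B"), _act("A", "M"), _act("B", "M")],
            ),
            sp.sqrt(_S1**2 + _S2**2 - 2 * _S1 * _S2 + 2 * _S1 + 2 * _S2 + 5),
            "value",
            as_printed=sp.sqrt(_S1**2 + _S2**2 - _S1 * _S2 + 2 * _S1 + 2 * _S2 + 5),
            expected=value_flags,
        ),
    ]


def get_reference(label: str) -> ReferenceNetwork:
    for ref in reference_networks():
        if ref.label == label:
            return ref
    raise KeyError(f"unknown reference network {label!r}")


# ---------------------------------------------------------------------------
# verification


def _symbolically_equal(a: sp.Expr, b: sp.Expr) -> bool:
    """Algebraic equality, robust to nested radicals.

    Tries direct simplification of the difference, then of the
    difference of squares (both expressions here are nonnegative), then
    falls back to exact rational evaluation at several points.
    """
    diff = sp.simplify(sp.radsimp(a - b))
    if diff == 0:
        return True
    if sp.simplify(sp.expand(a**2 - b**2)) == 0:
        # equal magnitudes; both branches are nonnegative on the domain
        probe = {_S1: sp.Rational(3, 7), _S2: sp.Rational(11, 5)}
        return sp.simplify(a.subs(probe) - b.subs(probe)) == 0
    probes = [
        {_S1: sp.Rational(1, 3), _S2: sp.Rational(5, 2)},
        {_S1: sp.Rational(9, 4), _S2: sp.Rational(2, 7)},
        {_S1: sp.Integer(4), _S2: sp.Integer(4)},
    ]
    return all(sp.simplify(a.subs(p) - b.subs(p)) == 0 for p in probes)


def printed_sequestration_value_antagonism_feasible() -> bool:
    """Whether the printed sequestration formula can satisfy value antagonism.

    For the printed form, m(s1,s2)^2 - m(s1,0)^2 = s2 (s2 - s1 + 2), so
    undershooting both axis responses needs s1 > s2 + 2 and (by input
    exchange) s2 > s1 + 2 at the same point -- an empty region. Returns
    the feasibility verdict computed symbolically.
    """
    printed = get_reference("sequestration").as_printed
    gap1 = sp.expand(printed**2 - printed.subs(_S2, 0) ** 2)
    gap2 = sp.expand(printed**2 - printed.subs(_S1, 0) ** 2)
    assert gap1 == sp.expand(_S2 * (_S2 - _S1 + 2))
    assert gap2 == sp.expand(_S1 * (_S1 - _S2 + 2))
    # with s1, s2 > 0 both gaps are negative only if the bracketed factors
    # are; their sum is a positive constant, so the region is empty
    factor_sum = sp.expand((_S2 - _S1 + 2) + (_S1 - _S2 + 2))
    return not (factor_sum.is_positive and factor_sum.is_constant())


def verify_equations(tol: float = 1e-6, grid: Optional[np.ndarray] = None) -> dict:
    """Check the compiled dynamics against every reference formula.

    For the five algebraically clean fixtures: symbolic equality of the
    derived closed form plus numeric grid agreement. For sequestration:
    full agreement with the normative formula everywhere and axis-only
    agreement with the printed variant, whose analytic inability to show
    value antagonism is recorded in the report.
    """
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    S1g, S2g = np.meshgrid(g, g, indexing="ij")
    report: dict[str, dict] = {}
    for ref in reference_networks():
        sys = build_rate_system(ref.topology)
        m_num, status = evaluate_points(sys, S1g.ravel(), S2g.ravel())
        f = sp.lambdify((_S1, _S2), ref.formula, "numpy")
        m_ref = np.asarray(f(S1g.ravel(), S2g.ravel()), dtype=float)
        numeric_err = float(np.max(np.abs(m_num - m_ref)))
        cf = closed_form_m(sys)
        entry = {
            "numeric_max_err": numeric_err,
            "numeric_ok": bool(np.all(status == "converged") and numeric_err <= tol),
            "symbolic_ok": cf is not None and _symbolically_equal(cf, ref.formula),
        }
        if ref.as_printed is not None:
            axis_match = _symbolically_equal(
                ref.formula.subs(_S2, 0), ref.as_printed.subs(_S2, 0)
            ) and _symbolically_equal(
                ref.formula.subs(_S1, 0), ref.as_printed.subs(_S1, 0)
            )
            entry["printed_axis_ok"] = bool(axis_match)
            entry["printed_value_antagonism_feasible"] = (
                printed_sequestration_value_antagonism_feasible()
            )
        entry["ok"] = entry["numeric_ok"] and entry["symbolic_ok"]
        report[ref.label] = entry
    report["all_ok"] = all(v["ok"] for k, v in report.items() if isinstance(v, dict))
    return report


#: every enumeration quantity with a published printed value
EXPECTED_COUNTS: list[tuple[str, str, object, int]] = [
    ("regulation/one_intermediate", "class_size", None, 216),
    ("regulation/one_intermediate", "count", 3, 8),
    ("regulation/one_intermediate", "unique", 3, 6),
    ("conversion/two_state", "class_size", None, 64),
    ("conversion/two_state", "viable", 3, 8),
    ("conversion/two_state", "unique_viable", 3, 3),
    ("binding/standard", "class_size", None, 128),
    ("binding/standard", "viable", 3, 12),
    ("regulation/two_intermediate", "class_size", None, 472392),
    ("regulation/two_intermediate", "count", 3, 2288),
    ("regulation/two_intermediate", "count", 4, 11440),
    ("regulation/two_intermediate", "count", 5, 41184),
    ("regulation/two_intermediate", "count", 6, 109824),
    ("conversion/three_state", "class_size", None, 2048),
    ("binding/standard", "count", 4, 35),
]


def verify_counts() -> dict:
    """Recompute every printed enumeration count and compare."""
    from .topology import (
        class_size,
        count_networks,
        count_viable,
        enumerate_networks,
        unique_networks,
    )

    rows = []
    for cls_id, kind, n, expected in EXPECTED_COUNTS:
        name, variant = cls_id.split("/")
        cls = InteractionClass(name, variant)
        if kind == "class_size":
            got = class_size(cls)
        elif kind == "count":
            got = count_networks(cls, n)
        elif kind == "viable":
            got = count_viable(cls, n)
        elif kind == "unique":
            got = len(unique_networks(list(enumerate_networks(cls, n))))
        else:  # unique_viable
            nets = [
                net
                for net in enumerate_networks(cls, n)
                if {"S1", "S2"} <= {e.source for e in net.edges}
                and any(e.target == "M" for e in net.edges)
            ]
            got = len(unique_networks(nets))
        rows.append(
            {"class": cls_id, "kind": kind, "n_edges": n, "expected": expected,
             "computed": got, "ok": got == expected}
        )
    return {"rows": rows, "all_ok": all(r["ok"] for r in rows)}


def verify_classifications(grid=None) -> dict:
    """Check each fixture reproduces its expected criteria flags."""
    report = {}
    for ref in reference_networks():
        res = classify(ref.topology, grid=grid)
        checks = {
            k: getattr(res, k) == v for k, v in ref.expected.items()
        }
        report[ref.label] = {
            "flags": {k: getattr(res, k) for k in ref.expected},
            "expected": ref.expected,
            "ok": all(checks.values()) and not res.excluded,
        }
    report["all_ok"] = all(v["ok"] for k, v in report.items() if isinstance(v, dict))
    return report
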