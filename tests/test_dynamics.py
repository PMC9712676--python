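"""Compiled rate equations, steady states, and response surfaces."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings

from netdeduce.dynamics import (
    CONVERGED,
    DIVERGED,
    NOT_CONVERGED,
    SolverOptions,
    build_rate_system,
    closed_form_m,
    evaluate_points,
    response_surface,
    steady_state,
)
from netdeduce.topology import Edge, InteractionClass, NetworkTopology, swap_inputs
from test_topology import topologies

S1, S2 = sp.symbols("s1 s2", nonnegative=True)


def _m(net, s1, s2):
    ss = steady_state(build_rate_system(net), s1, s2)
    assert ss.status == CONVERGED
    return ss.m


# -- agreement with the exact response formulas ----------------------------

POINTS = [(0.0, 0.0), (1.0, 1.0), (2.5, 0.0), (0.5, 7.0), (10.0, 10.0)]


@pytest.mark.parametrize(
    "label",
    [
        "double_repression",
        "pathway_saturation",
        "complex_formation",
        "mutual_inhibition",
        "competing_fluxes",
        "sequestration",
    ],
)
def test_steady_state_matches_formula(refs, label):
    ref = refs[label]
    f = sp.lambdify((S1, S2), ref.formula, "numpy")
    sys = build_rate_system(ref.topology)
    for a, b in POINTS:
        assert steady_state(sys, a, b).m == pytest.approx(float(f(a, b)), abs=1e-8)
    # and the vectorized fast path agrees
    pts = np.array(POINTS)
    m, status = evaluate_points(sys, pts[:, 0], pts[:, 1])
    assert np.all(status == CONVERGED)
    np.testing.assert_allclose(m, f(pts[:, 0], pts[:, 1]), atol=1e-8)


def test_specific_printed_values(refs):
    """Spot values obtained by direct substitution into the formulas."""
    assert _m(refs["pathway_saturation"].topology, 1, 1) == pytest.approx(7 / 4, abs=1e-9)
    assert _m(refs["complex_formation"].topology, 0, 0) == pytest.approx(
        (5 - np.sqrt(5)) / 2, abs=1e-9
    )
    assert _m(refs["mutual_inhibition"].topology, 0, 0) == pytest.approx(
        np.sqrt(5), abs=1e-9
    )
    assert _m(refs["competing_fluxes"].topology, 0, 0) == pytest.approx(5 / 3, abs=1e-9)


def test_isolated_output_settles_at_basal():
    """With no input edges the output balances production and decay at 1."""
    net = NetworkTopology(
        InteractionClass("conversion", "two_state"),
        frozenset([Edge("catalysis", "S1", "A>Astar"), Edge("catalysis", "S2", "A>Astar")]),
    )
    assert _m(net, 3.0, 4.0) == pytest.approx(1.0, abs=1e-9)


# -- closed forms ----------------------------------------------------------


def test_closed_form_matches_numeric(refs):
    ref = refs["competing_fluxes"]
    sys = build_rate_system(ref.topology)
    cf = closed_form_m(sys)
    assert cf is not None
    assert sp.simplify(cf - ref.formula) == 0
    f = sp.lambdify((S1, S2), cf, "numpy")
    g = np.linspace(0, 10, 11)
    A, B = np.meshgrid(g, g, indexing="ij")
    m, status = evaluate_points(sys, A.ravel(), B.ravel())
    assert np.all(status == CONVERGED)
    np.testing.assert_allclose(m, f(A.ravel(), B.ravel()), atol=1e-6)


def test_closed_form_absent_is_none_not_error():
    # a diverging system has no admissible steady-state branch
    net = NetworkTopology(
        InteractionClass("regulation", "one_intermediate"),
        frozenset(
            [
                Edge("regulation", "S1", "A", "down"),
                Edge("regulation", "S2", "A", "down"),
                Edge("regulation", "A", "M", "up"),
                Edge("regulation", "M", "M", "up"),
            ]
        ),
    )
    assert closed_form_m(build_rate_system(net)) is None


# -- divergence and failure handling ---------------------------------------


def test_self_activation_diverges():
    """Net self-up-regulation of M leaves dM/dt >= 1: no steady state."""
    net = NetworkTopology(
        InteractionClass("regulation", "one_intermediate"),
        frozenset(
            [
                Edge("regulation", "S1", "A", "down"),
                Edge("regulation", "S2", "A", "down"),
                Edge("regulation", "A", "M", "up"),
                Edge("regulation", "M", "M", "up"),
            ]
        ),
    )
    sys = build_rate_system(net)
    m, status = evaluate_points(sys, np.array([1.0]), np.array([1.0]))
    assert status[0] in (DIVERGED, NOT_CONVERGED)
    assert np.isnan(m[0])
    with pytest.raises(ValueError, match="no steady state"):
        _ = steady_state(sys, 1.0, 1.0).m


def test_mismatched_input_shapes_rejected(refs):
    sys = build_rate_system(refs["double_repression"].topology)
    with pytest.raises(ValueError, match="same shape"):
        evaluate_points(sys, np.zeros(3), np.zeros(4))


# -- conservation, positivity, initial conditions --------------------------


@pytest.mark.parametrize("label", ["pathway_saturation", "competing_fluxes"])
def test_conversion_conserves_total(refs, label):
    """The conserved states sum to 1 along the whole trajectory."""
    from scipy.integrate import solve_ivp

    sys = build_rate_system(refs[label].topology)
    states = [sys.species.index(s) for s in sys.conserved]
    sol = solve_ivp(
        lambda t, y: sys.rhs(y, 2.0, 3.0),
        (0, 100.0),
        sys.default_state(),
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
        t_eval=np.linspace(0, 100.0, 200),
    )
    totals = sol.y[states, :].sum(axis=0)
    np.testing.assert_allclose(totals, 1.0, atol=1e-8)


def test_converged_states_positive(refs):
    for ref in refs.values():
        ss = steady_state(build_rate_system(ref.topology), 1.5, 0.5)
        assert ss.status == CONVERGED
        assert ss.residual <= 1e-10
        produced = [s for s in ss.values if s not in ("C",)]
        assert all(ss.values[s] > 0 for s in produced)


def test_initial_condition_independence(refs):
    """The reachable steady state does not depend on where the dynamics start."""
    rng = np.random.default_rng(7)
    for ref in refs.values():
        sys = build_rate_system(ref.topology)
        base = steady_state(sys, 1.0, 2.0)
        for _ in range(20):
            x0 = rng.uniform(0.05, 3.0, size=len(sys.species))
            if sys.conserved:
                idx = [sys.species.index(s) for s in sys.conserved]
                x0[idx] /= x0[idx].sum()
            ss = steady_state(sys, 1.0, 2.0, x0=x0)
            assert ss.status == CONVERGED
            for sp_name in sys.species:
                assert ss.values[sp_name] == pytest.approx(
                    base.values[sp_name], abs=1e-6
                )


# -- equivariance under input exchange -------------------------------------


@settings(derandomize=True, max_examples=60, deadline=None)
@given(topologies())
def test_input_swap_equivariance(net):
    """m of the swapped network at (s2, s1) equals m of the network at (s1, s2)."""
    sys = build_rate_system(net)
    sys_sw = build_rate_system(swap_inputs(net))
    a = np.array([0.0, 1.0, 4.0])
    b = np.array([2.0, 0.5, 4.0])
    m1, st1 = evaluate_points(sys, a, b, integrate_fallback=False)
    m2, st2 = evaluate_points(sys_sw, b, a, integrate_fallback=False)
    assert list(st1) == list(st2)
    np.testing.assert_allclose(m1, m2, atol=1e-7, equal_nan=True)


# -- fast path vs integrator ------------------------------------------------


@settings(derandomize=True, max_examples=25, deadline=None)
@given(topologies())
def test_fast_path_agrees_with_integration(net):
    sys = build_rate_system(net)
    m, status = evaluate_points(sys, np.array([1.0]), np.array([3.0]))
    ss = steady_state(sys, 1.0, 3.0)
    if status[0] == CONVERGED:
        assert ss.status == CONVERGED
        assert m[0] == pytest.approx(ss.values["M"], abs=1e-7)
    else:
        assert ss.status in (DIVERGED, NOT_CONVERGED)


# -- response surfaces ------------------------------------------------------


def test_surface_bounds_and_validity(refs):
    surf = response_surface(refs["double_repression"].topology, np.arange(11.0))
    assert surf.valid
    assert np.all(surf.m > 0.5) and np.all(surf.m < 1.0)


def test_surface_of_symmetric_network_is_symmetric(refs):
    surf = response_surface(refs["complex_formation"].topology, np.arange(6.0))
    np.testing.assert_allclose(surf.m, surf.m.T, atol=1e-9)


def test_surface_transposes_under_input_swap(refs):
    net = refs["mutual_inhibition"].topology
    g = np.arange(6.0)
    np.testing.assert_allclose(
        response_surface(net, g).m,
        response_surface(swap_inputs(net), g).m.T,
        atol=1e-8,
    )


def test_surface_invalid_when_divergent():
    net = NetworkTopology(
        InteractionClass("regulation", "one_intermediate"),
        frozenset(
            [
                Edge("regulation", "S1", "A", "up"),
                Edge("regulation", "S2", "A", "up"),
                Edge("regulation", "A", "M", "up"),
                Edge("regulation", "M", "M", "up"),
            ]
        ),
    )
    surf = response_surface(net, np.array([0.0, 1.0]))
    assert not surf.valid


def test_negative_grid_rejected(refs):
    with pytest.raises(ValueError, match="nonnegative"):
        response_surface(refs["double_repression"].topology, np.array([-1.0, 0.0]))


def test_random_restart_verification(refs):
    """The fixtures have a unique reachable steady state: never ambiguous."""
    from netdeduce.dynamics import steady_state_with_restarts

    sys = build_rate_system(refs["mutual_inhibition"].topology)
    ss = steady_state_with_restarts(sys, 1.0, 4.0, n_restarts=5, seed=3)
    assert ss.status == CONVERGED
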