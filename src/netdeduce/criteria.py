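"""Response criteria: increased output, value/slope antagonism, synergy.

All criteria are evaluated on a steady-state response surface over a
nonnegative input grid with a strict-inequality margin ``eps``:

* increased output (precondition): each input alone raises the output
  above basal, ``m(s,0) > m(0,0)`` and ``m(0,s) > m(0,0)`` for every
  grid value s > 0. Networks failing it (or failing to converge) are
  excluded from any antagonism claim.
* value antagonism: some interior point has ``m(s1,s2) < m(s1,0)`` and
  ``m(s1,s2) < m(0,s2)``.
* value synergy: some interior point has ``m(s1,s2)`` above both
  single-input outputs.
* slope antagonism: for some pair (s1, s2) the single-input slopes
  ``dm(s1,0)/ds1`` and ``dm(0,s2)/ds2`` are positive while the diagonal
  slope ``dm/ds1 + dm/ds2`` at (s1, s2) is below each of them.

Derivatives come from the symbolic closed form when one is supplied,
otherwise from central finite differences of the steady-state solver
(one-sided on the s = 0 boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import sympy as sp

from .dynamics import (
    CONVERGED,
    ResponseSurface,
    SolverOptions,
    build_rate_system,
    response_surface,
)
from .topology import NetworkTopology

#: margin on every strict inequality
DEFAULT_EPS = 1e-6
#: finite-difference step for slopes
DEFAULT_H = 1e-3


@dataclass
class CriteriaResult:
    """Outcome of the response criteria for one network."""

    net: NetworkTopology
    increased_output: bool = False
    value_antagonism: bool = False
    slope_antagonism: bool = False
    value_synergy: bool = False
    witnesses: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    eps: float = DEFAULT_EPS
    grid: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return {
            "network": self.net.label(),
            "class": self.net.cls.name,
            "variant": self.net.cls.variant,
            "edge_count": self.net.edge_count,
            "increased_output": self.increased_output,
            "value_antagonism": self.value_antagonism,
            "slope_antagonism": self.slope_antagonism,
            "value_synergy": self.value_synergy,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
            "witnesses": {k: [list(map(float, w)) for w in v] for k, v in self.witnesses.items()},
        }


def _axis_values(surface: ResponseSurface) -> tuple[np.ndarray, np.ndarray, float]:
    m1 = surface.m[:, 0]  # m(s, 0)
    m2 = surface.m[0, :]  # m(0, s)
    return m1, m2, surface.m[0, 0]


def check_increased_output(surface: ResponseSurface, eps: float = DEFAULT_EPS) -> bool:
    """Does each input alone raise the output above basal at every grid level?"""
    if not surface.valid:
        raise ValueError("surface has non-converged points; network must be excluded")
    m1, m2, m00 = _axis_values(surface)
    return bool(np.all(m1[1:] > m00 + eps) and np.all(m2[1:] > m00 + eps))


def _value_witnesses(surface: ResponseSurface, eps: float, antagonism: bool) -> list:
    m = surface.m
    m1 = m[:, 0][:, None]  # m(s1, 0)
    m2 = m[0, :][None, :]  # m(0, s2)
    if antagonism:
        hit = (m < m1 - eps) & (m < m2 - eps)
    else:
        hit = (m > m1 + eps) & (m > m2 + eps)
    hit[0, :] = False
    hit[:, 0] = False
    ii, jj = np.nonzero(hit)
    return [
        (float(surface.s1_values[i]), float(surface.s2_values[j])) for i, j in zip(ii, jj)
    ]


def check_value_antagonism(
    surface: ResponseSurface, eps: float = DEFAULT_EPS
) -> tuple[bool, list[tuple[float, float]]]:
    """Interior points where both inputs together undershoot each alone."""
    w = _value_witnesses(surface, eps, antagonism=True)
    return bool(w), w


def check_value_synergy(
    surface: ResponseSurface, eps: float = DEFAULT_EPS
) -> tuple[bool, list[tuple[float, float]]]:
    w = _value_witnesses(surface, eps, antagonism=False)
    return bool(w), w


def _numeric_partials(surface: ResponseSurface, h: float) -> tuple[np.ndarray, ...]:
    """Axis slopes d1(s), d2(s) and the diagonal slope on the full grid,
    by central differences (forward at the s = 0 boundary)."""
    g = surface.s1_values
    zeros = np.zeros_like(g)
    lo = np.maximum(g - h, 0.0)
    hi = g + h
    span = hi - lo
    d1 = (surface.evaluate(hi, zeros) - surface.evaluate(lo, zeros)) / span
    d2 = (surface.evaluate(zeros, hi) - surface.evaluate(zeros, lo)) / span
    S1, S2 = np.meshgrid(g, surface.s2_values, indexing="ij")
    lo1 = np.maximum(S1 - h, 0.0)
    lo2 = np.maximum(S2 - h, 0.0)
    p1 = (surface.evaluate(S1 + h, S2) - surface.evaluate(lo1, S2)) / (S1 + h - lo1)
    p2 = (surface.evaluate(S1, S2 + h) - surface.evaluate(S1, lo2)) / (S2 + h - lo2)
    return d1, d2, p1 + p2


def _symbolic_partials(
    surface: ResponseSurface, closed_form: sp.Expr
) -> tuple[np.ndarray, ...]:
    s1, s2 = sp.symbols("s1 s2", nonnegative=True)
    dm1 = sp.lambdify((s1, s2), sp.diff(closed_form, s1), "numpy")
    dm2 = sp.lambdify((s1, s2), sp.diff(closed_form, s2), "numpy")
    g = surface.s1_values
    zeros = np.zeros_like(g)
    d1 = np.broadcast_to(dm1(g, zeros), g.shape).astype(float)
    d2 = np.broadcast_to(dm2(zeros, g), g.shape).astype(float)
    S1, S2 = np.meshgrid(g, surface.s2_values, indexing="ij")
    diag = np.broadcast_to(dm1(S1, S2) + dm2(S1, S2), S1.shape).astype(float)
    return d1, d2, diag


def check_slope_antagonism(
    surface: ResponseSurface,
    eps: float = DEFAULT_EPS,
    h: float = DEFAULT_H,
    closed_form: Optional[sp.Expr] = None,
) -> tuple[bool, list[tuple[float, float]]]:
    """Pairs (s1, s2) where both single-input slopes are positive but the
    diagonal slope at (s1, s2) falls below each of them."""
    if closed_form is not None:
        d1, d2, diag = _symbolic_partials(surface, closed_form)
    else:
        d1, d2, diag = _numeric_partials(surface, h)
    ok_axis = (d1[:, None] > eps) & (d2[None, :] > eps)
    hit = ok_axis & (diag < d1[:, None] - eps) & (diag < d2[None, :] - eps)
    hit &= np.isfinite(diag)
    ii, jj = np.nonzero(hit)
    w = [(float(surface.s1_values[i]), float(surface.s2_values[j])) for i, j in zip(ii, jj)]
    return bool(w), w


def slope(
    surface: ResponseSurface,
    point: tuple[float, float],
    direction: tuple[float, float],
    h: float = DEFAULT_H,
    closed_form: Optional[sp.Expr] = None,
) -> float:
    """Directional derivative of m at ``point`` along ``direction``.

    The direction is not normalized: ``(1, 0)`` gives the s1 partial and
    ``(1, 1)`` the diagonal slope (sum of partials).
    """
    p1, p2 = float(point[0]), float(point[1])
    v1, v2 = float(direction[0]), float(direction[1])
    if v1 == 0.0 and v2 == 0.0:
        raise ValueError("direction vector must be nonzero")
    gmax = float(surface.s1_values.max())
    if not (0.0 <= p1 <= gmax and 0.0 <= p2 <= gmax):
        raise ValueError(f"point {point} is outside the grid range [0, {gmax}]")
    if closed_form is not None:
        s1, s2 = sp.symbols("s1 s2", nonnegative=True)
        expr = v1 * sp.diff(closed_form, s1) + v2 * sp.diff(closed_form, s2)
        return float(expr.subs({s1: p1, s2: p2}).evalf())
    total = 0.0
    for v, axis in ((v1, 0), (v2, 1)):
        if v == 0.0:
            continue
        lo = max((p1 if axis == 0 else p2) - h, 0.0)
        hi = (p1 if axis == 0 else p2) + h
        if axis == 0:
            mhi, mlo = surface.evaluate(hi, p2), surface.evaluate(lo, p2)
        else:
            mhi, mlo = surface.evaluate(p1, hi), surface.evaluate(p1, lo)
        total += v * float(np.asarray(mhi - mlo).ravel()[0] / (hi - lo))
    return total


def classify(
    net: NetworkTopology,
    grid: Optional[Sequence[float]] = None,
    eps: float = DEFAULT_EPS,
    h: float = DEFAULT_H,
    opts: Optional[SolverOptions] = None,
    use_closed_form: bool = False,
    criteria: Sequence[str] = ("value", "slope"),
) -> CriteriaResult:
    """Full criteria bundle for one network.

    Evaluates the axis response first and excludes the network if any
    point fails to converge or the increased-output precondition fails;
    only then is the interior surface evaluated.
    """
    from .dynamics import closed_form_m, default_grid, evaluate_points

    sys = build_rate_system(net)
    opts = opts or SolverOptions()
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    result = CriteriaResult(net=net, eps=eps, grid=g)
    # axis sweep first: networks without a reachable steady state or
    # without a rising single-input response are excluded before any
    # interior work
    zeros = np.zeros_like(g)
    s1_ax = np.concatenate([g, zeros[1:]])
    s2_ax = np.concatenate([zeros, g[1:]])
    m_ax, st_ax = evaluate_points(sys, s1_ax, s2_ax, opts, stop_on_failure=True)
    if np.any(st_ax != CONVERGED):
        bad = st_ax[st_ax != CONVERGED][0]
        result.excluded = True
        result.exclusion_reason = f"non-converged axis point ({bad})"
        return result
    m1, m00 = m_ax[: len(g)], m_ax[0]
    m2 = m_ax[len(g):]
    if not (np.all(m1[1:] > m00 + eps) and np.all(m2 > m00 + eps)):
        result.excluded = True
        result.exclusion_reason = "fails increased-output precondition"
        return result
    result.increased_output = True
    S1, S2 = np.meshgrid(g, g, indexing="ij")
    m_grid, st_grid = evaluate_points(
        sys, S1.ravel(), S2.ravel(), opts, stop_on_failure=True
    )
    surface = ResponseSurface(
        sys, g, g.copy(), m_grid.reshape(S1.shape), st_grid.reshape(S1.shape), opts
    )
    if not surface.valid:
        bad = surface.status[surface.status != CONVERGED]
        result.excluded = True
        result.exclusion_reason = f"non-converged surface points ({bad[0]})"
        return result
    cf = closed_form_m(sys) if use_closed_form else None
    if "value" in criteria:
        result.value_antagonism, wa = check_value_antagonism(surface, eps)
        result.value_synergy, ws = check_value_synergy(surface, eps)
        result.witnesses["value_antagonism"] = wa[:10]
        result.witnesses["value_synergy"] = ws[:10]
    if "slope" in criteria:
        result.slope_antagonism, wsl = check_slope_antagonism(surface, eps, h, cf)
        result.witnesses["slope_antagonism"] = wsl[:10]
    return result
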