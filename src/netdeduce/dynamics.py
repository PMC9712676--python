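"""Deterministic rate equations and steady-state response surfaces.

Every network compiles to mass-action-style polynomial dynamics with all
rate constants and the conserved total set to 1:

* regulation -- species X obeys
  ``dX/dt = (1 + sum of up-regulators of X) - X * (1 + sum of down-regulators of X)``;
  inputs s1, s2 enter as constant regulator levels.
* conversion -- each directed link X->Y of the state chain carries flux
  ``X * (1 + sum of inputs catalyzing X->Y)`` (basal rate 1 in both
  directions of every link); the states sum to the conserved total 1;
  ``dM/dt = (1 + sum of activating states) - M``.
* binding -- ``dA/dt = (1 + inputs activating A) - A - A*B`` (and B
  likewise), ``dC/dt = A*B - C``, ``dM/dt = (1 + activators among A,B,C) - M``.
  The complex forms by consuming A and B and decays without returning them.

The output response is the steady state m(s1, s2). Two solvers are
provided: :func:`steady_state` integrates the ODEs from the default
initial condition (the normative definition, robust and divergence
aware), while the vectorized fast path used by :func:`response_surface`
solves the steady-state algebra directly (exact flux balance for
conversion chains, the closed-form quadratic for binding, damped
pseudo-transient Newton for regulation) and falls back to integration
for any point it cannot settle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .topology import (
    CONVERSION_LINKS,
    InteractionClass,
    NetworkTopology,
)

CONVERGED = "converged"
DIVERGED = "diverged"
NOT_CONVERGED = "not_converged"

#: residual below which a point counts as a steady state
RESIDUAL_TOL = 1e-10
#: any species above this level counts as divergence
DIVERGENCE_BOUND = 1e6
#: integration horizon for the normative solver
T_MAX = 1e4


@dataclass
class SolverOptions:
    residual_tol: float = RESIDUAL_TOL
    divergence_bound: float = DIVERGENCE_BOUND
    t_max: float = T_MAX


def default_grid(s_max: float = 10.0, step: float = 0.5) -> np.ndarray:
    """Default input scan ``{0, 0.5, ..., s_max}``.

    The maximum must exceed 2: value antagonism of the known minimal
    mutual-inhibition/sequestration surfaces only appears for inputs
    above 2.
    """
    n = int(round(s_max / step))
    return np.linspace(0.0, s_max, n + 1)


# ---------------------------------------------------------------------------
# compilation


@dataclass
class RateSystem:
    """Compiled deterministic dynamics of one topology (all parameters 1)."""

    net: NetworkTopology
    species: tuple[str, ...]
    kind: str  # "regulation" | "conversion" | "binding"
    # regulation: production/degradation coefficient matrices over
    # z = [1, s1, s2, *species]
    U: Optional[np.ndarray] = None
    D: Optional[np.ndarray] = None
    # conversion: directed links and per-link input catalysis coefficients
    links: tuple[tuple[str, str], ...] = ()
    link_cat: Optional[np.ndarray] = None  # (n_links, 2) multiplicity of s1, s2
    activators: tuple[str, ...] = ()  # species with an activation edge to M
    # binding: production boosts for A and B per input
    prod_boost: Optional[np.ndarray] = None  # (2, 2): rows A,B; cols s1,s2

    @property
    def conserved(self) -> tuple[str, ...]:
        return self.net.cls.spec.conserved

    def default_state(self) -> np.ndarray:
        x0 = np.ones(len(self.species))
        if self.conserved:
            idx = [self.species.index(s) for s in self.conserved]
            x0[idx] = 1.0 / len(self.conserved)
        return x0

    # -- pointwise right-hand side (used by the integrator) -------------

    def rhs(self, x: np.ndarray, s1: float, s2: float) -> np.ndarray:
        if self.kind == "regulation":
            z = np.concatenate(([1.0, s1, s2], x))
            return self.U @ z - x * (self.D @ z)
        if self.kind == "conversion":
            dx = np.zeros_like(x)
            im = self.species.index("M")
            for (src, tgt), (c1, c2) in zip(self.links, self.link_cat):
                flux = x[self.species.index(src)] * (1.0 + c1 * s1 + c2 * s2)
                dx[self.species.index(src)] -= flux
                dx[self.species.index(tgt)] += flux
            dx[im] = 1.0 + sum(x[self.species.index(a)] for a in self.activators) - x[im]
            return dx
        # binding
        ia, ib, ic, im = (self.species.index(s) for s in ("A", "B", "C", "M"))
        a, b, c, mm = x[ia], x[ib], x[ic], x[im]
        pa = 1.0 + self.prod_boost[0, 0] * s1 + self.prod_boost[0, 1] * s2
        pb = 1.0 + self.prod_boost[1, 0] * s1 + self.prod_boost[1, 1] * s2
        dx = np.empty_like(x)
        dx[ia] = pa - a - a * b
        dx[ib] = pb - b - a * b
        dx[ic] = a * b - c
        dx[im] = 1.0 + sum(x[self.species.index(s)] for s in self.activators) - mm
        return dx

    def sympy_rhs(self) -> tuple[list[sp.Symbol], sp.Symbol, sp.Symbol, list[sp.Expr]]:
        """Symbolic right-hand sides (species symbols, s1, s2, exprs)."""
        s1, s2 = sp.symbols("s1 s2", nonnegative=True)
        syms = [sp.Symbol(s, nonnegative=True) for s in self.species]
        subs = dict(zip(self.species, syms))
        exprs: list[sp.Expr] = []
        if self.kind == "regulation":
            z = [sp.Integer(1), s1, s2] + syms
            for i, sym in enumerate(syms):
                prod = sum(sp.nsimplify(self.U[i, j]) * z[j] for j in range(len(z)))
                deg = sum(sp.nsimplify(self.D[i, j]) * z[j] for j in range(len(z)))
                exprs.append(sp.expand(prod - sym * deg))
        elif self.kind == "conversion":
            dx = {s: sp.Integer(0) for s in self.species}
            for (src, tgt), (c1, c2) in zip(self.links, self.link_cat):
                flux = subs[src] * (1 + int(c1) * s1 + int(c2) * s2)
                dx[src] -= flux
                dx[tgt] += flux
            dx["M"] = 1 + sum(subs[a] for a in self.activators) - subs["M"]
            exprs = [sp.expand(dx[s]) for s in self.species]
        else:
            pa = 1 + int(self.prod_boost[0, 0]) * s1 + int(self.prod_boost[0, 1]) * s2
            pb = 1 + int(self.prod_boost[1, 0]) * s1 + int(self.prod_boost[1, 1]) * s2
            A, B, C = subs["A"], subs["B"], subs["C"]
            dx = {
                "A": pa - A - A * B,
                "B": pb - B - A * B,
                "C": A * B - C,
                "M": 1 + sum(subs[a] for a in self.activators) - subs["M"],
            }
            exprs = [sp.expand(dx[s]) for s in self.species]
        return syms, s1, s2, exprs


def build_rate_system(net: NetworkTopology) -> RateSystem:
    """Compile a topology into its rate equations (all parameters 1)."""
    cls = net.cls
    species = cls.spec.species
    if cls.name == "regulation":
        n = len(species)
        ncol = 3 + n
        col = {"S1": 1, "S2": 2, **{s: 3 + i for i, s in enumerate(species)}}
        U = np.zeros((n, ncol))
        D = np.zeros((n, ncol))
        U[:, 0] = 1.0  # basal production
        D[:, 0] = 1.0  # basal degradation
        for e in net.edges:
            i = species.index(e.target)
            if e.sign == "up":
                U[i, col[e.source]] += 1.0
            else:
                D[i, col[e.source]] += 1.0
        return RateSystem(net, species, "regulation", U=U, D=D)
    if cls.name == "conversion":
        links = CONVERSION_LINKS[cls.variant]
        link_cat = np.zeros((len(links), 2))
        activators = []
        for e in net.edges:
            if e.kind == "catalysis":
                src, tgt = e.target.split(">")
                li = links.index((src, tgt))
                link_cat[li, 0 if e.source == "S1" else 1] += 1.0
            else:
                activators.append(e.source)
        return RateSystem(
            net,
            species,
            "conversion",
            links=links,
            link_cat=link_cat,
            activators=tuple(sorted(activators)),
        )
    # binding
    prod = np.zeros((2, 2))
    activators = []
    for e in net.edges:
        if e.source in ("S1", "S2"):
            prod[0 if e.target == "A" else 1, 0 if e.source == "S1" else 1] += 1.0
        else:
            activators.append(e.source)
    return RateSystem(
        net, species, "binding", prod_boost=prod, activators=tuple(sorted(activators))
    )


# ---------------------------------------------------------------------------
# normative solver: ODE integration from the default initial condition


@dataclass
class SteadyState:
    values: dict[str, float]
    s1: float
    s2: float
    status: str
    residual: float

    @property
    def m(self) -> float:
        if self.status != CONVERGED:
            raise ValueError(f"no steady state: status is {self.status!r}")
        return self.values["M"]


def steady_state(
    sys: RateSystem,
    s1: float,
    s2: float,
    opts: SolverOptions | None = None,
    x0: Optional[np.ndarray] = None,
) -> SteadyState:
    """Integrate the rate equations until the residual drops below
    tolerance, divergence is detected, or ``t_max`` is exhausted."""
    opts = opts or SolverOptions()
    x = np.array(sys.default_state() if x0 is None else x0, dtype=float)

    def f(t, y):
        return sys.rhs(y, s1, s2)

    status = NOT_CONVERGED
    t = 0.0
    history = [x.copy()]
    for t_next in (1.0, 10.0, 100.0, 1e3, opts.t_max):
        if t_next <= t:
            continue
        try:
            sol = solve_ivp(f, (t, t_next), x, method="LSODA", rtol=1e-10, atol=1e-12)
        except (ValueError, FloatingPointError, OverflowError):
            return SteadyState(dict(zip(sys.species, x)), s1, s2, NOT_CONVERGED, math.inf)
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            # blow-up usually makes the integrator give up mid-interval
            xa = sol.y[:, -1] if sol.y.size else x
            if np.any(~np.isfinite(xa)) or np.any(np.abs(xa) > opts.divergence_bound):
                status = DIVERGED
                x = xa
                break
            return SteadyState(dict(zip(sys.species, x)), s1, s2, NOT_CONVERGED, math.inf)
        x = sol.y[:, -1]
        t = t_next
        history.append(x.copy())
        if np.any(np.abs(x) > opts.divergence_bound):
            status = DIVERGED
            break
        res = float(np.max(np.abs(sys.rhs(x, s1, s2))))
        if res < opts.residual_tol:
            status = CONVERGED
            break
    if status == NOT_CONVERGED and len(history) >= 3:
        # sub-bound but unbounded growth: a species climbing at every
        # checkpoint, still strongly (>2x over the last decade) and with
        # positive drive, has no steady state to reach
        rhs_end = sys.rhs(x, s1, s2)
        for i in range(len(x)):
            levels = [h[i] for h in history]
            if (
                all(b > a for a, b in zip(levels, levels[1:]))
                and levels[-1] > 2.0 * levels[-2]
                and rhs_end[i] > 0
            ):
                status = DIVERGED
                break
    residual = float(np.max(np.abs(sys.rhs(x, s1, s2)))) if np.all(np.isfinite(x)) else math.inf
    x = np.where(np.isfinite(x), x, np.inf)
    return SteadyState(dict(zip(sys.species, x)), s1, s2, status, residual)


def steady_state_with_restarts(
    sys: RateSystem,
    s1: float,
    s2: float,
    n_restarts: int = 10,
    seed: int = 0,
    opts: SolverOptions | None = None,
    atol: float = 1e-6,
) -> SteadyState:
    """Steady state with random-restart verification of uniqueness.

    Integrates from the default initial condition and from
    ``n_restarts`` random positive starts; if any converged restart
    disagrees beyond ``atol`` the returned status is ``"ambiguous"``,
    flagging a network that must be kept out of minimality claims.
    """
    base = steady_state(sys, s1, s2, opts)
    if base.status != CONVERGED:
        return base
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        x0 = rng.uniform(0.05, 3.0, size=len(sys.species))
        if sys.conserved:
            idx = [sys.species.index(s) for s in sys.conserved]
            x0[idx] /= x0[idx].sum()
        alt = steady_state(sys, s1, s2, opts, x0=x0)
        if alt.status == CONVERGED and any(
            abs(alt.values[k] - base.values[k]) > atol for k in base.values
        ):
            return SteadyState(base.values, s1, s2, "ambiguous", base.residual)
    return base


# ---------------------------------------------------------------------------
# fast vectorized steady states


def _regulation_ptc(
    sys: RateSystem, s1: np.ndarray, s2: np.ndarray, opts: SolverOptions
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-transient continuation (damped implicit Euler / Newton).

    Follows the flow from the default initial condition with a growing
    time step, so it settles on the steady state the dynamics reach and
    races past the divergence bound when none exists.
    """
    P = len(s1)
    n = len(sys.species)
    U, D = sys.U, sys.D
    X = np.tile(sys.default_state(), (P, 1))
    dt = np.full(P, 0.1)
    status = np.full(P, NOT_CONVERGED, dtype=object)
    active = np.ones(P, dtype=bool)
    Z = np.empty((P, 3 + n))
    Z[:, 0] = 1.0
    Z[:, 1] = s1
    Z[:, 2] = s2
    eye = np.eye(n)
    for _ in range(300):
        Z[:, 3:] = X
        prod = Z @ U.T  # (P, n)
        deg = Z @ D.T
        F = prod - X * deg
        res = np.max(np.abs(F), axis=1)
        newly_conv = active & (res < opts.residual_tol)
        status[newly_conv] = CONVERGED
        newly_div = active & (np.max(X, axis=1) > opts.divergence_bound)
        status[newly_div] = DIVERGED
        active &= ~(newly_conv | newly_div)
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        # J[p,i,j] = U[i,3+j] - delta_ij * deg[p,i] - X[p,i] * D[i,3+j]
        J = np.broadcast_to(U[:, 3:], (len(idx), n, n)).copy()
        J -= eye[None, :, :] * deg[idx, :, None]
        J -= X[idx, :, None] * D[None, :, 3:]
        A = eye[None, :, :] / dt[idx, None, None] - J
        try:
            step = np.linalg.solve(A, F[idx, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [np.linalg.lstsq(A[k], F[idx[k]], rcond=None)[0] for k in range(len(idx))]
            )
        step = np.where(np.isfinite(step), step, 0.0)
        X[idx] = np.clip(X[idx] + step, 0.0, 10 * opts.divergence_bound)
        dt[idx] = np.minimum(dt[idx] * 1.6, 1e8)
    m = X[:, sys.species.index("M")].copy()
    return m, status


def _conversion_direct(
    sys: RateSystem, s1: np.ndarray, s2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact flux balance of the conversion chain (detailed balance on a
    chain) plus the explicit output level."""
    rates = {
        link: 1.0 + c1 * s1 + c2 * s2 for link, (c1, c2) in zip(sys.links, sys.link_cat)
    }
    if sys.net.cls.variant == "two_state":
        r_fwd = rates[("A", "Astar")]
        r_bwd = rates[("Astar", "A")]
        astar = r_fwd / (r_fwd + r_bwd)
        vals = {"A": 1.0 - astar, "Astar": astar}
    else:
        wB = rates[("A", "B")] / rates[("B", "A")]
        wC = rates[("A", "C")] / rates[("C", "A")]
        tot = 1.0 + wB + wC
        vals = {"A": 1.0 / tot, "B": wB / tot, "C": wC / tot}
    m = 1.0 + sum(vals[a] for a in sys.activators)
    return np.asarray(m, dtype=float), np.full(len(s1), CONVERGED, dtype=object)


def _binding_direct(
    sys: RateSystem, s1: np.ndarray, s2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form steady state of the binding motif.

    With alpha/beta the production rates of A and B, the steady state
    solves A(1+B)=alpha, B(1+A)=beta, C=AB; B obeys the quadratic
    B^2 + (1+alpha-beta) B - beta = 0 with a unique nonnegative root.
    """
    alpha = 1.0 + sys.prod_boost[0, 0] * s1 + sys.prod_boost[0, 1] * s2
    beta = 1.0 + sys.prod_boost[1, 0] * s1 + sys.prod_boost[1, 1] * s2
    q = 1.0 + alpha - beta
    B = 0.5 * (-q + np.sqrt(q * q + 4.0 * beta))
    A = alpha / (1.0 + B)
    vals = {"A": A, "B": B, "C": A * B}
    m = 1.0 + sum(vals[a] for a in sys.activators)
    m = np.asarray(m, dtype=float)
    if m.ndim == 0:
        m = np.broadcast_to(m, s1.shape).copy()
    return m, np.full(len(s1), CONVERGED, dtype=object)


def evaluate_points(
    sys: RateSystem,
    s1: np.ndarray,
    s2: np.ndarray,
    opts: SolverOptions | None = None,
    integrate_fallback: bool = True,
    stop_on_failure: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized steady-state output m at paired input arrays.

    Returns ``(m, status)``; m is NaN wherever the status is not
    ``converged``. Points the fast path cannot settle are retried by
    integration; with ``stop_on_failure`` the retries stop at the first
    point confirmed unreachable (useful when any failure already decides
    the caller's outcome). Never raises on numeric failure mid-sweep.
    """
    opts = opts or SolverOptions()
    s1 = np.atleast_1d(np.asarray(s1, dtype=float))
    s2 = np.atleast_1d(np.asarray(s2, dtype=float))
    if s1.shape != s2.shape:
        raise ValueError("s1 and s2 arrays must have the same shape")
    with np.errstate(all="ignore"):
        if sys.kind == "conversion":
            m, status = _conversion_direct(sys, s1, s2)
        elif sys.kind == "binding":
            m, status = _binding_direct(sys, s1, s2)
        else:
            m, status = _regulation_ptc(sys, s1, s2, opts)
            if integrate_fallback:
                for i in np.nonzero(status == NOT_CONVERGED)[0]:
                    ss = steady_state(sys, float(s1[i]), float(s2[i]), opts)
                    status[i] = ss.status
                    if ss.status == CONVERGED:
                        m[i] = ss.values["M"]
                    elif stop_on_failure:
                        break
    m = np.where(status == CONVERGED, m, np.nan)
    return m, status


# ---------------------------------------------------------------------------
# closed forms


def closed_form_m(sys: RateSystem) -> Optional[sp.Expr]:
    """Symbolic steady-state output m(s1, s2), when solvable.

    Solves the polynomial steady-state system (with the conservation law
    substituted for one state equation) and returns the admissible
    branch: the solution whose species are nonnegative and that matches
    the numeric steady state at sample points. Returns ``None`` when no
    closed form is found; absence is a value, not an error.
    """
    syms, s1, s2, exprs = sys.sympy_rhs()
    eqs = list(exprs)
    if sys.conserved:
        # replace one redundant state equation by the conservation law
        idx = sys.species.index(sys.conserved[0])
        eqs[idx] = sum(syms[sys.species.index(s)] for s in sys.conserved) - 1
    try:
        sols = sp.solve(eqs, syms, dict=True)
    except Exception:
        return None
    if not sols:
        return None
    msym = syms[sys.species.index("M")]
    samples = [(sp.Rational(7, 10), sp.Rational(13, 10)), (sp.Rational(5, 2), sp.Rational(9, 10))]
    for sol in sols:
        if msym not in sol:
            continue
        ok = True
        for p1, p2 in samples:
            try:
                vals = {
                    sym: complex(sol[sym].subs({s1: p1, s2: p2}).evalf())
                    for sym in syms
                    if sym in sol
                }
            except (TypeError, ValueError):
                ok = False
                break
            if any(abs(v.imag) > 1e-9 or v.real < -1e-9 for v in vals.values()):
                ok = False
                break
            ref = steady_state(sys, float(p1), float(p2))
            if ref.status != CONVERGED or abs(vals[msym].real - ref.values["M"]) > 1e-6:
                ok = False
                break
        if ok:
            return sp.simplify(sol[msym])
    return None


# ---------------------------------------------------------------------------
# response surfaces


@dataclass
class ResponseSurface:
    """Steady-state output on a (s1, s2) grid, with per-point status.

    Also acts as an off-grid evaluator (for finite-difference slopes)
    through :meth:`evaluate`.
    """

    system: RateSystem
    s1_values: np.ndarray
    s2_values: np.ndarray
    m: np.ndarray  # shape (len(s1_values), len(s2_values))
    status: np.ndarray  # same shape, dtype=object
    opts: SolverOptions = field(default_factory=SolverOptions)

    @property
    def net(self) -> NetworkTopology:
        return self.system.net

    @property
    def valid(self) -> bool:
        return bool(np.all(self.status == CONVERGED))

    def evaluate(self, s1, s2) -> np.ndarray:
        """Steady-state m at arbitrary nonnegative inputs (NaN on failure)."""
        s1 = np.atleast_1d(np.asarray(s1, dtype=float))
        s2 = np.atleast_1d(np.asarray(s2, dtype=float))
        m, _ = evaluate_points(self.system, s1.ravel(), s2.ravel(), self.opts)
        return m.reshape(s1.shape)

    def to_frame(self):
        """Long-format table with columns s1, s2, m, status."""
        import pandas as pd

        rows = []
        for i, a in enumerate(self.s1_values):
            for j, b in enumerate(self.s2_values):
                rows.append((a, b, self.m[i, j], self.status[i, j]))
        return pd.DataFrame(rows, columns=["s1", "s2", "m", "status"])


def response_surface(
    net: NetworkTopology | RateSystem,
    grid: Optional[Sequence[float]] = None,
    opts: SolverOptions | None = None,
) -> ResponseSurface:
    """Evaluate m(s1, s2) on the grid (default ``{0, 0.5, ..., 10}``)."""
    sys = net if isinstance(net, RateSystem) else build_rate_system(net)
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any(g < 0):
        raise ValueError("grid points must be nonnegative")
    opts = opts or SolverOptions()
    S1, S2 = np.meshgrid(g, g, indexing="ij")
    m, status = evaluate_points(sys, S1.ravel(), S2.ravel(), opts)
    return ResponseSurface(
        sys, g, g.copy(), m.reshape(S1.shape), status.reshape(S1.shape), opts
    )
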