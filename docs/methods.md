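# Methods

## Model classes and rate-equation conventions

Every candidate network couples two constant inputs S1, S2 to one output
species M through a fixed mechanistic scaffold. The compiled dynamics use
unit parameters throughout — every rate constant is 1 and the conserved
total is 1 — so that the input–output function m(s1, s2) is a property
of topology alone.

**Regulation.** Each dynamical species X has basal zeroth-order
production and first-order degradation. An up-regulation edge R→X adds
the regulator level linearly to production; a down-regulation edge R⊣X
adds it linearly to the degradation rate constant:

    dX/dt = (1 + Σ_up r) − X · (1 + Σ_down r).

Inputs appear as constant regulator levels, never as dynamical species,
and act on M directly only in the `direct` variant. Variants fix which
positions exist: `direct` (S1→M, S2→M mandatory, M→M optional),
`one_intermediate` (S1→A, S2→A, A→M mandatory; A→A, M→A, M→M optional),
and `two_intermediate` (13 free signed positions: {S1,S2}→{A,B} and
{A,B,M}→{A,B,M}).

**Conversion.** A conserved species interconverts along a chain
(A ⇌ A\*, or B ⇌ A ⇌ C). Every directed link X→Y carries flux
X·(1 + Σ catalyzing inputs): the basal rate is 1 in *both* directions of
every link, and each catalysis edge adds the input level. States sum to
the conserved total 1. States with an activation edge add their level to
M's production: dM/dt = (1 + Σ_act x) − M.

**Binding.** A and B are produced (inputs add linearly to production),
degrade at rate 1, and combine at rate A·B into the complex C, which
decays at rate C *without returning molecules to A and B*:

    dA/dt = (1 + Σ inputs→A) − A − A·B        (B analogous)
    dC/dt = A·B − C
    dM/dt = (1 + Σ activators among A, B, C) − M.

These right-hand sides are normative for the package and are
regression-tested against the six exact input–output formulas in
`netdeduce.reference`. Two conventions deserve emphasis because
plausible alternatives break the exact formulas: additive (not
multiplicative) regulator contributions, and the absence of a +C return
flux in dA/dt and dB/dt — adding a unit-rate unbinding return term is
provably inconsistent with the complex-formation formula
m = ½[s1+s2+5−√((s1+s2+1)²+4)].

The sequestration network's response compiles to
√(s1²+s2²−**2**s1s2+2s1+2s2+5). A variant with cross term −s1s2
circulates in print; it agrees with the compiled form on both axes but
cannot satisfy the value-antagonism condition anywhere (the two required
inequalities, s1 > s2+2 and s2 > s1+2, are jointly infeasible — their
defining factors sum to the constant 4). The compiled form does
exhibit value antagonism (e.g. at s1 = s2 = 3) and moreover coincides
algebraically with the mutual-inhibition regulation network's response,
as both reduce to A(1+B) = 1+s1, B(1+A) = 1+s2, m = 1+A+B. The package
treats the compiled form as ground truth and reports the printed
variant's axis-only agreement explicitly rather than patching it.

## Edge accounting and symmetry

Only regulatory/catalysis/activation edges count toward a network's
complexity; scaffold infrastructure (basal turnover, the conversion
chain, the binding reaction) is free. The `two_intermediate` regulation
class is enumerated over its 13 free signed positions, giving
C(13,n)·2ⁿ networks per stratum (2288, 11 440, 41 184, 109 824 for
n = 3…6), while the class *total* follows the 2³·3¹⁰ = 472 392
accounting in which three designated edges are always present — the
total depends only on the counts of designated/optional positions, not
on which three are designated, so both conventions coexist
consistently.

Networks related by relabeling indistinguishable nodes are the same
mechanism. The symmetry group of each class is generated by the input
swap S1↔S2 plus, where intermediates are interchangeable, A↔B
(two-intermediate regulation, binding), A↔A\* (two-state conversion), or
B↔C (three-state conversion). `canonicalize` returns the
lexicographically smallest orbit member; the search evaluates one
representative per orbit, which is sound because every criterion is
invariant under relabeling (tested property). Including the
intermediate relabelings is what folds the 8 three-edge two-state
conversion candidates to 3 unique networks.

## Steady-state solvers

`steady_state` (normative): LSODA integration from the default initial
condition — produced species at 1, conserved states uniform at 1/n — in
expanding time chunks to t_max = 10⁴, declaring convergence when
max|dx/dt| < 10⁻¹⁰, divergence when any species exceeds 10⁶ or keeps
growing monotonically by more than 2× over the final time decade with
positive drive. Non-finite evaluations yield a failure status, never an
exception mid-sweep.

The survey path (`evaluate_points`) is exact or Newton-based, vectorized
across grid points:

* conversion chains: stationary flux balance of a linear chain (detailed
  balance), solved in closed form;
* binding: the unique nonnegative root of the steady-state quadratic
  B² + (1+α−β)B − β = 0 with α, β the production rates of A and B;
* regulation: pseudo-transient continuation — damped implicit-Euler
  Newton steps with a geometrically growing pseudo-time step (0.1 → 10⁸,
  ×1.6 per step, nonnegativity clipping) — which follows the flow from
  the default initial condition, converges quadratically near the
  attractor, and races past the divergence bound when no steady state
  exists. Points the fast path cannot settle fall back to integration;
  callers that only need to know *whether* all points converge stop at
  the first confirmed failure.

Multiple steady states are assumed absent for these bilinear systems
from the default initial condition; initial-condition independence is
verified on the six reference networks (20 random starts each in the
dynamics tests), and the fast path is cross-checked against integration
on randomized topologies. Sustained oscillations, if any topology
produced them, would be reported as non-convergence and the network
excluded — a conservative outcome for a steady-state criterion.

## Criteria defaults

* Grid: s1, s2 ∈ {0, 0.5, …, 10} (21 values). The known
  value-antagonism surfaces only undershoot their axis responses for
  inputs above 2, so any scan must extend well past 2; 10 gives
  comfortable margin while keeping surfaces 441 points. The criteria are
  existence claims ("there exist values…"), so a finite scan can only
  under-report; fixture classifications are verified stable from step
  1.0 down to 0.25 and for margins 10⁻⁴–10⁻⁶.
* Margin ε = 10⁻⁶ on every strict inequality — far above the solver
  residual (10⁻¹⁰) and far below the criterion gaps of the minimal
  networks (order 10⁻¹–1).
* Slopes: exact symbolic derivatives when a closed form is supplied,
  otherwise central differences with step h = 10⁻³ (one-sided at the
  s = 0 boundary). Slope antagonism pairs the diagonal slope at (s1,s2)
  against the axis slopes at (s1,0) and (0,s2) — the literal reading of
  the condition.
* The increased-output precondition is checked on the axes before any
  interior work; networks failing it, or failing to converge anywhere on
  the grid, are excluded with a recorded reason and never counted as
  antagonistic.

## Search

Strata are ordered by edge count within a fixed class; class escalation
(direct → one intermediate → two intermediates) is explicit in the API,
mirroring how nodes are added one at a time. Each stratum is
deduplicated before evaluation; exhaustiveness is auditable because
enumerated = Σ orbit sizes and evaluated + excluded = unique orbits.
The six-edge two-intermediate regulation stratum (109 824 networks,
31 040 orbits) is the one deliberately heavy computation; the default
reproduction verifies the published facts that are cheap to check
(strata 3–4 empty, mutual inhibition passes at six edges) and the
`--full` flag runs the complete sweep (strata 3–6; roughly ten minutes
on one CPU with this solver), which finds exactly five unique passing
six-edge networks, including mutual inhibition.

## Limitations

* All conclusions are at unit parameters and linear/bilinear kinetics:
  no Hill nonlinearities, bistability, noise, or time-dependent inputs.
  Minimality claims are relative to a class scaffold and its edge
  accounting, not absolute.
* The criteria scan a finite grid; a network antagonistic only outside
  [0, 10]² or between grid points would be missed. The published minima
  are all witnessed well inside the default grid.
* Closed forms are attempted with a general polynomial solve and may be
  absent for feedback-heavy regulation networks; absence falls back to
  numerics and is not an error.
* The identities of the two "less intuitive" six-edge value-antagonism
  regulation networks are established only by this package's own sweep;
  they have no independent published listing to compare against
  name-by-name.
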