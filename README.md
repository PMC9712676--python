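# netdeduce

Inverse deduction of minimal cell-signaling networks from responses to
multiple cues.

## The problem

Cells integrate multiple simultaneous stimuli — growth factors,
nutrients, mechanical cues — and sometimes respond *antagonistically*:
the response to two cues together is weaker than to either cue alone
(for example, cancer cell lines whose directional migration degrades
when two growth-factor gradients are presented together, or a bacterial
gene activated by each of two small molecules individually but not by
both). Instead of modeling a known pathway forward, `netdeduce` works
backward: given only the qualitative cell-level behaviour, it finds the
*minimal* biochemical network — fewest interactions — that can produce
it, by exhaustive enumeration within a mechanistic interaction class.

Three ubiquitous interaction mechanisms define the candidate classes:

* **regulation** — species are produced and degraded; a regulator adds
  linearly to its target's production rate (up-regulation) or to its
  degradation rate constant (down-regulation);
* **molecular conversion** — a conserved species interconverts among
  states (A ⇌ A\*, or B ⇌ A ⇌ C) with inputs catalyzing directed
  conversion fluxes;
* **reversible binding** — two produced species A and B combine into a
  complex C (sequestering both).

Each candidate network with inputs S₁, S₂ and output M compiles to
deterministic rate equations with **every rate constant and conserved
total set to 1**, so that only topology matters. The response is the
steady state m(s₁, s₂). A network must first pass the increased-output
precondition, m(s,0) > m(0,0) and m(0,s) > m(0,0); it then exhibits

* **value antagonism** if m(s₁,s₂) < m(s₁,0) and m(s₁,s₂) < m(0,s₂)
  somewhere, and
* **slope antagonism** if ∂m(s₁,0)/∂s₁ > 0 and ∂m(0,s₂)/∂s₂ > 0 while
  the diagonal slope ∂m/∂s₁ + ∂m/∂s₂ at (s₁,s₂) is smaller than each.

Searching each class in order of increasing edge count yields a sharp
structural dichotomy: slope antagonism is minimally achieved by two
pathways *converging* on a shared component (saturation), while value
antagonism requires two pathways at *cross-purposes* (mutual inhibition,
competing fluxes, or sequestration).

## Worked example

Evaluate the repression-of-a-repressor motif S₁⊣A, S₂⊣A, A⊣M, whose
steady state is m = (s₁+s₂+1)/(s₁+s₂+2):

```python
>>> from netdeduce import (InteractionClass, classify, find_minimal)
>>> from netdeduce.reference import get_reference
>>> net = get_reference("double_repression").topology
>>> res = classify(net)
>>> res.increased_output, res.slope_antagonism, res.value_antagonism
(True, True, False)
>>> res.witnesses["slope_antagonism"][0]
(1.5, 1.5)
```

Each input alone raises the output, the diagonal slope falls below both
axis slopes from (1.5, 1.5) outward — slope antagonism without value
antagonism, the signature of converging pathways. The search that
*discovers* this motif:

```python
>>> report = find_minimal(InteractionClass("regulation", "one_intermediate"), "slope")
>>> report.minimal_edge_count, [n.label() for n in report.minimal_networks]
(3, ['S1-|A, S2-|A, A-|M'])
```

Of the 8 three-edge candidates (6 after folding the S₁↔S₂ symmetry),
exactly one passes. The same machinery from the shell:

```
$ netdeduce enumerate --class regulation --variant two_intermediate --edges 4 --count
11440
$ netdeduce search --class binding --variant standard --criterion value --max-edges 7
{ ... "minimal_edge_count": 4, "minimal_networks": ["S1->A, S2->B, A->M, B->M"] ... }
$ netdeduce reproduce            # full concordance table (counts, formulas, searches)
$ netdeduce reproduce --full     # adds the 109,824-network six-edge regulation sweep
```

The four-edge binding minimum found above is the sequestration motif:
each input drives its own activator of M, and the two activators bind
each other away — with both inputs present, complex formation removes
them, m = √(s₁²+s₂²−2s₁s₂+2s₁+2s₂+5) dips below both single-input
responses (e.g. √17 at (3,3) versus √20 on the axes).

## Layout

| module | contents |
|---|---|
| `netdeduce.topology` | interaction classes, edge positions, enumeration, symmetry canonicalization |
| `netdeduce.dynamics` | rate-equation compiler, steady-state solvers, closed forms, response surfaces |
| `netdeduce.criteria` | increased-output precondition, value/slope antagonism, synergy, slopes |
| `netdeduce.search` | ascending-edge-count exhaustive search with checkpointing |
| `netdeduce.reference` | the six minimal networks with exact formulas; concordance verifiers |
| `netdeduce.io` / `netdeduce.cli` | topology JSON schema, DOT export, command-line interface |

See `docs/methods.md` for the modeling conventions, solver design, and
known limitations.
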