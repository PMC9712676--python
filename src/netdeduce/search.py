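"""Ascending-complexity exhaustive search for minimal antagonistic networks.

The search walks a class stratum by stratum (by edge count), deduplicates
topologies under the class symmetry group, evaluates each orbit
representative against the requested criterion, and stops at the first
stratum containing a passing network. Exhaustiveness is structural: each
stratum's orbit representatives partition the full enumeration, and the
criteria are invariant under the symmetry, so evaluating one
representative per orbit decides the whole orbit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .criteria import DEFAULT_EPS, DEFAULT_H, CriteriaResult, classify
from .dynamics import SolverOptions
from .topology import (
    InteractionClass,
    NetworkTopology,
    count_networks,
    enumerate_networks,
    mandatory_edge_count,
    unique_networks,
)

logger = logging.getLogger(__name__)

CRITERIA = ("value", "slope")


def _passes(result: CriteriaResult, criterion: str) -> bool:
    if result.excluded:
        return False
    return result.value_antagonism if criterion == "value" else result.slope_antagonism


@dataclass
class StratumReport:
    n_edges: int
    enumerated: int  # raw topologies before symmetry folding
    unique: int  # orbit representatives
    evaluated: int  # representatives passing the precondition
    excluded: int  # diverged / failed precondition
    passing: list[NetworkTopology] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_edges": self.n_edges,
            "enumerated": self.enumerated,
            "unique": self.unique,
            "evaluated": self.evaluated,
            "excluded": self.excluded,
            "passing": [n.label() for n in self.passing],
        }


@dataclass
class SearchReport:
    cls: InteractionClass
    criterion: str
    strata: list[StratumReport] = field(default_factory=list)

    @property
    def minimal_edge_count(self) -> Optional[int]:
        for s in self.strata:
            if s.passing:
                return s.n_edges
        return None

    @property
    def minimal_networks(self) -> list[NetworkTopology]:
        for s in self.strata:
            if s.passing:
                return list(s.passing)
        return []

    def to_dict(self) -> dict:
        return {
            "class": self.cls.name,
            "variant": self.cls.variant,
            "criterion": self.criterion,
            "minimal_edge_count": self.minimal_edge_count,
            "minimal_networks": [n.label() for n in self.minimal_networks],
            "strata": [s.to_dict() for s in self.strata],
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([s.to_dict() for s in self.strata])


def evaluate_all(
    cls: InteractionClass,
    n_edges: int,
    criterion: Optional[str] = None,
    grid: Optional[Sequence[float]] = None,
    eps: float = DEFAULT_EPS,
    h: float = DEFAULT_H,
    opts: Optional[SolverOptions] = None,
    checkpoint: Optional[Path] = None,
    checkpoint_every: int = 1000,
    sample: Optional[int] = None,
) -> list[tuple[NetworkTopology, CriteriaResult]]:
    """Classify every orbit representative of an edge-count stratum.

    ``criterion`` limits the work to one criterion ("value" or "slope");
    ``None`` evaluates both. ``sample`` keeps every k-th representative
    (deterministic stratified subsample) for smoke runs. ``checkpoint``
    names a JSON file updated every ``checkpoint_every`` networks so an
    interrupted sweep can resume.
    """
    wanted = CRITERIA if criterion is None else (criterion,)
    reps = unique_networks(list(enumerate_networks(cls, n_edges)))
    if sample is not None and sample > 1:
        reps = reps[::sample]
    done: dict[str, dict] = {}
    if checkpoint is not None and Path(checkpoint).exists():
        done = json.loads(Path(checkpoint).read_text())
    results: list[tuple[NetworkTopology, CriteriaResult]] = []
    since_save = 0
    for net in reps:
        key = net.label()
        if key in done:
            cached = done[key]
            res = CriteriaResult(net=net, eps=eps)
            res.increased_output = cached["increased_output"]
            res.value_antagonism = cached["value_antagonism"]
            res.slope_antagonism = cached["slope_antagonism"]
            res.value_synergy = cached["value_synergy"]
            res.excluded = cached["excluded"]
            res.exclusion_reason = cached["exclusion_reason"]
            res.witnesses = {
                k: [tuple(w) for w in v] for k, v in cached.get("witnesses", {}).items()
            }
            results.append((net, res))
            continue
        try:
            res = classify(net, grid=grid, eps=eps, h=h, opts=opts, criteria=wanted)
        except Exception as exc:  # pragma: no cover - defensive: never abort a sweep
            logger.warning("evaluation failed for %s: %s", key, exc)
            res = CriteriaResult(net=net, eps=eps, excluded=True,
                                 exclusion_reason=f"evaluation error: {exc}")
        results.append((net, res))
        if checkpoint is not None:
            done[key] = res.to_dict()
            since_save += 1
            if since_save >= checkpoint_every:
                Path(checkpoint).write_text(json.dumps(done))
                since_save = 0
    if checkpoint is not None and since_save:
        Path(checkpoint).write_text(json.dumps(done))
    return results


def results_to_frame(results: list[tuple[NetworkTopology, CriteriaResult]]):
    """Per-network result rows (one line per orbit representative),
    suitable for CSV export."""
    import pandas as pd

    rows = []
    for net, res in results:
        wit = (res.witnesses.get("value_antagonism") or
               res.witnesses.get("slope_antagonism") or [(None, None)])
        rows.append({
            "canonical_id": net.label(),
            "edges": net.edge_count,
            "increased_output": res.increased_output,
            "value_antag": res.value_antagonism,
            "slope_antag": res.slope_antagonism,
            "excluded": res.excluded,
            "witness_s1": wit[0][0],
            "witness_s2": wit[0][1],
        })
    return pd.DataFrame(rows)


def _stratum_report(
    cls: InteractionClass,
    n_edges: int,
    criterion: str,
    results: list[tuple[NetworkTopology, CriteriaResult]],
) -> StratumReport:
    passing = [net for net, res in results if _passes(res, criterion)]
    excluded = sum(1 for _, res in results if res.excluded)
    return StratumReport(
        n_edges=n_edges,
        enumerated=count_networks(cls, n_edges),
        unique=len(results),
        evaluated=len(results) - excluded,
        excluded=excluded,
        passing=passing,
    )


def find_minimal(
    cls: InteractionClass,
    criterion: str,
    max_edges: Optional[int] = None,
    min_edges: Optional[int] = None,
    grid: Optional[Sequence[float]] = None,
    eps: float = DEFAULT_EPS,
    h: float = DEFAULT_H,
    opts: Optional[SolverOptions] = None,
    checkpoint_dir: Optional[Path] = None,
    sample: Optional[int] = None,
) -> SearchReport:
    """Find the minimal network(s) of a class satisfying a criterion.

    Iterates edge counts upward from the class minimum, evaluating every
    orbit representative, and stops at the first stratum with at least
    one passing network (or at ``max_edges``).
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}, got {criterion!r}")
    n_positions = len(cls.spec.positions)
    hi = n_positions if max_edges is None else min(max_edges, n_positions)
    lo = mandatory_edge_count(cls) if min_edges is None else min_edges
    report = SearchReport(cls=cls, criterion=criterion)
    for n in range(lo, hi + 1):
        ckpt = (
            Path(checkpoint_dir) / f"{cls.name}_{cls.variant}_{criterion}_n{n}.json"
            if checkpoint_dir is not None
            else None
        )
        results = evaluate_all(
            cls, n, criterion, grid=grid, eps=eps, h=h, opts=opts,
            checkpoint=ckpt, sample=sample,
        )
        stratum = _stratum_report(cls, n, criterion, results)
        report.strata.append(stratum)
        logger.info(
            "%s %s stratum n=%d: %d unique, %d excluded, %d passing",
            cls, criterion, n, stratum.unique, stratum.excluded, len(stratum.passing),
        )
        if stratum.passing:
            break
    return report
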