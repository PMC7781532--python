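"""Inference of missing crosstalks by exhaustive single-edge addition.

Two candidate families are screened against one context's records:

* **OR candidates** — a new single-reactant activating reaction
  ``source => target`` for every ordered node pair (``N**2`` candidates,
  self-loops included: they model autoregulation), OR-combined with the
  target's existing reactions.
* **AND candidates** — the source node added as an extra activating
  reactant to an existing intermediate reaction's AND gate
  (``N * R_int`` candidates).

Each candidate is scored by re-validating a cloned model with the edge
inserted: ``delta = 100 * (corrected - broken) / N_records`` where
*corrected* counts records flipped wrong -> right and *broken* the reverse.
The input model is never mutated.  New edges inherit the network default
reaction parameters, so the screen itself is parameter-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .lde_engine import SimulationConfig
from .model import (
    ACTIVATING,
    INHIBITING,
    ExperimentRecord,
    ModelError,
    NetworkModel,
    ParameterSet,
    ReactionSpec,
)
from .validation import ValidationReport, validate

__all__ = [
    "CrosstalkCandidate",
    "ScreenSummary",
    "enumerate_or_candidates",
    "enumerate_and_candidates",
    "screen_crosstalks",
    "apply_candidate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrosstalkCandidate:
    """One proposed edge addition and, after screening, its score."""

    gate: str  # "OR" | "AND"
    source: str  # node id
    target: str  # node id (OR) or reaction id (AND)
    sign: str = ACTIVATING
    delta_validation: float = 0.0
    corrected: int = 0
    broken: int = 0
    duplicate: bool = False

    def describe(self) -> str:
        arrow = "=>" if self.sign == ACTIVATING else "=|"
        kind = "node" if self.gate == "OR" else "reaction"
        return f"{self.gate} {self.source} {arrow} {kind} {self.target}"


@dataclass(frozen=True)
class ScreenSummary:
    """Fractions of candidates that hurt / helped / left validation unchanged."""

    gate: str
    n_candidates: int
    frac_decreased: float
    frac_increased: float
    frac_unchanged: float
    frac_improved_multi: float  # net gain of more than one record

    def as_dict(self) -> Dict[str, float]:
        return {
            "gate": self.gate,
            "n_candidates": self.n_candidates,
            "frac_decreased": self.frac_decreased,
            "frac_increased": self.frac_increased,
            "frac_unchanged": self.frac_unchanged,
            "frac_improved_multi": self.frac_improved_multi,
        }


def enumerate_or_candidates(
    model: NetworkModel, include_inhibiting: bool = False
) -> List[CrosstalkCandidate]:
    """All ordered node pairs as new OR edges: exactly ``N**2`` activating
    candidates (doubled when inhibiting edges are requested)."""
    out = []
    for src in model.node_ids:
        for tgt in model.node_ids:
            out.append(CrosstalkCandidate(gate="OR", source=src, target=tgt))
            if include_inhibiting:
                out.append(
                    CrosstalkCandidate(
                        gate="OR", source=src, target=tgt, sign=INHIBITING
                    )
                )
    return out


def enumerate_and_candidates(model: NetworkModel) -> List[CrosstalkCandidate]:
    """All (node, intermediate reaction) pairs: exactly ``N * R_int``."""
    out = []
    for src in model.node_ids:
        for rxn in model.intermediate_reactions:
            out.append(CrosstalkCandidate(gate="AND", source=src, target=rxn.id))
    return out


def _is_duplicate(model: NetworkModel, cand: CrosstalkCandidate) -> bool:
    if cand.gate == "OR":
        return any(
            not r.is_input
            and r.target == cand.target
            and r.reactants == ((cand.source, cand.sign),)
            for r in model.reactions
        )
    rxn = model.reaction(cand.target)
    return any(rid == cand.source for rid, _ in rxn.reactants)


def _crosstalk_reaction_id(model: NetworkModel, cand: CrosstalkCandidate) -> str:
    base = f"xt_{cand.source}_{cand.target}"
    existing = {r.id for r in model.reactions}
    rid, i = base, 1
    while rid in existing:
        rid = f"{base}_{i}"
        i += 1
    return rid


def apply_candidate(
    model: NetworkModel,
    cand: CrosstalkCandidate,
    allow_duplicate: bool = False,
) -> NetworkModel:
    """Return a new model with the candidate edge permanently added.

    OR candidates append a fresh single-reactant reaction; AND candidates
    extend the target reaction's reactant list.  Duplicate insertions raise
    unless explicitly allowed; an allowed duplicate AND insertion is a no-op
    (the reactant is already in the gate), so its screening delta is zero.
    """
    if not model.has_node(cand.source):
        raise ModelError(f"crosstalk source node {cand.source!r} not in model")
    if _is_duplicate(model, cand):
        if not allow_duplicate:
            raise ModelError(
                f"candidate {cand.describe()} duplicates an existing edge"
            )
        if cand.gate == "AND":
            return model
    if cand.gate == "OR":
        if not model.has_node(cand.target):
            raise ModelError(f"crosstalk target node {cand.target!r} not in model")
        new = ReactionSpec(
            id=_crosstalk_reaction_id(model, cand),
            target=cand.target,
            reactants=((cand.source, cand.sign),),
        )
        return model.with_reactions((*model.reactions, new))
    if cand.gate != "AND":
        raise ModelError(f"unknown gate {cand.gate!r}")
    rxn = model.reaction(cand.target)
    if rxn.is_input:
        raise ModelError(f"cannot AND onto input reaction {rxn.id!r}")
    extended = replace(rxn, reactants=(*rxn.reactants, (cand.source, cand.sign)))
    return model.with_reactions(
        extended if r.id == rxn.id else r for r in model.reactions
    )


def screen_crosstalks(
    model: NetworkModel,
    params: ParameterSet,
    records: Sequence[ExperimentRecord],
    candidates: Sequence[CrosstalkCandidate],
    threshold: float = 0.01,
    config: SimulationConfig = SimulationConfig(),
    baseline: Optional[ValidationReport] = None,
) -> Tuple[List[CrosstalkCandidate], ScreenSummary]:
    """Score every candidate by the change in validation percent it causes.

    Returns the candidates ranked by delta descending (ties: corrected
    descending, then ``(source, target)`` lexicographic) together with the
    decrease/increase/no-effect summary fractions.  Pure over *model*.
    """
    if not candidates:
        raise ModelError("no candidates to screen")
    gates = {c.gate for c in candidates}
    if len(gates) > 1:
        raise ModelError("screen one gate family at a time")
    base_report = baseline or validate(
        model, params, records, threshold=threshold, config=config
    )
    base_match = {o.record_id: o.match for o in base_report.outcomes}
    n = len(records)

    scored: List[CrosstalkCandidate] = []
    for cand in candidates:
        dup = _is_duplicate(model, cand)
        trial = apply_candidate(model, cand, allow_duplicate=True)
        report = validate(trial, params, records, threshold=threshold, config=config)
        corrected = broken = 0
        for o in report.outcomes:
            was = base_match[o.record_id]
            if o.match and not was:
                corrected += 1
            elif was and not o.match:
                broken += 1
        scored.append(
            replace(
                cand,
                delta_validation=100.0 * (corrected - broken) / n,
                corrected=corrected,
                broken=broken,
                duplicate=dup,
            )
        )
    scored.sort(
        key=lambda c: (-c.delta_validation, -c.corrected, c.source, c.target)
    )
    n_c = len(scored)
    dec = sum(c.delta_validation < 0 for c in scored)
    inc = sum(c.delta_validation > 0 for c in scored)
    multi = sum(c.corrected - c.broken > 1 for c in scored)
    summary = ScreenSummary(
        gate=gates.pop(),
        n_candidates=n_c,
        frac_decreased=dec / n_c,
        frac_increased=inc / n_c,
        frac_unchanged=(n_c - dec - inc) / n_c,
        frac_improved_multi=multi / n_c,
    )
    return scored, summary
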