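"""Deterministic synthetic networks and experiment records.

Everything here is a pure function of its spec and seed, so every pipeline
stage is testable without external files.  Two families of generators:

* Toy topologies (``cascade``, ``branch``, ``feedback``, ``crosstalk_demo``)
  small enough to reason about by hand, used for oracle tests and the
  crosstalk recovery case.
* A dimension-matched synthetic stand-in for the curated hypertrophy
  inputs: a random acyclic network with 106 nodes / 191 reactions / 17
  receptor inputs and curated-style record tables (450 qualitative records,
  75 in each of four studied contexts; 100 semi-quantitative ISO-context
  records).  These mimic only the *shape* of the real supplementary tables
  (they are labelled synthetic), so structural and enumeration identities
  can be exercised at full scale.

Record generation uses the same 1% classification machinery as validation,
which makes the generator an exact oracle: with zero label noise the
generating parameters validate at exactly 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .crosstalk import CrosstalkCandidate
from .lde_engine import SimulationConfig
from .model import (
    ACTIVATING,
    DATA_CLASSES,
    INHIBITING,
    ExperimentRecord,
    ModelError,
    NetworkModel,
    NodeSpec,
    ParameterSet,
    Perturbation,
    ReactionSpec,
)
from .validation import ConditionCache, run_condition

__all__ = [
    "ToySpec",
    "RecordGenSpec",
    "make_toy_network",
    "make_records",
    "make_semiquant_records",
    "make_recovery_case",
    "make_sized_network",
    "make_survey_records",
]

_STUDIED_CONTEXTS = ("ISO", "PE", "AngII", "Stretch")


@dataclass(frozen=True)
class ToySpec:
    topology: str  # cascade | branch | feedback | crosstalk_demo
    n_nodes: int = 5
    inhibitor_fraction: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class RecordGenSpec:
    model: NetworkModel
    true_params: ParameterSet
    contexts: Tuple[str, ...]  # input node ids used as agonists
    n_records: int = 3  # per (context, data class)
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise < 0.5:
            raise ModelError("label_noise must lie in [0, 0.5)")


# ---------------------------------------------------------------------------
# Toy networks
# ---------------------------------------------------------------------------

def _sign(rng: np.random.Generator, inhibitor_fraction: float) -> str:
    return INHIBITING if rng.random() < inhibitor_fraction else ACTIVATING


def make_toy_network(spec: ToySpec) -> NetworkModel:
    """Build a seeded toy network of the requested topology."""
    if spec.n_nodes < 2:
        raise ModelError("toy networks need at least 2 nodes")
    rng = np.random.default_rng(spec.seed)
    if spec.topology == "cascade":
        names = [f"N{i+1}" for i in range(spec.n_nodes)]
        nodes = [
            NodeSpec(
                id=n,
                role="input" if i == 0 else
                ("output" if i == spec.n_nodes - 1 else "intermediate"),
            )
            for i, n in enumerate(names)
        ]
        reactions = [ReactionSpec(id="r_in", target=names[0], is_input=True)]
        for i in range(spec.n_nodes - 1):
            reactions.append(
                ReactionSpec(
                    id=f"r{i+1}",
                    target=names[i + 1],
                    reactants=((names[i], _sign(rng, spec.inhibitor_fraction)),),
                )
            )
        return NetworkModel(tuple(nodes), tuple(reactions))

    if spec.topology == "branch":
        if spec.n_nodes < 4:
            raise ModelError("branch topology needs >= 4 nodes")
        names = [f"N{i+1}" for i in range(spec.n_nodes)]
        nodes = [
            NodeSpec(id=n, role="input" if i == 0 else
                     ("output" if i == spec.n_nodes - 1 else "intermediate"))
            for i, n in enumerate(names)
        ]
        reactions = [ReactionSpec(id="r_in", target=names[0], is_input=True)]
        # Two chains from the root, both converging on the last node (OR).
        left = names[1:-1:2]
        right = names[2:-1:2]
        for chain_idx, chain in enumerate((left, right)):
            prev = names[0]
            for node in chain:
                reactions.append(
                    ReactionSpec(
                        id=f"r{len(reactions)}",
                        target=node,
                        reactants=((prev, _sign(rng, spec.inhibitor_fraction)),),
                    )
                )
                prev = node
            if chain:
                reactions.append(
                    ReactionSpec(
                        id=f"r{len(reactions)}",
                        target=names[-1],
                        reactants=((prev, ACTIVATING),),
                    )
                )
        return NetworkModel(tuple(nodes), tuple(reactions))

    if spec.topology == "feedback":
        if spec.n_nodes < 3:
            raise ModelError("feedback topology needs >= 3 nodes")
        base = make_toy_network(
            ToySpec("cascade", spec.n_nodes, spec.inhibitor_fraction, spec.seed)
        )
        names = list(base.node_ids)
        fb = ReactionSpec(
            id="r_fb", target=names[1], reactants=((names[-1], INHIBITING),)
        )
        return base.with_reactions((*base.reactions, fb))

    if spec.topology == "crosstalk_demo":
        return _crosstalk_demo()

    raise ModelError(f"unknown topology {spec.topology!r}")


def _crosstalk_demo() -> NetworkModel:
    """Two-input demo with an AND gate and an inhibiting edge.

    S1 -> A -> C feeds E through an AND with the inhibitor D; D itself is
    the AND of A and B (B driven by the second input S2); F reads out E.
    """
    nodes = (
        NodeSpec("S1", role="input"),
        NodeSpec("S2", role="input"),
        NodeSpec("A"),
        NodeSpec("B"),
        NodeSpec("C"),
        NodeSpec("D"),
        NodeSpec("E"),
        NodeSpec("F", role="output"),
    )
    reactions = (
        ReactionSpec("i1", target="S1", is_input=True),
        ReactionSpec("i2", target="S2", is_input=True),
        ReactionSpec("r1", target="A", reactants=(("S1", ACTIVATING),)),
        ReactionSpec("r2", target="B", reactants=(("S2", ACTIVATING),)),
        ReactionSpec("r3", target="C", reactants=(("A", ACTIVATING),)),
        ReactionSpec(
            "r4", target="D", reactants=(("A", ACTIVATING), ("B", ACTIVATING))
        ),
        ReactionSpec(
            "r5", target="E", reactants=(("D", INHIBITING), ("C", ACTIVATING))
        ),
        ReactionSpec("r6", target="F", reactants=(("E", ACTIVATING),)),
    )
    return NetworkModel(nodes, reactions)


# ---------------------------------------------------------------------------
# Record generation
# ---------------------------------------------------------------------------

def _eligible_nodes(model: NetworkModel) -> Tuple[List[str], List[str]]:
    outputs = [n.id for n in model.nodes if n.role == "output"]
    intermediates = [n.id for n in model.nodes if n.role == "intermediate"]
    if not outputs:
        outputs = intermediates[-1:]
    if not intermediates:
        raise ModelError("record generation needs intermediate nodes")
    return outputs, intermediates


def _draft_record(
    rng: np.random.Generator,
    model: NetworkModel,
    context: str,
    data_class: str,
    index: int,
) -> ExperimentRecord:
    outputs, intermediates = _eligible_nodes(model)
    rid = f"{context}_{data_class}_{index}"
    if data_class == "InputOutput":
        measured = outputs[rng.integers(len(outputs))]
        perts = (Perturbation("stimulus", context),)
    elif data_class == "InputIntermediate":
        measured = intermediates[rng.integers(len(intermediates))]
        perts = (Perturbation("stimulus", context),)
    elif data_class == "IntermediateInhibition":
        knocked = intermediates[rng.integers(len(intermediates))]
        pool = [x for x in intermediates + outputs if x != knocked]
        measured = pool[rng.integers(len(pool))]
        perts = (
            Perturbation("stimulus", context),
            Perturbation("knockdown", knocked),
        )
    else:  # IntermediateOverexpression
        oex = intermediates[rng.integers(len(intermediates))]
        pool = [x for x in intermediates + outputs if x != oex]
        measured = pool[rng.integers(len(pool))]
        with_stim = bool(rng.integers(2))
        perts = (
            (Perturbation("stimulus", context),) if with_stim else ()
        ) + (Perturbation("overexpression", oex),)
    return ExperimentRecord(
        record_id=rid,
        context=context,
        data_class=data_class,
        perturbations=perts,
        measured_node=measured,
        observed="nochange",  # placeholder, replaced by the simulated label
        source="synthetic",
    )


_FLIP = {"increase": "decrease", "decrease": "increase"}


def make_records(
    spec: RecordGenSpec, config: SimulationConfig = SimulationConfig()
) -> List[ExperimentRecord]:
    """Generate qualitative records labelled by the model's own predictions.

    Observed directions are the simulated classifications under
    ``true_params``; each label is then flipped with probability
    ``label_noise`` (a flip always produces a mismatching label), so
    ``validate(model, true_params, records)`` equals
    ``100 * (1 - realized flip fraction)`` exactly.
    """
    model = spec.model
    input_nodes = {r.target for r in model.input_reactions}
    for ctx in spec.contexts:
        if ctx not in input_nodes:
            raise ModelError(f"context {ctx!r} is not an input node of the model")
    rng = np.random.default_rng(spec.seed)
    drafts: List[ExperimentRecord] = []
    for ctx in spec.contexts:
        for data_class in DATA_CLASSES:
            for i in range(spec.n_records):
                drafts.append(_draft_record(rng, model, ctx, data_class, i))

    cache = ConditionCache(model, spec.true_params, config)
    labelled = []
    for rec in drafts:
        outcome = run_condition(
            model, spec.true_params, rec, cache=cache, config=config
        )
        labelled.append(
            ExperimentRecord(
                record_id=rec.record_id,
                context=rec.context,
                data_class=rec.data_class,
                perturbations=rec.perturbations,
                measured_node=rec.measured_node,
                observed=outcome.predicted,
                source=rec.source,
            )
        )

    # Flip decisions are drawn after all records exist, so the record stream
    # is identical across noise settings with the same seed.
    flip_mask = rng.random(len(labelled)) < spec.label_noise
    flip_choice = rng.integers(0, 2, size=len(labelled))
    out = []
    for rec, flip, choice in zip(labelled, flip_mask, flip_choice):
        if not flip:
            out.append(rec)
            continue
        if rec.observed in _FLIP:
            flipped = _FLIP[rec.observed]
        else:
            flipped = ("increase", "decrease")[choice]
        out.append(
            ExperimentRecord(
                record_id=rec.record_id,
                context=rec.context,
                data_class=rec.data_class,
                perturbations=rec.perturbations,
                measured_node=rec.measured_node,
                observed=flipped,
                source=rec.source,
            )
        )
    return out


def make_semiquant_records(
    model: NetworkModel,
    true_params: ParameterSet,
    context: str,
    n_records: int = 8,
    seed: int = 0,
    config: SimulationConfig = SimulationConfig(),
) -> List[ExperimentRecord]:
    """Fold-category records labelled from the model's own simulated folds."""
    rng = np.random.default_rng(seed)
    classes = ("InputIntermediate", "IntermediateInhibition")
    drafts = [
        _draft_record(rng, model, context, classes[i % len(classes)], i)
        for i in range(n_records)
    ]
    cache = ConditionCache(model, true_params, config)
    out = []
    for i, rec in enumerate(drafts):
        semiquant_draft = ExperimentRecord(
            record_id=f"sq_{rec.record_id}",
            context=rec.context,
            data_class=rec.data_class,
            perturbations=rec.perturbations,
            measured_node=rec.measured_node,
            observed="NC",  # placeholder with a semi-quantitative payload
            source="synthetic",
        )
        outcome = run_condition(
            model, true_params, semiquant_draft, cache=cache, config=config
        )
        out.append(
            ExperimentRecord(
                record_id=semiquant_draft.record_id,
                context=rec.context,
                data_class=rec.data_class,
                perturbations=rec.perturbations,
                measured_node=rec.measured_node,
                observed=outcome.predicted,
                source="synthetic",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Crosstalk recovery case
# ---------------------------------------------------------------------------

def make_recovery_case(
    seed: int = 0, config: SimulationConfig = SimulationConfig()
) -> Tuple[NetworkModel, List[ExperimentRecord], CrosstalkCandidate]:
    """Build (pruned model, noise-free records, withheld AND edge).

    Records are simulated from the *full* crosstalk demo network, including
    a co-stimulation context exercising the AND gate; the returned model has
    the gate's second input removed, so an AND screen over the pruned model
    must rank the withheld edge first.
    """
    full = _crosstalk_demo()
    withheld = CrosstalkCandidate(gate="AND", source="B", target="r4")

    co_stim = (Perturbation("stimulus", "S1"), Perturbation("stimulus", "S2"))

    def rec(rid, data_class, perts, measured, context):
        return ExperimentRecord(
            record_id=rid,
            context=context,
            data_class=data_class,
            perturbations=perts,
            measured_node=measured,
            observed="nochange",
            source="synthetic",
        )

    drafts = [
        # Co-stimulation context: the AND gate is engaged, so knocking down
        # its second input is visible at D and downstream of D.
        rec("co_D", "InputIntermediate", co_stim, "D", "S1S2"),
        rec("co_E", "InputIntermediate", co_stim, "E", "S1S2"),
        rec("co_inhB_D", "IntermediateInhibition",
            (*co_stim, Perturbation("knockdown", "B")), "D", "S1S2"),
        rec("co_inhB_E", "IntermediateInhibition",
            (*co_stim, Perturbation("knockdown", "B")), "E", "S1S2"),
        rec("co_inhB_F", "IntermediateInhibition",
            (*co_stim, Perturbation("knockdown", "B")), "F", "S1S2"),
        rec("co_inhA_C", "IntermediateInhibition",
            (*co_stim, Perturbation("knockdown", "A")), "C", "S1S2"),
        # Single-stimulus contexts keep the screen honest: candidates that
        # wire B into the S1 pathway break these records.
        rec("s1_C", "InputIntermediate",
            (Perturbation("stimulus", "S1"),), "C", "S1"),
        rec("s1_E", "InputIntermediate",
            (Perturbation("stimulus", "S1"),), "E", "S1"),
        rec("s1_F", "InputOutput",
            (Perturbation("stimulus", "S1"),), "F", "S1"),
        rec("s2_B", "InputIntermediate",
            (Perturbation("stimulus", "S2"),), "B", "S2"),
        rec("s1_oexB_D", "IntermediateOverexpression",
            (Perturbation("stimulus", "S1"),
             Perturbation("overexpression", "B")), "D", "S1"),
    ]

    cache = ConditionCache(full, ParameterSet(), config)
    records = []
    for draft in drafts:
        outcome = run_condition(full, ParameterSet(), draft, cache=cache,
                                config=config)
        records.append(
            ExperimentRecord(
                record_id=draft.record_id,
                context=draft.context,
                data_class=draft.data_class,
                perturbations=draft.perturbations,
                measured_node=draft.measured_node,
                observed=outcome.predicted,
                source="synthetic",
            )
        )

    pruned_reactions = tuple(
        ReactionSpec(
            "r4", target="D", reactants=(("A", ACTIVATING),)
        )
        if r.id == "r4"
        else r
        for r in full.reactions
    )
    pruned = full.with_reactions(pruned_reactions)
    return pruned, records, withheld


# ---------------------------------------------------------------------------
# Dimension-matched synthetic network and curated-style tables
# ---------------------------------------------------------------------------

def make_sized_network(
    seed: int = 0,
    n_nodes: int = 106,
    n_reactions: int = 191,
    n_inputs: int = 17,
    n_outputs: int = 7,
    inhibitor_fraction: float = 0.2,
    and_fraction: float = 0.15,
) -> NetworkModel:
    """Random acyclic network with the given dimensions (synthetic stand-in).

    The default dimensions mirror the curated hypertrophy network (106
    nodes, 191 reactions, 17 receptor inputs); only the dimensions are
    shared — the wiring is random.  Every non-input node is the target of at
    least one reaction, so the structural invariants hold.
    """
    if n_reactions < n_nodes:
        raise ModelError("need at least one reaction per non-input node + inputs")
    rng = np.random.default_rng(seed)
    input_names = list(_STUDIED_CONTEXTS[: min(4, n_inputs)]) + [
        f"In{i+1}" for i in range(len(_STUDIED_CONTEXTS[: min(4, n_inputs)]), n_inputs)
    ]
    n_other = n_nodes - n_inputs
    other_names = [f"X{i+1}" for i in range(n_other - n_outputs)] + [
        f"Out{i+1}" for i in range(n_outputs)
    ]
    nodes = [NodeSpec(nid, role="input") for nid in input_names]
    nodes += [
        NodeSpec(nid, role="output" if nid.startswith("Out") else "intermediate")
        for nid in other_names
    ]
    order = input_names + other_names  # topological order for acyclic wiring

    reactions = [
        ReactionSpec(f"i{i+1}", target=nid, is_input=True)
        for i, nid in enumerate(input_names)
    ]
    # One incoming reaction per non-input node guarantees reachability.
    for pos, nid in enumerate(other_names, start=n_inputs):
        src = order[rng.integers(pos)]
        reactions.append(
            ReactionSpec(
                f"r{len(reactions)-n_inputs+1}",
                target=nid,
                reactants=((src, _sign(rng, inhibitor_fraction)),),
            )
        )
    # Remaining reactions: random forward edges, occasionally AND pairs.
    while len(reactions) < n_reactions:
        tgt_pos = int(rng.integers(n_inputs, n_nodes))
        tgt = order[tgt_pos]
        n_reactants = 2 if rng.random() < and_fraction and tgt_pos >= 2 else 1
        src_pos = rng.choice(tgt_pos, size=n_reactants, replace=False)
        reactants = tuple(
            (order[int(s)], _sign(rng, inhibitor_fraction)) for s in src_pos
        )
        reactions.append(
            ReactionSpec(
                f"r{len(reactions)-n_inputs+1}", target=tgt, reactants=reactants
            )
        )
    return NetworkModel(tuple(nodes), tuple(reactions))


def make_survey_records(
    model: NetworkModel,
    seed: int = 0,
    per_studied_context: int = 75,
    n_total: int = 450,
    n_semiquant: int = 100,
) -> Tuple[List[ExperimentRecord], List[ExperimentRecord]]:
    """Curated-style record tables for a sized network (synthetic stand-in).

    Returns ``(qualitative, semiquant)`` with the shape of the curated
    compendium: ``n_total`` qualitative records of which
    ``per_studied_context`` fall in each of the four studied contexts (the
    rest spread over the remaining receptor inputs), plus ``n_semiquant``
    ISO-context fold-category records.  Labels are drawn at random — these
    tables exercise parsing, grouping and counting, not model agreement.
    """
    rng = np.random.default_rng(seed)
    inputs = [r.target for r in model.input_reactions]
    studied = [c for c in _STUDIED_CONTEXTS if c in inputs] or inputs[:4]
    others = [c for c in inputs if c not in studied]
    quota: List[str] = []
    for ctx in studied:
        quota += [ctx] * per_studied_context
    rest = n_total - len(quota)
    if rest < 0:
        raise ModelError("per-context quota exceeds the total record count")
    for i in range(rest):
        quota.append(others[i % len(others)] if others else studied[i % len(studied)])

    directions = ("increase", "decrease", "nochange")
    qualitative = []
    for i, ctx in enumerate(quota):
        data_class = DATA_CLASSES[int(rng.integers(len(DATA_CLASSES)))]
        draft = _draft_record(rng, model, ctx, data_class, i)
        qualitative.append(
            ExperimentRecord(
                record_id=f"q{i}",
                context=ctx,
                data_class=draft.data_class,
                perturbations=draft.perturbations,
                measured_node=draft.measured_node,
                observed=directions[int(rng.integers(3))],
                source="synthetic",
            )
        )

    iso = studied[0]
    categories = ("HL", "ML", "LL", "LH", "MH", "HH")
    semiquant = []
    for i in range(n_semiquant):
        data_class = DATA_CLASSES[int(rng.integers(len(DATA_CLASSES)))]
        draft = _draft_record(rng, model, iso, data_class, i)
        semiquant.append(
            ExperimentRecord(
                record_id=f"sq{i}",
                context=iso,
                data_class=draft.data_class,
                perturbations=draft.perturbations,
                measured_node=draft.measured_node,
                observed=categories[int(rng.integers(6))],
                source="synthetic",
            )
        )
    return qualitative, semiquant
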