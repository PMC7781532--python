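"""Core containers for logic-based ODE signaling models.

A signaling network is a directed, signed interaction graph: *nodes* are
signaling species with normalized activity in ``[0, Ymax]``, and *reactions*
are influence rules written in a flat Boolean dialect (``"!A & B => C"``).
Reactants within one rule combine through an AND gate; multiple rules sharing
a target combine through an OR gate. *Input reactions* (``"=> ISO"``) are the
sources through which experimental stimuli enter the network.

Per-element kinetic parameters (``EC50``, ``n``, ``W_R`` for reactions;
``Ymax``, ``Y0``, ``tau`` for nodes) may be stored on the element specs, in a
sparse override map, or fall back to network-wide defaults — that layered
resolution lives in :class:`ParameterSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Tuple

__all__ = [
    "ACTIVATING",
    "INHIBITING",
    "DEFAULT_PARAMETERS",
    "NODE_PARAMETERS",
    "REACTION_PARAMETERS",
    "FOLD_CATEGORIES",
    "DIRECTIONS",
    "DATA_CLASSES",
    "NodeSpec",
    "ReactionSpec",
    "NetworkModel",
    "Perturbation",
    "ParameterSet",
    "ExperimentRecord",
    "ModelError",
]

ACTIVATING = "activating"
INHIBITING = "inhibiting"

DIRECTIONS = ("increase", "decrease", "nochange")

#: Six semi-quantitative fold-change categories plus the in-silico
#: no-change code, ordered from strongest decrease to strongest increase.
FOLD_CATEGORIES = ("HL", "ML", "LL", "NC", "LH", "MH", "HH")

DATA_CLASSES = (
    "InputOutput",
    "InputIntermediate",
    "IntermediateInhibition",
    "IntermediateOverexpression",
)

NODE_PARAMETERS = ("Ymax", "Y0", "tau")
REACTION_PARAMETERS = ("EC50", "n", "W_R")

#: Network-wide defaults prior to estimation.  These are the published
#: defaults of the beta-adrenergic normalized-Hill model from which the
#: hypertrophy network inherited its parameterization: every reaction at
#: full weight, mild cooperativity, half-maximal activation at 0.5,
#: inputs silent at rest and fully active under stimulation.
DEFAULT_PARAMETERS: Mapping[str, float] = {
    "EC50": 0.5,
    "n": 1.4,
    "W_R": 1.0,
    "W_i": 0.0,
    "W_e": 1.0,
    "Ymax": 1.0,
    "Y0": 0.0,
    "tau": 1.0,
}


class ModelError(ValueError):
    """Structural or parameter inconsistency in a network model."""


@dataclass(frozen=True)
class NodeSpec:
    """One signaling species.

    ``ymax``/``y0``/``tau`` of ``None`` mean "use the network default".
    """

    id: str
    name: str = ""
    role: str = "intermediate"  # input | intermediate | output
    ymax: Optional[float] = None
    y0: Optional[float] = None
    tau: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.id or self.id != self.id.strip():
            raise ModelError(f"node id {self.id!r} must be non-empty and trimmed")
        if self.role not in ("input", "intermediate", "output"):
            raise ModelError(f"node {self.id!r}: unknown role {self.role!r}")
        if self.tau is not None and self.tau <= 0:
            raise ModelError(f"node {self.id!r}: tau must be > 0")
        if self.ymax is not None and self.ymax < 0:
            raise ModelError(f"node {self.id!r}: Ymax must be >= 0")
        if (
            self.y0 is not None
            and self.ymax is not None
            and not (0.0 <= self.y0 <= self.ymax)
        ):
            raise ModelError(f"node {self.id!r}: Y0 must lie in [0, Ymax]")


@dataclass(frozen=True)
class ReactionSpec:
    """One influence rule: a signed AND of reactants driving one target.

    ``reactants`` preserves the order of the rule string; an empty tuple with
    ``is_input=True`` denotes a source reaction.  ``weight``/``n``/``ec50``
    of ``None`` mean "use the network default".
    """

    id: str
    target: str
    reactants: Tuple[Tuple[str, str], ...] = ()
    is_input: bool = False
    weight: Optional[float] = None  # W_R
    n: Optional[float] = None
    ec50: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if not self.target:
            raise ModelError(f"reaction {self.id!r}: empty target")
        if self.is_input and self.reactants:
            raise ModelError(f"input reaction {self.id!r} must have no reactants")
        if not self.is_input and not self.reactants:
            raise ModelError(f"reaction {self.id!r} has no reactants")
        seen = set()
        for rid, sign in self.reactants:
            if sign not in (ACTIVATING, INHIBITING):
                raise ModelError(f"reaction {self.id!r}: bad sign {sign!r}")
            if rid in seen:
                raise ModelError(f"reaction {self.id!r}: duplicate reactant {rid!r}")
            seen.add(rid)

    @property
    def rule(self) -> str:
        """Canonical rule string (round-trips through the parser)."""
        if self.is_input:
            return f"=> {self.target}"
        lhs = " & ".join(
            ("!" if sign == INHIBITING else "") + rid for rid, sign in self.reactants
        )
        return f"{lhs} => {self.target}"


@dataclass(frozen=True)
class NetworkModel:
    """A signed interaction graph: nodes plus AND/OR-combined reactions."""

    nodes: Tuple[NodeSpec, ...]
    reactions: Tuple[ReactionSpec, ...]

    def __post_init__(self) -> None:
        node_ids = [n.id for n in self.nodes]
        if len(set(node_ids)) != len(node_ids):
            dup = sorted({i for i in node_ids if node_ids.count(i) > 1})
            raise ModelError(f"duplicate node ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelError(f"duplicate reaction ids: {dup}")
        known = set(node_ids)
        for r in self.reactions:
            if r.target not in known:
                raise ModelError(
                    f"reaction {r.id!r}: unknown target node {r.target!r}"
                )
            for rid, _ in r.reactants:
                if rid not in known:
                    raise ModelError(
                        f"reaction {r.id!r}: unknown reactant node {rid!r}"
                    )

    # -- lookup helpers -------------------------------------------------
    @property
    def node_ids(self) -> Tuple[str, ...]:
        return tuple(n.id for n in self.nodes)

    def node(self, node_id: str) -> NodeSpec:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def reaction(self, reaction_id: str) -> ReactionSpec:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(reaction_id)

    def has_node(self, node_id: str) -> bool:
        return any(n.id == node_id for n in self.nodes)

    def reactions_targeting(self, node_id: str) -> Tuple[ReactionSpec, ...]:
        return tuple(r for r in self.reactions if r.target == node_id)

    @property
    def input_reactions(self) -> Tuple[ReactionSpec, ...]:
        return tuple(r for r in self.reactions if r.is_input)

    @property
    def intermediate_reactions(self) -> Tuple[ReactionSpec, ...]:
        """All non-source reactions (the deletion/GSA factor space)."""
        return tuple(r for r in self.reactions if not r.is_input)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_inputs(self) -> int:
        return len(self.input_reactions)

    def with_reactions(self, reactions: Iterable[ReactionSpec]) -> "NetworkModel":
        return replace(self, reactions=tuple(reactions))

    def summary(self) -> str:
        return (
            f"{self.n_nodes} nodes, {self.n_reactions} reactions, "
            f"{self.n_inputs} input reactions"
        )


@dataclass(frozen=True)
class Perturbation:
    """One in-silico intervention.

    kind:
      * ``stimulus`` — drive an input reaction at the stimulated weight
        ``W_e`` (or an explicit ``value``); target is the input node or its
        input-reaction id.
      * ``knockdown`` — silence a node by setting its ``Ymax`` to zero.
      * ``overexpression`` — pin a node at its maximal activity (``Y0=Ymax``
        with an effectively infinite time constant).
      * ``reaction_deletion`` — set a reaction's weight ``W_R`` to zero.
      * ``reaction_weight`` — set a reaction's ``W_R`` to ``value``.
    """

    kind: str
    target: str
    value: Optional[float] = None

    KINDS = (
        "stimulus",
        "knockdown",
        "overexpression",
        "reaction_deletion",
        "reaction_weight",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ModelError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "reaction_weight" and self.value is None:
            raise ModelError("reaction_weight perturbation needs a value")


@dataclass(frozen=True)
class ParameterSet:
    """Layered parameters: sparse per-element overrides above network defaults.

    Resolution order for an element's parameter: explicit override keyed by
    ``(element_id, name)``; then the value stored on the element spec; then
    the network-wide default.
    """

    defaults: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARAMETERS)
    )
    overrides: Mapping[Tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(DEFAULT_PARAMETERS) - set(self.defaults)
        if missing:
            raise ModelError(f"parameter defaults missing {sorted(missing)}")
        self.check_values(self.defaults)
        for (elem, name), value in self.overrides.items():
            self.check_values({name: value}, where=f"override for {elem!r}")

    @staticmethod
    def check_values(values: Mapping[str, float], where: str = "defaults") -> None:
        for name in ("W_R", "W_i", "W_e"):
            if name in values and not (0.0 <= values[name] <= 1.0):
                raise ModelError(f"{where}: {name} must lie in [0, 1]")
        if "n" in values and values["n"] < 1.0:
            raise ModelError(f"{where}: n must be >= 1")
        if "EC50" in values and not (0.0 < values["EC50"] < 1.0):
            raise ModelError(f"{where}: EC50 must lie in (0, 1)")
        if "Ymax" in values and values["Ymax"] < 0:
            raise ModelError(f"{where}: Ymax must be >= 0")
        if "tau" in values and values["tau"] <= 0:
            raise ModelError(f"{where}: tau must be > 0")

    # -- derivation -----------------------------------------------------
    def with_defaults(self, **kwargs: float) -> "ParameterSet":
        new = dict(self.defaults)
        new.update(kwargs)
        return ParameterSet(new, dict(self.overrides))

    def with_overrides(
        self, updates: Mapping[Tuple[str, str], float]
    ) -> "ParameterSet":
        new = dict(self.overrides)
        new.update(updates)
        return ParameterSet(dict(self.defaults), new)

    # -- resolution -----------------------------------------------------
    def node_value(self, node: NodeSpec, name: str) -> float:
        if (node.id, name) in self.overrides:
            return self.overrides[(node.id, name)]
        stored = {"Ymax": node.ymax, "Y0": node.y0, "tau": node.tau}.get(name)
        if stored is not None:
            return stored
        return self.defaults[name]

    def reaction_value(self, reaction: ReactionSpec, name: str) -> float:
        if (reaction.id, name) in self.overrides:
            return self.overrides[(reaction.id, name)]
        stored = {"W_R": reaction.weight, "n": reaction.n, "EC50": reaction.ec50}.get(
            name
        )
        if stored is not None:
            return stored
        return self.defaults[name]


@dataclass(frozen=True)
class ExperimentRecord:
    """One curated perturbation -> measurement observation.

    Qualitative records carry a direction from :data:`DIRECTIONS`;
    semi-quantitative records carry a fold category from
    :data:`FOLD_CATEGORIES` (exclusive payloads).
    """

    record_id: str
    context: str
    data_class: str
    perturbations: Tuple[Perturbation, ...]
    measured_node: str
    observed: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.data_class not in DATA_CLASSES:
            raise ModelError(
                f"record {self.record_id!r}: unknown data class "
                f"{self.data_class!r}; expected one of {DATA_CLASSES}"
            )
        if self.observed not in DIRECTIONS and self.observed not in FOLD_CATEGORIES:
            raise ModelError(
                f"record {self.record_id!r}: unknown observation "
                f"{self.observed!r}"
            )
        if not self.perturbations:
            raise ModelError(f"record {self.record_id!r} has no perturbation")

    @property
    def is_semiquant(self) -> bool:
        return self.observed in FOLD_CATEGORIES

    def check_against(self, model: NetworkModel) -> None:
        """Raise if the record references elements absent from *model*."""
        if not model.has_node(self.measured_node):
            raise ModelError(
                f"record {self.record_id!r}: measured node "
                f"{self.measured_node!r} not in model"
            )
        rxn_ids = {r.id for r in model.reactions}
        for p in self.perturbations:
            if p.kind in ("knockdown", "overexpression"):
                if not model.has_node(p.target):
                    raise ModelError(
                        f"record {self.record_id!r}: perturbation target "
                        f"{p.target!r} not in model"
                    )
            elif p.kind == "stimulus":
                if not model.has_node(p.target) and p.target not in rxn_ids:
                    raise ModelError(
                        f"record {self.record_id!r}: stimulus target "
                        f"{p.target!r} not in model"
                    )
            else:
                if p.target not in rxn_ids:
                    raise ModelError(
                        f"record {self.record_id!r}: reaction {p.target!r} "
                        f"not in model"
                    )
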