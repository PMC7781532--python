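"""Reading and writing network model tables and experiment tables.

The canonical on-disk layout mirrors the Netflux spreadsheet convention: a
*species* sheet (one row per node) and a *reactions* sheet (one row per rule).
Both are accepted as a pair of CSV/TSV files named ``species.*`` and
``reactions.*`` inside a directory, as an explicit pair of paths, or as one
XLSX workbook with sheets named ``species`` and ``reactions``.

Experiment tables hold one record per row.  The perturbation column uses a
semicolon-separated token dialect::

    stim:ISO; inhib:CaMKII          # stimulate input ISO, knock down CaMKII
    oex:Ras                         # overexpress Ras
    del:r42  /  w:r42=0.3           # delete / reweight a reaction

Directions are normalized to increase/decrease/nochange and fold categories
to the seven codes HL ML LL NC LH MH HH.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .model import (
    ACTIVATING,
    DATA_CLASSES,
    DIRECTIONS,
    FOLD_CATEGORIES,
    INHIBITING,
    ExperimentRecord,
    ModelError,
    NetworkModel,
    NodeSpec,
    Perturbation,
    ReactionSpec,
)

__all__ = [
    "ParseError",
    "parse_rule",
    "parse_network",
    "parse_experiments",
    "write_network",
    "write_experiments",
]

log = logging.getLogger(__name__)


class ParseError(ModelError):
    """Malformed rule string or table."""


# ---------------------------------------------------------------------------
# Rule strings
# ---------------------------------------------------------------------------

def parse_rule(rule: str, reaction_id: str = "") -> ReactionSpec:
    """Parse one Boolean rule string into a (parameter-free) reaction.

    Grammar: ``[!]X ( & [!]Y )* => Z`` for signaling reactions, or ``=> Z``
    for a source (input) reaction.  ``!`` marks an inhibiting reactant.
    """
    if rule is None or not str(rule).strip():
        raise ParseError(f"reaction {reaction_id!r}: empty rule")
    text = str(rule).strip()
    if "=>" not in text:
        raise ParseError(f"reaction {reaction_id!r}: rule {text!r} lacks '=>'")
    lhs, _, rhs = text.partition("=>")
    target = rhs.strip()
    if not target or " " in target or "&" in target or "!" in target:
        raise ParseError(f"reaction {reaction_id!r}: bad target in rule {text!r}")
    rid = reaction_id or text
    if not lhs.strip():
        return ReactionSpec(id=rid, target=target, reactants=(), is_input=True)
    reactants: List[Tuple[str, str]] = []
    for token in lhs.split("&"):
        token = token.strip()
        if not token:
            raise ParseError(f"reaction {reaction_id!r}: empty reactant in {text!r}")
        sign = ACTIVATING
        if token.startswith("!"):
            sign = INHIBITING
            token = token[1:].strip()
        if not token or any(c in token for c in "!& "):
            raise ParseError(
                f"reaction {reaction_id!r}: malformed reactant in {text!r}"
            )
        if token in [r for r, _ in reactants]:
            raise ParseError(
                f"reaction {reaction_id!r}: duplicate reactant {token!r} in {text!r}"
            )
        reactants.append((token, sign))
    return ReactionSpec(id=rid, target=target, reactants=tuple(reactants))


# ---------------------------------------------------------------------------
# Table helpers
# ---------------------------------------------------------------------------

def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() == ".tsv":
        return pd.read_csv(path, sep="\t", dtype=str)
    return pd.read_csv(path, dtype=str)


def _locate_sheets(path: Union[str, Path]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        species = pd.read_excel(path, sheet_name="species", dtype=str)
        reactions = pd.read_excel(path, sheet_name="reactions", dtype=str)
        return species, reactions
    if path.is_dir():
        found = {}
        for stem in ("species", "reactions"):
            for ext in (".csv", ".tsv"):
                cand = path / f"{stem}{ext}"
                if cand.exists():
                    found[stem] = _read_table(cand)
                    break
            else:
                raise ParseError(f"no {stem}.csv/.tsv found under {path}")
        return found["species"], found["reactions"]
    raise ParseError(
        f"{path}: expected an .xlsx workbook or a directory with "
        "species/reactions tables"
    )


def _opt_float(value, where: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if not text or text.lower() in ("nan", "default", "-"):
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"{where}: non-numeric value {value!r}") from exc


def _warn_extra_columns(df: pd.DataFrame, expected: Sequence[str], sheet: str) -> None:
    extra = [c for c in df.columns if c not in expected]
    if extra:
        log.warning("%s sheet: ignoring unrecognized columns %s", sheet, extra)


# ---------------------------------------------------------------------------
# Network tables
# ---------------------------------------------------------------------------

_SPECIES_COLS = ("id", "name", "role", "Ymax", "Y0", "tau")
_REACTION_COLS = ("id", "rule", "W_R", "n", "EC50")


def parse_network(path: Union[str, Path]) -> NetworkModel:
    """Read a species + reactions table pair into a :class:`NetworkModel`.

    Per-element parameter columns are optional; empty cells mean "use the
    network default".  Node ids are case-sensitive and trimmed.
    """
    species, reactions = _locate_sheets(path)
    for col in ("id",):
        if col not in species.columns:
            raise ParseError(f"species sheet: missing required column {col!r}")
    for col in ("id", "rule"):
        if col not in reactions.columns:
            raise ParseError(f"reactions sheet: missing required column {col!r}")
    _warn_extra_columns(species, _SPECIES_COLS, "species")
    _warn_extra_columns(reactions, _REACTION_COLS, "reactions")

    nodes = []
    for i, row in species.iterrows():
        nid = str(row["id"]).strip()
        where = f"species row {i} ({nid!r})"
        nodes.append(
            NodeSpec(
                id=nid,
                name=str(row.get("name", "") or "").strip()
                if "name" in species.columns and not pd.isna(row.get("name"))
                else "",
                role=str(row["role"]).strip()
                if "role" in species.columns and not pd.isna(row.get("role"))
                else "intermediate",
                ymax=_opt_float(row.get("Ymax"), where),
                y0=_opt_float(row.get("Y0"), where),
                tau=_opt_float(row.get("tau"), where),
            )
        )
    node_ids = {n.id for n in nodes}

    specs = []
    for i, row in reactions.iterrows():
        rid = str(row["id"]).strip()
        where = f"reactions row {i} ({rid!r})"
        spec = parse_rule(row["rule"], reaction_id=rid)
        unknown = [
            nid
            for nid in [spec.target, *(r for r, _ in spec.reactants)]
            if nid not in node_ids
        ]
        if unknown:
            raise ParseError(f"{where}: undeclared node(s) {unknown}")
        specs.append(
            ReactionSpec(
                id=spec.id,
                target=spec.target,
                reactants=spec.reactants,
                is_input=spec.is_input,
                weight=_opt_float(row.get("W_R"), where),
                n=_opt_float(row.get("n"), where),
                ec50=_opt_float(row.get("EC50"), where),
            )
        )
    model = NetworkModel(nodes=tuple(nodes), reactions=tuple(specs))
    log.info("parsed network: %s", model.summary())
    return model


def write_network(model: NetworkModel, path: Union[str, Path]) -> Path:
    """Write *model* as species.csv + reactions.csv under *path* (a directory).

    Round-trip property: ``parse_network(write_network(m))`` reproduces ids,
    rule strings and stored per-element parameters.
    """
    if not model.nodes or not model.reactions:
        raise ModelError("refusing to write an empty model")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    species = pd.DataFrame(
        {
            "id": [n.id for n in model.nodes],
            "name": [n.name for n in model.nodes],
            "role": [n.role for n in model.nodes],
            "Ymax": [n.ymax for n in model.nodes],
            "Y0": [n.y0 for n in model.nodes],
            "tau": [n.tau for n in model.nodes],
        }
    )
    reactions = pd.DataFrame(
        {
            "id": [r.id for r in model.reactions],
            "rule": [r.rule for r in model.reactions],
            "W_R": [r.weight for r in model.reactions],
            "n": [r.n for r in model.reactions],
            "EC50": [r.ec50 for r in model.reactions],
        }
    )
    species.to_csv(path / "species.csv", index=False)
    reactions.to_csv(path / "reactions.csv", index=False)
    return path


# ---------------------------------------------------------------------------
# Experiment tables
# ---------------------------------------------------------------------------

_DIRECTION_ALIASES = {
    "increase": "increase",
    "decrease": "decrease",
    "nochange": "nochange",
    "no change": "nochange",
    "no_change": "nochange",
    "unchanged": "nochange",
}
_DIRECTION_SUGGESTIONS = {
    "up": "increase",
    "down": "decrease",
    "higher": "increase",
    "lower": "decrease",
    "+": "increase",
    "-": "decrease",
}

_CLASS_ALIASES = {dc.lower(): dc for dc in DATA_CLASSES}
_CLASS_ALIASES.update(
    {
        "input-output": "InputOutput",
        "input-intermediate": "InputIntermediate",
        "intermediate-inhibition": "IntermediateInhibition",
        "intermediate-overexpression": "IntermediateOverexpression",
    }
)

_EXPERIMENT_COLS = (
    "record_id",
    "context",
    "data_class",
    "perturbations",
    "measured_node",
    "observed",
    "source",
)


def _parse_perturbation_token(token: str, where: str) -> Perturbation:
    token = token.strip()
    if ":" not in token and not token.startswith("w:"):
        raise ParseError(f"{where}: malformed perturbation token {token!r}")
    kind, _, rest = token.partition(":")
    kind = kind.strip().lower()
    rest = rest.strip()
    if kind == "stim":
        return Perturbation("stimulus", rest)
    if kind == "inhib":
        return Perturbation("knockdown", rest)
    if kind == "oex":
        return Perturbation("overexpression", rest)
    if kind == "del":
        return Perturbation("reaction_deletion", rest)
    if kind == "w":
        target, _, value = rest.partition("=")
        if not value:
            raise ParseError(f"{where}: weight token {token!r} needs '=<value>'")
        return Perturbation("reaction_weight", target.strip(), float(value))
    raise ParseError(
        f"{where}: unknown perturbation kind {kind!r} "
        "(expected stim/inhib/oex/del/w)"
    )


def _normalize_observed(token: str, where: str) -> str:
    text = str(token).strip()
    if text.upper() in FOLD_CATEGORIES:
        return text.upper()
    lowered = text.lower()
    if lowered in _DIRECTION_ALIASES:
        return _DIRECTION_ALIASES[lowered]
    if lowered in _DIRECTION_SUGGESTIONS:
        raise ParseError(
            f"{where}: unknown direction {token!r}; did you mean "
            f"{_DIRECTION_SUGGESTIONS[lowered]!r}?"
        )
    raise ParseError(
        f"{where}: unknown observation {token!r}; expected one of "
        f"{DIRECTIONS} or a fold category {FOLD_CATEGORIES}"
    )


def parse_experiments(path: Union[str, Path]) -> List[ExperimentRecord]:
    """Read an experiment table (CSV/TSV/XLSX) into records."""
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        df = pd.read_excel(path, dtype=str)
    else:
        df = _read_table(path)
    for col in ("context", "data_class", "perturbations", "measured_node", "observed"):
        if col not in df.columns:
            raise ParseError(f"experiment table: missing required column {col!r}")
    _warn_extra_columns(df, _EXPERIMENT_COLS, "experiments")

    records: List[ExperimentRecord] = []
    for i, row in df.iterrows():
        rid = (
            str(row["record_id"]).strip()
            if "record_id" in df.columns and not pd.isna(row.get("record_id"))
            else f"record{i}"
        )
        where = f"experiment row {i} ({rid!r})"
        cls_token = str(row["data_class"]).strip()
        data_class = _CLASS_ALIASES.get(cls_token.lower())
        if data_class is None:
            raise ParseError(
                f"{where}: unknown data class {cls_token!r}; "
                f"expected one of {DATA_CLASSES}"
            )
        pert_cell = row["perturbations"]
        if pd.isna(pert_cell) or not str(pert_cell).strip():
            raise ParseError(f"{where}: no perturbation given")
        perts = tuple(
            _parse_perturbation_token(tok, where)
            for tok in str(pert_cell).split(";")
            if tok.strip()
        )
        records.append(
            ExperimentRecord(
                record_id=rid,
                context=str(row["context"]).strip(),
                data_class=data_class,
                perturbations=perts,
                measured_node=str(row["measured_node"]).strip(),
                observed=_normalize_observed(row["observed"], where),
                source=str(row.get("source", "") or "")
                if "source" in df.columns and not pd.isna(row.get("source"))
                else "",
            )
        )
    if not records:
        raise ParseError(f"{path}: experiment table is empty")
    return records


def _perturbation_token(p: Perturbation) -> str:
    if p.kind == "stimulus":
        return f"stim:{p.target}"
    if p.kind == "knockdown":
        return f"inhib:{p.target}"
    if p.kind == "overexpression":
        return f"oex:{p.target}"
    if p.kind == "reaction_deletion":
        return f"del:{p.target}"
    return f"w:{p.target}={p.value}"


def write_experiments(
    records: Iterable[ExperimentRecord], path: Union[str, Path]
) -> Path:
    """Write records as one-row-per-record CSV (round-trips through
    :func:`parse_experiments`)."""
    records = list(records)
    if not records:
        raise ModelError("refusing to write an empty record list")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "context": [r.context for r in records],
            "data_class": [r.data_class for r in records],
            "perturbations": [
                "; ".join(_perturbation_token(p) for p in r.perturbations)
                for r in records
            ],
            "measured_node": [r.measured_node for r in records],
            "observed": [r.observed for r in records],
            "source": [r.source for r in records],
        }
    )
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df.to_csv(path, index=False, sep=sep)
    return path
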