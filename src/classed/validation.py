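"""Automated qualitative and semi-quantitative model validation.

Each experimental record is simulated twice — a control condition and a
treated condition, both to steady state — and the change in the measured
node's activity is classified as an increase, decrease or no change against
an in-silico threshold (default 1% relative change).  The validation percent
is the fraction of records whose predicted direction (or fold category)
matches the curated observation.

Control/treatment pairing follows the record's data class:

* ``InputOutput`` / ``InputIntermediate`` — control is the resting state
  (all inputs at ``W_i``); treatment applies the context stimulus.
* ``IntermediateInhibition`` — control is the stimulus alone; treatment adds
  the node knockdown.
* ``IntermediateOverexpression`` — control is the resting state; treatment
  applies the overexpression (plus the stimulus when the record has one).

Semi-quantitative records are scored through the fold change
``treated/control`` mapped to seven categories:
HL (<0.2), ML (0.2–0.5), LL (0.5–0.99), NC (0.99–1.01), LH (1.01–2),
MH (2–5), HH (>5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lde_engine import SimulationConfig, simulate
from .model import (
    DIRECTIONS,
    FOLD_CATEGORIES,
    ExperimentRecord,
    ModelError,
    NetworkModel,
    ParameterSet,
    Perturbation,
)

__all__ = [
    "PredictionOutcome",
    "ValidationReport",
    "classify_change",
    "classify_fold_change",
    "run_condition",
    "validate",
    "validate_semiquant",
    "ConditionCache",
]

log = logging.getLogger(__name__)

#: Relative-change threshold (fraction, 0.01 = 1%) separating a predicted
#: increase/decrease from no change.
DEFAULT_THRESHOLD = 0.01

#: Below this control activity (times Ymax) the percent change falls back to
#: the absolute change expressed in percent of Ymax.
EPS_CONTROL = 1.0e-4

#: Additive guard on numerator and denominator of semi-quantitative folds.
EPS_FOLD = 1.0e-3


@dataclass(frozen=True)
class PredictionOutcome:
    record_id: str
    context: str
    data_class: str
    measured_node: str
    control_activity: float
    treated_activity: float
    percent_change: float
    predicted: str
    observed: str
    match: bool
    resolved: bool = True


@dataclass
class ValidationReport:
    """Per-record outcomes plus aggregate validation percents."""

    outcomes: List[PredictionOutcome]
    mode: str = "qualitative"  # or semiquant-strict / semiquant-lenient

    @property
    def n_records(self) -> int:
        return len(self.outcomes)

    @property
    def n_resolved(self) -> int:
        return sum(o.resolved for o in self.outcomes)

    @property
    def n_matches(self) -> int:
        return sum(o.match for o in self.outcomes if o.resolved)

    @property
    def validation_percent(self) -> float:
        n = self.n_resolved
        return 100.0 * self.n_matches / n if n else float("nan")

    def _breakdown(self, key) -> Dict:
        groups: Dict = {}
        for o in self.outcomes:
            if not o.resolved:
                continue
            groups.setdefault(key(o), [0, 0])
            groups[key(o)][0] += o.match
            groups[key(o)][1] += 1
        return {
            k: {"percent": 100.0 * m / n, "matches": m, "records": n}
            for k, (m, n) in sorted(groups.items())
        }

    @property
    def by_class(self) -> Dict[str, Dict]:
        return self._breakdown(lambda o: o.data_class)

    @property
    def by_context(self) -> Dict[str, Dict]:
        return self._breakdown(lambda o: o.context)

    @property
    def by_class_context(self) -> Dict[Tuple[str, str], Dict]:
        return self._breakdown(lambda o: (o.data_class, o.context))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "record_id": [o.record_id for o in self.outcomes],
                "context": [o.context for o in self.outcomes],
                "data_class": [o.data_class for o in self.outcomes],
                "measured_node": [o.measured_node for o in self.outcomes],
                "control": [o.control_activity for o in self.outcomes],
                "treated": [o.treated_activity for o in self.outcomes],
                "percent_change": [o.percent_change for o in self.outcomes],
                "predicted": [o.predicted for o in self.outcomes],
                "observed": [o.observed for o in self.outcomes],
                "match": [o.match for o in self.outcomes],
                "resolved": [o.resolved for o in self.outcomes],
            }
        )

    def summary(self) -> Dict:
        return {
            "mode": self.mode,
            "validation_percent": self.validation_percent,
            "matches": self.n_matches,
            "records": self.n_resolved,
            "unresolved": self.n_records - self.n_resolved,
            "by_class": self.by_class,
            "by_context": self.by_context,
        }


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_change(
    treated: float,
    control: float,
    threshold: float = DEFAULT_THRESHOLD,
    ymax: float = 1.0,
) -> Tuple[str, float]:
    """Classify a treated-vs-control activity change as a direction.

    Returns ``(direction, percent_change)``.  The change is relative to the
    control; when the control is effectively zero (below
    ``EPS_CONTROL * ymax``) the absolute change in percent of ``Ymax`` is
    used so near-zero baselines do not explode.
    """
    floor = EPS_CONTROL * max(ymax, 1.0e-12)
    if control >= floor:
        pct = 100.0 * (treated - control) / control
    else:
        pct = 100.0 * (treated - control) / max(ymax, 1.0e-12)
    cut = 100.0 * threshold
    if pct > cut:
        return "increase", pct
    if pct < -cut:
        return "decrease", pct
    return "nochange", pct


def classify_fold_change(fold: float) -> str:
    """Map a fold change (treated/control) to a semi-quantitative category."""
    if not np.isfinite(fold) or fold <= 0.0:
        raise ModelError(f"fold change must be positive and finite, got {fold}")
    if fold < 0.2:
        return "HL"
    if fold < 0.5:
        return "ML"
    if fold <= 0.99:
        return "LL"
    if fold <= 1.01:
        return "NC"
    if fold <= 2.0:
        return "LH"
    if fold <= 5.0:
        return "MH"
    return "HH"


def _category_direction(cat: str) -> str:
    if cat in ("LH", "MH", "HH"):
        return "increase"
    if cat in ("LL", "ML", "HL"):
        return "decrease"
    return "nochange"


# ---------------------------------------------------------------------------
# Condition simulation
# ---------------------------------------------------------------------------

def _split_conditions(
    record: ExperimentRecord,
) -> Tuple[Tuple[Perturbation, ...], Tuple[Perturbation, ...]]:
    """Derive (control, treatment) perturbation tuples from the data class."""
    stimuli = tuple(p for p in record.perturbations if p.kind == "stimulus")
    if record.data_class in ("InputOutput", "InputIntermediate"):
        return (), record.perturbations
    if record.data_class == "IntermediateInhibition":
        return stimuli, record.perturbations
    # IntermediateOverexpression: resting control; stimulus (if any) only in
    # the treated arm together with the overexpression.
    return (), record.perturbations


class ConditionCache:
    """Memoize steady states per unique perturbation set for one model."""

    def __init__(
        self,
        model: NetworkModel,
        params: ParameterSet,
        config: SimulationConfig = SimulationConfig(),
    ) -> None:
        self.model = model
        self.params = params
        self.config = config
        self._cache: Dict[Tuple, object] = {}

    def steady_state(self, perturbations: Sequence[Perturbation]):
        key = tuple(sorted((p.kind, p.target, p.value) for p in perturbations))
        if key not in self._cache:
            self._cache[key] = simulate(
                self.model, self.params, perturbations, config=self.config
            )
        return self._cache[key]


def run_condition(
    model: NetworkModel,
    params: ParameterSet,
    record: ExperimentRecord,
    threshold: float = DEFAULT_THRESHOLD,
    cache: Optional[ConditionCache] = None,
    config: SimulationConfig = SimulationConfig(),
) -> PredictionOutcome:
    """Simulate one record's control and treated conditions and score it.

    A non-converged simulation yields an unresolved outcome (excluded from
    aggregate percents) rather than an exception.
    """
    record.check_against(model)
    cache = cache or ConditionCache(model, params, config)
    control_p, treated_p = _split_conditions(record)
    control = cache.steady_state(control_p)
    treated = cache.steady_state(treated_p)
    resolved = control.converged and treated.converged
    c = control.activity(record.measured_node)
    t = treated.activity(record.measured_node)
    ymax = params.node_value(model.node(record.measured_node), "Ymax")
    if record.is_semiquant:
        fold = (t + EPS_FOLD) / (c + EPS_FOLD)
        predicted = classify_fold_change(fold)
        pct = 100.0 * (fold - 1.0)
    else:
        predicted, pct = classify_change(t, c, threshold=threshold, ymax=ymax)
    return PredictionOutcome(
        record_id=record.record_id,
        context=record.context,
        data_class=record.data_class,
        measured_node=record.measured_node,
        control_activity=c,
        treated_activity=t,
        percent_change=pct,
        predicted=predicted,
        observed=record.observed,
        match=bool(resolved and predicted == record.observed),
        resolved=resolved,
    )


def validate(
    model: NetworkModel,
    params: ParameterSet,
    records: Sequence[ExperimentRecord],
    threshold: float = DEFAULT_THRESHOLD,
    config: SimulationConfig = SimulationConfig(),
) -> ValidationReport:
    """Score all qualitative records; deterministic given model + params."""
    if not records:
        raise ModelError("validate() needs at least one record")
    cache = ConditionCache(model, params, config)
    outcomes = [
        run_condition(model, params, r, threshold=threshold, cache=cache, config=config)
        for r in records
    ]
    unresolved = sum(not o.resolved for o in outcomes)
    if unresolved:
        log.warning("%d of %d conditions did not converge", unresolved, len(outcomes))
    return ValidationReport(outcomes=outcomes)


def validate_semiquant(
    model: NetworkModel,
    params: ParameterSet,
    records: Sequence[ExperimentRecord],
    lenient: bool = False,
    config: SimulationConfig = SimulationConfig(),
) -> ValidationReport:
    """Score semi-quantitative records by fold-change category.

    Strict mode (default) requires the identical category; lenient mode
    accepts the same direction within one category level.
    """
    if not records:
        raise ModelError("validate_semiquant() needs at least one record")
    if any(not r.is_semiquant for r in records):
        raise ModelError("validate_semiquant() got a qualitative record")
    cache = ConditionCache(model, params, config)
    outcomes = []
    order = {c: i for i, c in enumerate(FOLD_CATEGORIES)}
    for r in records:
        o = run_condition(model, params, r, cache=cache, config=config)
        if lenient and o.resolved and not o.match:
            same_dir = _category_direction(o.predicted) == _category_direction(
                o.observed
            )
            adjacent = abs(order[o.predicted] - order[o.observed]) <= 1
            if same_dir and adjacent:
                o = PredictionOutcome(**{**o.__dict__, "match": True})
        outcomes.append(o)
    return ValidationReport(
        outcomes=outcomes, mode="semiquant-lenient" if lenient else "semiquant-strict"
    )
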