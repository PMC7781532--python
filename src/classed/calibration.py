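"""Parameter estimation against qualitative and semi-quantitative data.

Stage 1 estimates the four network-wide defaults — Hill coefficient ``n``,
reaction weight ``W_R``, resting input weight ``W_i`` and stimulated input
weight ``W_e`` — by maximizing the overall validation percent over all
contexts.  Stage 3 calibrates per-reaction ``EC50`` for a small subset of
key reactions (typically the top-ranked reactions from the sensitivity
screen) against qualitative plus semi-quantitative records with equal weight
per record.

The objective is a validation *percent*, i.e. a piecewise-constant step
function of the parameters, so gradient methods and simplex shrinkage stall
on its plateaus.  The search is a seeded multi-start scatter of random
initial points, each refined by a derivative-free compass pattern search
whose initial step is a quarter of each parameter's range — large enough to
hop between plateaus — and which halves the step whenever no axial move
improves the objective.  Ties between equally good optima are broken toward
the smallest Euclidean distance from the starting defaults (minimal
revision).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .lde_engine import SimulationConfig, hill_constants
from .model import ExperimentRecord, ModelError, NetworkModel, ParameterSet
from .validation import validate, validate_semiquant

__all__ = [
    "EstimationResult",
    "DEFAULT_BOUNDS",
    "estimate_defaults",
    "objective_landscape",
    "calibrate_ec50",
]

log = logging.getLogger(__name__)

#: Search bounds.  ``W_i`` is kept low (baselines are sub-maximal at rest),
#: ``W_e`` high (an applied agonist strongly activates its receptor), and the
#: EC50 window excludes the transfer-function singularity for the default n.
DEFAULT_BOUNDS: Mapping[str, Tuple[float, float]] = {
    "n": (1.0, 10.0),
    "W_R": (0.0, 1.0),
    "W_i": (0.0, 0.5),
    "W_e": (0.5, 1.0),
    "EC50": (0.2, 0.6),
}

_DEFAULT_PARAM_NAMES = ("n", "W_R", "W_i", "W_e")


@dataclass
class EstimationResult:
    """Best parameters, their objective, and the full start-by-start trace."""

    best_params: ParameterSet
    best_objective: float
    best_values: Dict[str, float]
    starts: List[Tuple[np.ndarray, np.ndarray, float]]  # (start, optimum, objective)
    seed: int

    @property
    def n_starts(self) -> int:
        return len(self.starts)


def _is_valid_point(names: Sequence[str], x: np.ndarray, base: ParameterSet) -> bool:
    """Reject points where (n, EC50) sit on the transfer-function singularity."""
    values = dict(zip(names, x))
    n = values.get("n", base.defaults["n"])
    ec50 = values.get("EC50", base.defaults["EC50"])
    try:
        hill_constants(n, ec50)
    except ModelError:
        return False
    return True


def _pattern_search(
    objective,
    x0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    max_evals: int,
    min_step: float = 0.01,
) -> Tuple[np.ndarray, float]:
    """Compass pattern search maximizing a (possibly piecewise-constant)
    objective; the initial step of a quarter range lets it cross plateaus."""
    x = x0.copy()
    f = objective(x)
    evals = 1
    step = 0.25 * (hi - lo)
    while evals < max_evals and np.max(step / (hi - lo)) > min_step:
        improved = False
        for j in range(x.size):
            for sgn in (1.0, -1.0):
                cand = x.copy()
                cand[j] = np.clip(cand[j] + sgn * step[j], lo[j], hi[j])
                fc = objective(cand)
                evals += 1
                if fc > f:
                    x, f, improved = cand, fc, True
                    break
                if evals >= max_evals:
                    break
            if improved or evals >= max_evals:
                break
        if not improved:
            step *= 0.5
    return x, f


def _multistart(
    objective,
    names: Sequence[str],
    bounds: Sequence[Tuple[float, float]],
    reference: np.ndarray,
    n_starts: int,
    seed: int,
    maxiter: int,
) -> Tuple[np.ndarray, float, List[Tuple[np.ndarray, np.ndarray, float]]]:
    """Seeded scatter of starts + pattern-search refinement, maximizing."""
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = lo + (hi - lo) * rng.random((n_starts, len(bounds)))
    trace: List[Tuple[np.ndarray, np.ndarray, float]] = []
    best_x, best_f = None, -np.inf
    for x0 in starts:
        xopt, fopt = _pattern_search(objective, x0, lo, hi, max_evals=maxiter)
        trace.append((x0, xopt, fopt))
        better = fopt > best_f + 1e-12
        tie = abs(fopt - best_f) <= 1e-12 and best_x is not None
        if better or (
            tie
            and np.linalg.norm(xopt - reference) < np.linalg.norm(best_x - reference)
        ):
            best_x, best_f = xopt, fopt
    return best_x, best_f, trace


def estimate_defaults(
    model: NetworkModel,
    records: Sequence[ExperimentRecord],
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    n_starts: int = 100,
    seed: int = 0,
    base_params: Optional[ParameterSet] = None,
    threshold: float = 0.01,
    maxiter: int = 60,
    config: SimulationConfig = SimulationConfig(),
) -> EstimationResult:
    """Estimate the four network-wide defaults (n, W_R, W_i, W_e).

    Maximizes the overall validation percent over *records* with a seeded
    multi-start derivative-free search; deterministic given ``seed``.
    """
    if not records:
        raise ModelError("estimate_defaults() needs records")
    base = base_params or ParameterSet()
    merged = dict(DEFAULT_BOUNDS)
    if bounds:
        merged.update(bounds)
    names = _DEFAULT_PARAM_NAMES
    bnds = [merged[name] for name in names]
    for name, (lo, hi) in zip(names, bnds):
        probe = base.with_defaults(**{name: lo})
        probe2 = base.with_defaults(**{name: hi})  # raises on invariant breach
        del probe, probe2

    def objective(x: np.ndarray) -> float:
        if not _is_valid_point(names, x, base):
            return -np.inf
        params = base.with_defaults(**dict(zip(names, x)))
        return validate(
            model, params, records, threshold=threshold, config=config
        ).validation_percent

    reference = np.array([base.defaults[name] for name in names])
    best_x, best_f, trace = _multistart(
        objective, names, bnds, reference, n_starts, seed, maxiter
    )
    best_values = dict(zip(names, map(float, best_x)))
    return EstimationResult(
        best_params=base.with_defaults(**best_values),
        best_objective=float(best_f),
        best_values=best_values,
        starts=trace,
        seed=seed,
    )


def objective_landscape(
    model: NetworkModel,
    records: Sequence[ExperimentRecord],
    pair: Tuple[str, str],
    grid: Mapping[str, Sequence[float]],
    at: Optional[ParameterSet] = None,
    threshold: float = 0.01,
    config: SimulationConfig = SimulationConfig(),
) -> Tuple[np.ndarray, np.ndarray]:
    """Grid-evaluate the validation percent over one parameter pair.

    Returns ``(percent_matrix, valid_mask)`` with rows indexed by the first
    parameter of *pair*.  Cells straddling the ``EC50**n = 0.5`` singularity
    are flagged invalid (NaN in the matrix, False in the mask), not skipped
    silently.
    """
    if pair not in (("W_R", "n"), ("n", "W_R"), ("W_e", "W_i"), ("W_i", "W_e")):
        raise ModelError(f"unsupported landscape pair {pair!r}")
    base = at or ParameterSet()
    a_name, b_name = pair
    a_vals = np.asarray(grid[a_name], float)
    b_vals = np.asarray(grid[b_name], float)
    out = np.full((a_vals.size, b_vals.size), np.nan)
    ok = np.zeros_like(out, dtype=bool)
    for i, a in enumerate(a_vals):
        for j, b in enumerate(b_vals):
            values = {a_name: float(a), b_name: float(b)}
            if not _is_valid_point(list(values), np.array(list(values.values())), base):
                continue
            params = base.with_defaults(**values)
            out[i, j] = validate(
                model, params, records, threshold=threshold, config=config
            ).validation_percent
            ok[i, j] = True
    return out, ok


def calibrate_ec50(
    model: NetworkModel,
    params: ParameterSet,
    reaction_subset: Sequence[str],
    qual_records: Sequence[ExperimentRecord],
    semiquant_records: Sequence[ExperimentRecord],
    bounds: Tuple[float, float] = (0.2, 0.6),
    n_starts: int = 20,
    seed: int = 0,
    lenient: bool = False,
    maxiter: int = 80,
    config: SimulationConfig = SimulationConfig(),
) -> EstimationResult:
    """Calibrate per-reaction EC50 for a selected subset of key reactions.

    The combined objective gives each record equal weight:
    ``100 * (matches_qual + matches_semi) / (N_qual + N_semi)``.  An empty
    subset returns the input parameters with their current objective.
    """
    rxn_ids = {r.id for r in model.reactions}
    for rid in reaction_subset:
        if rid not in rxn_ids:
            raise ModelError(f"calibration subset reaction {rid!r} not in model")
    n_total = len(qual_records) + len(semiquant_records)
    if n_total == 0:
        raise ModelError("calibrate_ec50() needs records")

    def combined(p: ParameterSet) -> float:
        matches = 0
        if qual_records:
            matches += validate(model, p, qual_records, config=config).n_matches
        if semiquant_records:
            matches += validate_semiquant(
                model, p, semiquant_records, lenient=lenient, config=config
            ).n_matches
        return 100.0 * matches / n_total

    if not reaction_subset:
        f0 = combined(params)
        return EstimationResult(
            best_params=params,
            best_objective=f0,
            best_values={},
            starts=[],
            seed=seed,
        )

    def objective(x: np.ndarray) -> float:
        overrides = {(rid, "EC50"): float(v) for rid, v in zip(reaction_subset, x)}
        for (rid, _), v in overrides.items():
            n = params.reaction_value(model.reaction(rid), "n")
            try:
                hill_constants(n, v)
            except ModelError:
                return -np.inf
        return combined(params.with_overrides(overrides))

    reference = np.array(
        [
            params.reaction_value(model.reaction(rid), "EC50")
            for rid in reaction_subset
        ]
    )
    bnds = [bounds] * len(reaction_subset)
    best_x, best_f, trace = _multistart(
        objective, list(reaction_subset), bnds, reference, n_starts, seed, maxiter
    )
    best_values = {rid: float(v) for rid, v in zip(reaction_subset, best_x)}
    best_params = params.with_overrides(
        {(rid, "EC50"): v for rid, v in best_values.items()}
    )
    return EstimationResult(
        best_params=best_params,
        best_objective=float(best_f),
        best_values=best_values,
        starts=trace,
        seed=seed,
    )
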