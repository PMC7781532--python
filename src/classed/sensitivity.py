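"""Key-reaction identification: deletion scan and Morris/Sobol global GSA.

Three complementary analyses rank the influence of individual signaling
reactions on a context's agreement with data:

* **Single-reaction deletion** — set each intermediate reaction's weight
  ``W_R`` to zero, one at a time, and record the change in validation
  percent per context.  Reactions are categorized as *non-sensitive* (no
  effect anywhere), *direct* (effect in exactly one context) or *shared*
  (effect in two or more contexts).
* **Morris elementary-effects screening** — a cheap global screen over the
  per-reaction ``EC50`` (the most influential reaction parameter in this
  formalism).  Factors are scaled to the unit hypercube on a grid of ``p``
  levels with step ``Delta = p / (2(p-1))``; random trajectories of ``k+1``
  points are oversampled and a spread-maximizing subset retained (greedy
  max-min under the aggregate inter-trajectory point distance).  The mean
  absolute elementary effect mu* ranks factors; sigma flags interaction /
  nonlinearity; |mu|/mu* near 1 flags a monotone effect.
* **Sobol variance decomposition** with the Jansen estimators — main
  (``S_i``), total (``T_i``) and closed-pair second-order (``S_ij``)
  variance shares from base matrices A, B and column-swapped hybrids, with
  percentile bootstrap confidence intervals over the sample rows.  The pair
  synergy score relates ``S_ij`` to the factors' higher-order effects
  ``(T_i - S_i) + (T_j - S_j)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import qmc

from .lde_engine import SimulationConfig, hill_constants
from .model import ExperimentRecord, ModelError, NetworkModel, ParameterSet
from .validation import validate

__all__ = [
    "DeletionScanResult",
    "MorrisResult",
    "SobolResult",
    "ObjectiveSpec",
    "deletion_scan",
    "morris_screen",
    "select_important",
    "sobol_analysis",
    "convergence_check",
]

log = logging.getLogger(__name__)

_ZERO_TOL = 1.0e-9


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

@dataclass
class ObjectiveSpec:
    """A scalar objective over unit-hypercube factors.

    For the standard use case (validation percent of one context as a
    function of selected reactions' EC50) build it with
    :meth:`for_validation`; any deterministic callable can be wrapped with
    :meth:`from_function` (used by the analytic oracles in the test suite).
    """

    func: Callable[[np.ndarray], float]
    factor_names: Tuple[str, ...]
    evaluations: int = 0

    @property
    def k(self) -> int:
        return len(self.factor_names)

    def __call__(self, u: np.ndarray) -> float:
        self.evaluations += 1
        return float(self.func(np.asarray(u, float)))

    @classmethod
    def from_function(
        cls, func: Callable[[np.ndarray], float], names: Sequence[str]
    ) -> "ObjectiveSpec":
        return cls(func=func, factor_names=tuple(names))

    @classmethod
    def for_validation(
        cls,
        model: NetworkModel,
        params: ParameterSet,
        records: Sequence[ExperimentRecord],
        factors: Optional[Sequence[str]] = None,
        parameter: str = "EC50",
        bounds: Tuple[float, float] = (0.2, 0.6),
        threshold: float = 0.01,
        config: SimulationConfig = SimulationConfig(),
    ) -> "ObjectiveSpec":
        """Validation percent as a function of per-reaction parameter values.

        ``factors`` defaults to every intermediate (non-input) reaction; unit
        coordinates are mapped affinely onto ``bounds``.
        """
        names = tuple(
            factors
            if factors is not None
            else (r.id for r in model.intermediate_reactions)
        )
        rxn_ids = {r.id for r in model.intermediate_reactions}
        unknown = [f for f in names if f not in rxn_ids]
        if unknown:
            raise ModelError(f"GSA factors not intermediate reactions: {unknown}")
        lo, hi = bounds
        if parameter == "EC50":
            for rid in names:
                n = params.reaction_value(model.reaction(rid), "n")
                for edge in (lo, hi):
                    hill_constants(n, edge)  # bounds must avoid the singularity

        def func(u: np.ndarray) -> float:
            values = lo + (hi - lo) * np.clip(u, 0.0, 1.0)
            p = params.with_overrides(
                {(rid, parameter): float(v) for rid, v in zip(names, values)}
            )
            return validate(
                model, p, records, threshold=threshold, config=config
            ).validation_percent

        return cls(func=func, factor_names=names)

    @classmethod
    def for_output_activity(
        cls,
        model: NetworkModel,
        params: ParameterSet,
        perturbations: Sequence = (),
        outputs: Optional[Sequence[str]] = None,
        factors: Optional[Sequence[str]] = None,
        parameter: str = "EC50",
        bounds: Tuple[float, float] = (0.2, 0.6),
        config: SimulationConfig = SimulationConfig(),
    ) -> "ObjectiveSpec":
        """Alternative objective: mean steady-state activity of output nodes.

        Unlike the validation percent (a step function that only moves when a
        predicted direction flips), this objective responds continuously to
        the varied parameters, which is useful on small networks and for
        cross-checking that the key-reaction ranking does not depend on the
        choice of objective.
        """
        from .lde_engine import simulate

        names = tuple(
            factors
            if factors is not None
            else (r.id for r in model.intermediate_reactions)
        )
        outs = tuple(
            outputs
            if outputs is not None
            else (n.id for n in model.nodes if n.role == "output")
        )
        if not outs:
            raise ModelError("no output nodes designated")
        lo, hi = bounds

        def func(u: np.ndarray) -> float:
            values = lo + (hi - lo) * np.clip(u, 0.0, 1.0)
            p = params.with_overrides(
                {(rid, parameter): float(v) for rid, v in zip(names, values)}
            )
            res = simulate(model, p, perturbations, config=config)
            return float(np.mean([res.activity(o) for o in outs]))

        return cls(func=func, factor_names=names)


# ---------------------------------------------------------------------------
# Deletion scan
# ---------------------------------------------------------------------------

@dataclass
class DeletionScanResult:
    """Per-reaction, per-context change in validation percent after deletion."""

    deltas: Dict[str, Dict[str, float]]  # reaction -> context -> after - before
    baselines: Dict[str, float]  # context -> baseline percent

    @property
    def contexts(self) -> Tuple[str, ...]:
        return tuple(self.baselines)

    def category(self, reaction_id: str) -> str:
        hits = sum(
            abs(d) > _ZERO_TOL for d in self.deltas[reaction_id].values()
        )
        if hits == 0:
            return "non_sensitive"
        return "direct" if hits == 1 else "shared"

    @property
    def categories(self) -> Dict[str, str]:
        return {rid: self.category(rid) for rid in self.deltas}

    def sensitive(self, context: str) -> List[str]:
        """Reactions whose deletion changes the context's validation percent."""
        return [
            rid for rid, d in self.deltas.items() if abs(d[context]) > _ZERO_TOL
        ]

    def ranked(self, context: str) -> List[Tuple[str, float]]:
        return sorted(
            ((rid, d[context]) for rid, d in self.deltas.items()),
            key=lambda kv: (kv[1], kv[0]),
        )


def deletion_scan(
    model: NetworkModel,
    params: ParameterSet,
    records_by_context: Mapping[str, Sequence[ExperimentRecord]],
    threshold: float = 0.01,
    config: SimulationConfig = SimulationConfig(),
) -> DeletionScanResult:
    """One-by-one removal (``W_R = 0``) of every intermediate reaction."""
    baselines = {
        ctx: validate(model, params, recs, threshold=threshold, config=config)
        .validation_percent
        for ctx, recs in records_by_context.items()
    }
    deltas: Dict[str, Dict[str, float]] = {}
    for rxn in model.intermediate_reactions:
        knocked = params.with_overrides({(rxn.id, "W_R"): 0.0})
        deltas[rxn.id] = {
            ctx: validate(model, knocked, recs, threshold=threshold, config=config)
            .validation_percent
            - baselines[ctx]
            for ctx, recs in records_by_context.items()
        }
    return DeletionScanResult(deltas=deltas, baselines=baselines)


# ---------------------------------------------------------------------------
# Morris elementary effects
# ---------------------------------------------------------------------------

@dataclass
class MorrisResult:
    factor_names: Tuple[str, ...]
    mu_star: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    elementary_effects: np.ndarray  # (trajectories, k)
    evaluations: int
    seed: int

    def monotonic(self, cutoff: float = 0.99) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(self.mu_star > 0, np.abs(self.mu) / self.mu_star, 0.0)
        return ratio >= cutoff

    def important(self, threshold: float) -> np.ndarray:
        return self.mu_star > threshold


def _morris_trajectory(k: int, p: int, delta: float, rng: np.random.Generator):
    """One random Morris trajectory of k+1 points on the p-level unit grid."""
    n_base = p // 2  # base levels {0, 1/(p-1), ..., 1/2 - delta + 1/2}
    base = rng.integers(0, n_base, size=k) / (p - 1)
    directions = rng.integers(0, 2, size=k) * 2 - 1  # ±1
    # A +delta step must stay in [0,1]: base in [0, 1-delta] guarantees the
    # up-step; for a down-step start from base + delta instead.
    start = np.where(directions > 0, base, base + delta)
    order = rng.permutation(k)
    points = np.empty((k + 1, k))
    points[0] = start
    x = start.copy()
    for step, j in enumerate(order, start=1):
        x = x.copy()
        x[j] += directions[j] * delta
        points[step] = x
    return points


def _trajectory_distances(trajs: np.ndarray) -> np.ndarray:
    """Aggregate pairwise point-distance between trajectories (Campolongo)."""
    T, P, k = trajs.shape
    flat = trajs.reshape(T, P, k)
    dist = np.zeros((T, T))
    for a in range(T):
        diff = flat[a][:, None, None, :] - flat[a + 1 :][None, :, :, :]
        d = np.sqrt((diff**2).sum(axis=-1)).sum(axis=(0, 2))
        dist[a, a + 1 :] = d
        dist[a + 1 :, a] = d
    return dist


def _select_spread(dist: np.ndarray, m: int) -> List[int]:
    """Greedy max-min subset selection from a distance matrix."""
    T = dist.shape[0]
    if m >= T:
        return list(range(T))
    first = int(np.unravel_index(np.argmax(dist), dist.shape)[0])
    chosen = [first]
    remaining = set(range(T)) - {first}
    while len(chosen) < m:
        best, best_score = None, -1.0
        for cand in sorted(remaining):
            score = min(dist[cand, c] for c in chosen)
            if score > best_score:
                best, best_score = cand, score
        chosen.append(best)
        remaining.discard(best)
    return chosen


def morris_screen(
    objective: ObjectiveSpec,
    levels: int = 8,
    trajectories: int = 16,
    oversample: int = 300,
    seed: int = 0,
) -> MorrisResult:
    """Morris elementary-effects screen over the objective's unit factors.

    Generates ``oversample`` random trajectories, keeps the ``trajectories``
    most spread-out ones, and evaluates ``trajectories * (k+1)`` objective
    values.  Elementary effects are signed finite differences over the grid
    step ``Delta = p / (2(p-1))``.
    """
    k = objective.k
    if k < 1:
        raise ModelError("Morris screen needs at least one factor")
    if levels % 2 != 0:
        raise ModelError("Morris levels must be even")
    if trajectories > oversample:
        raise ModelError("trajectories cannot exceed the oversample pool")
    p = levels
    delta = p / (2.0 * (p - 1.0))
    rng = np.random.default_rng(seed)
    pool = np.stack(
        [_morris_trajectory(k, p, delta, rng) for _ in range(oversample)]
    )
    if trajectories < oversample:
        chosen = _select_spread(_trajectory_distances(pool), trajectories)
    else:
        chosen = list(range(oversample))
    selected = pool[chosen]

    evals_before = objective.evaluations
    ee = np.empty((trajectories, k))
    for t_i, traj in enumerate(selected):
        f = np.array([objective(x) for x in traj])
        for step in range(1, k + 1):
            jumps = traj[step] - traj[step - 1]
            j = int(np.argmax(np.abs(jumps)))
            ee[t_i, j] = (f[step] - f[step - 1]) / jumps[j]
    return MorrisResult(
        factor_names=objective.factor_names,
        mu_star=np.abs(ee).mean(axis=0),
        mu=ee.mean(axis=0),
        sigma=ee.std(axis=0, ddof=1) if trajectories > 1 else np.zeros(k),
        elementary_effects=ee,
        evaluations=objective.evaluations - evals_before,
        seed=seed,
    )


def select_important(morris: MorrisResult, threshold: float) -> List[str]:
    """Factors with mu* above the threshold, ranked by mu* descending."""
    if threshold <= 0:
        raise ModelError("Morris importance threshold must be > 0")
    flagged = [
        (name, float(ms))
        for name, ms in zip(morris.factor_names, morris.mu_star)
        if ms > threshold
    ]
    flagged.sort(key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in flagged]


# ---------------------------------------------------------------------------
# Sobol (Jansen estimators)
# ---------------------------------------------------------------------------

@dataclass
class SobolResult:
    factor_names: Tuple[str, ...]
    S: np.ndarray  # main effects
    T: np.ndarray  # total effects
    S_ci: np.ndarray  # (k, 2) 95% percentile bootstrap
    T_ci: np.ndarray
    pairs: Tuple[Tuple[str, str], ...]
    S2: np.ndarray  # second-order S_ij per pair
    S2_ci: np.ndarray
    synergy: np.ndarray  # S_ij / ((T_i - S_i) + (T_j - S_j))
    N: int
    seed: int
    evaluations: int

    def ranked_total(self) -> List[Tuple[str, float]]:
        order = np.argsort(-self.T)
        return [(self.factor_names[i], float(self.T[i])) for i in order]


def _jansen(fA, fB, fAB, V):
    """Jansen estimators given f(A), f(B) and f(A_B^(i)) per factor/pair."""
    T = ((fA[None, :] - fAB) ** 2).mean(axis=1) / (2.0 * V)
    S = 1.0 - ((fB[None, :] - fAB) ** 2).mean(axis=1) / (2.0 * V)
    return S, T


def sobol_analysis(
    objective: ObjectiveSpec,
    N: int = 1024,
    seed: int = 0,
    bootstrap_reps: int = 2000,
    pairs: bool = True,
) -> SobolResult:
    """Variance-based Sobol analysis with Jansen estimators.

    Uses scrambled Sobol' base matrices ``A`` and ``B`` (``N`` rows each),
    the column-swapped hybrids ``A_B^(i)`` for main/total effects and
    ``A_B^(i,j)`` for the closed pair effects
    ``S_ij = S^c_ij - S_i - S_j``.  95% confidence intervals come from a
    percentile bootstrap over the ``N`` sample rows.  The synergy score of a
    pair is ``S_ij / ((T_i - S_i) + (T_j - S_j))`` (zero when the
    higher-order denominator vanishes).
    """
    k = objective.k
    if N < 64:
        raise ModelError("Sobol sample size N must be >= 64")
    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
    base = sampler.random(N)
    A, B = base[:, :k], base[:, k:]

    evals_before = objective.evaluations
    fA = np.array([objective(x) for x in A])
    fB = np.array([objective(x) for x in B])
    fAB = np.empty((k, N))
    for i in range(k):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fAB[i] = [objective(x) for x in ABi]
    pair_idx: List[Tuple[int, int]] = (
        [(i, j) for i in range(k) for j in range(i + 1, k)] if pairs else []
    )
    fABij = np.empty((len(pair_idx), N))
    for p_i, (i, j) in enumerate(pair_idx):
        ABij = A.copy()
        ABij[:, i] = B[:, i]
        ABij[:, j] = B[:, j]
        fABij[p_i] = [objective(x) for x in ABij]

    allf = np.concatenate([fA, fB])
    V = float(allf.var(ddof=1))
    if V < 1.0e-12:
        raise ModelError("objective has zero variance over the sample; "
                         "Sobol indices are undefined")

    S, T = _jansen(fA, fB, fAB, V)
    if pair_idx:
        Sc, _ = _jansen(fA, fB, fABij, V)
        S2 = np.array([Sc[p] - S[i] - S[j] for p, (i, j) in enumerate(pair_idx)])
    else:
        S2 = np.empty(0)

    # Percentile bootstrap over rows.
    rng = np.random.default_rng(seed + 1)
    S_bs = np.empty((bootstrap_reps, k))
    T_bs = np.empty((bootstrap_reps, k))
    S2_bs = np.empty((bootstrap_reps, len(pair_idx)))
    for b in range(bootstrap_reps):
        idx = rng.integers(0, N, size=N)
        fA_b, fB_b, fAB_b = fA[idx], fB[idx], fAB[:, idx]
        V_b = float(np.concatenate([fA_b, fB_b]).var(ddof=1))
        if V_b < 1.0e-12:
            S_bs[b], T_bs[b] = S, T
            if pair_idx:
                S2_bs[b] = S2
            continue
        S_b, T_b = _jansen(fA_b, fB_b, fAB_b, V_b)
        S_bs[b], T_bs[b] = S_b, T_b
        if pair_idx:
            Sc_b, _ = _jansen(fA_b, fB_b, fABij[:, idx], V_b)
            S2_bs[b] = [
                Sc_b[p] - S_b[i] - S_b[j] for p, (i, j) in enumerate(pair_idx)
            ]
    q = [2.5, 97.5]
    S_ci = np.percentile(S_bs, q, axis=0).T if bootstrap_reps else np.empty((k, 2))
    T_ci = np.percentile(T_bs, q, axis=0).T if bootstrap_reps else np.empty((k, 2))
    S2_ci = (
        np.percentile(S2_bs, q, axis=0).T
        if bootstrap_reps and pair_idx
        else np.empty((len(pair_idx), 2))
    )

    # Synergy is a ratio of two variance fractions; when a pair has no
    # higher-order variance the denominator is pure Monte-Carlo noise, so it
    # is reported as zero below a 1%-of-variance floor.
    synergy = np.zeros(len(pair_idx))
    for p_i, (i, j) in enumerate(pair_idx):
        denom = (T[i] - S[i]) + (T[j] - S[j])
        synergy[p_i] = S2[p_i] / denom if abs(denom) > 1.0e-2 else 0.0

    names = objective.factor_names
    return SobolResult(
        factor_names=names,
        S=S,
        T=T,
        S_ci=S_ci,
        T_ci=T_ci,
        pairs=tuple((names[i], names[j]) for i, j in pair_idx),
        S2=S2,
        S2_ci=S2_ci,
        synergy=synergy,
        N=N,
        seed=seed,
        evaluations=objective.evaluations - evals_before,
    )


def convergence_check(
    objective_factory: Callable[[], ObjectiveSpec],
    N_grid: Sequence[int],
    seed: int = 0,
    tolerance: float = 0.05,
    bootstrap_reps: int = 0,
) -> Dict:
    """Track Sobol index drift over increasing sample sizes.

    ``objective_factory`` must return a fresh objective per call (evaluation
    counters are per-objective).  Convergence is flagged when the largest
    main/total index change between successive sample sizes falls below
    ``tolerance``.
    """
    if list(N_grid) != sorted(N_grid) or len(N_grid) < 1:
        raise ModelError("N_grid must be a non-empty increasing sequence")
    rows = []
    prev = None
    drifts = []
    for N in N_grid:
        res = sobol_analysis(
            objective_factory(), N=N, seed=seed,
            bootstrap_reps=bootstrap_reps, pairs=False,
        )
        rows.append({"N": N, "S": res.S.copy(), "T": res.T.copy()})
        if prev is not None:
            drifts.append(
                float(
                    max(
                        np.max(np.abs(res.S - prev.S)),
                        np.max(np.abs(res.T - prev.T)),
                    )
                )
            )
        prev = res
    converged = bool(drifts and drifts[-1] < tolerance) or len(N_grid) == 1
    return {"table": rows, "drift": drifts, "converged": converged}
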