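"""Modified normalized-Hill logic-based ODE (LDE) engine.

Each node activity :math:`y_i \\in [0, Y_{max,i}]` follows

.. math::

    \\frac{dy_i}{dt} = \\frac{Y_{max,i}\\, F_i(y) - y_i}{\\tau_i}

where the production term :math:`F_i` OR-combines (noisy-OR,
:math:`1-\\prod(1-x)`) every reaction targeting node *i*.  A signaling
reaction contributes the AND of its reactant terms; an input (source)
reaction contributes its input weight — :math:`W_i` at rest, :math:`W_e`
under stimulus.

The transfer function is the normalized Hill sigmoid

.. math::

    f_{act}(x) = \\frac{B x^n}{K^n + x^n},\\quad
    B = \\frac{EC_{50}^n - 1}{2 EC_{50}^n - 1},\\quad K^n = B - 1,

which satisfies :math:`f(0)=0`, :math:`f(1)=1`, :math:`f(EC_{50})=1/2` and is
singular only at :math:`EC_{50}^n = 1/2`.  Two deliberate modifications to
the classic formalism:

* **Inhibition** enters as :math:`1 - W_R f_{act}(x)` so that lowering an
  inhibitory reaction's weight *raises* downstream activity, and deleting it
  (:math:`W_R = 0`) restores the un-inhibited baseline exactly.
* **AND gate** output is divided by the mean of its inputs to the power
  :math:`m-1` (``m`` = number of inputs), which keeps the gate output on the
  same order of magnitude as its inputs for wide gates.

Perturbation semantics: knockdown sets a node's :math:`Y_{max}` to zero;
overexpression pins the node at :math:`Y_{max}` (implemented as an exact
clamp by default, or literally as :math:`Y_0 = Y_{max}`, :math:`\\tau=10^9`);
reaction deletion sets :math:`W_R = 0`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    ACTIVATING,
    INHIBITING,
    ModelError,
    NetworkModel,
    ParameterSet,
    Perturbation,
)

__all__ = [
    "HillConstants",
    "SimulationConfig",
    "SimulationResult",
    "hill_constants",
    "hill_activation",
    "activator_term",
    "inhibitor_term",
    "and_gate",
    "or_gate",
    "build_rhs",
    "simulate",
    "LARGE_TAU",
]

#: Literal time constant used for overexpression when clamping is disabled.
LARGE_TAU = 1.0e9

_SINGULARITY_EPS = 1.0e-9


@dataclass(frozen=True)
class HillConstants:
    """Gain ``B`` and half-max constant ``K^n`` derived from ``(n, EC50)``."""

    B: float
    Kn: float  # K**n = B - 1; kept in this form so EC50**n > 0.5 stays real


def hill_constants(n: float, ec50: float) -> HillConstants:
    """Derive the normalized-Hill constants; reject the singular parameter set.

    Raises :class:`ModelError` when ``EC50**n`` is within a small epsilon of
    0.5, where the gain ``B`` diverges.
    """
    if n < 1.0:
        raise ModelError(f"Hill coefficient n={n} must be >= 1")
    if not 0.0 < ec50 < 1.0:
        raise ModelError(f"EC50={ec50} must lie in (0, 1)")
    e = ec50**n
    if abs(2.0 * e - 1.0) < 2.0 * _SINGULARITY_EPS:
        raise ModelError(
            f"singular transfer function: EC50**n = {e:.9f} is too close to 0.5"
        )
    b = (e - 1.0) / (2.0 * e - 1.0)
    return HillConstants(B=b, Kn=b - 1.0)


def hill_activation(
    x: Union[float, np.ndarray], n: float, ec50: float
) -> Union[float, np.ndarray]:
    """Normalized Hill sigmoid: f(0)=0, f(1)=1, f(EC50)=0.5, monotone on [0,1]."""
    c = hill_constants(n, ec50)
    xc = np.clip(x, 0.0, 1.0)
    xn = xc**n
    return c.B * xn / (c.Kn + xn)


def activator_term(
    x: Union[float, np.ndarray], w: float, n: float, ec50: float
) -> Union[float, np.ndarray]:
    """Weighted activation: ``W_R * f_act(x)``; zero when the reaction is deleted."""
    return w * hill_activation(x, n, ec50)


def inhibitor_term(
    x: Union[float, np.ndarray], w: float, n: float, ec50: float
) -> Union[float, np.ndarray]:
    """Weighted inhibition: ``1 - W_R * f_act(x)``.

    Decreasing ``W_R`` relieves the inhibition; ``W_R = 0`` returns 1 so a
    deleted inhibitory reaction restores the un-inhibited baseline.
    """
    return 1.0 - w * hill_activation(x, n, ec50)


def and_gate(terms: Sequence[float]) -> float:
    """AND of ``m`` gate inputs: ``prod(terms) / mean(terms)**(m-1)``.

    The mean-normalization keeps the output on the inputs' order of
    magnitude for wide gates; a single input passes through unchanged and a
    zero mean (all inputs zero) yields zero.
    """
    arr = np.asarray(terms, dtype=float)
    if arr.size == 0:
        raise ModelError("AND gate needs at least one input")
    if arr.size == 1:
        return float(arr[0])
    mean = float(arr.mean())
    if mean <= 0.0:
        return 0.0
    # mean * prod(terms/mean) == prod(terms)/mean**(m-1), without underflow
    return float(mean * np.prod(arr / mean))


def or_gate(terms: Sequence[float]) -> float:
    """Noisy-OR combination ``1 - prod(1 - term)``; empty input yields 0."""
    arr = np.asarray(terms, dtype=float)
    if arr.size == 0:
        return 0.0
    return float(1.0 - np.prod(1.0 - arr))


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical knobs for steady-state and time-point integration.

    ``tol_ss`` is the steady-state criterion
    ``max_i |dy_i/dt| / max(Ymax_i, eps) < tol_ss``; ``t_max`` defaults to
    ``40 * max(tau)``.  ``oex_clamp`` selects the exact-clamp implementation
    of overexpression over the literal ``tau = 1e9`` variant.
    """

    tol_ss: float = 1.0e-6
    t_max: Optional[float] = None
    rtol: float = 1.0e-6
    atol: float = 1.0e-9
    method: str = "LSODA"
    oex_clamp: bool = True


@dataclass
class SimulationResult:
    """Final activities, optional trajectory, and a convergence flag."""

    node_ids: Tuple[str, ...]
    activities: np.ndarray
    converged: bool
    t_end: float
    trajectory: Optional[Tuple[np.ndarray, np.ndarray]] = None  # (t, y[t, node])
    residual: float = float("nan")

    def activity(self, node_id: str) -> float:
        return float(self.activities[self.node_ids.index(node_id)])

    def as_dict(self) -> Dict[str, float]:
        return {nid: float(a) for nid, a in zip(self.node_ids, self.activities)}


class _CompiledSystem:
    """Model + parameters + perturbations flattened into arrays for the RHS."""

    def __init__(
        self,
        model: NetworkModel,
        params: ParameterSet,
        perturbations: Sequence[Perturbation] = (),
        config: SimulationConfig = SimulationConfig(),
    ) -> None:
        self.model = model
        self.config = config
        self.node_ids = model.node_ids
        index = {nid: i for i, nid in enumerate(self.node_ids)}
        n_nodes = len(self.node_ids)

        self.ymax = np.array(
            [params.node_value(nd, "Ymax") for nd in model.nodes], float
        )
        self.y0 = np.array([params.node_value(nd, "Y0") for nd in model.nodes], float)
        self.tau = np.array([params.node_value(nd, "tau") for nd in model.nodes], float)
        self.clamped = np.zeros(n_nodes, dtype=bool)

        rxn_ids = {r.id for r in model.reactions}
        input_by_node = {r.target: r.id for r in model.input_reactions}
        stimulated: Dict[str, Optional[float]] = {}
        deleted: Dict[str, float] = {}
        for p in perturbations:
            if p.kind == "stimulus":
                rid = p.target if p.target in rxn_ids else input_by_node.get(p.target)
                if rid is None or not model.reaction(rid).is_input:
                    raise ModelError(
                        f"stimulus target {p.target!r} is not an input reaction"
                    )
                stimulated[rid] = p.value
            elif p.kind == "knockdown":
                if p.target not in index:
                    raise ModelError(f"knockdown target {p.target!r} not in model")
                i = index[p.target]
                self.ymax[i] = 0.0
                self.y0[i] = 0.0
            elif p.kind == "overexpression":
                if p.target not in index:
                    raise ModelError(
                        f"overexpression target {p.target!r} not in model"
                    )
                i = index[p.target]
                self.y0[i] = self.ymax[i]
                if config.oex_clamp:
                    self.clamped[i] = True
                else:
                    self.tau[i] = LARGE_TAU
            elif p.kind in ("reaction_deletion", "reaction_weight"):
                if p.target not in rxn_ids:
                    raise ModelError(f"reaction {p.target!r} not in model")
                deleted[p.target] = 0.0 if p.kind == "reaction_deletion" else p.value

        # Flatten all non-input reactions into per-reactant-entry arrays so
        # the RHS evaluates them in a handful of vectorized numpy ops.
        gates = [r for r in model.reactions if not r.is_input]
        self._input_product = np.ones(n_nodes)  # static prod(1 - w_in) per node
        for r in model.input_reactions:
            if r.id in stimulated:
                value = stimulated[r.id]
                w = (
                    value
                    if value is not None
                    else params.overrides.get((r.id, "W_e"), params.defaults["W_e"])
                )
            else:
                w = params.overrides.get((r.id, "W_i"), params.defaults["W_i"])
            self._input_product[index[r.target]] *= 1.0 - float(w)

        ridx, inhib, rxn_of, targets, w_r, n_r, b_r, kn_r, m_r = (
            [], [], [], [], [], [], [], [], []
        )
        for g_i, r in enumerate(gates):
            w = deleted.get(r.id, params.reaction_value(r, "W_R"))
            n = params.reaction_value(r, "n")
            ec50 = params.reaction_value(r, "EC50")
            consts = hill_constants(n, ec50)
            targets.append(index[r.target])
            w_r.append(float(w))
            n_r.append(float(n))
            b_r.append(consts.B)
            kn_r.append(consts.Kn)
            m_r.append(len(r.reactants))
            for rid, sign in r.reactants:
                ridx.append(index[rid])
                inhib.append(sign == INHIBITING)
                rxn_of.append(g_i)
        self._ridx = np.asarray(ridx, dtype=int)
        self._inhib = np.asarray(inhib, dtype=bool)
        self._targets = np.asarray(targets, dtype=int)
        self._m = np.asarray(m_r, dtype=float)
        rxn_of_arr = np.asarray(rxn_of, dtype=int)
        self._rxn_of = rxn_of_arr
        self._offsets = np.searchsorted(rxn_of_arr, np.arange(len(gates)))
        # per-entry broadcast of the owning reaction's constants
        self._w_e = np.asarray(w_r)[rxn_of_arr]
        self._n_e = np.asarray(n_r)[rxn_of_arr]
        self._b_e = np.asarray(b_r)[rxn_of_arr]
        self._kn_e = np.asarray(kn_r)[rxn_of_arr]

        self._free_tau = self.tau[~self.clamped & (self.tau < 1.0e8)]
        self.y_init = np.minimum(self.y0, self.ymax)
        self._xcap = np.minimum(self.ymax, 1.0)

    # -- derivative contract -------------------------------------------
    def production(self, y: np.ndarray) -> np.ndarray:
        """OR-combined production term F_i(y) per node."""
        one_minus = self._input_product.copy()
        if self._targets.size:
            x = np.clip(y, 0.0, self._xcap)
            xn = x[self._ridx] ** self._n_e
            f = self._b_e * xn / (self._kn_e + xn)
            terms = np.where(self._inhib, 1.0 - self._w_e * f, self._w_e * f)
            mean = np.add.reduceat(terms, self._offsets) / self._m
            # mean * prod(terms/mean) avoids underflow of mean**(m-1)
            safe_mean = np.where(mean > 0.0, mean, 1.0)
            ratios = terms / safe_mean[self._rxn_of]
            contrib = np.where(
                mean > 0.0, mean * np.multiply.reduceat(ratios, self._offsets), 0.0
            )
            np.multiply.at(one_minus, self._targets, 1.0 - contrib)
        return 1.0 - one_minus

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = (self.ymax * self.production(y) - y) / self.tau
        dy[self.clamped] = 0.0
        return dy

    def residual(self, y: np.ndarray) -> float:
        dy = self(0.0, y)
        return float(np.max(np.abs(dy) / np.maximum(self.ymax, 1.0e-9)))

    @property
    def t_max(self) -> float:
        if self.config.t_max is not None:
            return self.config.t_max
        base = float(self._free_tau.max()) if self._free_tau.size else 1.0
        return 40.0 * base


def build_rhs(
    model: NetworkModel,
    params: ParameterSet,
    perturbations: Sequence[Perturbation] = (),
    config: SimulationConfig = SimulationConfig(),
) -> _CompiledSystem:
    """Compile the model into a callable ``(t, y) -> dy/dt``.

    The returned object also exposes ``y_init``, ``production`` and the
    steady-state ``residual`` helper.
    """
    return _CompiledSystem(model, params, perturbations, config)


def simulate(
    model: NetworkModel,
    params: ParameterSet,
    perturbations: Sequence[Perturbation] = (),
    t_end: Optional[float] = None,
    mode: str = "steady_state",
    config: SimulationConfig = SimulationConfig(),
) -> SimulationResult:
    """Integrate the LDE system to steady state or to a fixed time point.

    In ``steady_state`` mode the system is integrated in chunks with an
    adaptive stiff-capable solver until the scaled derivative norm drops
    below ``config.tol_ss`` or ``t_max`` is reached; non-convergence is
    flagged on the result rather than raised.  ``timepoint`` mode integrates
    to ``t_end`` and returns the trajectory.
    """
    sys_ = build_rhs(model, params, perturbations, config)
    y = sys_.y_init.copy()

    if mode == "timepoint":
        if t_end is None:
            raise ModelError("timepoint mode requires t_end")
        if t_end == 0.0:
            return SimulationResult(
                node_ids=sys_.node_ids,
                activities=y,
                converged=True,
                t_end=0.0,
                trajectory=(np.array([0.0]), y[None, :].copy()),
                residual=sys_.residual(y),
            )
        t_eval = np.linspace(0.0, t_end, 101)
        sol = solve_ivp(
            sys_,
            (0.0, t_end),
            y,
            method=config.method,
            rtol=config.rtol,
            atol=config.atol,
            t_eval=t_eval,
        )
        if not sol.success:
            raise ModelError(f"ODE solver failed: {sol.message}")
        yT = np.clip(sol.y.T, 0.0, None)
        return SimulationResult(
            node_ids=sys_.node_ids,
            activities=yT[-1],
            converged=True,
            t_end=float(t_end),
            trajectory=(sol.t, yT),
            residual=sys_.residual(yT[-1]),
        )

    if mode != "steady_state":
        raise ModelError(f"unknown simulation mode {mode!r}")

    t_max = sys_.t_max if t_end is None else t_end
    res = sys_.residual(y)
    t = 0.0
    if res >= config.tol_ss and t_max > 0.0:
        scale = np.maximum(sys_.ymax, 1.0e-9)

        # Terminal event a factor below tol_ss so the returned state is
        # strictly inside the convergence region after the final clip.
        def settled(t_, y_):
            dy = sys_(t_, y_)
            return float(np.max(np.abs(dy) / scale)) - 0.1 * config.tol_ss

        settled.terminal = True
        settled.direction = -1
        sol = solve_ivp(
            sys_,
            (0.0, t_max),
            y,
            method=config.method,
            rtol=config.rtol,
            atol=config.atol,
            events=settled,
        )
        if not sol.success:
            raise ModelError(f"ODE solver failed: {sol.message}")
        y = np.clip(sol.y[:, -1], 0.0, np.maximum(sys_.ymax, 0.0))
        t = float(sol.t[-1])
        res = sys_.residual(y)
    return SimulationResult(
        node_ids=sys_.node_ids,
        activities=y,
        converged=bool(res < config.tol_ss),
        t_end=t,
        residual=res,
    )
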