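# Methods

## Model formulation

The engine integrates a logic-based ODE (LDE) system over a signed
interaction graph.  Node activities are normalized to `[0, Ymax]`
(dimensionless); time is measured in units of the node time constant `tau`
(default 1, uniform across nodes and overridable per node — whether distinct
time scales should separate signaling from transcriptional species is left
to the user, as the formalism is agnostic).  For node *i*

    dy_i/dt = (Ymax_i * F_i(y) - y_i) / tau_i

with `F_i` the noisy-OR over all reactions targeting *i*.  Reactant
activities are clamped to `[0, min(Ymax, 1)]` before entering the transfer
function so solver overshoot cannot propagate out-of-range arguments.

**Transfer function.**  The normalized Hill sigmoid
`f(x) = B x^n / (K^n + x^n)` with `B = (EC50^n - 1)/(2 EC50^n - 1)` and
`K^n = B - 1` satisfies `f(0)=0`, `f(1)=1`, `f(EC50)=0.5` by construction
and is singular only where `EC50^n = 0.5`; parameter sets within 1e-9 of
the singularity are rejected, and search/sampling bounds for `EC50`
(default `[0.2, 0.6]`) are checked against it up front.  `K^n` is kept in
product form so the branch `EC50^n > 0.5` (where `K` itself is not real but
the ratio is well-defined, monotone and normalized) works without complex
arithmetic.

**Gates.**  Within a reaction, reactant terms — `W_R * f(x)` for activators,
`1 - W_R * f(x)` for inhibitors — combine through a mean-normalized AND,
`prod(t_k) / mean(t)^(m-1)`, computed as `mean * prod(t_k/mean)` to avoid
underflow.  The mean normalization keeps wide gates (m > 3) on the same
order of magnitude as their inputs, so perturbations of a single input stay
visible at the output.  The inhibition form `1 - W_R f(x)` makes two
behaviors hold simultaneously: lowering an inhibitory weight *raises*
downstream activity, and `W_R = 0` returns a purely inhibited target to its
un-inhibited baseline.  The reaction weight is folded into each reactant
term (rather than multiplying the whole AND product) because that single
rule yields both stated `W_R = 0` behaviors for mixed-sign reactions.

A consequence worth stating explicitly: for a reaction with at least one
activating reactant, setting `W_R = 0` is exactly equivalent to physically
removing the reaction (the AND annihilates).  For a *pure-inhibition*
reaction the two differ by design — `W_R = 0` restores the baseline
(term 1) while removing the table row silences the production channel
(term absent).  The deletion scan therefore always uses `W_R = 0`, never
row removal.

**Perturbations.**  Stimulus raises an input reaction's weight from `W_i`
(resting, default 0) to `W_e` (default 1) or an explicit value; knockdown
sets `Ymax = 0`; overexpression pins the node at `Ymax`.  Overexpression is
implemented as an exact clamp (`dy = 0`, `y = Ymax`) by default, with a
config switch (`oex_clamp=False`) for the literal large-time-constant
variant (`Y0 = Ymax`, `tau = 1e9`); the two agree to solver tolerance and
the clamp avoids needless stiffness.

**Integration.**  `scipy.integrate.solve_ivp` with LSODA (configurable),
`rtol = 1e-6`, `atol = 1e-9`.  Steady state is declared when
`max_i |dy_i/dt| / max(Ymax_i, 1e-9) < tol_ss` (default 1e-6), detected by
a terminal event placed a factor of 10 inside the tolerance so the
returned state is strictly converged after final clipping; integration is
capped at `t_max = 40 * max(tau)`.  Non-convergence is flagged on the
result — validation excludes and counts such conditions instead of scoring
them, so oscillatory trial models (which arise naturally during crosstalk
screening when feedback edges are inserted) cannot silently bias a screen.

## Validation

Control/treatment pairs are derived from the record's data class
(input–output and input–intermediate: rest vs stimulus;
intermediate-inhibition: stimulus vs stimulus+knockdown;
intermediate-overexpression: rest vs overexpression, with the stimulus only
in the treated arm when the record carries one).  Changes are classified
relative to the control at a 1% threshold, interpreted as *relative* change;
when the control activity is below `1e-4 * Ymax` the absolute change in
percent of `Ymax` is used instead, since normalized baselines are often
exactly zero.  Observed "no change" records are scored like any others.
Semi-quantitative folds are guarded additively (`(t + 1e-3)/(c + 1e-3)`) and
mapped to seven categories (HL < 0.2, ML < 0.5, LL ≤ 0.99, NC ≤ 1.01,
LH ≤ 2, MH ≤ 5, HH > 5); matching is strict-category by default with an
optional lenient mode (same direction within one level), and each report
states its mode.  Aggregate percents are exact record-weighted means, so the
overall percent always reconciles with the per-class breakdown.

## Parameter estimation

The estimation objective — a validation percent — is piecewise constant, so
gradient solvers and shrinking simplices stall on its plateaus.  Both
estimation stages therefore use a seeded multi-start scatter (uniform in the
bounded box; `n_starts` defaults to 100) with each start refined by a
compass pattern search whose initial step is a quarter of each parameter's
range (large enough to hop between plateaus) and which halves the step when
no axial move improves the objective, stopping at 1% of the range or an
evaluation cap.  Ties between equal optima break toward the smallest
Euclidean distance from the original defaults, i.e. minimal revision.
Bounds default to `n ∈ [1, 10]`, `W_R ∈ [0, 1]`, `W_i ∈ [0, 0.5]`,
`W_e ∈ [0.5, 1]`, `EC50 ∈ [0.2, 0.6]`; points violating the
transfer-function singularity score `-inf` rather than erroring mid-search.
EC50 calibration weights every record equally:
`100 * (matches_qual + matches_semi) / (N_qual + N_semi)`.

## Sensitivity analysis

*Deletion scan*: per context, `W_R = 0` one intermediate reaction at a time;
reactions are categorized non-sensitive / direct (one affected context) /
shared (several).

*Morris screening*: factors (per-reaction `EC50` by default) are scaled to
the unit hypercube on `p = 8` levels with step `Delta = p/(2(p-1))`;
trajectories follow the standard randomized construction (random base on
the lower half-grid, random step directions and factor order).  From an
oversampled pool (default 300) the most spread-out subset (default 16) is
kept by greedy max–min selection under the aggregate inter-trajectory
point-distance (the Campolongo distance); the selection strategy sits
behind this one implementation, chosen because spread maximization is the
documented intent of uniformity-oriented samplers.  Elementary effects are
signed finite differences over `Delta`; `mu*` (mean |EE|) ranks factors,
`sigma` flags nonlinearity/interaction, and `|mu|/mu* >= 0.99` flags a
monotone effect (a numeric stand-in for a visual dichotomy).  Cost is
exactly `trajectories * (k+1)` evaluations.

*Sobol indices*: scrambled Sobol' base matrices `A`, `B` (seeded), Jansen
estimators `T_i = mean((f(A)-f(A_B^i))^2)/(2V)` and
`S_i = 1 - mean((f(B)-f(A_B^i))^2)/(2V)`, second-order indices from
closed-pair hybrid matrices (`S_ij = S^c_ij - S_i - S_j`), and 95%
percentile bootstrap CIs over the `N` sample rows (default 2,000
replicates; production-scale replicate counts are reachable by argument).
The pair synergy score is `S_ij / ((T_i - S_i) + (T_j - S_j))`, reported as
zero when the higher-order denominator is below 1% of variance (below that
it is Monte-Carlo noise).  A zero-variance objective raises instead of
returning undefined indices.  Two objectives are provided: the context
validation percent (default) and the mean activity of designated output
nodes, which responds continuously and is the right choice on small
networks where direction flips are rare.

## Crosstalk screening

OR candidates are one new activating single-reactant reaction per ordered
node pair — `N^2` including self-loops (autoregulation); inhibiting edges
are available behind a flag that doubles the space.  AND candidates attach
one node as an extra activating reactant to each intermediate reaction
(`N * R_int`).  New edges inherit the default reaction parameters, keeping
the screen parameter-free.  Each candidate is scored on a cloned model —
the input model is never mutated — by `delta = 100*(corrected - broken)/N`;
ranking is delta, then corrected, then lexicographic.  Candidates
duplicating an existing edge are flagged; a duplicate AND insertion is a
no-op (the reactant is already in the gate), so its delta is zero.  Only
single additions are screened; sequential greedy revision is supported by
applying a candidate and re-screening.

## Synthetic data

The generators serve two distinct purposes.  Toy topologies (cascade,
branch, feedback, and a two-input crosstalk demo with an AND gate and an
inhibiting edge) back the oracle tests: records are labelled by the model's
own classified predictions under known "true" parameters, using the same 1%
threshold machinery as validation, so zero-noise records validate at
exactly 100% and label noise lowers the percent by exactly the realized
flip fraction.  The crosstalk recovery case simulates records from the full
demo network — including a co-stimulation context that engages the AND gate
— then withholds the gate's second input, guaranteeing by construction that
exactly one single-edge addition restores full agreement.

Separately, a dimension-matched random acyclic network (106 nodes, 191
reactions, 17 receptor inputs — the published dimensions of the curated
hypertrophy network) and curated-shape record tables (450 qualitative
records, 75 per studied context; 100 semi-quantitative ISO-context records)
exercise parsing, counting and enumeration identities at full scale.  These
stand-ins share only their *dimensions* with the real curated inputs: their
wiring and labels are random, so passing tests demonstrate structural and
bookkeeping correctness, not biological agreement.  What the synthetic data
cannot show: the generators produce self-consistent labels (plus optional
symmetric label noise), whereas real curated data carry systematic
context-dependent disagreements, inter-lab variability and literature
curation error; absolute validation percents on real tables will therefore
behave differently even though every mechanism exercised here is identical.

## Problem sizes

Tests and the acceptance script run desk-scale configurations chosen to
keep the full suite in minutes: toy networks of 5–8 nodes, 8–16 records per
validation, 4–8 estimation starts with ~50 objective evaluations each,
Morris with 4 trajectories on ≤ 20 factors, Sobol at N = 8192 on the
three-factor Ishigami benchmark, and relaxed solver tolerances
(`tol_ss = 1e-5`, `rtol = 1e-5`, steady-state error ~1e-6 — three orders of
magnitude below the 1% classification threshold) where many simulations are
batched.  Production-scale settings (100 starts, 16 trajectories from an
oversample of 300, N up to 1e5, 1e5 bootstrap replicates) are plain
arguments.

## Known limitations

* The pipeline scores steady states (or a fixed time point); transient
  dynamics are simulated but never fitted.
* One default parameter set serves all reactions except where overridden;
  full per-reaction parameterization is out of scope.
* The crosstalk screen adds one edge at a time, so synergistic pairs of
  missing edges can only be found greedily (apply, then re-screen).
* Validation percents carry no statistical uncertainty; they are exact
  fractions of a fixed record set.
* The Morris trajectory-selection criterion and the second-order pair
  construction are reasonable canonical choices among several in the
  literature; both are recorded in result metadata and swappable.
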