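import numpy as np
import pytest

from classed.fixtures import RecordGenSpec, ToySpec, make_records, make_toy_network
from classed.model import ModelError, ParameterSet
from classed.sensitivity import (
    ObjectiveSpec,
    convergence_check,
    deletion_scan,
    morris_screen,
    select_important,
    sobol_analysis,
)
from classed.validation import validate


def ishigami(u, a=7.0, b=0.1):
    x = -np.pi + 2.0 * np.pi * np.asarray(u, float)
    return float(np.sin(x[0]) + a * np.sin(x[1]) ** 2 + b * x[2] ** 4 * np.sin(x[0]))


def ishigami_analytic(a=7.0, b=0.1):
    """Closed-form Sobol indices of the Ishigami function."""
    V = a**2 / 8 + b * np.pi**4 / 5 + b**2 * np.pi**8 / 18 + 0.5
    S1 = 0.5 * (1 + b * np.pi**4 / 5) ** 2 / V
    S2 = a**2 / 8 / V
    T3 = 8 * b**2 * np.pi**8 / 225 / V
    T1 = S1 + T3  # the x1-x3 interaction is the only one
    return {"V": V, "S1": S1, "S2": S2, "S3": 0.0, "T1": T1, "T3": T3}


class TestDeletionScan:
    def test_unreachable_reaction_has_zero_delta(self, demo, params):
        # records measure only C (downstream of A alone); r2/r4/r5/r6 cannot
        # affect it, so their deletion deltas vanish
        from classed.model import ExperimentRecord, Perturbation

        recs = [
            ExperimentRecord(
                "r1", "S1", "InputIntermediate",
                (Perturbation("stimulus", "S1"),), "C", "increase",
            )
        ]
        scan = deletion_scan(demo, params, {"S1": recs})
        for rid in ("r2", "r4", "r5", "r6"):
            assert scan.deltas[rid]["S1"] == 0.0
        assert scan.category("r2") == "non_sensitive"
        # the direct S1 -> A -> C path is load-bearing
        assert scan.deltas["r1"]["S1"] < 0
        assert scan.category("r1") == "direct"

    def test_cascade_deletion_flips_all_increases(self, params):
        model = make_toy_network(ToySpec("cascade", 4, seed=0))
        recs = [
            r
            for r in make_records(
                RecordGenSpec(model, params, ("N1",), n_records=2, seed=0)
            )
            # stimulus-only records: deletion of the first step turns every
            # observed increase into a predicted nochange, and nothing else
            if r.data_class in ("InputOutput", "InputIntermediate")
        ]
        increase_share = sum(r.observed == "increase" for r in recs) / len(recs)
        assert increase_share > 0
        scan = deletion_scan(model, params, {"N1": recs})
        assert scan.deltas["r1"]["N1"] == pytest.approx(-100.0 * increase_share)

    def test_matches_physical_removal_for_activating_reactions(self, demo, params):
        recs = make_records(
            RecordGenSpec(demo, params, ("S1", "S2"), n_records=2, seed=2)
        )
        scan = deletion_scan(demo, params, {"all": recs})
        removed = demo.with_reactions(r for r in demo.reactions if r.id != "r3")
        phys = validate(removed, params, recs).validation_percent
        base = scan.baselines["all"]
        assert scan.deltas["r3"]["all"] == pytest.approx(phys - base)


class TestMorris:
    def test_constant_objective(self):
        obj = ObjectiveSpec.from_function(lambda u: 1.0, ["a", "b", "c"])
        res = morris_screen(obj, trajectories=4, oversample=20, seed=0)
        assert np.all(res.mu_star == 0) and np.all(res.sigma == 0)

    def test_linear_objective_analytic_effects(self):
        obj = ObjectiveSpec.from_function(
            lambda u: 3.0 * u[0], [f"f{i}" for i in range(20)]
        )
        res = morris_screen(obj, levels=8, trajectories=4, oversample=50, seed=2)
        assert res.mu_star[0] == pytest.approx(3.0)
        assert res.mu[0] == pytest.approx(3.0)  # monotone: mu == mu*
        assert res.sigma[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(res.mu_star[1:] == 0.0)
        assert res.monotonic()[0]

    def test_cost_accounting(self):
        k = 7
        obj = ObjectiveSpec.from_function(lambda u: float(u.sum()), list("abcdefg"))
        res = morris_screen(obj, trajectories=5, oversample=30, seed=1)
        assert res.evaluations == 5 * (k + 1)

    def test_mu_star_dominates_mu(self):
        obj = ObjectiveSpec.from_function(
            lambda u: float(np.sin(6 * u[0]) + u[1] ** 2), ["a", "b"]
        )
        res = morris_screen(obj, trajectories=8, oversample=40, seed=3)
        assert np.all(res.mu_star >= np.abs(res.mu) - 1e-12)

    def test_select_important_nesting_and_ranking(self):
        obj = ObjectiveSpec.from_function(
            lambda u: 3.0 * u[0] + 1.0 * u[1], ["a", "b", "c"]
        )
        res = morris_screen(obj, trajectories=4, oversample=20, seed=4)
        assert select_important(res, 2.0) == ["a"]
        assert select_important(res, 0.5) == ["a", "b"]
        assert set(select_important(res, 2.0)) <= set(select_important(res, 0.5))
        assert select_important(res, 10.0) == []

    def test_invalid_configs(self):
        obj = ObjectiveSpec.from_function(lambda u: 0.0, ["a"])
        with pytest.raises(ModelError):
            morris_screen(obj, levels=7)
        with pytest.raises(ModelError):
            morris_screen(obj, trajectories=10, oversample=5)


class TestSobol:
    def test_single_factor_owns_all_variance(self):
        obj = ObjectiveSpec.from_function(lambda u: float(u[0]), ["x"])
        res = sobol_analysis(obj, N=512, seed=0, bootstrap_reps=200, pairs=False)
        assert res.S[0] == pytest.approx(1.0, abs=0.05)
        assert res.T[0] == pytest.approx(1.0, abs=0.05)

    def test_additive_function_has_no_interaction(self):
        obj = ObjectiveSpec.from_function(
            lambda u: float(u[0] + u[1]), ["x1", "x2"]
        )
        res = sobol_analysis(obj, N=1024, seed=1, bootstrap_reps=300)
        assert res.S2[0] == pytest.approx(0.0, abs=0.05)
        assert res.synergy[0] == pytest.approx(0.0, abs=0.1)
        lo, hi = res.S2_ci[0]
        assert lo <= 0.0 <= hi or abs(res.S2[0]) < 0.05

    def test_ishigami_within_bootstrap_ci(self):
        truth = ishigami_analytic()
        obj = ObjectiveSpec.from_function(ishigami, ["x1", "x2", "x3"])
        res = sobol_analysis(obj, N=2048, seed=2, bootstrap_reps=400)
        for est, ci, key in [
            (res.S[0], res.S_ci[0], "S1"),
            (res.S[1], res.S_ci[1], "S2"),
            (res.S[2], res.S_ci[2], "S3"),
            (res.T[2], res.T_ci[2], "T3"),
        ]:
            lo, hi = ci
            slack = 0.02  # finite-N bias allowance around the percentile CI
            assert lo - slack <= truth[key] <= hi + slack, key
        # x1-x3 carries the only interaction
        pair_13 = res.pairs.index(("x1", "x3"))
        assert res.S2[pair_13] == pytest.approx(truth["T3"], abs=0.08)

    def test_total_bounds_main(self):
        obj = ObjectiveSpec.from_function(ishigami, ["x1", "x2", "x3"])
        res = sobol_analysis(obj, N=1024, seed=3, bootstrap_reps=100, pairs=False)
        assert np.all(res.T >= res.S - 0.05)

    def test_zero_variance_rejected(self):
        obj = ObjectiveSpec.from_function(lambda u: 42.0, ["x"])
        with pytest.raises(ModelError, match="variance"):
            sobol_analysis(obj, N=128, seed=0, bootstrap_reps=10, pairs=False)

    def test_evaluation_accounting(self):
        obj = ObjectiveSpec.from_function(lambda u: float(u[0] - u[1]), ["a", "b"])
        res = sobol_analysis(obj, N=128, seed=5, bootstrap_reps=10, pairs=True)
        # N*(k+2) base/hybrid evaluations plus N per pair matrix
        assert res.evaluations == 128 * (2 + 2) + 128 * 1


class TestConvergence:
    def test_linear_objective_converges_immediately(self):
        make = lambda: ObjectiveSpec.from_function(
            lambda u: float(u[0]), ["x"]
        )
        out = convergence_check(make, [128, 256, 512], seed=0)
        assert out["converged"]
        assert all(d < 0.1 for d in out["drift"])

    def test_ishigami_drift_shrinks(self):
        make = lambda: ObjectiveSpec.from_function(ishigami, ["x1", "x2", "x3"])
        out = convergence_check(make, [256, 1024, 4096], seed=1, tolerance=0.05)
        assert out["drift"][-1] <= out["drift"][0] + 0.05
        assert out["converged"]


class TestPipelineSmoke:
    def test_single_driving_reaction_ranks_first(self):
        """When only one screened reaction lies on the path to the output,
        that reaction tops both the Morris and the Sobol ranking."""
        from classed.model import Perturbation

        model = make_toy_network(ToySpec("crosstalk_demo"))
        # sub-maximal stimulation of S1 alone: B stays silent, so of the
        # screened factors only r6 (E => F) can move the output F
        base = ParameterSet().with_defaults(W_e=0.7)
        pert = [Perturbation("stimulus", "S1")]
        factors = ["r2", "r4", "r6"]

        def make_obj():
            return ObjectiveSpec.for_output_activity(
                model, base, pert, outputs=["F"], factors=factors,
                bounds=(0.3, 0.6),
            )

        morris = morris_screen(make_obj(), trajectories=4, oversample=12, seed=0)
        ranked = select_important(morris, 1e-9)
        assert ranked == ["r6"]
        sob = sobol_analysis(make_obj(), N=64, seed=0, bootstrap_reps=50,
                             pairs=False)
        assert sob.ranked_total()[0][0] == "r6"
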