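import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from classed.fixtures import ToySpec, make_toy_network
from classed.lde_engine import (
    SimulationConfig,
    activator_term,
    and_gate,
    build_rhs,
    hill_activation,
    hill_constants,
    inhibitor_term,
    or_gate,
    simulate,
)
from classed.model import (
    ACTIVATING,
    INHIBITING,
    ModelError,
    NetworkModel,
    NodeSpec,
    ParameterSet,
    Perturbation,
    ReactionSpec,
)

# a (n, EC50) grid that stays clear of the EC50**n = 0.5 singularity
VALID_PARAMS = [(1.4, 0.5), (2.0, 0.3), (1.0, 0.4), (4.0, 0.6), (1.4, 0.25)]


class TestTransferFunction:
    @pytest.mark.parametrize("n,ec50", VALID_PARAMS)
    def test_normalization_constraints(self, n, ec50):
        assert hill_activation(0.0, n, ec50) == pytest.approx(0.0, abs=1e-12)
        assert hill_activation(1.0, n, ec50) == pytest.approx(1.0, rel=1e-12)
        assert hill_activation(ec50, n, ec50) == pytest.approx(0.5, rel=1e-12)

    @pytest.mark.parametrize("n,ec50", VALID_PARAMS)
    def test_monotone_and_bounded(self, n, ec50):
        x = np.linspace(0, 1, 201)
        f = hill_activation(x, n, ec50)
        assert np.all(np.diff(f) >= -1e-12)
        assert f.min() >= 0 and f.max() <= 1 + 1e-12

    def test_singularity_rejected(self):
        with pytest.raises(ModelError, match="singular"):
            hill_constants(1.0, 0.5)  # EC50**n exactly 0.5

    def test_weight_terms(self):
        assert activator_term(1.0, 1.0, 1.4, 0.5) == pytest.approx(1.0)
        assert activator_term(0.7, 0.0, 1.4, 0.5) == 0.0
        assert activator_term(0.5, 0.5, 1.4, 0.5) == pytest.approx(0.25)
        assert inhibitor_term(0.9, 0.0, 1.4, 0.5) == 1.0  # deleted inhibition
        assert inhibitor_term(0.0, 1.0, 1.4, 0.5) == pytest.approx(1.0)
        assert inhibitor_term(1.0, 1.0, 1.4, 0.5) == pytest.approx(0.0)

    def test_lower_inhibition_weight_raises_term(self):
        weights = np.linspace(0, 1, 11)
        vals = [inhibitor_term(0.8, w, 1.4, 0.5) for w in weights]
        assert np.all(np.diff(vals) < 0)


class TestGates:
    @given(
        x=st.floats(0, 1),
        m=st.integers(1, 6),
    )
    @settings(max_examples=50, deadline=None)
    def test_and_of_equal_inputs_is_identity(self, x, m):
        assert and_gate([x] * m) == pytest.approx(x, abs=1e-9)

    def test_and_examples(self):
        assert and_gate([0.4, 0.8]) == pytest.approx(0.32 / 0.6)
        assert and_gate([0.0, 0.9]) == 0.0
        assert and_gate([0.3]) == pytest.approx(0.3)
        with pytest.raises(ModelError):
            and_gate([])

    @given(terms=st.lists(st.floats(0, 1), min_size=0, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_or_laws(self, terms):
        v = or_gate(terms)
        assert -1e-12 <= v <= 1 + 1e-12
        assert or_gate([*terms, 1.0]) == pytest.approx(1.0)
        assert or_gate([*terms, 0.0]) == pytest.approx(v, abs=1e-9)
        if len(terms) == 1:
            assert v == pytest.approx(terms[0], abs=1e-12)

    def test_or_closed_form(self):
        assert or_gate([0.5, 0.5]) == pytest.approx(0.75)
        assert or_gate([]) == 0.0


class TestBuildRhs:
    def test_two_node_chain_fixed_point(self, params):
        m = make_toy_network(ToySpec("cascade", 2, seed=0))
        for w in (0.25, 0.6, 1.0):
            res = simulate(m, params, [Perturbation("stimulus", "N1", w)])
            assert res.converged
            assert res.activity("N1") == pytest.approx(w, abs=1e-5)
            assert res.activity("N2") == pytest.approx(
                hill_activation(w, 1.4, 0.5), abs=1e-5
            )

    def test_silent_network_zero_fixed_point(self, cascade5, params):
        sys_ = build_rhs(cascade5, params)  # W_i = 0, Y0 = 0
        assert np.allclose(sys_(0.0, np.zeros(cascade5.n_nodes)), 0.0)

    def test_overexpression_pins_node(self, cascade5, params):
        res = simulate(cascade5, params, [Perturbation("overexpression", "N3")])
        assert res.activity("N3") == pytest.approx(1.0)
        traj = simulate(
            cascade5,
            params,
            [Perturbation("overexpression", "N3")],
            t_end=5.0,
            mode="timepoint",
        )
        idx = traj.node_ids.index("N3")
        assert np.allclose(traj.trajectory[1][:, idx], 1.0, atol=1e-6)

    def test_overexpression_literal_matches_clamp(self, cascade5, params):
        pert = [Perturbation("overexpression", "N2")]
        clamp = simulate(cascade5, params, pert)
        literal = simulate(
            cascade5, params, pert, config=SimulationConfig(oex_clamp=False)
        )
        assert np.allclose(clamp.activities, literal.activities, atol=1e-5)

    def test_knockdown_silences_node(self, cascade5, params):
        res = simulate(
            cascade5,
            params,
            [Perturbation("stimulus", "N1"), Perturbation("knockdown", "N3")],
        )
        assert res.activity("N3") == 0.0
        assert res.activity("N4") == pytest.approx(0.0, abs=1e-6)

    def test_missing_perturbation_target(self, cascade5, params):
        with pytest.raises(ModelError):
            simulate(cascade5, params, [Perturbation("knockdown", "ghost")])
        with pytest.raises(ModelError):
            # stimulus must hit an input reaction, not an intermediate node
            simulate(cascade5, params, [Perturbation("stimulus", "N3")])


class TestSimulate:
    def test_t_end_zero_returns_initial_state(self, cascade5, params):
        res = simulate(cascade5, params, t_end=0.0, mode="timepoint")
        assert np.allclose(res.activities, 0.0)
        assert res.t_end == 0.0

    def test_acyclic_steady_state_matches_fixed_point_oracle(self, params):
        from conftest import fixed_point_steady_state

        for seed in (3, 7):
            m = make_toy_network(
                ToySpec("cascade", 5, seed=seed, inhibitor_fraction=0.3)
            )
            pert = [Perturbation("stimulus", "N1", 0.8)]
            ode = simulate(m, params, pert)
            fp = fixed_point_steady_state(m, params, pert)
            assert ode.converged
            assert np.max(np.abs(ode.activities - fp)) < 1e-5

    def test_negative_feedback_matches_root_oracle(self, params):
        nodes = (NodeSpec("A"), NodeSpec("B"))
        reactions = (
            ReactionSpec("i", "A", is_input=True),
            ReactionSpec("ra", "B", reactants=(("A", ACTIVATING),)),
            ReactionSpec("rb", "A", reactants=(("B", INHIBITING),)),
        )
        m = NetworkModel(nodes, reactions)
        w = 0.6
        f = lambda x: hill_activation(x, 1.4, 0.5)
        # A = OR(w, 1 - f(B)), B = f(A) -> scalar root in A
        root = brentq(lambda a: 1 - (1 - w) * f(f(a)) - a, 0, 1)
        res = simulate(m, params, [Perturbation("stimulus", "A", w)])
        assert res.converged
        assert res.activity("A") == pytest.approx(root, abs=1e-5)
        assert res.activity("B") == pytest.approx(f(root), abs=1e-5)

    def test_boundedness_along_trajectory(self, params):
        m = make_toy_network(ToySpec("feedback", 5, seed=2))
        res = simulate(
            m,
            params,
            [Perturbation("stimulus", "N1")],
            t_end=30.0,
            mode="timepoint",
        )
        assert res.trajectory[1].min() >= -1e-6
        assert res.trajectory[1].max() <= 1.0 + 1e-6

    def test_monotonicity_in_input_weight(self, params):
        m = make_toy_network(ToySpec("branch", 7, seed=4))  # all activating
        acts = [
            simulate(m, params, [Perturbation("stimulus", "N1", w)]).activities
            for w in (0.2, 0.5, 0.9)
        ]
        assert np.all(acts[1] >= acts[0] - 1e-7)
        assert np.all(acts[2] >= acts[1] - 1e-7)

    def test_deletion_equals_zero_weight(self, demo, params):
        pert = [Perturbation("stimulus", "S1"), Perturbation("stimulus", "S2")]
        removed = demo.with_reactions(r for r in demo.reactions if r.id != "r5")
        zeroed = params.with_overrides({("r5", "W_R"): 0.0})
        a = simulate(removed, params, pert)
        b = simulate(demo, zeroed, pert)
        for nid in removed.node_ids:
            assert a.activity(nid) == pytest.approx(b.activity(nid), abs=1e-6)
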