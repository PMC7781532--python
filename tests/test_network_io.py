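import numpy as np
import pandas as pd
import pytest

from classed.fixtures import (
    RecordGenSpec,
    ToySpec,
    make_records,
    make_sized_network,
    make_survey_records,
    make_toy_network,
)
from classed.model import ACTIVATING, INHIBITING, ModelError, ParameterSet
from classed.network_io import (
    ParseError,
    parse_experiments,
    parse_network,
    parse_rule,
    write_experiments,
    write_network,
)


class TestParseRule:
    @pytest.mark.parametrize(
        "rule,reactants,target,is_input",
        [
            ("A => B", (("A", ACTIVATING),), "B", False),
            ("!A & B => C", (("A", INHIBITING), ("B", ACTIVATING)), "C", False),
            ("=> ISO", (), "ISO", True),
            ("  !X &  Y &  Z =>  W ", (("X", INHIBITING), ("Y", ACTIVATING),
                                       ("Z", ACTIVATING)), "W", False),
        ],
    )
    def test_examples(self, rule, reactants, target, is_input):
        spec = parse_rule(rule)
        assert spec.reactants == reactants
        assert spec.target == target
        assert spec.is_input is is_input

    @pytest.mark.parametrize(
        "bad", ["", "A =>", "=>", "A & => B", "A B => C", "A & A => B", "A"]
    )
    def test_malformed(self, bad):
        with pytest.raises(ParseError):
            parse_rule(bad, reaction_id="rX")


class TestNetworkTables:
    def test_toy_counts(self, tmp_path):
        (tmp_path / "species.csv").write_text("id\nA\nB\nC\n")
        (tmp_path / "reactions.csv").write_text(
            "id,rule\ni1,=> A\nr1,A => B\nr2,!B => C\n"
        )
        m = parse_network(tmp_path)
        assert (m.n_nodes, m.n_reactions, m.n_inputs) == (3, 3, 1)

    def test_undeclared_node_names_offender(self, tmp_path):
        (tmp_path / "species.csv").write_text("id\nA\n")
        (tmp_path / "reactions.csv").write_text("id,rule\nr1,Q => A\n")
        with pytest.raises(ParseError, match="Q"):
            parse_network(tmp_path)

    def test_missing_column(self, tmp_path):
        (tmp_path / "species.csv").write_text("id\nA\n")
        (tmp_path / "reactions.csv").write_text("id\nr1\n")
        with pytest.raises(ParseError, match="rule"):
            parse_network(tmp_path)

    @pytest.mark.parametrize(
        "spec",
        [
            ToySpec("cascade", 6, seed=2, inhibitor_fraction=0.4),
            ToySpec("branch", 7, seed=3),
            ToySpec("crosstalk_demo"),
        ],
        ids=["cascade", "branch", "crosstalk_demo"],
    )
    def test_round_trip_identity(self, tmp_path, spec):
        m = make_toy_network(spec)
        reparsed = parse_network(write_network(m, tmp_path / "m"))
        assert reparsed.node_ids == m.node_ids
        assert [r.rule for r in reparsed.reactions] == [r.rule for r in m.reactions]
        assert [r.id for r in reparsed.reactions] == [r.id for r in m.reactions]
        assert reparsed.n_inputs == m.n_inputs

    def test_parameter_columns_round_trip(self, tmp_path):
        (tmp_path / "species.csv").write_text(
            "id,role,Ymax,Y0,tau\nA,input,1.0,,2.0\nB,intermediate,0.8,0.1,\n"
        )
        (tmp_path / "reactions.csv").write_text(
            "id,rule,W_R,n,EC50\ni1,=> A,,,\nr1,A => B,0.5,2.0,0.4\n"
        )
        m = parse_network(tmp_path)
        assert m.node("A").tau == 2.0 and m.node("A").ymax == 1.0
        assert m.node("B").y0 == 0.1 and m.node("B").tau is None
        r = m.reaction("r1")
        assert (r.weight, r.n, r.ec50) == (0.5, 2.0, 0.4)
        again = parse_network(write_network(m, tmp_path / "again"))
        assert again.reaction("r1").ec50 == 0.4
        assert again.node("B").y0 == 0.1

    def test_row_order_independence(self, tmp_path):
        m = make_toy_network(ToySpec("branch", 7, seed=5))
        write_network(m, tmp_path / "m")
        for name in ("species.csv", "reactions.csv"):
            df = pd.read_csv(tmp_path / "m" / name)
            df.sample(frac=1, random_state=0).to_csv(
                tmp_path / "m" / name, index=False
            )
        shuffled = parse_network(tmp_path / "m")
        assert set(shuffled.node_ids) == set(m.node_ids)
        assert {r.rule for r in shuffled.reactions} == {r.rule for r in m.reactions}
        assert shuffled.n_inputs == m.n_inputs

    def test_empty_model_write_rejected(self, tmp_path):
        from classed.model import NetworkModel

        with pytest.raises(ModelError):
            write_network(NetworkModel((), ()), tmp_path / "empty")

    def test_sized_network_dimensions(self):
        m = make_sized_network(seed=0)
        assert (m.n_nodes, m.n_reactions, m.n_inputs) == (106, 191, 17)
        assert len(m.intermediate_reactions) == 174
        # every non-input node is someone's target
        targets = {r.target for r in m.reactions}
        assert all(n.id in targets for n in m.nodes)


class TestExperimentTables:
    def test_survey_counts_round_trip(self, tmp_path):
        model = make_sized_network(seed=1)
        qual, semi = make_survey_records(model, seed=1)
        write_experiments(qual, tmp_path / "qual.csv")
        write_experiments(semi, tmp_path / "semi.tsv")
        parsed = parse_experiments(tmp_path / "qual.csv")
        assert len(parsed) == 450
        by_ctx = {}
        for r in parsed:
            by_ctx[r.context] = by_ctx.get(r.context, 0) + 1
        for ctx in ("ISO", "PE", "AngII", "Stretch"):
            assert by_ctx[ctx] == 75
        semi_parsed = parse_experiments(tmp_path / "semi.tsv")
        assert len(semi_parsed) == 100
        assert all(r.is_semiquant for r in semi_parsed)
        assert all(r.context == "ISO" for r in semi_parsed)

    def test_generated_records_round_trip(self, tmp_path, cascade5, params):
        recs = make_records(
            RecordGenSpec(cascade5, params, ("N1",), n_records=2, seed=4)
        )
        write_experiments(recs, tmp_path / "r.csv")
        back = parse_experiments(tmp_path / "r.csv")
        assert [r.record_id for r in back] == [r.record_id for r in recs]
        assert [r.observed for r in back] == [r.observed for r in recs]
        assert [r.perturbations for r in back] == [r.perturbations for r in recs]

    def test_direction_vocabulary_suggestion(self, tmp_path):
        (tmp_path / "x.csv").write_text(
            "record_id,context,data_class,perturbations,measured_node,observed\n"
            "r1,ISO,InputOutput,stim:ISO,X,up\n"
        )
        with pytest.raises(ParseError, match="increase"):
            parse_experiments(tmp_path / "x.csv")

    def test_missing_perturbation_rejected(self, tmp_path):
        (tmp_path / "x.csv").write_text(
            "record_id,context,data_class,perturbations,measured_node,observed\n"
            "r1,ISO,InputOutput,,X,increase\n"
        )
        with pytest.raises(ParseError, match="no perturbation"):
            parse_experiments(tmp_path / "x.csv")

    def test_unknown_class_rejected(self, tmp_path):
        (tmp_path / "x.csv").write_text(
            "record_id,context,data_class,perturbations,measured_node,observed\n"
            "r1,ISO,Mystery,stim:ISO,X,increase\n"
        )
        with pytest.raises(ParseError, match="Mystery"):
            parse_experiments(tmp_path / "x.csv")
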