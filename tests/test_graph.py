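"""Node-graph construction rules, classification and validation."""

import numpy as np
import pytest

from odegraph import ModelGraph
from odegraph.errors import (
    ArityError,
    CycleError,
    DuplicateAssignerError,
    NameCollisionError,
    NodeKindError,
    NoInputPinError,
    NoOutputPinError,
    PinOccupiedError,
    UnknownNodeError,
)

from conftest import random_valid_graph


@pytest.fixture
def graph():
    return ModelGraph("test")


class TestAddTerm:
    def test_returns_fresh_id_and_no_links(self, graph):
        before = len(graph.nodes)
        tid = graph.add_term("S", 99.0)
        assert tid in graph.nodes
        assert len(graph.nodes) == before + 1
        assert graph.links == {}

    def test_empty_name_rejected(self, graph):
        with pytest.raises(NameCollisionError):
            graph.add_term("", 1.0)

    def test_duplicate_name_rejected(self, graph):
        graph.add_term("g", 1.0)
        with pytest.raises(NameCollisionError):
            graph.add_term("g", 2.0)


class TestAddExpression:
    def test_creates_empty_pins(self, graph):
        eid = graph.add_expression("*", "infection", 3)
        assert graph.node(eid).arity == 3
        assert graph.incoming(eid) == {}

    @pytest.mark.parametrize("op", ["+", "-", "*", "/"])
    def test_arithmetic_needs_two_operands(self, graph, op):
        with pytest.raises(ArityError):
            graph.add_expression(op, "x", 1)

    def test_extension_arity_mismatch(self, graph, listing2_file):
        from odegraph.extensions import load_extensions

        load_extensions([listing2_file], registry=graph.extensions)
        with pytest.raises(ArityError):
            graph.add_expression("pow", "p", 3)  # pow has arity 2
        eid = graph.add_expression("pow", "p", 2)
        assert graph.node(eid).operator == "pow"


class TestAddAssigner:
    def test_one_ode_per_variable(self, graph):
        i = graph.add_term("I", 1.0)
        graph.add_assigner(i)
        with pytest.raises(DuplicateAssignerError):
            graph.add_assigner(i)

    def test_target_must_be_term(self, graph):
        e = graph.add_expression("+", "x", 2)
        with pytest.raises(NodeKindError):
            graph.add_assigner(e)

    def test_default_name_follows_target(self, graph):
        i = graph.add_term("I", 1.0)
        a = graph.add_assigner(i)
        assert graph.node(a).name == "I ode"


class TestConnect:
    def test_term_to_expression(self, graph):
        s = graph.add_term("S", 1.0)
        e = graph.add_expression("*", "infection", 2)
        lid = graph.connect(s, e, 1)
        assert graph.links[lid].destination_pin == 1

    def test_into_term_forbidden(self, graph):
        s = graph.add_term("S", 1.0)
        t = graph.add_term("T", 1.0)
        with pytest.raises(NoInputPinError):
            graph.connect(s, t, 0)

    def test_out_of_assigner_forbidden(self, graph):
        s = graph.add_term("S", 1.0)
        a = graph.add_assigner(s)
        e = graph.add_expression("+", "x", 2)
        with pytest.raises(NoOutputPinError):
            graph.connect(a, e, 0)

    def test_occupied_pin_forbidden(self, graph):
        s = graph.add_term("S", 1.0)
        i = graph.add_term("I", 1.0)
        e = graph.add_expression("+", "x", 2)
        graph.connect(s, e, 0)
        with pytest.raises(PinOccupiedError):
            graph.connect(i, e, 0)

    def test_pin_out_of_range(self, graph):
        s = graph.add_term("S", 1.0)
        e = graph.add_expression("+", "x", 2)
        with pytest.raises(ArityError):
            graph.connect(s, e, 2)

    def test_cycle_rejected(self, graph):
        e1 = graph.add_expression("+", "a", 2)
        e2 = graph.add_expression("+", "b", 2)
        graph.connect(e1, e2, 0)
        with pytest.raises(CycleError):
            graph.connect(e2, e1, 0)

    def test_self_loop_rejected(self, graph):
        e = graph.add_expression("+", "a", 2)
        with pytest.raises(CycleError):
            graph.connect(e, e, 0)

    def test_unknown_node(self, graph):
        e = graph.add_expression("+", "a", 2)
        with pytest.raises(UnknownNodeError):
            graph.connect("zz9", e, 0)

    def test_fanout_from_one_output_allowed(self, graph):
        s = graph.add_term("S", 1.0)
        e = graph.add_expression("-", "x", 3)
        for pin in range(3):
            graph.connect(s, e, pin)
        assert len(graph.links) == 3


class TestClassifyTerms:
    def test_sir_partition(self, sir_graph):
        variables, constants = sir_graph.classify_terms()
        names = lambda ids: [sir_graph.node(i).name for i in ids]
        assert names(variables) == ["S", "I", "R"]
        assert names(constants) == ["b_d", "g"]

    def test_no_assigners_means_all_constants(self, graph):
        graph.add_term("a", 1.0)
        graph.add_term("b", 2.0)
        variables, constants = graph.classify_terms()
        assert variables == []
        assert len(constants) == 2

    def test_extended_sir_counts(self, extended_sir_graph):
        variables, constants = extended_sir_graph.classify_terms()
        assert len(variables) == 4
        assert len(constants) == 7


class TestValidate:
    def test_complete_fixture_is_clean(self, any_fixture_graph):
        assert any_fixture_graph.validate() == []

    def test_unconnected_pin_reported_per_pin(self, graph):
        s = graph.add_term("S", 1.0)
        e = graph.add_expression("*", "x", 3)
        graph.connect(s, e, 0)
        graph.connect(s, e, 1)
        graph.connect(e, graph.add_assigner(s), 0)
        codes = [v.code for v in graph.validate()]
        assert codes == ["unconnected-pin"]

    def test_empty_assigner(self, graph):
        s = graph.add_term("S", 1.0)
        graph.add_assigner(s)
        codes = [v.code for v in graph.validate()]
        assert codes == ["empty-assigner"]

    def test_zero_state_variables(self, graph):
        graph.add_term("a", 1.0)
        codes = [v.code for v in graph.validate()]
        assert "no-state-variables" in codes

    def test_non_finite_value(self, graph):
        s = graph.add_term("S", float("nan"))
        graph.connect(s, graph.add_assigner(s), 0)
        codes = [v.code for v in graph.validate()]
        assert codes == ["non-finite-value"]

    def test_dangling_extension_operator(self, graph):
        s = graph.add_term("S", 1.0)
        e = graph.add_expression("mystery", "m", 2)
        graph.connect(s, e, 0)
        graph.connect(s, e, 1)
        graph.connect(e, graph.add_assigner(s), 0)
        codes = [v.code for v in graph.validate()]
        assert codes == ["dangling-operator"]

    def test_orphan_term_is_a_warning_only(self, graph):
        s = graph.add_term("S", 1.0)
        graph.add_term("unused", 3.0)
        graph.connect(s, graph.add_assigner(s), 0)
        assert graph.validate() == []
        warnings = graph.validate(include_warnings=True)
        assert [v.code for v in warnings] == ["orphan-term"]


class TestRandomizedProperties:
    def test_connect_is_total_over_node_kind_pairs(self):
        """Every attempted connection either succeeds or raises one of the
        documented error classes — never anything else."""
        rng = np.random.default_rng(42)
        allowed = (NoInputPinError, NoOutputPinError, PinOccupiedError,
                   CycleError, ArityError)
        for _ in range(50):
            g = random_valid_graph(rng)
            ids = list(g.nodes)
            for _ in range(30):
                src, dst = rng.choice(ids, size=2)
                pin = int(rng.integers(0, 4))
                try:
                    g.connect(str(src), str(dst), pin)
                except allowed:
                    pass

    def test_acyclicity_preserved_by_construction(self):
        import networkx as nx

        rng = np.random.default_rng(7)
        for _ in range(30):
            g = random_valid_graph(rng)
            dg = nx.DiGraph()
            dg.add_nodes_from(g.nodes)
            dg.add_edges_from(
                (l.source, l.destination) for l in g.links.values())
            assert list(nx.topological_sort(dg))  # raises on a cycle

    def test_classification_partitions_terms(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            g = random_valid_graph(rng)
            variables, constants = g.classify_terms()
            assert len(variables) + len(constants) == sum(
                1 for _ in g.terms())
            assert not set(variables) & set(constants)

    def test_valid_graphs_simulate_without_structural_errors(self):
        """validate() == [] implies compile_rhs accepts the graph."""
        from odegraph.errors import SimulationError
        from odegraph.simulation import compile_rhs

        rng = np.random.default_rng(3)
        for _ in range(20):
            g = random_valid_graph(rng)
            assert g.validate() == []
            rhs = compile_rhs(g)  # structural acceptance is the property
            n_vars = len(g.classify_terms()[0])
            try:
                out = rhs(0.0, np.ones(n_vars))
            except SimulationError:
                continue  # numerical accident (random division by zero)
            assert out.shape == (n_vars,)
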