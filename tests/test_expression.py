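"""Expression-tree recovery, infix rendering and evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from odegraph.errors import (
    EvaluationError,
    IncompleteExpressionError,
    UnboundSymbolError,
)
from odegraph.expression import (
    Call,
    Leaf,
    build_expression_tree,
    evaluate,
    leaf_names,
    render_infix,
)
from odegraph import ModelGraph

from conftest import random_tree


def L(name):
    return Leaf(term_id=name, name=name)


class TestBuildTree:
    def test_sir_r_ode_is_g_times_i(self, sir_graph):
        assigner = next(a for a in sir_graph.assigners()
                        if sir_graph.node(a.target).name == "R")
        tree = build_expression_tree(sir_graph, assigner.id)
        assert render_infix(tree) == "g * I"

    def test_bare_term_assigner_gives_leaf(self):
        g = ModelGraph()
        x = g.add_term("X", 1.0)
        y = g.add_term("Y", 2.0)
        a = g.add_assigner(x)
        g.connect(y, a, 0)
        tree = build_expression_tree(g, a)
        assert tree == Leaf(term_id=y, name="Y")

    def test_children_follow_pin_order_not_link_order(self):
        g = ModelGraph()
        a = g.add_term("a", 1.0)
        b = g.add_term("b", 2.0)
        e = g.add_expression("/", "q", 2)
        g.connect(b, e, 1)  # later pin connected first
        g.connect(a, e, 0)
        assert render_infix(build_expression_tree(g, e)) == "a / b"

    def test_empty_pin_raises(self):
        g = ModelGraph()
        a = g.add_term("a", 1.0)
        e = g.add_expression("+", "q", 2)
        g.connect(a, e, 0)
        with pytest.raises(IncompleteExpressionError):
            build_expression_tree(g, e)


class TestRenderInfix:
    @pytest.mark.parametrize("tree, expected", [
        (Call("*", (L("b_d"), L("S"), L("I"))), "b_d * S * I"),
        (Call("-", (Call("*", (L("b_d"), L("S"), L("I"))),
                    Call("*", (L("g"), L("I"))))),
         "b_d * S * I - g * I"),
        (Call("*", (L("a"), Call("+", (L("b"), L("c"))))), "a * (b + c)"),
        (Call("+", (L("a"), L("b"), L("c"))), "a + b + c"),
        (Call("-", (L("a"), Call("+", (L("b"), L("c"))))), "a - (b + c)"),
        (Call("-", (Call("+", (L("a"), L("b"))), L("c"))), "a + b - c"),
        (Call("/", (Call("*", (L("a"), L("b"))), L("c"))), "a * b / c"),
        (Call("/", (L("a"), Call("*", (L("b"), L("c"))))), "a / (b * c)"),
        (Call("-", (L("a"), Call("-", (L("b"), L("c"))))), "a - (b - c)"),
    ])
    def test_precedence_and_spacing(self, tree, expected):
        assert render_infix(tree) == expected

    def test_rendering_is_deterministic(self):
        rng = np.random.default_rng(0)
        tree = random_tree(rng, ["a", "b", "c"])
        assert render_infix(tree) == render_infix(tree)


class TestEvaluate:
    def test_product(self):
        tree = Call("*", (L("b_d"), L("S"), L("I")))
        assert evaluate(tree, {"b_d": 1, "S": 2, "I": 3}) == 6

    def test_left_fold_division(self):
        tree = Call("/", (L("a"), L("b"), L("c")))
        assert evaluate(tree, {"a": 8, "b": 2, "c": 2}) == 2

    def test_left_fold_subtraction(self):
        tree = Call("-", (L("a"), L("b"), L("c")))
        assert evaluate(tree, {"a": 1, "b": 2, "c": 3}) == -4

    def test_division_by_zero_names_subexpression(self):
        tree = Call("/", (L("x"), L("y")))
        with pytest.raises(EvaluationError) as exc:
            evaluate(tree, {"x": 1.0, "y": 0.0})
        assert exc.value.expression_text == "x / y"

    def test_missing_binding(self):
        with pytest.raises(UnboundSymbolError):
            evaluate(L("q"), {"x": 1.0})

    def test_permutation_invariance_for_add_and_mul(self):
        rng = np.random.default_rng(5)
        bindings = {"a": 1.5, "b": -0.75, "c": 2.25}
        for op in "+*":
            tree = Call(op, (L("a"), L("b"), L("c")))
            perm = Call(op, (L("c"), L("a"), L("b")))
            assert evaluate(tree, bindings) == pytest.approx(
                evaluate(perm, bindings), rel=1e-15)

    @pytest.mark.parametrize("op", ["-", "/"])
    def test_order_sensitivity_for_sub_and_div(self, op):
        bindings = {"a": 7.0, "b": 2.0}
        tree = Call(op, (L("a"), L("b")))
        swapped = Call(op, (L("b"), L("a")))
        assert evaluate(tree, bindings) != evaluate(swapped, bindings)


@st.composite
def trees(draw, names=("a", "b", "c", "d")):
    return draw(st.recursive(
        st.sampled_from(names).map(L),
        lambda children: st.builds(
            Call,
            st.sampled_from(["+", "-", "*", "/"]),
            st.lists(children, min_size=2, max_size=4).map(tuple)),
        max_leaves=12))


class TestOracleEquivalence:
    """render_infix followed by an independent parser (the host Python
    parser via eval) recovers exactly the tree evaluator's value."""

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(trees(), st.integers(0, 2 ** 31 - 1))
    def test_eval_matches_python_parse_of_rendered_text(self, tree, seed):
        rng = np.random.default_rng(seed)
        bindings = {n: float(rng.uniform(0.5, 2.0))
                    for n in leaf_names(tree)}
        try:
            ours = evaluate(tree, bindings)
        except EvaluationError:
            return  # a random denominator hit exactly zero
        oracle = eval(render_infix(tree), {"__builtins__": {}}, bindings)
        assert ours == pytest.approx(oracle, rel=1e-12, abs=1e-300)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(trees())
    def test_rendered_text_is_unambiguous(self, tree):
        """Re-parsing the rendered text left-associatively yields a string
        that renders back to itself (fixed point)."""
        import ast

        text = render_infix(tree)
        rebuilt = _tree_from_ast(ast.parse(text, mode="eval").body)
        assert render_infix(rebuilt) == text


def _tree_from_ast(node):
    import ast

    ops = {ast.Add: "+", ast.Sub: "-", ast.Mult: "*", ast.Div: "/"}
    if isinstance(node, ast.Name):
        return L(node.id)
    assert isinstance(node, ast.BinOp)
    op = ops[type(node.op)]
    left = _tree_from_ast(node.left)
    right = _tree_from_ast(node.right)
    # fold same-op left chains back into n-ary calls
    if isinstance(left, Call) and left.operator == op:
        return Call(op, left.children + (right,))
    return Call(op, (left, right))
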