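"""Expression trees: recovery from the graph, rendering, evaluation.

The dataflow graph encodes each ODE right-hand side implicitly in its
links; this module recovers the explicit recursive expression, renders it
as infix text, and evaluates it numerically.

N-ary arithmetic nodes evaluate as a left-to-right fold in pin order:
``((p0 op p1) op p2) ...``, so ``-`` and ``/`` over three pins mean
``p0 - p1 - p2`` and ``p0 / p1 / p2``. Rendering parenthesizes a child
when its operator binds less tightly than its parent's, or equally
tightly in a non-first position; the rendered text therefore parses back
(left-associatively) to exactly the same tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

from .errors import (
    EvaluationError,
    ExtensionResolutionError,
    IncompleteExpressionError,
    UnboundSymbolError,
)
from .graph import (
    ARITHMETIC_OPERATORS,
    AssignerNode,
    ExpressionNode,
    ModelGraph,
    TermNode,
)

#: operator precedence; leaves and function calls bind tightest
_PRECEDENCE = {"+": 1, "-": 1, "*": 2, "/": 2}
_CALL_PRECEDENCE = 3


@dataclass(frozen=True)
class Leaf:
    """A reference to a Term node."""

    term_id: str
    name: str


@dataclass(frozen=True)
class Call:
    """An operator applied to ordered children.

    ``operator`` is an arithmetic symbol or a loaded ExtensionFunction.
    """

    operator: object
    children: tuple

    @property
    def is_arithmetic(self) -> bool:
        return self.operator in ARITHMETIC_OPERATORS


ExpressionTree = Union[Leaf, Call]


def build_expression_tree(graph: ModelGraph, root: str) -> ExpressionTree:
    """Recover the expression tree rooted at an Expression or Assigner node.

    Children are ordered by destination-pin index; for an Assigner root the
    tree of its single input is returned. Extension operators are resolved
    against ``graph.extensions``. An unconnected pin anywhere in the
    reachable subgraph raises IncompleteExpressionError.
    """
    node = graph.node(root)

    if isinstance(node, TermNode):
        return Leaf(node.id, node.name)

    if isinstance(node, AssignerNode):
        incoming = graph.incoming(node.id)
        if 0 not in incoming:
            raise IncompleteExpressionError(
                f"assigner {node.name!r} has no input expression")
        return build_expression_tree(graph, incoming[0].source)

    assert isinstance(node, ExpressionNode)
    incoming = graph.incoming(node.id)
    children = []
    for pin in range(node.arity):
        if pin not in incoming:
            raise IncompleteExpressionError(
                f"expression {node.name!r} input pin {pin} is unconnected")
        children.append(build_expression_tree(graph, incoming[pin].source))
    if node.is_arithmetic:
        operator: object = node.operator
    else:
        try:
            operator = graph.extensions[node.operator]
        except KeyError:
            raise ExtensionResolutionError(
                f"extension function {node.operator!r} used by "
                f"{node.name!r} is not loaded") from None
    return Call(operator, tuple(children))


def _precedence(tree: ExpressionTree) -> int:
    if isinstance(tree, Leaf) or not tree.is_arithmetic:
        return _CALL_PRECEDENCE
    return _PRECEDENCE[tree.operator]


def render_infix(tree: ExpressionTree, *, code: bool = False,
                 names: Optional[Mapping[str, str]] = None) -> str:
    """Render a tree as deterministic infix text.

    Operands are joined by `` + ``, `` - ``, `` * ``, `` / `` in pin order
    with minimal, precedence-driven parentheses. Extension calls render via
    their display format when one is declared — unless ``code`` is set, in
    which case call notation ``name(a, b)`` is always used so the text is
    valid source for code generation. ``names`` optionally remaps leaf names
    (codegen passes sanitized identifiers).
    """
    if isinstance(tree, Leaf):
        return names[tree.name] if names else tree.name

    parts = [render_infix(c, code=code, names=names) for c in tree.children]

    if not tree.is_arithmetic:
        from .extensions import render_extension_call

        if code:
            return f"{tree.operator.name}({', '.join(parts)})"
        return render_extension_call(tree.operator, parts)

    prec = _PRECEDENCE[tree.operator]
    rendered = []
    for i, (child, text) in enumerate(zip(tree.children, parts)):
        child_prec = _precedence(child)
        if child_prec < prec or (child_prec == prec and i > 0):
            text = f"({text})"
        rendered.append(text)
    return f" {tree.operator} ".join(rendered)


def evaluate(tree: ExpressionTree,
             bindings: Mapping[str, float]) -> float:
    """Numerically evaluate a tree under name→value bindings.

    Arithmetic nodes fold left-to-right; extension nodes call their loaded
    function. Division by zero raises EvaluationError carrying the rendered
    text of the offending subexpression.
    """
    if isinstance(tree, Leaf):
        try:
            return bindings[tree.name]
        except KeyError:
            raise UnboundSymbolError(
                f"no value bound for term {tree.name!r}") from None

    values = [evaluate(c, bindings) for c in tree.children]

    if not tree.is_arithmetic:
        return tree.operator.callable(*values)

    op = tree.operator
    acc = values[0]
    for v in values[1:]:
        if op == "+":
            acc = acc + v
        elif op == "-":
            acc = acc - v
        elif op == "*":
            acc = acc * v
        else:
            if v == 0:
                raise EvaluationError(
                    f"division by zero in {render_infix(tree)!r}",
                    expression_text=render_infix(tree))
            acc = acc / v
    return acc


def leaf_names(tree: ExpressionTree) -> list[str]:
    """All distinct leaf names in left-to-right order."""
    out: list[str] = []

    def walk(t: ExpressionTree) -> None:
        if isinstance(t, Leaf):
            if t.name not in out:
                out.append(t.name)
        else:
            for c in t.children:
                walk(c)

    walk(tree)
    return out
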