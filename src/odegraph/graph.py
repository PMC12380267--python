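"""Typed node-graph model for ODE systems.

A model is a directed acyclic dataflow graph over three node kinds:

* **Term** — a named quantity (state variable, parameter or constant) with
  one output pin and no inputs.
* **Expression** — one operator (``+ - * /`` or a user extension function)
  over N ordered input pins, one output pin.
* **Assigner** — a terminal node binding the expression arriving on its
  single input pin as the right-hand side of one term's ODE.

Links always go from an output pin to an input pin; each input pin holds at
most one link, while output pins may fan out. A term is a *state variable*
iff some assigner targets it (its value is then the initial condition);
every other term is a constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Optional, Union

from .errors import (
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

ARITHMETIC_OPERATORS = ("+", "-", "*", "/")

#: severity levels used by :meth:`ModelGraph.validate`
ERROR = "error"
WARNING = "warning"


@dataclass
class TermNode:
    """A named quantity: state variable (if assigned an ODE) or constant."""

    id: str
    name: str
    value: float
    position: Optional[tuple[float, float]] = None  # opaque GUI metadata

    kind = "term"


@dataclass
class ExpressionNode:
    """One operator applied to ``arity`` ordered inputs."""

    id: str
    name: str
    operator: str  # "+", "-", "*", "/" or an extension function name
    arity: int
    position: Optional[tuple[float, float]] = None

    kind = "expression"

    @property
    def is_arithmetic(self) -> bool:
        return self.operator in ARITHMETIC_OPERATORS


@dataclass
class AssignerNode:
    """Terminal node: its input expression becomes d(target)/dt."""

    id: str
    name: str
    target: str  # id of the TermNode whose ODE this defines
    position: Optional[tuple[float, float]] = None

    kind = "assigner"


Node = Union[TermNode, ExpressionNode, AssignerNode]


@dataclass
class Link:
    """A directed connection from an output pin to one input pin."""

    id: str
    source: str
    destination: str
    destination_pin: int


@dataclass
class Violation:
    """One validation finding. ``severity`` is ``"error"`` or ``"warning"``."""

    code: str
    severity: str
    message: str
    node_id: Optional[str] = None

    def __str__(self) -> str:
        where = f" [{self.node_id}]" if self.node_id else ""
        return f"{self.code}{where}: {self.message}"


class ModelGraph:
    """The complete node-and-link model plus simulation settings.

    Nodes and links keep insertion order; that order is the canonical order
    for classification, serialization and code generation.
    """

    def __init__(self, name: str = "model", notes: str = ""):
        self.name = name
        self.notes = notes
        self.nodes: dict[str, Node] = {}
        self.links: dict[str, Link] = {}
        self.extension_refs: list[str] = []
        #: registry of loaded ExtensionFunction objects, keyed by name
        #: (populated by extensions.resolve_model_extensions or manually)
        self.extensions: dict = {}
        # sim_config assigned lazily to avoid an import cycle with simulation
        from .simulation import SimulationConfig

        self.sim_config = SimulationConfig()
        self._node_counter = 0
        self._link_counter = 0

    # -- id allocation ---------------------------------------------------

    def _new_node_id(self, prefix: str) -> str:
        self._node_counter += 1
        return f"{prefix}{self._node_counter}"

    def _new_link_id(self) -> str:
        self._link_counter += 1
        return f"l{self._link_counter}"

    # -- lookups ---------------------------------------------------------

    def node(self, node_id: str) -> Node:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise UnknownNodeError(f"no node with id {node_id!r}") from None

    def terms(self) -> Iterator[TermNode]:
        return (n for n in self.nodes.values() if isinstance(n, TermNode))

    def expressions(self) -> Iterator[ExpressionNode]:
        return (n for n in self.nodes.values() if isinstance(n, ExpressionNode))

    def assigners(self) -> Iterator[AssignerNode]:
        return (n for n in self.nodes.values() if isinstance(n, AssignerNode))

    def term_by_name(self, name: str) -> TermNode:
        for t in self.terms():
            if t.name == name:
                return t
        raise UnknownNodeError(f"no term named {name!r}")

    def incoming(self, node_id: str) -> dict[int, Link]:
        """Links arriving at ``node_id``, keyed by destination pin index."""
        return {
            l.destination_pin: l
            for l in self.links.values()
            if l.destination == node_id
        }

    def _input_arity(self, node: Node) -> int:
        if isinstance(node, ExpressionNode):
            return node.arity
        if isinstance(node, AssignerNode):
            return 1
        return 0

    # -- construction ----------------------------------------------------

    def add_term(self, name: str, value: float,
                 position: Optional[tuple[float, float]] = None) -> str:
        """Create a Term node and return its id.

        Term names must be unique: they become identifiers in generated code.
        """
        if not name:
            raise NameCollisionError("term name must be non-empty")
        if any(t.name == name for t in self.terms()):
            raise NameCollisionError(f"a term named {name!r} already exists")
        node = TermNode(self._new_node_id("t"), name, float(value), position)
        self.nodes[node.id] = node
        return node.id

    def add_expression(self, operator, name: str, arity: int,
                       position: Optional[tuple[float, float]] = None) -> str:
        """Create an Expression node with ``arity`` empty input pins.

        ``operator`` is one of ``+ - * /``, an extension function name, or an
        ExtensionFunction object (which is then registered on the graph).
        Arithmetic operators need at least two operands; an extension
        operator's arity must equal the function's declared parameter count.
        """
        # accept a loaded ExtensionFunction directly
        if hasattr(operator, "arity") and hasattr(operator, "name"):
            func = operator
            self.extensions.setdefault(func.name, func)
            operator = func.name
        if not isinstance(operator, str) or not operator:
            raise NodeKindError(f"invalid operator: {operator!r}")
        if arity < 1:
            raise ArityError("an expression needs at least one input pin")
        if operator in ARITHMETIC_OPERATORS:
            if arity < 2:
                raise ArityError(
                    f"arithmetic operator {operator!r} needs at least two "
                    f"operands, got arity {arity}"
                )
        elif operator in self.extensions:
            declared = self.extensions[operator].arity
            if arity != declared:
                raise ArityError(
                    f"extension {operator!r} has arity {declared}, "
                    f"requested {arity}"
                )
        # unknown extension operators are deferred to validate(), which
        # reports them as dangling once extension files are resolved
        node = ExpressionNode(self._new_node_id("e"), name, operator,
                              int(arity), position)
        self.nodes[node.id] = node
        return node.id

    def add_assigner(self, target: str, name: str = "",
                     position: Optional[tuple[float, float]] = None) -> str:
        """Create an Assigner for the term ``target`` and return its id.

        One assigner per variable: a second right-hand side for the same ODE
        is rejected.
        """
        target_node = self.node(target)
        if not isinstance(target_node, TermNode):
            raise NodeKindError(
                f"assigner target must be a Term, got {target_node.kind} "
                f"{target!r}"
            )
        for a in self.assigners():
            if a.target == target:
                raise DuplicateAssignerError(
                    f"term {target_node.name!r} already has an ODE "
                    f"(assigner {a.id})"
                )
        if not name:
            name = f"{target_node.name} ode"
        node = AssignerNode(self._new_node_id("a"), name, target, position)
        self.nodes[node.id] = node
        return node.id

    def connect(self, source: str, destination: str,
                destination_pin: int = 0) -> str:
        """Link ``source``'s output pin to one input pin of ``destination``.

        Connections are unidirectional and checked at call time: Terms have
        no input pins, Assigners no output pins, each input pin holds one
        link, and a link may never close a cycle.
        """
        src = self.node(source)
        dst = self.node(destination)
        if isinstance(src, AssignerNode):
            raise NoOutputPinError(
                f"assigner {src.name!r} has no output pin (terminal node)"
            )
        if isinstance(dst, TermNode):
            raise NoInputPinError(
                f"term {dst.name!r} has no input pins (initial node)"
            )
        if source == destination:
            raise CycleError("a node cannot feed its own input")
        n_pins = self._input_arity(dst)
        if not 0 <= destination_pin < n_pins:
            raise ArityError(
                f"pin {destination_pin} out of range for {dst.name!r} "
                f"({n_pins} input pins)"
            )
        if destination_pin in self.incoming(destination):
            raise PinOccupiedError(
                f"input pin {destination_pin} of {dst.name!r} is occupied"
            )
        if self._reaches(destination, source):
            raise CycleError(
                f"linking {src.name!r} -> {dst.name!r} would create a cycle"
            )
        link = Link(self._new_link_id(), source, destination, destination_pin)
        self.links[link.id] = link
        return link.id

    def _reaches(self, start: str, goal: str) -> bool:
        """True if ``goal`` is reachable from ``start`` along links."""
        stack, seen = [start], set()
        while stack:
            nid = stack.pop()
            if nid == goal:
                return True
            if nid in seen:
                continue
            seen.add(nid)
            stack.extend(
                l.destination for l in self.links.values() if l.source == nid
            )
        return False

    # -- classification and validation -----------------------------------

    def classify_terms(self) -> tuple[list[str], list[str]]:
        """Partition term ids into (state variables, constants).

        A term is a state variable iff some assigner targets it; both lists
        preserve node-insertion order.
        """
        targeted = {a.target for a in self.assigners()}
        variables = [t.id for t in self.terms() if t.id in targeted]
        constants = [t.id for t in self.terms() if t.id not in targeted]
        return variables, constants

    def validate(self, include_warnings: bool = False) -> list[Violation]:
        """Check simulatability; an empty list means the model can run.

        Errors: unconnected expression pins, empty assigner inputs, zero
        state variables, extension operators with no loaded function, and
        non-finite term values. Orphan terms (no connections, no assigner)
        are reported as warnings only when ``include_warnings`` is set.
        """
        out: list[Violation] = []
        for node in self.nodes.values():
            if isinstance(node, ExpressionNode):
                have = self.incoming(node.id)
                for pin in range(node.arity):
                    if pin not in have:
                        out.append(Violation(
                            "unconnected-pin", ERROR,
                            f"expression {node.name!r} input pin {pin} is "
                            f"unconnected", node.id))
                if (not node.is_arithmetic
                        and node.operator not in self.extensions):
                    out.append(Violation(
                        "dangling-operator", ERROR,
                        f"extension function {node.operator!r} is not "
                        f"loaded", node.id))
            elif isinstance(node, AssignerNode):
                if 0 not in self.incoming(node.id):
                    out.append(Violation(
                        "empty-assigner", ERROR,
                        f"assigner {node.name!r} has no input expression",
                        node.id))
            elif isinstance(node, TermNode):
                if not math.isfinite(node.value):
                    out.append(Violation(
                        "non-finite-value", ERROR,
                        f"term {node.name!r} has non-finite value "
                        f"{node.value}", node.id))
        variables, _ = self.classify_terms()
        if not variables:
            out.append(Violation(
                "no-state-variables", ERROR,
                "no assigner targets any term: nothing to integrate"))
        if include_warnings:
            targeted = {a.target for a in self.assigners()}
            linked = ({l.source for l in self.links.values()}
                      | {l.destination for l in self.links.values()})
            for t in self.terms():
                if t.id not in targeted and t.id not in linked:
                    out.append(Violation(
                        "orphan-term", WARNING,
                        f"term {t.name!r} is connected to nothing", t.id))
        return out

    # -- structural equality (used by IR round-trip tests) ----------------

    def _structure(self):
        def node_key(n: Node):
            if isinstance(n, TermNode):
                payload = ("term", n.name, n.value)
            elif isinstance(n, ExpressionNode):
                payload = ("expression", n.name, n.operator, n.arity)
            else:
                payload = ("assigner", n.name, n.target)
            return (n.id, payload, n.position)

        return (
            self.name,
            self.notes,
            tuple(node_key(n) for n in self.nodes.values()),
            tuple((l.source, l.destination, l.destination_pin)
                  for l in self.links.values()),
            self.sim_config,
            tuple(self.extension_refs),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModelGraph):
            return NotImplemented
        return self._structure() == other._structure()

    def __repr__(self) -> str:
        return (f"<ModelGraph {self.name!r}: {len(self.nodes)} nodes, "
                f"{len(self.links)} links>")
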