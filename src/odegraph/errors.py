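"""Exception hierarchy.

Every error family a caller may want to branch on gets its own class; the
CLI maps families to distinct exit statuses.
"""


class OdeGraphError(Exception):
    """Base class for all package errors."""


# --- graph construction -------------------------------------------------

class GraphError(OdeGraphError):
    """Structural error while building or editing a model graph."""


class NameCollisionError(GraphError):
    """Two terms share a name (term names become code identifiers)."""


class NodeKindError(GraphError):
    """An operation received a node of the wrong kind."""


class ArityError(GraphError):
    """Pin count incompatible with the operator or extension function."""


class DuplicateAssignerError(GraphError):
    """A state variable already has an ODE right-hand side."""


class NoInputPinError(GraphError):
    """Attempted to connect into a node with no input pins (a Term)."""


class NoOutputPinError(GraphError):
    """Attempted to connect out of a node with no output pins (an Assigner)."""


class PinOccupiedError(GraphError):
    """The destination input pin already holds a link."""


class CycleError(GraphError):
    """The link would make the directed link graph cyclic."""


class UnknownNodeError(GraphError):
    """A node id does not resolve in the graph."""


# --- expression trees ---------------------------------------------------

class ExpressionError(OdeGraphError):
    """Error while building, rendering or evaluating an expression tree."""


class IncompleteExpressionError(ExpressionError):
    """An input pin reachable from the tree root is unconnected."""


class UnboundSymbolError(ExpressionError):
    """A leaf term name is missing from the evaluation bindings."""


class EvaluationError(ExpressionError):
    """Arithmetic failure (e.g. division by zero) in a subexpression.

    Carries the rendered text of the offending subexpression.
    """

    def __init__(self, message: str, expression_text: str | None = None):
        super().__init__(message)
        self.expression_text = expression_text


# --- intermediate representation ---------------------------------------

class IRError(OdeGraphError):
    """Error in the JSON intermediate representation."""


class IRParseError(IRError):
    """The document is not valid JSON; carries the parse location."""


class IRSchemaError(IRError):
    """The document is valid JSON but violates the model schema."""


class IRReferenceError(IRError):
    """A link or assigner references a node id absent from the document."""


# --- extensions ---------------------------------------------------------

class ExtensionError(OdeGraphError):
    """Error in the user-extension (plugin node) system."""


class ExtensionLoadError(ExtensionError):
    """The extension file could not be parsed or executed."""


class ExtensionArityError(ExtensionError):
    """A decorated function has zero parameters, or a call/arity mismatch."""


class ExtensionCollisionError(ExtensionError):
    """Two loaded extension functions share a name."""


class ExtensionResolutionError(ExtensionError):
    """A referenced extension file is missing, or an operator is undefined."""


# --- code generation ----------------------------------------------------

class CodegenError(OdeGraphError):
    """Error while generating a standalone simulation script."""


class TemplateError(CodegenError):
    """The template lacks a required placeholder; names it."""


class InvalidModelError(CodegenError):
    """The graph failed validation; carries the violation list."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations)
        super().__init__(f"model is not simulatable: {lines}")


# --- simulation ---------------------------------------------------------

class SimulationError(OdeGraphError):
    """Numerical integration failed; carries time and expression context."""

    def __init__(self, message: str, time: float | None = None,
                 expression_text: str | None = None):
        super().__init__(message)
        self.time = time
        self.expression_text = expression_text


class ConfigError(OdeGraphError):
    """Simulation settings violate their invariants."""
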