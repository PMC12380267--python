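"""User-defined function nodes loaded from plugin source files.

An extension file is ordinary Python source in which functions marked with
the :func:`node` decorator become new expression-node kinds. The number of
function parameters determines the number of input pins; an optional
``format`` string with ``$1``, ``$2``, ... placeholders customizes how
calls are displayed (default is standard function notation).

Loading executes the file in a dedicated namespace that provides the
decorator and the ``math`` module; it is always an explicit action (a CLI
flag or a model's recorded extension references), never directory scanning.
"""

from __future__ import annotations

import ast
import inspect
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

from .errors import (
    ExtensionArityError,
    ExtensionCollisionError,
    ExtensionLoadError,
    ExtensionResolutionError,
)

_PLACEHOLDER_RE = re.compile(r"\$(\d+)")


def node(func: Optional[Callable] = None, *, format: Optional[str] = None):
    """Mark a function as an extension node.

    Usable bare (``@node``) or with a display format
    (``@node(format="$1 ^ $2")``). The decorated function is returned
    unchanged, so extension files remain valid standalone Python.
    """

    def mark(f: Callable) -> Callable:
        f.__ode_node__ = True
        f.__node_format__ = format
        return f

    if func is not None:
        return mark(func)
    return mark


@dataclass
class ExtensionFunction:
    """A user-defined node kind parsed from a plugin file."""

    name: str
    arity: int
    callable: Callable
    format: Optional[str] = None
    #: source of the decorated function itself (including the decorator)
    source_text: str = ""
    #: full source of the file it came from (imports and helpers included),
    #: embedded verbatim in generated code so helper calls keep working
    module_source: str = ""
    origin: Optional[str] = None

    def __eq__(self, other):
        return self is other

    def __hash__(self):
        return id(self)


def _validate_format(func_name: str, fmt: Optional[str], arity: int) -> None:
    if fmt is None:
        return
    for m in _PLACEHOLDER_RE.finditer(fmt):
        k = int(m.group(1))
        if not 1 <= k <= arity:
            raise ExtensionLoadError(
                f"format of {func_name!r} references ${k} but the function "
                f"has {arity} parameter(s)")


def load_extension(path) -> list[ExtensionFunction]:
    """Load every ``@node``-decorated function from a plugin file.

    Functions are returned in file order. Undecorated functions are ignored
    as nodes but remain part of the file's embedded source, so decorated
    functions that call them still work in generated code.
    """
    path = Path(path)
    if not path.is_file():
        raise ExtensionResolutionError(f"extension file not found: {path}")
    source = path.read_text(encoding="utf-8")

    try:
        tree = ast.parse(source, filename=str(path))
    except SyntaxError as exc:
        raise ExtensionLoadError(
            f"{path}:{exc.lineno}:{exc.offset}: {exc.msg}") from exc

    namespace: dict = {"node": node, "math": math, "__name__": path.stem}
    try:
        exec(compile(tree, str(path), "exec"), namespace)
    except Exception as exc:  # noqa: BLE001 — plugin code may fail anyhow
        raise ExtensionLoadError(f"error executing {path}: {exc}") from exc

    functions: list[ExtensionFunction] = []
    for stmt in tree.body:
        if not isinstance(stmt, ast.FunctionDef):
            continue
        obj = namespace.get(stmt.name)
        if not getattr(obj, "__ode_node__", False):
            continue
        params = inspect.signature(obj).parameters
        arity = sum(
            1 for p in params.values()
            if p.kind in (p.POSITIONAL_ONLY, p.POSITIONAL_OR_KEYWORD)
        )
        if arity == 0:
            raise ExtensionArityError(
                f"{path}: function {stmt.name!r} takes no parameters; "
                f"a node needs at least one input pin")
        fmt = getattr(obj, "__node_format__", None)
        _validate_format(stmt.name, fmt, arity)
        functions.append(ExtensionFunction(
            name=stmt.name,
            arity=arity,
            callable=obj,
            format=fmt,
            source_text=ast.get_source_segment(source, stmt) or "",
            module_source=source,
            origin=str(path),
        ))
    return functions


def render_extension_call(func: ExtensionFunction,
                          rendered_args: list[str]) -> str:
    """Render a call for display.

    Default is ``name(arg1, arg2, ...)``; a declared format replaces each
    ``$k`` with the k-th rendered argument (placeholders may repeat).
    """
    if len(rendered_args) != func.arity:
        raise ExtensionArityError(
            f"{func.name!r} takes {func.arity} argument(s), "
            f"got {len(rendered_args)}")
    if func.format is None:
        return f"{func.name}({', '.join(rendered_args)})"
    return _PLACEHOLDER_RE.sub(
        lambda m: rendered_args[int(m.group(1)) - 1], func.format)


def load_extensions(paths, registry: Optional[dict] = None
                    ) -> dict[str, ExtensionFunction]:
    """Load several files into one registry, rejecting name collisions."""
    registry = {} if registry is None else registry
    for p in paths:
        for func in load_extension(p):
            if func.name in registry:
                raise ExtensionCollisionError(
                    f"extension function {func.name!r} defined in both "
                    f"{registry[func.name].origin} and {func.origin}")
            registry[func.name] = func
    return registry


def resolve_model_extensions(graph, base_dir=None) -> dict[str, ExtensionFunction]:
    """Load every extension file a model references and attach the registry.

    Relative references resolve against ``base_dir`` (typically the model
    file's directory). Afterwards every extension operator used by an
    expression node must resolve, else a dangling-operator error is raised.
    """
    from .graph import ExpressionNode

    base = Path(base_dir) if base_dir is not None else Path(".")
    paths = []
    for ref in graph.extension_refs:
        p = Path(ref)
        if not p.is_absolute():
            p = base / p
        if not p.is_file():
            raise ExtensionResolutionError(f"extension file not found: {p}")
        paths.append(p)
    registry = load_extensions(paths, registry=dict(graph.extensions))
    for n in graph.nodes.values():
        if isinstance(n, ExpressionNode) and not n.is_arithmetic:
            if n.operator not in registry:
                raise ExtensionResolutionError(
                    f"expression {n.name!r} uses extension function "
                    f"{n.operator!r}, which no loaded file defines")
    graph.extensions = registry
    return registry
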