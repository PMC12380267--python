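"""Template-based generation of standalone simulation scripts.

A validated model graph is flattened into a :class:`CodegenContext`
(populations, constants, ODE right-hand-side texts, embedded extension
sources, simulation settings) and substituted into a Jinja template. The
default template ships with the package and produces a self-contained
Python script depending only on numpy, scipy and matplotlib; it integrates
on the same reporting grid as the in-process simulator, so the two paths
produce identical trajectories.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import jinja2

from .errors import InvalidModelError, TemplateError
from .expression import build_expression_tree, render_infix
from .graph import ModelGraph

_IDENT_RE = re.compile(r"[^0-9A-Za-z_]")

#: names the default template vocabulary requires
REQUIRED_PLACEHOLDERS = (
    "populations", "constants", "odes", "extension_sources", "sim",
    "csv_path",
)

#: identifiers the generated script itself uses; model names may not
#: shadow them after sanitization
_RESERVED = {
    "t", "y", "np", "math", "sys", "csv", "plt", "matplotlib", "node",
    "system", "constants", "initial_values", "constant_values", "times",
    "trajectories", "solution", "variable_names", "start_time", "time_step",
    "end_time", "rel_tol", "abs_tol", "method", "solve_ivp",
}


def sanitize_identifier(name: str, taken: Optional[set[str]] = None) -> str:
    """Turn a display name into a valid, collision-free identifier.

    Characters outside ``[A-Za-z0-9_]`` become underscores; a leading digit
    gets an underscore prefix; a numeric suffix is appended on collision
    with ``taken`` (which is updated in place when given).
    """
    ident = _IDENT_RE.sub("_", name)
    if ident[0].isdigit():
        ident = "_" + ident
    if taken is not None:
        candidate, k = ident, 1
        while candidate in taken:
            k += 1
            candidate = f"{ident}_{k}"
        taken.add(candidate)
        ident = candidate
    return ident


@dataclass
class CodegenContext:
    """Everything the template needs, in aligned insertion order."""

    model_name: str
    populations: list[dict]  # {"identifier", "initial_value"}
    constants: list[dict]    # {"identifier", "value"}
    odes: list[dict]         # {"identifier", "rhs_text"}, aligned with populations
    extension_sources: list[str]
    sim: dict
    csv_path: str = "results.csv"
    combined_plot_path: str = "combined.png"
    plot_prefix: str = "population_"


def build_context(graph: ModelGraph, *, csv_path: str = "results.csv",
                  combined_plot_path: str = "combined.png",
                  plot_prefix: str = "population_") -> CodegenContext:
    """Flatten a validated graph into a codegen context.

    Populations and constants come from ``classify_terms`` in insertion
    order; each ODE right-hand side is the code-mode rendering of its
    assigner's expression tree with sanitized leaf identifiers. Refuses a
    graph that fails validation, carrying the violation list.
    """
    violations = graph.validate()
    if violations:
        raise InvalidModelError(violations)

    var_ids, const_ids = graph.classify_terms()
    taken = set(_RESERVED)
    idents = {}
    for tid in var_ids + const_ids:
        term = graph.node(tid)
        idents[term.name] = sanitize_identifier(term.name, taken)

    populations = [
        {"identifier": idents[graph.node(t).name],
         "initial_value": repr(graph.node(t).value)}
        for t in var_ids
    ]
    constants = [
        {"identifier": idents[graph.node(t).name],
         "value": repr(graph.node(t).value)}
        for t in const_ids
    ]

    odes = []
    used_extensions: list = []
    for tid in var_ids:
        assigner = next(a for a in graph.assigners() if a.target == tid)
        tree = build_expression_tree(graph, assigner.id)
        _collect_extensions(tree, used_extensions)
        odes.append({
            "identifier": idents[graph.node(tid).name],
            "rhs_text": render_infix(tree, code=True, names=idents),
        })

    # one embedded copy per source file, in first-use order, so decorated
    # functions can keep calling their file-local helpers
    sources, seen_origins = [], set()
    for func in used_extensions:
        key = func.origin or id(func)
        if key in seen_origins:
            continue
        seen_origins.add(key)
        sources.append(func.module_source or func.source_text)

    return CodegenContext(
        model_name=graph.name,
        populations=populations,
        constants=constants,
        odes=odes,
        extension_sources=sources,
        sim={
            "start_time": repr(graph.sim_config.start_time),
            "time_step": repr(graph.sim_config.time_step),
            "end_time": repr(graph.sim_config.end_time),
            "rel_tol": repr(graph.sim_config.rel_tol),
            "abs_tol": repr(graph.sim_config.abs_tol),
            "method": graph.sim_config.method,
            "x_label": graph.sim_config.x_label,
            "y_label": graph.sim_config.y_label,
        },
        csv_path=csv_path,
        combined_plot_path=combined_plot_path,
        plot_prefix=plot_prefix,
    )


def _collect_extensions(tree, out: list) -> None:
    from .expression import Call

    if isinstance(tree, Call):
        if not tree.is_arithmetic and tree.operator not in out:
            out.append(tree.operator)
        for c in tree.children:
            _collect_extensions(c, out)


def default_template() -> str:
    """The template shipped with the package."""
    return (resources.files("odegraph") / "templates"
            / "simulation.py.jinja").read_text(encoding="utf-8")


def generate_source(context: CodegenContext,
                    template: Optional[str] = None) -> str:
    """Substitute a context into a template, yielding a runnable script.

    The template must reference every required placeholder
    (:data:`REQUIRED_PLACEHOLDERS`); a missing one raises TemplateError
    naming it. Generation is deterministic: the same context yields
    byte-identical source.
    """
    text = default_template() if template is None else template
    for name in REQUIRED_PLACEHOLDERS:
        if not re.search(rf"\b{name}\b", text):
            raise TemplateError(
                f"template does not reference required placeholder {name!r}")
    env = jinja2.Environment(undefined=jinja2.StrictUndefined,
                             keep_trailing_newline=True)
    try:
        return env.from_string(text).render(
            model_name=context.model_name,
            populations=context.populations,
            constants=context.constants,
            odes=context.odes,
            extension_sources=context.extension_sources,
            sim=context.sim,
            csv_path=context.csv_path,
            combined_plot_path=context.combined_plot_path,
            plot_prefix=context.plot_prefix,
        )
    except jinja2.UndefinedError as exc:
        raise TemplateError(f"template references an unknown name: {exc}")


def export_script(graph: ModelGraph, path, *, template: Optional[str] = None,
                  csv_path: Optional[str] = None) -> str:
    """Generate and write the standalone script for a graph; returns source.

    Output paths default to the script's own stem (``<stem>.csv`` etc.) so
    the exported file runs with zero arguments from any directory.
    """
    path = Path(path)
    stem = path.stem
    context = build_context(
        graph,
        csv_path=csv_path or f"{stem}.csv",
        combined_plot_path=f"{stem}_combined.png",
        plot_prefix=f"{stem}_",
    )
    source = generate_source(context, template)
    path.write_text(source, encoding="utf-8")
    return source
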