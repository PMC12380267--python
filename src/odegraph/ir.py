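"""JSON intermediate representation: save and load model graphs.

The on-disk format is a UTF-8 JSON document (documented machine-readably in
``docs/ir-schema.json``)::

    {
      "format_version": "1.0",
      "metadata": {"name": ..., "notes": ...},
      "nodes": [
        {"id": ..., "kind": "term",       "name": ..., "value": ...},
        {"id": ..., "kind": "expression", "name": ..., "operator": ...,
         "arity": ...},
        {"id": ..., "kind": "assigner",   "name": ..., "target": ...}
      ],
      "links": [{"source": ..., "destination": ..., "destination_pin": ...}],
      "simulation": {"start_time": ..., "time_step": ..., "end_time": ...,
                     "x_label": ..., "y_label": ...,
                     "rel_tol": ..., "abs_tol": ..., "method": ...},
      "extensions": ["relative/path/to/extension.py", ...]
    }

Node records may carry an optional ``"position": [x, y]`` pair, preserved
verbatim and never interpreted. Extension paths are stored relative to the
model file's directory so shared models re-load their plugins. Output is
deterministic (insertion order, stable keys), making diffs meaningful.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional

from .errors import IRParseError, IRReferenceError, IRSchemaError
from .graph import (
    ARITHMETIC_OPERATORS,
    AssignerNode,
    ExpressionNode,
    Link,
    ModelGraph,
    TermNode,
)
from .simulation import SimulationConfig

FORMAT_VERSION = "1.0"


def _node_record(node) -> dict:
    rec: dict = {"id": node.id, "kind": node.kind, "name": node.name}
    if isinstance(node, TermNode):
        rec["value"] = node.value
    elif isinstance(node, ExpressionNode):
        rec["operator"] = node.operator
        rec["arity"] = node.arity
    else:
        rec["target"] = node.target
    if node.position is not None:
        rec["position"] = list(node.position)
    return rec


def serialize(graph: ModelGraph) -> str:
    """Serialize a graph to deterministic JSON text."""
    doc = {
        "format_version": FORMAT_VERSION,
        "metadata": {"name": graph.name, "notes": graph.notes},
        "nodes": [_node_record(n) for n in graph.nodes.values()],
        "links": [
            {
                "source": l.source,
                "destination": l.destination,
                "destination_pin": l.destination_pin,
            }
            for l in graph.links.values()
        ],
        "simulation": {
            "start_time": graph.sim_config.start_time,
            "time_step": graph.sim_config.time_step,
            "end_time": graph.sim_config.end_time,
            "x_label": graph.sim_config.x_label,
            "y_label": graph.sim_config.y_label,
            "rel_tol": graph.sim_config.rel_tol,
            "abs_tol": graph.sim_config.abs_tol,
            "method": graph.sim_config.method,
        },
        "extensions": list(graph.extension_refs),
    }
    return json.dumps(doc, indent=2) + "\n"


def save(graph: ModelGraph, path) -> None:
    Path(path).write_text(serialize(graph), encoding="utf-8")


# --- deserialization ----------------------------------------------------

def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise IRSchemaError(f"{context}: missing required field {key!r}")
    return mapping[key]


def _number(value, context: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise IRSchemaError(f"{context}: expected a number, got {value!r}")
    return float(value)


def _text(value, context: str) -> str:
    if not isinstance(value, str):
        raise IRSchemaError(f"{context}: expected a string, got {value!r}")
    return value


def _position(rec: dict, context: str) -> Optional[tuple[float, float]]:
    if "position" not in rec:
        return None
    pos = rec["position"]
    if (not isinstance(pos, (list, tuple)) or len(pos) != 2):
        raise IRSchemaError(f"{context}: position must be a [x, y] pair")
    return (_number(pos[0], context), _number(pos[1], context))


def deserialize(text: str) -> ModelGraph:
    """Parse IR text back into a ModelGraph.

    Raises IRParseError (with location) on malformed JSON, IRSchemaError on
    structural problems (naming the offending field), and IRReferenceError
    when a link or assigner points at a node id the document does not
    define. ``deserialize(serialize(g))`` is structurally equal to ``g``.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise IRParseError(
            f"invalid JSON at line {exc.lineno}, column {exc.colno}: "
            f"{exc.msg}") from exc
    if not isinstance(doc, dict):
        raise IRSchemaError("document root must be a JSON object")

    version = _text(_require(doc, "format_version", "document"), "format_version")
    if version != FORMAT_VERSION:
        raise IRSchemaError(
            f"unknown format_version {version!r} "
            f"(this reader understands {FORMAT_VERSION!r})")

    meta = _require(doc, "metadata", "document")
    if not isinstance(meta, dict):
        raise IRSchemaError("metadata: expected an object")
    graph = ModelGraph(
        name=_text(_require(meta, "name", "metadata"), "metadata.name"),
        notes=_text(meta.get("notes", ""), "metadata.notes"),
    )

    nodes = _require(doc, "nodes", "document")
    if not isinstance(nodes, list):
        raise IRSchemaError("nodes: expected a list")
    for i, rec in enumerate(nodes):
        ctx = f"nodes[{i}]"
        if not isinstance(rec, dict):
            raise IRSchemaError(f"{ctx}: expected an object")
        nid = _text(_require(rec, "id", ctx), f"{ctx}.id")
        if nid in graph.nodes:
            raise IRSchemaError(f"{ctx}: duplicate node id {nid!r}")
        kind = _text(_require(rec, "kind", ctx), f"{ctx}.kind")
        name = _text(_require(rec, "name", ctx), f"{ctx}.name")
        pos = _position(rec, ctx)
        if kind == "term":
            value = _number(_require(rec, "value", ctx), f"{ctx}.value")
            graph.nodes[nid] = TermNode(nid, name, value, pos)
        elif kind == "expression":
            operator = _text(_require(rec, "operator", ctx), f"{ctx}.operator")
            arity = _require(rec, "arity", ctx)
            if not isinstance(arity, int) or isinstance(arity, bool) or arity < 1:
                raise IRSchemaError(f"{ctx}.arity: expected a positive integer")
            if operator in ARITHMETIC_OPERATORS and arity < 2:
                raise IRSchemaError(
                    f"{ctx}: arithmetic operator {operator!r} needs arity >= 2")
            graph.nodes[nid] = ExpressionNode(nid, name, operator, arity, pos)
        elif kind == "assigner":
            target = _text(_require(rec, "target", ctx), f"{ctx}.target")
            graph.nodes[nid] = AssignerNode(nid, name, target, pos)
        else:
            raise IRSchemaError(f"{ctx}: unknown node kind {kind!r}")

    # resolve references now that all nodes exist
    for nid, n in graph.nodes.items():
        if isinstance(n, AssignerNode):
            if n.target not in graph.nodes:
                raise IRReferenceError(
                    f"assigner {nid!r} targets missing node {n.target!r}")
            if not isinstance(graph.nodes[n.target], TermNode):
                raise IRSchemaError(
                    f"assigner {nid!r} must target a term node")

    links = _require(doc, "links", "document")
    if not isinstance(links, list):
        raise IRSchemaError("links: expected a list")
    seen_pins: set[tuple[str, int]] = set()
    for i, rec in enumerate(links):
        ctx = f"links[{i}]"
        if not isinstance(rec, dict):
            raise IRSchemaError(f"{ctx}: expected an object")
        src = _text(_require(rec, "source", ctx), f"{ctx}.source")
        dst = _text(_require(rec, "destination", ctx), f"{ctx}.destination")
        pin = _require(rec, "destination_pin", ctx)
        if not isinstance(pin, int) or isinstance(pin, bool) or pin < 0:
            raise IRSchemaError(
                f"{ctx}.destination_pin: expected a non-negative integer")
        for endpoint in (src, dst):
            if endpoint not in graph.nodes:
                raise IRReferenceError(
                    f"{ctx}: references missing node {endpoint!r}")
        if (dst, pin) in seen_pins:
            raise IRSchemaError(
                f"{ctx}: destination pin {pin} of {dst!r} is bound twice")
        seen_pins.add((dst, pin))
        lid = graph._new_link_id()
        graph.links[lid] = Link(lid, src, dst, pin)

    sim = _require(doc, "simulation", "document")
    if not isinstance(sim, dict):
        raise IRSchemaError("simulation: expected an object")
    graph.sim_config = SimulationConfig(
        start_time=_number(_require(sim, "start_time", "simulation"),
                           "simulation.start_time"),
        time_step=_number(_require(sim, "time_step", "simulation"),
                          "simulation.time_step"),
        end_time=_number(_require(sim, "end_time", "simulation"),
                         "simulation.end_time"),
        x_label=_text(sim.get("x_label", "Time"), "simulation.x_label"),
        y_label=_text(sim.get("y_label", "Population"), "simulation.y_label"),
        rel_tol=_number(sim.get("rel_tol", 1e-6), "simulation.rel_tol"),
        abs_tol=_number(sim.get("abs_tol", 1e-9), "simulation.abs_tol"),
        method=_text(sim.get("method", "RK45"), "simulation.method"),
    )

    exts = doc.get("extensions", [])
    if not isinstance(exts, list):
        raise IRSchemaError("extensions: expected a list of paths")
    graph.extension_refs = [_text(p, "extensions[]") for p in exts]

    # keep fresh ids collision-free after loading
    numeric = [
        int(m.group(1))
        for nid in graph.nodes
        if (m := re.fullmatch(r"[a-z]+(\d+)", nid))
    ]
    graph._node_counter = max(numeric, default=0)
    return graph


def load(path) -> ModelGraph:
    """Load a model file; attaches no extensions (see resolve_model_extensions)."""
    return deserialize(Path(path).read_text(encoding="utf-8"))
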