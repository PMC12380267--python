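{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "odegraph model intermediate representation",
  "description": "On-disk JSON encoding of a node-graph ODE model: nodes, links, simulation settings and extension-file references. Extension paths are relative to the model file's directory.",
  "type": "object",
  "required": ["format_version", "metadata", "nodes", "links", "simulation"],
  "properties": {
    "format_version": {"const": "1.0"},
    "metadata": {
      "type": "object",
      "required": ["name"],
      "properties": {
        "name": {"type": "string"},
        "notes": {"type": "string"}
      }
    },
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "kind", "name"],
        "properties": {
          "id": {"type": "string"},
          "kind": {"enum": ["term", "expression", "assigner"]},
          "name": {"type": "string"},
          "value": {
            "type": "number",
            "description": "term nodes only: initial condition for state variables, fixed value for constants"
          },
          "operator": {
            "type": "string",
            "description": "expression nodes only: '+', '-', '*', '/' or an extension function name"
          },
          "arity": {
            "type": "integer",
            "minimum": 1,
            "description": "expression nodes only: number of input pins; >= 2 for arithmetic operators"
          },
          "target": {
            "type": "string",
            "description": "assigner nodes only: id of the term node whose ODE this defines"
          },
          "position": {
            "type": "array",
            "items": {"type": "number"},
            "minItems": 2,
            "maxItems": 2,
            "description": "opaque editor coordinates; preserved, never interpreted"
          }
        }
      }
    },
    "links": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source", "destination", "destination_pin"],
        "properties": {
          "source": {"type": "string"},
          "destination": {"type": "string"},
          "destination_pin": {"type": "integer", "minimum": 0}
        }
      }
    },
    "simulation": {
      "type": "object",
      "required": ["start_time", "time_step", "end_time"],
      "properties": {
        "start_time": {"type": "number"},
        "time_step": {"type": "number", "exclusiveMinimum": 0},
        "end_time": {"type": "number"},
        "x_label": {"type": "string"},
        "y_label": {"type": "string"},
        "rel_tol": {"type": "number", "exclusiveMinimum": 0},
        "abs_tol": {"type": "number", "exclusiveMinimum": 0},
        "method": {"type": "string"}
      }
    },
    "extensions": {
      "type": "array",
      "items": {"type": "string"}
    }
  }
}
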