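{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "rdme run configuration",
  "description": "Schema of the TOML run configuration consumed by `rdme run -c config.toml` (TOML maps 1:1 onto this JSON structure).",
  "type": "object",
  "required": ["model"],
  "properties": {
    "model": {
      "type": "string",
      "description": "Builtin model name ('min', 'neuron-transport', 'sphere-absorption') or 'module.path:builder' of a user function builder(mesh, tspan=..., seed=...) returning an RDMEModel or (model, generators)."
    },
    "solver": {"enum": ["nsm", "dfsp"], "default": "nsm"},
    "seed": {"type": "integer", "default": 0},
    "output": {"type": "string", "default": "trajectory.h5"},
    "mode": {"enum": ["foreground", "background", "bg"], "default": "foreground"},
    "mesh": {
      "type": "object",
      "properties": {
        "kind": {"enum": ["capsule", "box", "interval", "icosphere", "sphere", "neuron", "gmsh"]},
        "length": {"type": "number"}, "radius": {"type": "number"},
        "h": {"type": "number"}, "xsep": {"type": "number", "minimum": 0},
        "nx": {"type": "integer"}, "ny": {"type": "integer"}, "nz": {"type": "integer"},
        "lx": {"type": "number"}, "ly": {"type": "number"}, "lz": {"type": "number"},
        "n": {"type": "integer"}, "subdivisions": {"type": "integer"},
        "path": {"type": "string", "description": "Gmsh .msh ASCII file (kind='gmsh')"},
        "seed": {"type": "integer"}
      }
    },
    "tspan": {
      "type": "object",
      "properties": {
        "t_end": {"type": "number", "exclusiveMinimum": 0},
        "dt": {"type": "number", "exclusiveMinimum": 0}
      }
    },
    "dfsp": {
      "type": "object",
      "description": "Required when solver='dfsp'.",
      "required": ["tau"],
      "properties": {
        "tau": {"type": "number", "exclusiveMinimum": 0, "description": "macro time-step tau_D (s)"},
        "max_jump": {"type": "integer", "minimum": 1, "default": 10},
        "tol": {"type": "number", "default": 0.001},
        "cache_path": {"type": "string", "description": "directory for cached DFSP tables"}
      }
    },
    "model_options": {"type": "object", "description": "Extra keyword arguments passed to the model builder."}
  }
}
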