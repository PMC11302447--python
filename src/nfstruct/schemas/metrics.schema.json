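{
  "description": "Validated metrics for one graph level; all counts are non-negative.",
  "properties": {
    "level": {
      "title": "Level",
      "type": "string"
    },
    "n_nodes": {
      "minimum": 0,
      "title": "N Nodes",
      "type": "integer"
    },
    "n_edges": {
      "minimum": 0,
      "title": "N Edges",
      "type": "integer"
    },
    "n_processes": {
      "minimum": 0,
      "title": "N Processes",
      "type": "integer"
    },
    "n_operations_starting": {
      "minimum": 0,
      "title": "N Operations Starting",
      "type": "integer"
    },
    "n_operations_following": {
      "minimum": 0,
      "title": "N Operations Following",
      "type": "integer"
    },
    "n_sources": {
      "minimum": 0,
      "title": "N Sources",
      "type": "integer"
    },
    "n_sinks": {
      "minimum": 0,
      "title": "N Sinks",
      "type": "integer"
    },
    "n_simple_paths_source_to_sink": {
      "minimum": 0,
      "title": "N Simple Paths Source To Sink",
      "type": "integer"
    },
    "path_cap_hit": {
      "default": false,
      "title": "Path Cap Hit",
      "type": "boolean"
    },
    "longest_path_len": {
      "minimum": 0,
      "title": "Longest Path Len",
      "type": "integer"
    },
    "n_weak_components": {
      "minimum": 0,
      "title": "N Weak Components",
      "type": "integer"
    },
    "has_cycle": {
      "default": false,
      "title": "Has Cycle",
      "type": "boolean"
    },
    "max_in_degree": {
      "minimum": 0,
      "title": "Max In Degree",
      "type": "integer"
    },
    "max_out_degree": {
      "minimum": 0,
      "title": "Max Out Degree",
      "type": "integer"
    }
  },
  "required": [
    "level",
    "n_nodes",
    "n_edges",
    "n_processes",
    "n_operations_starting",
    "n_operations_following",
    "n_sources",
    "n_sinks",
    "n_simple_paths_source_to_sink",
    "longest_path_len",
    "n_weak_components",
    "max_in_degree",
    "max_out_degree"
  ],
  "title": "MetricsReport",
  "type": "object"
}
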