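"""Per-graph structural metrics and their JSON serialization.

The committed metric set covers size (nodes, edges, per-kind counts), shape
(degrees, weak components), and path structure (source-to-sink simple paths,
longest path).  Simple-path enumeration is capped at 10^6 with an explicit
cap-hit flag, since path counts can explode combinatorially.  On cyclic graphs
the longest path is computed on the condensation (each strongly connected
component contracted to one step) and ``has_cycle`` is set.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import networkx as nx
from pydantic import BaseModel, Field

from .graph_build import StructureGraph

PATH_CAP = 10 ** 6


class MetricsReport(BaseModel):
    """Validated metrics for one graph level; all counts are non-negative."""

    level: str
    n_nodes: int = Field(ge=0)
    n_edges: int = Field(ge=0)
    n_processes: int = Field(ge=0)
    n_operations_starting: int = Field(ge=0)
    n_operations_following: int = Field(ge=0)
    n_sources: int = Field(ge=0)
    n_sinks: int = Field(ge=0)
    n_simple_paths_source_to_sink: int = Field(ge=0)
    path_cap_hit: bool = False
    longest_path_len: int = Field(ge=0)
    n_weak_components: int = Field(ge=0)
    has_cycle: bool = False
    max_in_degree: int = Field(ge=0)
    max_out_degree: int = Field(ge=0)


def _count_simple_paths(dg: nx.DiGraph, sources, sinks, cap: int):
    """Count simple source-to-sink paths with >= 1 edge, up to *cap*."""
    count = 0
    sink_set = set(sinks)
    for s in sources:
        for snk in sinks:
            if s == snk:
                continue
            for _ in nx.all_simple_paths(dg, s, snk):
                count += 1
                if count >= cap:
                    return count, True
    return count, False


def compute_metrics(graph: StructureGraph) -> MetricsReport:
    g = graph.g
    dg = nx.DiGraph(g)  # path/degree statistics over node sequences
    kinds = [d.get("kind", "") for _, d in g.nodes(data=True)]
    sources = [n for n in dg.nodes if dg.in_degree(n) == 0]
    sinks = [n for n in dg.nodes if dg.out_degree(n) == 0]
    n_paths, cap_hit = _count_simple_paths(dg, sources, sinks, PATH_CAP)

    has_cycle = not nx.is_directed_acyclic_graph(dg) if dg.number_of_nodes() else False
    if dg.number_of_nodes() == 0:
        longest = 0
    elif has_cycle:
        cond = nx.condensation(dg)
        longest = nx.dag_longest_path_length(cond)
    else:
        longest = nx.dag_longest_path_length(dg)

    return MetricsReport(
        level=graph.level,
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_processes=kinds.count("process"),
        n_operations_starting=kinds.count("starting_op"),
        n_operations_following=kinds.count("following_op"),
        n_sources=len(sources),
        n_sinks=len(sinks),
        n_simple_paths_source_to_sink=n_paths,
        path_cap_hit=cap_hit,
        longest_path_len=longest,
        n_weak_components=nx.number_weakly_connected_components(dg) if dg.number_of_nodes() else 0,
        has_cycle=has_cycle,
        max_in_degree=max((d for _, d in g.in_degree()), default=0),
        max_out_degree=max((d for _, d in g.out_degree()), default=0),
    )


def write_metrics_json(reports: Dict[str, MetricsReport], path: Path) -> None:
    """Write one JSON document with one validated object per graph level."""
    doc = {}
    for level, report in reports.items():
        MetricsReport.model_validate(report.model_dump())  # re-validate invariants
        doc[level] = report.model_dump()
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def metrics_schema() -> dict:
    """JSON Schema of one per-level report (also shipped under schemas/)."""
    return MetricsReport.model_json_schema()
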