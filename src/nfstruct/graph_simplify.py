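"""Contraction of the specification graph into its two simplified levels.

The *dependency graph* removes following operations; the *process dependency
graph* keeps only processes.  In both, two kept nodes are connected when the
specification graph links them through removed nodes.  The default reading is
*removed-internal* contraction: an edge u -> v exists iff some directed path
u -> ... -> v has all its internal vertices removed.  This preserves
reachability between kept nodes exactly, without adding shortcut edges between
nodes already mediated by other kept nodes.  The literal transitive-closure
reading (u -> v iff any path exists) is available behind ``closure=True``.
"""

from __future__ import annotations

from typing import Callable, Hashable

from .graph_build import DEPENDENCY, PROCESS, StructureGraph


def contract_graph(g: StructureGraph, keep: Callable[[Hashable], bool],
                   level: str = "specification", closure: bool = False) -> StructureGraph:
    """Contract *g* onto the nodes satisfying *keep*.

    Parallel duplicate edges are collapsed and edge labels dropped.  A
    self-loop u -> u survives only when the original graph has one, or when a
    cycle through removed nodes returns to u.
    """
    out = StructureGraph(level=level)
    kept = [n for n in g.g.nodes if keep(n)]
    kept_set = set(kept)
    for n in kept:
        d = g.g.nodes[n]
        out.g.add_node(n, label=d.get("label", n), kind=d.get("kind", ""),
                       span=d.get("span"))
    for u in kept:
        targets: list = []
        seen_t = set()
        if closure:
            # any directed path of length >= 1
            visited = set()
            stack = [v for v in _succ(g, u)]
            while stack:
                x = stack.pop()
                if x in visited:
                    continue
                visited.add(x)
                if x in kept_set and x not in seen_t:
                    seen_t.add(x)
                    targets.append(x)
                stack.extend(_succ(g, x))
        else:
            # paths whose internal nodes are all removed
            visited_removed = set()
            stack = [v for v in _succ(g, u)]
            while stack:
                x = stack.pop()
                if x in kept_set:
                    if x not in seen_t:
                        seen_t.add(x)
                        targets.append(x)
                    continue
                if x in visited_removed:
                    continue
                visited_removed.add(x)
                stack.extend(_succ(g, x))
        for v in sorted(targets, key=_node_order(out)):
            out.g.add_edge(u, v, label="")
    return out


def _succ(g: StructureGraph, n):
    seen = set()
    for _, v in g.g.out_edges(n):
        if v not in seen:
            seen.add(v)
            yield v


def _node_order(out: StructureGraph):
    order = {n: i for i, n in enumerate(out.g.nodes)}
    return lambda n: order.get(n, len(order))


def derive_dependency_graph(g: StructureGraph, closure: bool = False) -> StructureGraph:
    """Keep processes and starting operations; drop following operations."""
    return contract_graph(
        g, lambda n: g.kind(n) in ("process", "starting_op"),
        level=DEPENDENCY, closure=closure)


def derive_process_dependency_graph(g: StructureGraph, closure: bool = False) -> StructureGraph:
    """Keep only processes and their inter-dependencies."""
    return contract_graph(g, lambda n: g.kind(n) == "process",
                          level=PROCESS, closure=closure)
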