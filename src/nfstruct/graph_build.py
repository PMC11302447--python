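"""Assembly of the specification graph from wired workflow elements.

The specification graph is the complete static structure of a workflow: one
node per process call instance and per operation (a group of connected channel
operators), and one edge per (producer, consumer) pair of every channel,
oriented along the data flow and labelled with the channel name.  Because all
conditional branches are represented together, the graph may contain cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

SPECIFICATION = "specification"
DEPENDENCY = "dependency"
PROCESS = "process"


@dataclass
class StructureGraph:
    """A labelled directed multigraph at one of three simplification levels."""

    level: str
    g: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)

    # -- convenience views -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def nodes(self):
        """``(id, label, kind)`` triples in insertion order."""
        return [(n, d.get("label", n), d.get("kind", "")) for n, d in self.g.nodes(data=True)]

    def edges(self):
        """``(src, dst, label)`` triples in insertion order."""
        return [(u, v, d.get("label", "")) for u, v, d in self.g.edges(data=True)]

    def kind(self, node) -> str:
        return self.g.nodes[node].get("kind", "")

    def isomorphic_to(self, other: "StructureGraph") -> bool:
        """Label-preserving isomorphism: node (kind, label) and edge labels."""
        nm = nx.algorithms.isomorphism.categorical_node_match(["kind", "label"], ["", ""])
        em = nx.algorithms.isomorphism.categorical_multiedge_match("label", "")
        return nx.is_isomorphic(self.g, other.g, node_match=nm, edge_match=em)


def build_specification_graph(project) -> StructureGraph:
    """Build the specification-level graph from a cleanly wired project.

    Subworkflow calls were already flattened at wiring time (their internal
    nodes inlined, take/emit channels spliced onto the caller), so this step
    is a direct transcription: nodes in wiring order, then the full
    producer x consumer edge set of every channel.
    """
    sg = StructureGraph(level=SPECIFICATION)
    wiring = project.wiring
    if wiring is None:
        return sg
    for node in wiring.nodes:
        sg.g.add_node(node.id, label=node.label, kind=node.kind, span=node.span,
                      n_consumed=len(node.consumed))
    for ch in wiring.channels:
        for p in ch.producers:
            for c in ch.consumers:
                sg.g.add_edge(p, c, label=ch.label)
    classify_operations(sg, wiring)
    return sg


def classify_operations(graph: StructureGraph, wiring=None) -> StructureGraph:
    """Set each operation node's kind: *starting* iff it consumes no channel.

    An operation consuming only dangling (never-produced) channels still has
    declared inputs and is therefore *following*, even though it has no
    in-edges.
    """
    for n, d in graph.g.nodes(data=True):
        if d.get("kind") == "process":
            continue
        n_consumed = d.get("n_consumed", graph.g.in_degree(n))
        d["kind"] = "starting_op" if n_consumed == 0 else "following_op"
    return graph
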