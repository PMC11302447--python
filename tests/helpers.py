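"""Shared test utilities: independent oracles and output re-parsers.

Everything here is deliberately written against the *definitions* (path
enumeration, transitive closure, grammar shapes) rather than reusing the
implementation's algorithms, so agreement is meaningful.
"""

from __future__ import annotations

import random
import re

import networkx as nx

from nfstruct.graph_build import SPECIFICATION, StructureGraph


# ---------------------------------------------------------------------------
# random structure graphs (for contraction / metrics properties)

def random_structure_graph(seed: int, max_nodes: int = 12,
                           p_extra_edge: float = 0.25,
                           p_cycle: float = 0.2) -> StructureGraph:
    """A random mostly-DAG specification graph with mixed node kinds."""
    rng = random.Random(seed)
    n = rng.randint(1, max_nodes)
    g = nx.MultiDiGraph()
    kinds = []
    for i in range(n):
        kind = rng.choice(["process", "starting_op", "following_op", "process"])
        kinds.append(kind)
        g.add_node(f"n{i}", label=f"N{i}", kind=kind)
    for i in range(1, n):
        j = rng.randrange(i)
        g.add_edge(f"n{j}", f"n{i}", label=f"ch{j}_{i}")
        if rng.random() < p_extra_edge and i >= 2:
            k = rng.randrange(i)
            g.add_edge(f"n{k}", f"n{i}", label=f"ch{k}_{i}b")
    if n >= 3 and rng.random() < p_cycle:
        # one back edge to license cycles
        a, b = sorted(rng.sample(range(n), 2))
        g.add_edge(f"n{b}", f"n{a}", label="back")
    return StructureGraph(level=SPECIFICATION, g=g)


# ---------------------------------------------------------------------------
# contraction oracle: removed-internal paths via explicit path enumeration

def oracle_contract_edges(g: StructureGraph, keep) -> set:
    """Edge set u->v s.t. a directed path exists whose internal nodes are all
    removed, found by enumerating simple paths with networkx."""
    dg = nx.DiGraph()
    dg.add_nodes_from(g.g.nodes)
    dg.add_edges_from((u, v) for u, v, _ in g.g.edges(keys=True))
    kept = [x for x in g.g.nodes if keep(x)]
    out = set()
    for u in kept:
        for v in kept:
            if u == v:
                if dg.has_edge(u, u):
                    out.add((u, u))
                    continue
                found = False
                for r in dg.successors(u):
                    if keep(r):
                        continue
                    for p in nx.all_simple_paths(dg, r, u):
                        if all(not keep(x) for x in p[:-1]):
                            found = True
                            break
                    if found:
                        break
                if found:
                    out.add((u, u))
            else:
                if dg.has_edge(u, v):
                    out.add((u, v))
                    continue
                for p in nx.all_simple_paths(dg, u, v):
                    if all(not keep(x) for x in p[1:-1]):
                        out.add((u, v))
                        break
    return out


def oracle_reachable_pairs(g, nodes) -> set:
    """Transitive-closure oracle: ordered pairs (u, v), u != v, u reaches v."""
    dg = nx.DiGraph()
    dg.add_nodes_from(g.g.nodes)
    dg.add_edges_from((u, v) for u, v, _ in g.g.edges(keys=True))
    node_set = set(nodes)
    out = set()
    for u in nodes:
        for v in nx.descendants(dg, u):
            if v in node_set and v != u:
                out.add((u, v))
    return out


# ---------------------------------------------------------------------------
# metrics oracle: exhaustive simple-path enumeration

def enumerate_simple_paths(g: StructureGraph) -> list[list[str]]:
    dg = nx.DiGraph()
    dg.add_nodes_from(g.g.nodes)
    dg.add_edges_from((u, v) for u, v, _ in g.g.edges(keys=True))
    paths: list[list[str]] = []

    def rec(path: list[str]) -> None:
        paths.append(list(path))
        for v in dg.successors(path[-1]):
            if v not in path:
                path.append(v)
                rec(path)
                path.pop()

    for n in dg.nodes:
        rec([n])
    return paths


def oracle_path_stats(g: StructureGraph):
    """(n_source_to_sink_simple_paths, longest_path_edges) by enumeration."""
    dg = nx.DiGraph()
    dg.add_nodes_from(g.g.nodes)
    dg.add_edges_from((u, v) for u, v, _ in g.g.edges(keys=True))
    sources = {n for n in dg.nodes if dg.in_degree(n) == 0}
    sinks = {n for n in dg.nodes if dg.out_degree(n) == 0}
    paths = enumerate_simple_paths(g)
    n_paths = sum(1 for p in paths
                  if len(p) >= 2 and p[0] in sources and p[-1] in sinks)
    longest = max((len(p) - 1 for p in paths), default=0)
    return n_paths, longest


# ---------------------------------------------------------------------------
# serialization re-parsers (grammar checks + cross-format comparison)

_MMD_NODE = re.compile(r'^    (\w+)(\["(.*)"\]|\(\["(.*)"\]\)|\(\("(.*)"\)\))$')
_MMD_EDGE = re.compile(r'^    (\w+) -->(?:\|"(.*)"\|)? (\w+)$')


def parse_mermaid(text: str):
    """Parse our flowchart dialect; raises ValueError on any unknown line."""
    lines = text.rstrip("\n").split("\n")
    if lines[0] != "flowchart TD":
        raise ValueError("missing flowchart header")
    nodes: dict[str, tuple[str, str]] = {}
    edges = []
    for line in lines[1:]:
        nm = _MMD_NODE.match(line)
        if nm:
            mid = nm.group(1)
            if nm.group(3) is not None:
                nodes[mid] = (nm.group(3), "process")
            elif nm.group(4) is not None:
                nodes[mid] = (nm.group(4), "starting_op")
            else:
                nodes[mid] = (nm.group(5), "following_op")
            continue
        em = _MMD_EDGE.match(line)
        if em:
            edges.append((em.group(1), em.group(3), em.group(2) or ""))
            continue
        raise ValueError(f"unparseable mermaid line: {line!r}")
    for u, v, _ in edges:
        if u not in nodes or v not in nodes:
            raise ValueError("edge endpoint not declared")
    return nodes, edges


_DOT_NODE = re.compile(r'^    "((?:[^"\\]|\\.)*)" \[label="((?:[^"\\]|\\.)*)", shape=(\w+)\];$')
_DOT_EDGE = re.compile(r'^    "((?:[^"\\]|\\.)*)" -> "((?:[^"\\]|\\.)*)"'
                       r'(?: \[label="((?:[^"\\]|\\.)*)"\])?;$')
_DOT_SHAPE_KIND = {"box": "process", "ellipse": "starting_op", "oval": "following_op"}


def _dot_unquote(s: str) -> str:
    return s.replace('\\"', '"').replace("\\\\", "\\")


def parse_dot(text: str):
    lines = text.rstrip("\n").split("\n")
    if lines[0] != "digraph workflow {" or lines[-1] != "}":
        raise ValueError("missing digraph frame")
    nodes: dict[str, tuple[str, str]] = {}
    edges = []
    for line in lines[1:-1]:
        nm = _DOT_NODE.match(line)
        if nm:
            nodes[_dot_unquote(nm.group(1))] = (_dot_unquote(nm.group(2)),
                                                _DOT_SHAPE_KIND[nm.group(3)])
            continue
        em = _DOT_EDGE.match(line)
        if em:
            edges.append((_dot_unquote(em.group(1)), _dot_unquote(em.group(2)),
                          _dot_unquote(em.group(3) or "")))
            continue
        raise ValueError(f"unparseable dot line: {line!r}")
    for u, v, _ in edges:
        if u not in nodes or v not in nodes:
            raise ValueError("edge endpoint not declared")
    return nodes, edges


def serialization_signature(nodes: dict, edges: list, labelled: bool):
    """Comparable (node multiset, edge multiset) keyed by display labels."""
    node_sig = sorted(nodes.values())
    edge_sig = sorted((nodes[u][0], nodes[v][0], lbl if labelled else "")
                      for u, v, lbl in edges)
    return node_sig, edge_sig


# ---------------------------------------------------------------------------
# RO-Crate structural conformance

def check_ro_crate(doc: dict) -> None:
    assert doc["@context"] == "https://w3id.org/ro/crate/1.1/context"
    graph = doc["@graph"]
    by_id = {e["@id"]: e for e in graph}
    desc = by_id["ro-crate-metadata.json"]
    assert desc["conformsTo"]["@id"].startswith("https://w3id.org/ro/crate/")
    assert desc["about"]["@id"] == "./"
    root = by_id["./"]
    assert "Dataset" in ([root["@type"]] if isinstance(root["@type"], str)
                         else root["@type"])
    main_id = root["mainEntity"]["@id"]
    main = by_id[main_id]
    types = main["@type"] if isinstance(main["@type"], list) else [main["@type"]]
    assert "ComputationalWorkflow" in types
    lang = by_id[main["programmingLanguage"]["@id"]]
    assert lang["name"] == "Nextflow"
    for part in root.get("hasPart", []):
        assert part["@id"] in by_id, f"dangling hasPart {part['@id']}"
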