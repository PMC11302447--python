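"""Contraction correctness, reachability preservation, closure variant."""

import networkx as nx
import pytest

from helpers import (oracle_contract_edges, oracle_reachable_pairs,
                     random_structure_graph)
from nfstruct.graph_build import SPECIFICATION, StructureGraph
from nfstruct.graph_simplify import (contract_graph, derive_dependency_graph,
                                     derive_process_dependency_graph)


def chain_graph(*kinds):
    g = nx.MultiDiGraph()
    for i, k in enumerate(kinds):
        g.add_node(f"n{i}", label=f"N{i}", kind=k)
        if i:
            g.add_edge(f"n{i-1}", f"n{i}", label=f"c{i}")
    return StructureGraph(level=SPECIFICATION, g=g)


class TestContractGraph:
    def test_keep_everything_is_identity_modulo_labels(self):
        g = chain_graph("starting_op", "process", "following_op")
        out = contract_graph(g, lambda n: True)
        assert set(out.g.nodes) == set(g.g.nodes)
        assert sorted((u, v) for u, v, _ in out.edges()) == [("n0", "n1"), ("n1", "n2")]
        assert all(l == "" for _, _, l in out.edges())

    def test_chain_through_removed_node(self):
        g = chain_graph("process", "following_op", "process")
        out = contract_graph(g, lambda n: g.kind(n) == "process")
        assert sorted(out.g.nodes) == ["n0", "n2"]
        assert [(u, v) for u, v, _ in out.edges()] == [("n0", "n2")]

    def test_parallel_duplicate_edges_collapse(self):
        g = chain_graph("process", "process")
        g.g.add_edge("n0", "n1", label="second")
        out = contract_graph(g, lambda n: True)
        assert out.n_edges == 1

    def test_no_shortcut_across_kept_mediator(self):
        # P0 -> P1 -> P2 all kept: no direct P0 -> P2 edge is added
        g = chain_graph("process", "process", "process")
        out = contract_graph(g, lambda n: True)
        assert ("n0", "n2") not in {(u, v) for u, v, _ in out.edges()}

    def test_closure_reading_adds_the_transitive_edge(self):
        g = chain_graph("process", "process", "process")
        out = contract_graph(g, lambda n: True, closure=True)
        assert ("n0", "n2") in {(u, v) for u, v, _ in out.edges()}

    def test_self_loop_only_from_cycle_through_removed(self):
        g = chain_graph("process", "following_op")
        g.g.add_edge("n1", "n0", label="back")  # cycle n0 -> n1 -> n0
        out = contract_graph(g, lambda n: g.kind(n) == "process")
        assert [(u, v) for u, v, _ in out.edges()] == [("n0", "n0")]
        # without the cycle no self-loop appears
        g2 = chain_graph("process", "following_op", "process")
        out2 = contract_graph(g2, lambda n: g2.kind(n) == "process")
        assert all(u != v for u, v, _ in out2.edges())

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_path_enumeration_oracle(self, seed):
        g = random_structure_graph(seed)
        for keep in (lambda n: g.kind(n) in ("process", "starting_op"),
                     lambda n: g.kind(n) == "process"):
            got = {(u, v) for u, v, _ in contract_graph(g, keep).edges()}
            assert got == oracle_contract_edges(g, keep), f"seed={seed}"

    @pytest.mark.parametrize("seed", range(30))
    def test_contraction_is_idempotent(self, seed):
        g = random_structure_graph(seed)
        keep = lambda n: g.kind(n) == "process"
        once = contract_graph(g, keep, level="process")
        twice = contract_graph(once, lambda n: once.kind(n) == "process",
                               level="process")
        assert set(once.g.nodes) == set(twice.g.nodes)
        assert {(u, v) for u, v, _ in once.edges()} == \
               {(u, v) for u, v, _ in twice.edges()}


class TestDerivedLevels:
    def test_levels_and_monotone_node_sets(self):
        g = chain_graph("starting_op", "following_op", "process", "process")
        dep = derive_dependency_graph(g)
        proc = derive_process_dependency_graph(g)
        assert dep.level == "dependency" and proc.level == "process"
        assert set(proc.g.nodes) <= set(dep.g.nodes) <= set(g.g.nodes)
        assert all(dep.kind(n) != "following_op" for n in dep.g.nodes)
        assert all(proc.kind(n) == "process" for n in proc.g.nodes)

    def test_graph_without_following_ops_unchanged(self):
        g = chain_graph("starting_op", "process", "process")
        dep = derive_dependency_graph(g)
        assert set(dep.g.nodes) == set(g.g.nodes)
        assert {(u, v) for u, v, _ in dep.edges()} == \
               {(u, v) for u, v, _ in g.edges()}

    def test_starting_op_to_process_through_op(self):
        g = chain_graph("starting_op", "following_op", "process")
        dep = derive_dependency_graph(g)
        assert [(u, v) for u, v, _ in dep.edges()] == [("n0", "n2")]

    def test_zero_process_graph_contracts_to_empty(self):
        g = chain_graph("starting_op", "following_op")
        proc = derive_process_dependency_graph(g)
        assert proc.n_nodes == 0 and proc.n_edges == 0

    @pytest.mark.parametrize("seed", range(60))
    def test_reachability_preserved_for_kept_pairs(self, seed):
        g = random_structure_graph(seed)
        for derive in (derive_dependency_graph, derive_process_dependency_graph):
            out = derive(g)
            kept = list(out.g.nodes)
            assert oracle_reachable_pairs(out, kept) == \
                   oracle_reachable_pairs(g, kept), f"seed={seed}"
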