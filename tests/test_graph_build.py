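"""Specification-graph assembly and operation classification."""

import networkx as nx

from nfstruct.extract import load_project
from nfstruct.diagnostics import validate_project
from nfstruct.fixtures import generate_workflow_fixture
from nfstruct.graph_build import build_specification_graph

PROC = """process {name} {{
    input:
    val x

    output:
    path 'o.txt'

    script:
    \"\"\"
    echo hi
    \"\"\"
}}
"""


def _graph(project_dir, body, defs=""):
    main = project_dir({
        "main.nf": ("nextflow.enable.dsl=2\n" + defs + "\nworkflow {\n"
                    + "".join(f"    {l}\n" for l in body) + "}\n")})
    project = load_project(main)
    assert validate_project(project) == []
    return build_specification_graph(project)


class TestBuild:
    def test_three_node_chain(self, project_dir):
        g = _graph(project_dir,
                   ["ch = Channel.of(1)", "P(ch)", "P.out.view()"],
                   PROC.format(name="P"))
        kinds = sorted(k for _, _, k in g.nodes())
        assert kinds == ["following_op", "process", "starting_op"]
        assert g.n_edges == 2
        labels = sorted(l for _, _, l in g.edges())
        assert labels == ["P.out", "ch"]

    def test_empty_entry_workflow(self, project_dir):
        g = _graph(project_dir, [])
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_conditional_feedback_forms_cycle(self, project_dir):
        # a conditional rewires a downstream product back onto an
        # upstream-consumed channel name: both instances are represented
        # together, so the union has a strongly connected component
        g = _graph(project_dir, [
            "src = Channel.of(1)",
            "if (params.again) {",
            "    mid = fin.map { it }",
            "} else {",
            "    mid = src.map { it }",
            "}",
            "fin = mid.filter { it }",
        ])
        sccs = list(nx.strongly_connected_components(nx.DiGraph(g.g)))
        assert max(len(s) for s in sccs) > 1

    def test_two_instances_under_aliases_stay_distinct(self, project_dir):
        main = project_dir({
            "main.nf": ("nextflow.enable.dsl=2\n"
                        "include { P; P as P2 } from './m'\n"
                        "workflow {\n    ch = Channel.of(1)\n"
                        "    P(ch)\n    P2(ch)\n}\n"),
            "m.nf": PROC.format(name="P"),
        })
        project = load_project(main)
        assert validate_project(project) == []
        g = build_specification_graph(project)
        assert sorted(l for _, l, k in g.nodes() if k == "process") == ["P", "P2"]

    def test_subworkflow_flattened_into_caller(self, project_dir):
        sub = ("workflow SUB {\n    take:\n    t\n\n    main:\n"
               "    m = t.map { it }\n    P(m)\n\n    emit:\n    o = P.out\n}\n")
        g = _graph(project_dir,
                   ["ch = Channel.of(1)", "SUB(ch)", "SUB.out.o.view()"],
                   PROC.format(name="P") + sub)
        # no subworkflow node: factory, internal op, process, sink
        assert g.n_nodes == 4
        assert sorted(k for _, _, k in g.nodes()) == [
            "following_op", "following_op", "process", "starting_op"]
        # the spliced emit edge carries the inner channel
        assert ("P.out" in {l for _, _, l in g.edges()})

    def test_node_count_matches_calls_plus_operations(self, project_dir, tmp_path):
        from nfstruct.fixtures import emit_nextflow_source
        fx = generate_workflow_fixture(4, 6, dsl="DSL2", p_branch=0.3,
                                       p_multifile=0.5, seed=5)
        d = tmp_path / "fx"
        emit_nextflow_source(fx, d)
        project = load_project(d / "main.nf")
        assert validate_project(project) == []
        g = build_specification_graph(project)
        w = project.wiring
        n_proc_calls = sum(1 for c in w.calls if c.callee_kind == "process")
        assert g.n_nodes == n_proc_calls + len(w.operations)


class TestClassification:
    def test_factory_is_starting(self, project_dir):
        g = _graph(project_dir, ["ch = Channel.of(1)"])
        assert [k for _, _, k in g.nodes()] == ["starting_op"]

    def test_map_on_process_output_is_following(self, project_dir):
        g = _graph(project_dir,
                   ["ch = Channel.of(1)", "P(ch)", "x = P.out.map { it }"],
                   PROC.format(name="P"))
        assert [k for _, l, k in g.nodes() if l == "map"] == ["following_op"]

    def test_dangling_input_operation_is_following(self, project_dir):
        # `unseen` has no producer: the op is a graph source but still has a
        # declared input, so it is a following operation
        g = _graph(project_dir, ["x = unseen.map { it }"])
        (node,) = g.nodes()
        assert node[2] == "following_op"
        assert g.g.in_degree(node[0]) == 0

    def test_determinism_of_ids_and_edges(self, project_dir, tmp_path):
        from nfstruct.fixtures import emit_nextflow_source
        fx = generate_workflow_fixture(3, 5, dsl="DSL2", seed=11)
        d = tmp_path / "det"
        emit_nextflow_source(fx, d)
        g1 = build_specification_graph(load_project(d / "main.nf"))
        g2 = build_specification_graph(load_project(d / "main.nf"))
        assert list(g1.g.nodes) == list(g2.g.nodes)
        assert list(g1.g.edges(data=True)) == list(g2.g.edges(data=True))
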