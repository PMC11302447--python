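"""Mermaid/DOT serialization, PNG fallback, and RO-Crate generation."""

import json

import networkx as nx
import pytest

from helpers import (check_ro_crate, parse_dot, parse_mermaid,
                     serialization_signature)
from nfstruct.export import build_ro_crate, parse_manifest, render_png, to_dot, to_mermaid
from nfstruct.extract import load_project
from nfstruct.diagnostics import validate_project
from nfstruct.fixtures import emit_nextflow_source, generate_workflow_fixture
from nfstruct.graph_build import SPECIFICATION, StructureGraph, build_specification_graph


def tiny_graph():
    g = nx.MultiDiGraph()
    g.add_node("a b", label="P1", kind="process")  # id with a space
    g.add_node("c", label="map", kind="following_op")
    g.add_edge("a b", "c", label="ch")
    return StructureGraph(level=SPECIFICATION, g=g)


class TestMermaid:
    def test_empty_graph_is_header_only(self):
        assert to_mermaid(StructureGraph(level=SPECIFICATION)) == "flowchart TD\n"

    def test_edge_rendered_with_arrow(self):
        text = to_mermaid(tiny_graph())
        nodes, edges = parse_mermaid(text)
        assert len(edges) == 1 and edges[0][2] == ""

    def test_labels_flag_adds_channel_names(self):
        nodes, edges = parse_mermaid(to_mermaid(tiny_graph(), show_labels=True))
        assert edges[0][2] == "ch"

    def test_quote_in_label_escaped(self):
        g = tiny_graph()
        g.g.nodes["c"]["label"] = 'say "hi"'
        nodes, _ = parse_mermaid(to_mermaid(g))
        assert ("say #quot;hi#quot;", "following_op") in nodes.values()


class TestDot:
    def test_empty_graph(self):
        assert to_dot(StructureGraph(level=SPECIFICATION)) == "digraph workflow {\n}\n"

    def test_identifiers_quoted(self):
        text = to_dot(tiny_graph())
        assert '"a b"' in text
        parse_dot(text)  # grammar-clean

    def test_shapes_encode_kinds(self):
        nodes, _ = parse_dot(to_dot(tiny_graph()))
        assert nodes["a b"] == ("P1", "process")
        assert nodes["c"] == ("map", "following_op")


class TestCrossFormat:
    @pytest.mark.parametrize("seed", range(10))
    def test_mermaid_and_dot_encode_identical_sets(self, seed, tmp_path):
        fx = generate_workflow_fixture(3, 5, dsl="DSL2", p_multifile=0.5, seed=seed)
        d = tmp_path / "fx"
        emit_nextflow_source(fx, d)
        project = load_project(d / "main.nf")
        assert validate_project(project) == []
        g = build_specification_graph(project)
        m = serialization_signature(*parse_mermaid(to_mermaid(g, show_labels=True)),
                                    labelled=True)
        dsig = serialization_signature(*parse_dot(to_dot(g, show_labels=True)),
                                       labelled=True)
        assert m == dsig
        # every node and edge appears exactly once
        assert len(m[0]) == g.n_nodes and len(m[1]) == g.n_edges

    def test_serialization_is_deterministic(self):
        g = tiny_graph()
        assert to_mermaid(g) == to_mermaid(g)
        assert to_dot(g) == to_dot(g)


class TestRenderPng:
    def test_missing_renderer_is_a_warning_not_an_error(self, tmp_path, monkeypatch):
        monkeypatch.setattr("nfstruct.export.shutil.which", lambda _: None)
        out = render_png(to_dot(tiny_graph()), tmp_path / "g.png")
        assert out is None
        assert not (tmp_path / "g.png").exists()


class TestManifest:
    def test_manifest_block_parsed(self):
        cfg = "manifest {\n    name = 'wf'\n    author = 'A. Person'\n}\n"
        meta = parse_manifest(cfg)
        assert meta == {"name": "wf", "author": "A. Person"}

    def test_readme_title_fallback(self):
        assert parse_manifest(None, "# My Workflow\n\ntext")["name"] == "My Workflow"


class TestRoCrate:
    def _project(self, project_dir, config=None):
        files = {"main.nf": "nextflow.enable.dsl=2\nworkflow { }\n"}
        if config:
            files["nextflow.config"] = config
        return load_project(project_dir(files))

    def test_minimal_project_conformant(self, project_dir):
        doc = build_ro_crate(self._project(project_dir))
        check_ro_crate(doc)

    def test_manifest_author_verbatim(self, project_dir):
        doc = build_ro_crate(self._project(
            project_dir, config="manifest {\n    author = 'A. Person'\n}\n"))
        by_id = {e["@id"]: e for e in doc["@graph"]}
        assert by_id["#author"]["name"] == "A. Person"

    def test_no_metadata_still_valid(self, project_dir):
        doc = build_ro_crate(self._project(project_dir))
        by_id = {e["@id"]: e for e in doc["@graph"]}
        assert "name" not in by_id["./"]
        check_ro_crate(doc)

    def test_json_round_trip_unchanged(self, project_dir):
        doc = build_ro_crate(self._project(project_dir))
        assert json.loads(json.dumps(doc)) == doc

    def test_processes_listed_in_extension(self, project_dir, tmp_path):
        fx = generate_workflow_fixture(2, 3, dsl="DSL2", seed=1)
        d = tmp_path / "fx"
        emit_nextflow_source(fx, d)
        project = load_project(d / "main.nf")
        doc = build_ro_crate(project, graph_files=("spec.mmd",))
        by_id = {e["@id"]: e for e in doc["@graph"]}
        ext = by_id["#workflow-structure"]
        assert "PROC_1" in ext["nfstruct:processes"]
        assert ext["nfstruct:graphFiles"] == ["spec.mmd"]
        check_ro_crate(doc)
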