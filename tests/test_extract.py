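"""Extraction of definitions, includes, calls, operations and channels."""

import pytest

from nfstruct.diagnostics import Code, Collector, validate_project
from nfstruct.extract import (extract_process_definitions,
                              extract_subworkflow_definitions, load_project,
                              scan_includes)
from nfstruct.preprocess import NextflowFile

PROC = """process {name} {{
    input:
    val x

    output:
    path 'o.txt'{emit}

    script:
    \"\"\"
    echo hi
    \"\"\"
}}
"""


def proc(name, emit=""):
    return PROC.format(name=name, emit=emit)


def codes(diags):
    return [d.code for d in diags]


class TestProcessDefinitions:
    def test_two_blocks_two_defs(self):
        nf = NextflowFile.from_text("m.nf", proc("A") + "\n" + proc("B"))
        defs = extract_process_definitions(nf)
        assert [p.name for p in defs] == ["A", "B"]

    def test_named_emit_parsed(self):
        nf = NextflowFile.from_text("m.nf", proc("A", emit=", emit: report"))
        (p,) = extract_process_definitions(nf)
        assert [o.emit_name for o in p.output_decls] == ["report"]

    def test_duplicate_input_sections_flagged(self):
        src = ("process A {\n    input:\n    val x\n    input:\n    val y\n"
               "    output:\n    path 'o.txt'\n    script:\n"
               '    """\n    echo 1\n    """\n}\n')
        coll = Collector()
        extract_process_definitions(NextflowFile.from_text("m.nf", src), coll)
        assert codes(coll.items) == [Code.E_BAD_DEFINITION]

    def test_script_kind_detected(self):
        src = proc("A").replace("script:", "exec:")
        (p,) = extract_process_definitions(NextflowFile.from_text("m.nf", src))
        assert p.script_kind == "exec"


class TestIncludes:
    def test_resolved_include(self, project_dir):
        main = project_dir({
            "main.nf": "nextflow.enable.dsl=2\ninclude { FASTQC } from './modules/fastqc'\nworkflow { }\n",
            "modules/fastqc.nf": proc("FASTQC"),
        })
        nf = NextflowFile.from_path(main, "main.nf")
        coll = Collector()
        (inc,) = scan_includes(nf, coll, base_dir=main.parent)
        assert inc.items == [("FASTQC", None)]
        assert inc.resolved_path == "modules/fastqc.nf"
        assert not coll.items

    def test_missing_include_names_the_path(self, project_dir):
        main = project_dir({
            "main.nf": "nextflow.enable.dsl=2\ninclude { X } from './modules/gone'\nworkflow { }\n"})
        coll = Collector()
        scan_includes(NextflowFile.from_path(main, "main.nf"), coll,
                      base_dir=main.parent)
        assert codes(coll.items) == [Code.E_INCLUDE_MISSING]
        assert "gone" in coll.items[0].message

    def test_alias_resolves_to_original_definition(self, project_dir):
        main = project_dir({
            "main.nf": ("nextflow.enable.dsl=2\n"
                        "include { X as Y } from './m'\n"
                        "workflow {\n    ch = Channel.of(1)\n    Y(ch)\n}\n"),
            "m.nf": proc("X"),
        })
        project = load_project(main)
        assert validate_project(project) == []
        (call,) = project.wiring.calls
        assert call.callee_name == "Y"
        # the node label is the aliased local name
        assert project.wiring.nodes[-1].label == "Y"

    def test_include_inside_workflow_body_flagged(self, project_dir):
        main = project_dir({
            "main.nf": ("nextflow.enable.dsl=2\n"
                        "workflow {\n    include { X } from './m'\n}\n"),
            "m.nf": proc("X"),
        })
        assert codes(validate_project(load_project(main))) == [Code.E_INCLUDE_IN_WORKFLOW]

    def test_item_missing_from_included_file(self, project_dir):
        main = project_dir({
            "main.nf": ("nextflow.enable.dsl=2\n"
                        "include { NOPE } from './m'\nworkflow { }\n"),
            "m.nf": proc("X"),
        })
        assert codes(validate_project(load_project(main))) == [Code.E_UNDEFINED_ELEMENT]


class TestSubworkflowDefinitions:
    def test_entry_and_named_separated(self):
        src = "workflow { }\n\nworkflow SUB {\n    main:\n    x = Channel.of(1)\n}\n"
        defs = extract_subworkflow_definitions(NextflowFile.from_text("m.nf", src))
        assert [d.name for d in defs] == [None, "SUB"]

    def test_take_names_parsed(self):
        src = "workflow S {\n    take:\n    a\n    b\n\n    main:\n    a.view()\n}\n"
        (d,) = extract_subworkflow_definitions(NextflowFile.from_text("m.nf", src))
        assert d.takes == ["a", "b"]

    def test_duplicate_emit_sections_flagged(self):
        src = ("workflow S {\n    main:\n    x = Channel.of(1)\n"
               "    emit:\n    x\n    emit:\n    x\n}\n")
        coll = Collector()
        extract_subworkflow_definitions(NextflowFile.from_text("m.nf", src), coll)
        assert codes(coll.items) == [Code.E_BAD_DEFINITION]


class TestWorkflowBodyWiring:
    def _load(self, project_dir, body, extra=""):
        main = project_dir({
            "main.nf": ("nextflow.enable.dsl=2\n" + proc("P") + extra
                        + "\nworkflow {\n"
                        + "".join(f"    {l}\n" for l in body) + "}\n")})
        return load_project(main)

    def test_factory_then_call(self, project_dir):
        project = self._load(project_dir, ["ch = Channel.of(1, 2)", "P(ch)"])
        assert validate_project(project) == []
        w = project.wiring
        assert len(w.calls) == 1 and len(w.operations) == 1
        assert w.operations[0].operator_chain == []
        (ch,) = [c for c in w.channels if c.label == "ch"]
        assert len(ch.producers) == 1 and len(ch.consumers) == 1

    def test_chained_operators_collapse_to_one_operation(self, project_dir):
        project = self._load(project_dir, [
            "ch = Channel.of(1)", "P(ch)",
            "out = P.out.map { it }.filter { it }"])
        assert validate_project(project) == []
        op = project.wiring.operations[-1]
        assert op.operator_chain == ["map", "filter"]

    def test_empty_body_yields_nothing(self, project_dir):
        project = self._load(project_dir, [])
        assert validate_project(project) == []
        assert project.wiring.nodes == []

    def test_call_arity_mismatch(self, project_dir):
        project = self._load(project_dir, ["ch = Channel.of(1)", "P(ch, ch)"])
        assert codes(validate_project(project)) == [Code.E_ARITY]
        assert "expected 1" in validate_project(project)[0].message

    def test_channel_name_collision_with_element(self, project_dir):
        project = self._load(project_dir, ["P = Channel.of(1)"])
        assert codes(validate_project(project)) == [Code.E_NAME_COLLISION]

    def test_undefined_bare_call(self, project_dir):
        project = self._load(project_dir, ["GHOST(1)"])
        assert codes(validate_project(project)) == [Code.E_UNDEFINED_ELEMENT]

    def test_conditional_branches_both_extracted(self, project_dir):
        project = self._load(project_dir, [
            "ch = Channel.of(1)",
            "if (params.x) {",
            "    y = ch.map { it }",
            "} else {",
            "    y = ch.filter { it }",
            "}",
            "P(y)"])
        assert validate_project(project) == []
        chains = [tuple(o.operator_chain) for o in project.wiring.operations]
        assert ("map",) in chains and ("filter",) in chains
        (y,) = [c for c in project.wiring.channels if c.label == "y"]
        assert len(y.producers) == 2 and len(y.consumers) == 1


class TestPipeChains:
    def _load(self, project_dir, body, defs=None):
        defs = proc("P") if defs is None else defs
        main = project_dir({
            "main.nf": ("nextflow.enable.dsl=2\n" + defs
                        + "\nworkflow {\n"
                        + "".join(f"    {l}\n" for l in body) + "}\n")})
        return load_project(main)

    def test_factory_piped_into_process(self, project_dir):
        project = self._load(project_dir, ["ch = Channel.of(1)", "ch | P"])
        assert validate_project(project) == []
        assert len(project.wiring.calls) == 1

    def test_first_element_unknown(self, project_dir):
        project = self._load(project_dir, ["ghost | map { it }"])
        assert codes(validate_project(project)) == [Code.E_PIPE_FIRST_UNKNOWN]

    def test_unknown_stage_is_unsupported(self, project_dir):
        project = self._load(project_dir,
                             ["ch = Channel.of(1)", "ch | P | frobnicate"])
        diags = validate_project(project)
        assert codes(diags) == [Code.U_PIPE_UNKNOWN]
        assert diags[0].severity.value == "unsupported"

    def test_operator_stages_group_into_one_operation(self, project_dir):
        project = self._load(project_dir,
                             ["ch = Channel.of(1)", "out = ch | map { it } | filter { it }"])
        assert validate_project(project) == []
        op = project.wiring.operations[-1]
        assert op.operator_chain == ["map", "filter"]


class TestEmitReferences:
    def _load(self, project_dir, body, defs):
        main = project_dir({
            "main.nf": ("nextflow.enable.dsl=2\n" + defs
                        + "\nworkflow {\n"
                        + "".join(f"    {l}\n" for l in body) + "}\n")})
        return load_project(main)

    def test_single_output_out_resolves(self, project_dir):
        project = self._load(project_dir,
                             ["ch = Channel.of(1)", "P(ch)", "P.out.view()"],
                             proc("P"))
        assert validate_project(project) == []

    def test_never_called_element(self, project_dir):
        project = self._load(project_dir, ["x = Q.out.map { it }"], proc("Q"))
        assert codes(validate_project(project)) == [Code.E_EMIT_NOT_CALLED]

    def test_multi_output_process_in_single_channel_context(self, project_dir):
        two_out = PROC.format(name="M", emit=", emit: a").replace(
            "path 'o.txt', emit: a", "path 'o.txt', emit: a\n    path 'p.txt', emit: b")
        project = self._load(project_dir,
                             ["ch = Channel.of(1)", "M(ch)", "x = M.out.map { it }"],
                             two_out)
        assert codes(validate_project(project)) == [Code.E_EMIT_MULTIPLE]

    def test_subworkflow_with_two_emits_in_operation(self, project_dir):
        sub = ("workflow SUB {\n    take:\n    t\n\n    main:\n"
               "    m = t.map { it }\n\n    emit:\n    a = m\n    b = m\n}\n")
        project = self._load(project_dir,
                             ["ch = Channel.of(1)", "SUB(ch)",
                              "x = SUB.out.map { it }"], sub)
        assert codes(validate_project(project)) == [Code.E_SUBWF_EMIT_COUNT]

    def test_tuple_destructuring_of_call(self, project_dir):
        project = self._load(project_dir,
                             ["ch = Channel.of(1)", "(a, b) = P(ch)"], proc("P"))
        assert codes(validate_project(project)) == [Code.U_TUPLE_CALL]

    def test_ternary_tuple(self, project_dir):
        project = self._load(project_dir,
                             ["(a, b) = params.x ? [1, 2] : [3, 4]"], proc("P"))
        assert codes(validate_project(project)) == [Code.U_TERNARY_TUPLE]


class TestDsl1Wiring:
    def test_set_and_into_create_named_channels(self, project_dir):
        main = project_dir({"main.nf": (
            "reads = Channel.fromPath('*.fq')\n"
            "reads.into { a; b }\n"
            "a.map { it }.set { c }\n")})
        project = load_project(main)
        assert validate_project(project) == []
        assert project.dsl.value == "DSL1"
        table = project.wiring.channel_tables["main"]
        assert set(table) == {"reads", "a", "b", "c"}
        into_op = [o for o in project.wiring.operations
                   if o.operator_chain == ["into"]][0]
        assert len(into_op.produced) == 2

    def test_process_wired_by_from_and_into(self, project_dir):
        main = project_dir({"main.nf": (
            "reads = Channel.fromPath('*.fq')\n"
            + PROC.format(name="M", emit="").replace("val x", "val x from reads")
                 .replace("path 'o.txt'", "file 'o.txt' into results")
            + "results.view()\n")})
        project = load_project(main)
        assert validate_project(project) == []
        table = project.wiring.channel_tables["main"]
        assert len(table["reads"].consumers) == 1
        assert len(table["results"].producers) == 1

    def test_extraction_is_deterministic(self, project_dir, tmp_path):
        src = {"main.nf": ("reads = Channel.fromPath('*.fq')\n"
                           "reads.set { x }\n")}
        main = project_dir(src)
        p1, p2 = load_project(main), load_project(main)
        ids1 = [n.id for n in p1.wiring.nodes]
        ids2 = [n.id for n in p2.wiring.nodes]
        assert ids1 == ids2
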