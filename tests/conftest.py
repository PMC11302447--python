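from __future__ import annotations

from pathlib import Path

import pytest

from nfstruct.diagnostics import validate_project
from nfstruct.extract import load_project
from nfstruct.fixtures import emit_nextflow_source
from nfstruct.graph_build import build_specification_graph


@pytest.fixture
def project_dir(tmp_path):
    """Write a dict of path -> source under tmp_path; returns main.nf path."""

    def write(files: dict[str, str], main: str = "main.nf") -> Path:
        for rel, text in files.items():
            dest = tmp_path / rel
            dest.parent.mkdir(parents=True, exist_ok=True)
            dest.write_text(text, encoding="utf-8")
        return tmp_path / main

    return write


@pytest.fixture
def analyze_fixture(tmp_path):
    """Emit a generated fixture and load it; returns (project, diagnostics)."""

    counter = [0]

    def run(fixture):
        counter[0] += 1
        d = tmp_path / f"fx{counter[0]}"
        emit_nextflow_source(fixture, d)
        project = load_project(d / "main.nf")
        return project, validate_project(project)

    return run


@pytest.fixture
def spec_graph_of(analyze_fixture):
    """Parse a clean fixture into its specification graph (asserting clean)."""

    def run(fixture):
        project, diags = analyze_fixture(fixture)
        assert diags == [], [f"{d.code.value}: {d.message}" for d in diags]
        return build_specification_graph(project)

    return run
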