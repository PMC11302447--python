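"""Serialization of structure graphs (Mermaid, DOT, optional PNG) and the
RO-Crate JSON-LD description of the analysed project.

All text output is deterministic: nodes are ordered by id, edges by
(src, dst, label), so repeated runs on identical input are byte-identical and
diffable in version control.
"""

from __future__ import annotations

import json
import re
import shutil
import subprocess
import logging
from pathlib import Path
from typing import Optional

from .graph_build import StructureGraph

log = logging.getLogger("nfstruct")

RO_CRATE_CONTEXT = "https://w3id.org/ro/crate/1.1/context"
RO_CRATE_PROFILE = "https://w3id.org/ro/crate/1.1"


# ---------------------------------------------------------------------------
# graph serialization

def _sorted_nodes(g: StructureGraph):
    return sorted(g.g.nodes(data=True), key=lambda nd: nd[0])


def _sorted_edges(g: StructureGraph):
    return sorted(((u, v, d.get("label", "")) for u, v, d in g.g.edges(data=True)),
                  key=lambda e: (e[0], e[1], e[2]))


def _mermaid_escape(text: str) -> str:
    return text.replace('"', "#quot;")


def to_mermaid(g: StructureGraph, show_labels: bool = False) -> str:
    """Render as a Mermaid ``flowchart TD`` document.

    Processes are rectangles, starting operations stadium-shaped, following
    operations circles.  Edge labels carry channel names at the specification
    level when *show_labels* is set.
    """
    lines = ["flowchart TD"]
    ids = {n: f"n{i}" for i, (n, _) in enumerate(_sorted_nodes(g))}
    for n, d in _sorted_nodes(g):
        label = _mermaid_escape(d.get("label", n))
        kind = d.get("kind", "")
        mid = ids[n]
        if kind == "process":
            lines.append(f'    {mid}["{label}"]')
        elif kind == "starting_op":
            lines.append(f'    {mid}(["{label}"])')
        else:
            lines.append(f'    {mid}(("{label}"))')
    for u, v, label in _sorted_edges(g):
        if show_labels and label:
            lines.append(f'    {ids[u]} -->|"{_mermaid_escape(label)}"| {ids[v]}')
        else:
            lines.append(f"    {ids[u]} --> {ids[v]}")
    return "\n".join(lines) + "\n"


def _dot_quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


_DOT_SHAPES = {"process": "box", "starting_op": "ellipse", "following_op": "oval"}


def to_dot(g: StructureGraph, show_labels: bool = False) -> str:
    """Render as a Graphviz DOT ``digraph`` with quoted identifiers."""
    lines = ["digraph workflow {"]
    for n, d in _sorted_nodes(g):
        shape = _DOT_SHAPES.get(d.get("kind", ""), "oval")
        attrs = f"label={_dot_quote(d.get('label', n))}, shape={shape}"
        lines.append(f"    {_dot_quote(n)} [{attrs}];")
    for u, v, label in _sorted_edges(g):
        attr = f" [label={_dot_quote(label)}]" if show_labels and label else ""
        lines.append(f"    {_dot_quote(u)} -> {_dot_quote(v)}{attr};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def render_png(dot_text: str, out_path: Path) -> Optional[Path]:
    """Render DOT text to PNG via the ``dot`` executable, if present.

    PNG output is optional: when no renderer is on PATH the function logs a
    warning and returns None instead of failing.
    """
    exe = shutil.which("dot")
    if exe is None:
        log.warning("graphviz 'dot' executable not found; skipping PNG rendering")
        return None
    try:
        subprocess.run([exe, "-Tpng", "-o", str(out_path)], input=dot_text.encode(),
                       check=True, capture_output=True)
    except (OSError, subprocess.CalledProcessError) as exc:
        log.warning("PNG rendering failed: %s", exc)
        return None
    return Path(out_path)


# ---------------------------------------------------------------------------
# project metadata

_MANIFEST_KEYS = ("name", "author", "description", "homePage", "mainScript",
                  "version", "nextflowVersion")


def parse_manifest(config_source: Optional[str], readme_source: Optional[str] = None) -> dict:
    """Recover name/author/description/... from the config manifest block,
    falling back to a README title for the name."""
    meta: dict = {}
    if config_source:
        m = re.search(r"manifest\s*\{", config_source)
        if m:
            depth = 0
            start = config_source.index("{", m.start())
            end = start
            for i in range(start, len(config_source)):
                if config_source[i] == "{":
                    depth += 1
                elif config_source[i] == "}":
                    depth -= 1
                    if depth == 0:
                        end = i
                        break
            block = config_source[start + 1 : end]
            for key in _MANIFEST_KEYS:
                km = re.search(rf"{key}\s*=\s*(['\"])(.*?)\1", block)
                if km:
                    meta[key] = km.group(2)
    if "name" not in meta and readme_source:
        tm = re.match(r"#\s*(.+)", readme_source.strip())
        if tm:
            meta["name"] = tm.group(1).strip()
    return meta


# ---------------------------------------------------------------------------
# RO-Crate

def build_ro_crate(project, graph_files: tuple = ()) -> dict:
    """Build an RO-Crate JSON-LD document describing the project.

    The crate follows the base profile: a metadata descriptor, a root dataset
    whose ``mainEntity`` is the main file typed as a ComputationalWorkflow in
    the Nextflow language, one File entity per project file, and recovered
    name/description/author metadata.  Extracted processes and subworkflows
    are attached under a clearly namespaced extension entity.
    """
    meta = parse_manifest(project.config_source, project.readme_source)
    main = project.main_path

    descriptor = {
        "@id": "ro-crate-metadata.json",
        "@type": "CreativeWork",
        "conformsTo": {"@id": RO_CRATE_PROFILE},
        "about": {"@id": "./"},
    }
    file_ids = sorted(project.files)
    root: dict = {
        "@id": "./",
        "@type": "Dataset",
        "mainEntity": {"@id": main},
        "hasPart": [{"@id": fid} for fid in file_ids],
    }
    if "name" in meta:
        root["name"] = meta["name"]
    if "description" in meta:
        root["description"] = meta["description"]
    if "author" in meta:
        root["author"] = {"@id": "#author"}

    processes = sorted(p.name for fe in project.elements.values() for p in fe.processes)
    subworkflows = sorted(w.name for fe in project.elements.values()
                          for w in fe.workflows if w.name)

    entities = [descriptor, root]
    for fid in file_ids:
        ent: dict = {"@id": fid, "@type": "File"}
        if fid == main:
            ent["@type"] = ["File", "SoftwareSourceCode", "ComputationalWorkflow"]
            ent["programmingLanguage"] = {"@id": "#nextflow"}
            ent["name"] = meta.get("name", main)
            if processes:
                ent["hasPart"] = [{"@id": f"#process-{p}"} for p in processes]
        entities.append(ent)
    entities.append({
        "@id": "#nextflow",
        "@type": "ComputerLanguage",
        "name": "Nextflow",
        "identifier": "https://www.nextflow.io/",
        "url": "https://www.nextflow.io/",
    })
    if "author" in meta:
        entities.append({"@id": "#author", "@type": "Person", "name": meta["author"]})
    for p in processes:
        entities.append({"@id": f"#process-{p}", "@type": "SoftwareSourceCode",
                         "name": p})
    extension: dict = {
        "@id": "#workflow-structure",
        "@type": "CreativeWork",
        "name": "statically reconstructed workflow structure",
        "nfstruct:processes": processes,
        "nfstruct:subworkflows": subworkflows,
        "nfstruct:dsl": project.dsl.value if project.dsl else None,
    }
    if graph_files:
        extension["nfstruct:graphFiles"] = sorted(graph_files)
    entities.append(extension)

    return {"@context": RO_CRATE_CONTEXT, "@graph": entities}


def write_ro_crate(project, out_dir: Path, graph_files: tuple = ()) -> Path:
    doc = build_ro_crate(project, graph_files)
    path = Path(out_dir) / "ro-crate-metadata.json"
    path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    return path
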