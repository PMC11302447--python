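"""Extraction of processes, subworkflows, includes, calls and operations.

The analysis is extraction-based: rather than parsing full Groovy, the cleaned
and string-masked views from :mod:`nfstruct.preprocess` are scanned for the
handful of constructs that determine workflow structure — ``process`` and
``workflow`` blocks, ``include`` directives, function definitions, and the
statements inside workflow bodies (channel factories, operator chains, process
and subworkflow calls, pipe chains, conditional branches).

Loading a project runs in phases mirroring how the information depends on
itself:

1. *preprocess* — clean the main file, tally brackets, identify the DSL;
2. *extract* — parse every reachable file (recursing through DSL2 includes)
   into definitions, and resolve include items;
3. *wire* — walk the entry workflow's statements, resolving calls and binding
   channels into a flat node/channel model (subworkflow calls are inlined with
   their take/emit channels spliced onto the caller's).

Each phase only starts when the previous one produced no diagnostics; within a
phase all findings are collected before stopping, so a user sees every
same-phase problem at once.
"""

from __future__ import annotations

import logging
import posixpath
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

from .diagnostics import Code, Collector, Diagnostic
from .preprocess import DslVersion, NextflowFile, detect_dsl_version

log = logging.getLogger("nfstruct")

# ---------------------------------------------------------------------------
# operator vocabulary

#: Recognized channel operators (editable registry).  Unknown method calls on
#: channel expressions are treated as operators with a warning — except inside
#: pipe chains, where an unknown stage is an unsupported pattern.
OPERATORS = {
    "map", "filter", "flatten", "flatMap", "collect", "collectFile", "mix",
    "join", "combine", "concat", "cross", "groupTuple", "splitCsv",
    "splitText", "splitFasta", "splitFastq", "unique", "distinct", "first",
    "last", "take", "count", "sum", "min", "max", "ifEmpty", "view", "set",
    "into", "branch", "multiMap", "merge", "transpose", "buffer", "collate",
    "randomSample", "toList", "toSortedList", "toInteger", "dump", "tap",
    "until", "subscribe", "reduce", "groupBy", "phase", "choice",
}

#: Operators whose arguments may themselves be channels.
CHANNEL_ARG_OPERATORS = {"mix", "join", "combine", "concat", "cross", "merge", "phase", "tap"}

#: Channel factory methods on ``Channel`` / ``channel``.
FACTORIES = {"of", "from", "fromPath", "fromFilePairs", "fromSRA", "fromList",
             "value", "empty", "watchPath"}

#: Groovy/Nextflow calls that are structurally inert.
BUILTIN_CALLS = {"println", "print", "error", "exit", "assert", "file", "log",
                 "sleep", "String", "Integer", "Math"}

_INPUT_QUALIFIERS = {"val", "path", "file", "tuple", "env", "stdin", "each", "set"}


# ---------------------------------------------------------------------------
# domain types

@dataclass
class InputDecl:
    qualifier: str
    name: str
    from_channel: Optional[str] = None  # DSL1 wiring
    raw: str = ""


@dataclass
class OutputDecl:
    qualifier: str
    expr: str
    emit_name: Optional[str] = None
    into_channels: Tuple[str, ...] = ()  # DSL1 wiring
    raw: str = ""


@dataclass
class ProcessDef:
    name: str
    input_decls: list[InputDecl]
    output_decls: list[OutputDecl]
    script_kind: str  # script | shell | exec
    file: str
    span: Tuple[int, int]  # start-line, end-line

    @property
    def arity(self) -> int:
        return len(self.input_decls)


@dataclass
class Statement:
    """One workflow-body statement with aligned cleaned/masked text."""

    text: str
    masked: str
    file: NextflowFile
    offset: int  # char offset of the statement start in the file

    @property
    def span(self) -> Tuple[int, int]:
        return self.file.locate(self.offset)


@dataclass
class SubworkflowDef:
    name: Optional[str]  # None = anonymous entry workflow
    takes: list[str]
    body_statements: list[Statement]
    emit_statements: list[Statement]
    file: str
    span: Tuple[int, int]

    @property
    def arity(self) -> int:
        return len(self.takes)


@dataclass
class FunctionDef:
    name: str
    file: str
    span: Tuple[int, int]


@dataclass
class IncludeDirective:
    items: list[Tuple[str, Optional[str]]]  # (name, alias-or-None)
    source_path: str
    resolved_path: Optional[str]
    file: str
    span: Tuple[int, int]
    offset: int = 0


@dataclass
class Channel:
    """A data conduit: producers and consumers are node ids."""

    key: str
    label: str
    producers: list[str] = field(default_factory=list)
    consumers: list[str] = field(default_factory=list)


@dataclass
class Node:
    """A future graph node: a process call instance or an operation."""

    id: str
    label: str
    kind: str  # "process" | "operation"
    span: Tuple[str, int, int]  # file, line, col
    consumed: list[Channel] = field(default_factory=list)
    produced: list[Channel] = field(default_factory=list)
    operator_chain: list[str] = field(default_factory=list)
    enclosing: str = ""


@dataclass
class CallSite:
    callee_name: str
    callee_kind: str  # "process" | "subworkflow"
    args: list[str]
    enclosing_workflow: str
    span: Tuple[str, int, int]
    instance_id: str


@dataclass
class CallRecord:
    """Wiring-time record of one call: local name plus its output channels."""

    local_name: str
    kind: str
    outputs: list[Tuple[Optional[str], Channel]]  # (emit name, channel)
    node_id: Optional[str]


# ---------------------------------------------------------------------------
# text utilities (all structural scanning runs on masked text)

_OPENERS = "({["
_CLOSERS = ")}]"


def find_matching(masked: str, open_idx: int) -> int:
    """Index of the delimiter matching ``masked[open_idx]`` (pre-balanced text)."""
    opener = masked[open_idx]
    closer = {"(": ")", "{": "}", "[": "]"}[opener]
    depth = 0
    for i in range(open_idx, len(masked)):
        c = masked[i]
        if c == opener:
            depth += 1
        elif c == closer:
            depth -= 1
            if depth == 0:
                return i
    return len(masked) - 1


def top_level_split(masked: str, sep: str) -> list[Tuple[int, int]]:
    """Spans between single-char separators occurring at bracket depth 0.

    ``||`` is not treated as a pipe separator when splitting on ``|``.
    """
    spans = []
    depth = 0
    start = 0
    i = 0
    n = len(masked)
    while i < n:
        c = masked[i]
        if c in _OPENERS:
            depth += 1
        elif c in _CLOSERS:
            depth -= 1
        elif c == sep and depth == 0:
            if sep == "|" and (masked[i + 1 : i + 2] == "|" or masked[i - 1 : i] == "|"):
                i += 1
                continue
            spans.append((start, i))
            start = i + 1
        i += 1
    spans.append((start, n))
    return spans


def _find_assignment(masked: str) -> int:
    """Offset of a top-level ``=`` (not ==, <=, >=, !=, augmented), or -1."""
    depth = 0
    for i, c in enumerate(masked):
        if c in _OPENERS:
            depth += 1
        elif c in _CLOSERS:
            depth -= 1
        elif c == "=" and depth == 0:
            prev = masked[i - 1] if i else ""
            nxt = masked[i + 1] if i + 1 < len(masked) else ""
            if prev not in "=!<>+-*/%&|^" and nxt != "=" and nxt != "~":
                return i
    return -1


def _has_top_level(masked: str, char: str) -> bool:
    depth = 0
    for i, c in enumerate(masked):
        if c in _OPENERS:
            depth += 1
        elif c in _CLOSERS:
            depth -= 1
        elif c == char and depth == 0:
            if char == "|" and (masked[i + 1 : i + 2] == "|" or masked[i - 1 : i] == "|"):
                continue
            return True
    return False


def _split_segments(masked: str) -> list[Tuple[int, int]]:
    """Split a chained expression on top-level ``.`` into method segments.

    A dot directly followed by a digit (decimal literal) or preceded by
    nothing is not a segment boundary.
    """
    spans = []
    depth = 0
    start = 0
    for i, c in enumerate(masked):
        if c in _OPENERS:
            depth += 1
        elif c in _CLOSERS:
            depth -= 1
        elif c == "." and depth == 0:
            nxt = masked[i + 1 : i + 2]
            if nxt.isdigit():
                continue
            spans.append((start, i))
            start = i + 1
    spans.append((start, len(masked)))
    return spans


_SEGMENT_RE = re.compile(r"^\s*(\w+)\s*(.*)$", re.S)


def _parse_segment(masked_seg: str):
    """Return ``(name, args_span_rel or None, rest)`` for one chain segment."""
    m = _SEGMENT_RE.match(masked_seg)
    if not m:
        return None, None, ""
    name = m.group(1)
    rest = m.group(2)
    rest_off = m.start(2)
    args_span = None
    if rest.startswith("("):
        close = find_matching(rest, 0)
        args_span = (rest_off + 1, rest_off + close)
        rest = rest[close + 1 :]
    return name, args_span, rest


# ---------------------------------------------------------------------------
# per-file extraction

@dataclass
class FileElements:
    file: NextflowFile
    processes: list[ProcessDef] = field(default_factory=list)
    workflows: list[SubworkflowDef] = field(default_factory=list)
    anonymous: Optional[SubworkflowDef] = None
    functions: list[FunctionDef] = field(default_factory=list)
    includes: list[IncludeDirective] = field(default_factory=list)
    top_statements: list[Statement] = field(default_factory=list)
    items: list = field(default_factory=list)  # (kind, obj) in source order


_KW_PROCESS = re.compile(r"process\s+(\w+)\s*\{")
_KW_WORKFLOW = re.compile(r"workflow(?:\s+(\w+))?\s*\{")
_KW_INCLUDE = re.compile(r"include\s*\{")
_KW_DEF = re.compile(r"def\s+(\w+)\s*\(")
_SECTION_RE = re.compile(r"(?m)^[ \t]*(input|output|script|shell|exec|when|stub)\s*:")
_WF_SECTION_RE = re.compile(r"(?m)^[ \t]*(take|main|emit)\s*:")
_EMIT_ANNOT = re.compile(r",\s*emit\s*:\s*(\w+)")
_DSL1_FROM = re.compile(r"\bfrom\s+([\w.]+(?:\s*\.\s*\w+(?:\([^)]*\))?)*)")
_DSL1_INTO = re.compile(r"\binto\s+(.+)$")


def _line_continues(acc_masked: str, next_line: str) -> bool:
    tail = acc_masked.rstrip()
    if tail.endswith(("|", ".", ",", "=", "(", "&&", "||", "+")):
        return True
    nxt = next_line.lstrip()
    return nxt.startswith((".", "|", "else"))


def split_statements(nf: NextflowFile, start: int, end: int) -> list[Statement]:
    """Split a body span into statements (line-based, bracket-aware)."""
    cleaned = nf.cleaned_source[start:end]
    masked = nf.masked_source[start:end]
    statements: list[Statement] = []
    lines_m = masked.split("\n")
    lines_c = cleaned.split("\n")
    offs: list[int] = []
    o = 0
    for lm in lines_m:
        offs.append(o)
        o += len(lm) + 1

    i = 0
    n = len(lines_m)
    while i < n:
        if not lines_m[i].strip():
            i += 1
            continue
        begin = i
        depth = 0
        acc_m: list[str] = []
        while i < n:
            line = lines_m[i]
            acc_m.append(line)
            for c in line:
                if c in _OPENERS:
                    depth += 1
                elif c in _CLOSERS:
                    depth -= 1
            i += 1
            if depth > 0:
                continue
            nxt = lines_m[i] if i < n else ""
            if _line_continues("\n".join(acc_m), nxt):
                continue
            break
        text = "\n".join(lines_c[begin:i])
        mtext = "\n".join(lines_m[begin:i])
        lead = len(mtext) - len(mtext.lstrip())
        statements.append(Statement(
            text=text[lead:], masked=mtext[lead:], file=nf,
            offset=start + offs[begin] + lead))
    return statements


def _parse_process(nf: NextflowFile, name: str, body_start: int, body_end: int,
                   span: Tuple[int, int], collector: Collector) -> ProcessDef:
    masked = nf.masked_source[body_start:body_end]
    cleaned = nf.cleaned_source[body_start:body_end]
    sections: list[Tuple[str, int, int]] = []  # name, content start, header start
    for m in _SECTION_RE.finditer(masked):
        depth = 0
        for c in masked[: m.start()]:
            if c in _OPENERS:
                depth += 1
            elif c in _CLOSERS:
                depth -= 1
        if depth == 0:
            sections.append((m.group(1), m.end(), m.start()))

    names = [s[0] for s in sections]
    for sec in ("input", "output"):
        if names.count(sec) > 1:
            off = body_start + [s for s in sections if s[0] == sec][1][2]
            collector.add(Code.E_BAD_DEFINITION,
                          f"process '{name}' has multiple {sec} sections",
                          nf.path, nf.locate(off))

    def section_content(idx: int) -> Tuple[int, int]:
        start = sections[idx][1]
        end = sections[idx + 1][2] if idx + 1 < len(sections) else len(masked)
        return start, end

    input_decls: list[InputDecl] = []
    output_decls: list[OutputDecl] = []
    script_kind = "script"
    for idx, (sec, _, _) in enumerate(sections):
        s, e = section_content(idx)
        content_c = cleaned[s:e]
        if sec == "input":
            for line in content_c.split("\n"):
                line = line.strip().rstrip(";")
                if not line:
                    continue
                parts = line.split(None, 1)
                qual = parts[0] if parts[0] in _INPUT_QUALIFIERS else "val"
                rest = parts[1] if len(parts) > 1 else ""
                fm = _DSL1_FROM.search(line)
                from_ch = fm.group(1).split(".")[0].strip() if fm else None
                input_decls.append(InputDecl(qualifier=qual,
                                             name=(rest.split(",")[0].strip() or qual),
                                             from_channel=from_ch, raw=line))
        elif sec == "output":
            for line in content_c.split("\n"):
                line = line.strip().rstrip(";")
                if not line:
                    continue
                parts = line.split(None, 1)
                qual = parts[0] if parts[0] in _INPUT_QUALIFIERS else "val"
                em = _EMIT_ANNOT.search(line)
                im = _DSL1_INTO.search(line)
                into: Tuple[str, ...] = ()
                if im:
                    into = tuple(x.strip() for x in im.group(1).split(",") if x.strip())
                expr = _EMIT_ANNOT.sub("", _DSL1_INTO.sub("", line))
                output_decls.append(OutputDecl(qualifier=qual, expr=expr.strip(),
                                               emit_name=em.group(1) if em else None,
                                               into_channels=into, raw=line))
        elif sec in ("script", "shell", "exec"):
            script_kind = sec

    emit_names = [o.emit_name for o in output_decls if o.emit_name]
    if len(emit_names) != len(set(emit_names)):
        collector.add(Code.E_BAD_DEFINITION,
                      f"process '{name}' declares duplicate emit names", nf.path,
                      (span[0], 1))
    return ProcessDef(name=name, input_decls=input_decls, output_decls=output_decls,
                      script_kind=script_kind, file=nf.path, span=span)


def _parse_workflow(nf: NextflowFile, name: Optional[str], body_start: int,
                    body_end: int, span: Tuple[int, int],
                    collector: Collector) -> SubworkflowDef:
    masked = nf.masked_source[body_start:body_end]
    sections: list[Tuple[str, int, int]] = []
    for m in _WF_SECTION_RE.finditer(masked):
        depth = 0
        for c in masked[: m.start()]:
            if c in _OPENERS:
                depth += 1
            elif c in _CLOSERS:
                depth -= 1
        if depth == 0:
            sections.append((m.group(1), m.end(), m.start()))

    counts: dict[str, int] = {}
    for s in sections:
        counts[s[0]] = counts.get(s[0], 0) + 1
    for sec, cnt in counts.items():
        if cnt > 1:
            off = body_start + [s for s in sections if s[0] == sec][1][2]
            collector.add(Code.E_BAD_DEFINITION,
                          f"workflow '{name or '<entry>'}' has multiple {sec} sections",
                          nf.path, nf.locate(off))

    takes: list[str] = []
    body_statements: list[Statement] = []
    emit_statements: list[Statement] = []
    if not sections:
        body_statements = split_statements(nf, body_start, body_end)
    else:
        # content before the first section header belongs to main
        head_end = body_start + sections[0][2]
        body_statements.extend(split_statements(nf, body_start, head_end))
        for idx, (sec, cstart, _) in enumerate(sections):
            cend = body_start + (sections[idx + 1][2] if idx + 1 < len(sections)
                                 else len(masked))
            abs_start = body_start + cstart
            if sec == "take":
                for line in nf.cleaned_source[abs_start:cend].split("\n"):
                    t = line.strip().rstrip(";")
                    if t and re.fullmatch(r"\w+", t):
                        takes.append(t)
            elif sec == "main":
                body_statements.extend(split_statements(nf, abs_start, cend))
            else:
                emit_statements.extend(split_statements(nf, abs_start, cend))

    wf = SubworkflowDef(name=name, takes=takes, body_statements=body_statements,
                        emit_statements=emit_statements, file=nf.path, span=span)
    for stmt in body_statements:
        if re.match(r"include\b", stmt.masked):
            collector.add(Code.E_INCLUDE_IN_WORKFLOW,
                          f"include directive inside workflow '{name or '<entry>'}'",
                          nf.path, stmt.span, stmt.text.split("\n")[0])
    return wf


def parse_file(nf: NextflowFile, collector: Collector) -> FileElements:
    """Scan one cleaned file for its top-level constructs."""
    fe = FileElements(file=nf)
    masked = nf.masked_source
    pos = 0
    n = len(masked)
    stmt_buf_start: Optional[int] = None

    def flush_statements(upto: int) -> None:
        nonlocal stmt_buf_start
        if stmt_buf_start is None:
            return
        for st in split_statements(nf, stmt_buf_start, upto):
            fe.top_statements.append(st)
            fe.items.append(("statement", st))
        stmt_buf_start = None

    while pos < n:
        m = re.compile(r"\S").search(masked, pos)
        if not m:
            break
        pos = m.start()
        line_start = masked.rfind("\n", 0, pos) + 1
        at_line_head = masked[line_start:pos].strip() == ""

        km = _KW_PROCESS.match(masked, pos)
        if km and at_line_head:
            flush_statements(pos)
            brace = masked.index("{", km.start())
            close = find_matching(masked, brace)
            span = (nf.locate(pos)[0], nf.locate(close)[0])
            pd = _parse_process(nf, km.group(1), brace + 1, close, span, collector)
            fe.processes.append(pd)
            fe.items.append(("process", pd))
            pos = close + 1
            continue
        km = _KW_WORKFLOW.match(masked, pos)
        if km and at_line_head:
            flush_statements(pos)
            brace = masked.index("{", km.start())
            close = find_matching(masked, brace)
            span = (nf.locate(pos)[0], nf.locate(close)[0])
            wf = _parse_workflow(nf, km.group(1), brace + 1, close, span, collector)
            if wf.name is None:
                fe.anonymous = wf
            else:
                fe.workflows.append(wf)
            fe.items.append(("workflow", wf))
            pos = close + 1
            continue
        km = _KW_INCLUDE.match(masked, pos)
        if km and at_line_head:
            flush_statements(pos)
            brace = masked.index("{", km.start())
            close = find_matching(masked, brace)
            items_text = nf.cleaned_source[brace + 1 : close]
            items: list[Tuple[str, Optional[str]]] = []
            for part in re.split(r"[;\n]", items_text):
                pm = re.match(r"\s*(\w+)(?:\s+as\s+(\w+))?\s*$", part)
                if pm:
                    items.append((pm.group(1), pm.group(2)))
            fm = re.compile(r"\s*from\s*(['\"])").match(masked, close + 1)
            source_path = ""
            end = close + 1
            if fm:
                q = fm.group(1)
                qend = masked.index(q, fm.end())
                source_path = nf.cleaned_source[fm.end() : qend]
                end = qend + 1
            inc = IncludeDirective(items=items, source_path=source_path,
                                   resolved_path=None, file=nf.path,
                                   span=nf.locate(pos), offset=pos)
            fe.includes.append(inc)
            fe.items.append(("include", inc))
            pos = end
            continue
        km = _KW_DEF.match(masked, pos)
        if km and at_line_head:
            flush_statements(pos)
            paren = masked.index("(", km.start())
            pclose = find_matching(masked, paren)
            fd = FunctionDef(name=km.group(1), file=nf.path,
                             span=(nf.locate(pos)[0], nf.locate(pclose)[0]))
            bm = re.compile(r"\s*\{").match(masked, pclose + 1)
            if bm:
                bclose = find_matching(masked, bm.end() - 1)
                fd = FunctionDef(name=km.group(1), file=nf.path,
                                 span=(nf.locate(pos)[0], nf.locate(bclose)[0]))
                pos = bclose + 1
            else:
                pos = pclose + 1
            fe.functions.append(fd)
            fe.items.append(("function", fd))
            continue

        # plain top-level statement: buffer up to the next construct
        if stmt_buf_start is None:
            stmt_buf_start = pos
        nl = masked.find("\n", pos)
        eol = nl if nl != -1 else n
        depth = 0
        i = pos
        while i < n:
            c = masked[i]
            if c in _OPENERS:
                depth += 1
            elif c in _CLOSERS:
                depth -= 1
            if c == "\n" and depth == 0:
                break
            i += 1
        pos = i + 1

    flush_statements(n)
    return fe


# spec-facing wrappers -------------------------------------------------------

def extract_process_definitions(nf: NextflowFile,
                                collector: Optional[Collector] = None) -> list[ProcessDef]:
    return parse_file(nf, Collector() if collector is None else collector).processes


def extract_subworkflow_definitions(nf: NextflowFile,
                                    collector: Optional[Collector] = None) -> list[SubworkflowDef]:
    fe = parse_file(nf, Collector() if collector is None else collector)
    out = list(fe.workflows)
    if fe.anonymous is not None:
        out.insert(0, fe.anonymous)
    return out


def scan_includes(nf: NextflowFile, collector: Optional[Collector] = None,
                  base_dir: Optional[Path] = None) -> list[IncludeDirective]:
    coll = Collector() if collector is None else collector
    fe = parse_file(nf, coll)
    if base_dir is not None:
        for inc in fe.includes:
            _resolve_include(inc, base_dir, nf.path, coll)
    return fe.includes


def _resolve_include(inc: IncludeDirective, root: Path, including_rel: str,
                     collector: Collector) -> None:
    src = inc.source_path.strip()
    if not src:
        return
    if not src.endswith(".nf"):
        src = src + ".nf"
    rel = posixpath.normpath(posixpath.join(posixpath.dirname(including_rel), src))
    if (root / rel).is_file():
        inc.resolved_path = rel
    else:
        collector.add(Code.E_INCLUDE_MISSING,
                      f"included file '{inc.source_path}' does not exist "
                      f"(resolved to '{rel}')", inc.file, inc.span)


# ---------------------------------------------------------------------------
# wiring

class Wiring:
    """Flat node/channel model accumulated while walking the entry workflow."""

    def __init__(self) -> None:
        self.nodes: list[Node] = []
        self.channels: list[Channel] = []
        self.calls: list[CallSite] = []
        self.operations: list[Node] = []
        self.channel_tables: dict[str, dict[str, Channel]] = {}
        self._name_seq: dict[Tuple[str, str], int] = {}

    def next_id(self, prefix: str, name: str) -> str:
        k = (prefix, name)
        self._name_seq[k] = self._name_seq.get(k, 0) + 1
        return f"{prefix}{name}#{self._name_seq[k]}"

    def new_channel(self, key: str, label: str) -> Channel:
        ch = Channel(key=key, label=label)
        self.channels.append(ch)
        return ch


class Scope:
    """One workflow body being wired: local channels plus call history."""

    def __init__(self, project: "WorkflowProject", wiring: Wiring, namespace: dict,
                 scope_id: str, enclosing: str, collector: Collector):
        self.project = project
        self.wiring = wiring
        self.namespace = namespace  # local name -> ("process"|"subworkflow"|"function", def)
        self.id = scope_id
        self.enclosing = enclosing
        self.collector = collector
        self.channels: dict[str, Channel] = {}
        self.last_call: dict[str, CallRecord] = {}
        wiring.channel_tables[scope_id] = self.channels

    # -- channels ----------------------------------------------------------

    def get_or_create(self, name: str) -> Channel:
        ch = self.channels.get(name)
        if ch is None:
            ch = self.wiring.new_channel(f"{self.id}:{name}", name)
            self.channels[name] = ch
        return ch

    def produce(self, name: str, node: Node, stmt: Statement) -> Optional[Channel]:
        entry = self.namespace.get(name)
        if entry is not None:
            self.collector.add(
                Code.E_NAME_COLLISION,
                f"channel '{name}' collides with the {entry[0]} of the same name",
                stmt.file.path, stmt.span, stmt.text.split("\n")[0])
            return None
        ch = self.get_or_create(name)
        ch.producers.append(node.id)
        node.produced.append(ch)
        return ch

    def consume(self, ch: Channel, node: Node) -> None:
        ch.consumers.append(node.id)
        node.consumed.append(ch)

    # -- node factories ----------------------------------------------------

    def new_op_node(self, stmt: Statement, label: str, chain: list[str]) -> Node:
        nid = self.wiring.next_id(self.id + "/", "op")
        line, col = stmt.span
        node = Node(id=nid, label=label, kind="operation",
                    span=(stmt.file.path, line, col), operator_chain=chain,
                    enclosing=self.enclosing)
        self.wiring.nodes.append(node)
        self.wiring.operations.append(node)
        return node

    # -- statement wiring --------------------------------------------------

    def wire_statements(self, statements: list[Statement]) -> None:
        for stmt in statements:
            self.wire_statement(stmt)

    def wire_statement(self, stmt: Statement) -> None:
        m = stmt.masked
        if not m.strip():
            return
        if re.match(r"include\b", m):
            # already diagnosed at extraction time; never wired
            return
        if re.match(r"if\s*\(", m):
            self._wire_if(stmt)
            return
        eq = _find_assignment(m)
        if eq != -1:
            lhs_m = m[:eq]
            if re.match(r"\s*\(", lhs_m):
                self._wire_tuple_assignment(stmt, lhs_m, eq)
                return
            lm = re.fullmatch(r"\s*(\w+)\s*", lhs_m)
            if lm:
                self._wire_assignment(stmt, lm.group(1), eq)
                return
            return  # dotted / indexed target: structurally inert
        self._wire_expression_statement(stmt)

    def _wire_if(self, stmt: Statement) -> None:
        """Recurse into every conditional branch, merging them in this scope."""
        m = stmt.masked
        pos = 0
        while True:
            im = re.compile(r"if\s*\(").search(m, pos)
            if im:
                pclose = find_matching(m, m.index("(", im.start()))
                bm = re.compile(r"\s*\{").match(m, pclose + 1)
                if not bm:
                    return
                bclose = find_matching(m, bm.end() - 1)
                self._wire_branch_body(stmt, bm.end(), bclose)
                pos = bclose + 1
            em = re.compile(r"\s*else\b").match(m, pos)
            if not em:
                return
            pos = em.end()
            if re.compile(r"\s*if\s*\(").match(m, pos):
                continue  # else-if: loop handles it
            bm = re.compile(r"\s*\{").match(m, pos)
            if not bm:
                return
            bclose = find_matching(m, bm.end() - 1)
            self._wire_branch_body(stmt, bm.end(), bclose)
            return

    def _wire_branch_body(self, stmt: Statement, rel_start: int, rel_end: int) -> None:
        start = stmt.offset + rel_start
        end = stmt.offset + rel_end
        for sub in split_statements(stmt.file, start, end):
            self.wire_statement(sub)

    def _wire_tuple_assignment(self, stmt: Statement, lhs_m: str, eq: int) -> None:
        rhs_m = stmt.masked[eq + 1 :]
        if _has_top_level(rhs_m, "?"):
            self.collector.add(Code.U_TERNARY_TUPLE,
                               "ternary conditional assigned to a tuple is not supported",
                               stmt.file.path, stmt.span, stmt.text.split("\n")[0])
            return
        cm = re.match(r"\s*(\w+)\s*\(", rhs_m)
        if cm and cm.group(1) in self.namespace and \
                self.namespace[cm.group(1)][0] in ("process", "subworkflow"):
            self.collector.add(Code.U_TUPLE_CALL,
                               "tuple destructuring of a call result is not supported",
                               stmt.file.path, stmt.span, stmt.text.split("\n")[0])
            return
        # tuple of plain expressions: structurally inert

    def _wire_assignment(self, stmt: Statement, target: str, eq: int) -> None:
        rhs_c = stmt.text[eq + 1 :].strip()
        rhs_m = stmt.masked[eq + 1 :].strip()
        rhs_off = stmt.offset + eq + 1 + (len(stmt.masked[eq + 1 :]) - len(stmt.masked[eq + 1 :].lstrip()))
        if _has_top_level(rhs_m, "|"):
            self.wire_pipe(stmt, rhs_c, rhs_m, rhs_off, produced_names=[target])
            return
        cm = re.match(r"(\w+)\s*\(", rhs_m)
        if cm and not rhs_m.startswith(("Channel", "channel")) and \
                "." not in rhs_m[: cm.end()]:
            entry = self.namespace.get(cm.group(1))
            if entry and entry[0] in ("process", "subworkflow"):
                record = self.wire_call(stmt, rhs_c, rhs_m, rhs_off)
                if record and len(record.outputs) == 1:
                    # alias binding: the name refers to the call's single output
                    if target not in self.channels and self.namespace.get(target) is None:
                        self.channels[target] = record.outputs[0][1]
                return
        self.wire_expr(stmt, rhs_c, rhs_m, rhs_off, produced_names=[target],
                       need_value=False)

    def _wire_expression_statement(self, stmt: Statement) -> None:
        c, m = stmt.text, stmt.masked
        if _has_top_level(m, "|"):
            self.wire_pipe(stmt, c, m, stmt.offset, produced_names=[])
            return
        cm = re.match(r"(\w+)\s*\(", m)
        if cm and "." not in m[: cm.start() + len(cm.group(1))]:
            name = cm.group(1)
            entry = self.namespace.get(name)
            if entry and entry[0] in ("process", "subworkflow"):
                self.wire_call(stmt, c, m, stmt.offset)
                return
            if entry and entry[0] == "function":
                return
            if name in BUILTIN_CALLS or name in ("for", "while", "switch"):
                return
            # bare call to something never defined anywhere reachable
            self.collector.add(Code.E_UNDEFINED_ELEMENT,
                               f"'{name}' is called but not defined in any reachable file",
                               stmt.file.path, stmt.span, stmt.text.split("\n")[0])
            return
        if re.fullmatch(r"\w+", m.strip()):
            return
        self.wire_expr(stmt, c, m, stmt.offset, produced_names=[], need_value=False)

    # -- calls -------------------------------------------------------------

    def wire_call(self, stmt: Statement, c_expr: str, m_expr: str,
                  off: int) -> Optional[CallRecord]:
        cm = re.match(r"\s*(\w+)\s*\(", m_expr)
        if not cm:
            return None
        name = cm.group(1)
        popen = m_expr.index("(", cm.start())
        pclose = find_matching(m_expr, popen)
        args_m = m_expr[popen + 1 : pclose]
        args_c = c_expr[popen + 1 : pclose]
        entry = self.namespace.get(name)
        if entry is None or entry[0] == "function":
            self.collector.add(Code.E_UNDEFINED_ELEMENT,
                               f"'{name}' is called but not defined in any reachable file",
                               stmt.file.path, stmt.span, stmt.text.split("\n")[0])
            return None
        kind, defn = entry

        arg_channels: list[Channel] = []
        arg_labels: list[str] = []
        if args_m.strip():
            for s, e in top_level_split(args_m, ","):
                a_c, a_m = args_c[s:e].strip(), args_m[s:e].strip()
                if not a_m:
                    continue
                ch = self._channel_from_arg(stmt, a_c, a_m, off + popen + 1 + s)
                arg_channels.append(ch)
                arg_labels.append(a_c)

        expected = defn.arity
        if len(arg_channels) != expected:
            self.collector.add(
                Code.E_ARITY,
                f"call to {kind} '{name}' has {len(arg_channels)} argument(s), "
                f"expected {expected}",
                stmt.file.path, stmt.span, stmt.text.split("\n")[0])
            return None

        line, col = stmt.span
        if kind == "process":
            nid = self.wiring.next_id(self.id + "/", name)
            node = Node(id=nid, label=name, kind="process",
                        span=(stmt.file.path, line, col), enclosing=self.enclosing)
            self.wiring.nodes.append(node)
            for ch in arg_channels:
                if ch is not None:
                    self.consume(ch, node)
            outputs: list[Tuple[Optional[str], Channel]] = []
            for i, od in enumerate(defn.output_decls):
                label = f"{name}.out.{od.emit_name}" if od.emit_name else f"{name}.out"
                och = self.wiring.new_channel(f"{nid}.out.{i}", label)
                och.producers.append(nid)
                node.produced.append(och)
                outputs.append((od.emit_name, och))
            record = CallRecord(local_name=name, kind=kind, outputs=outputs, node_id=nid)
            self.wiring.calls.append(CallSite(
                callee_name=name, callee_kind=kind, args=arg_labels,
                enclosing_workflow=self.enclosing, span=(stmt.file.path, line, col),
                instance_id=nid))
        else:  # subworkflow: inline its body, splicing take/emit channels
            instance = self.wiring.next_id(self.id + "/", name)
            self.wiring.calls.append(CallSite(
                callee_name=name, callee_kind=kind, args=arg_labels,
                enclosing_workflow=self.enclosing, span=(stmt.file.path, line, col),
                instance_id=instance))
            sub_ns = self.project.namespaces.get(defn.file, self.namespace)
            sub = Scope(self.project, self.wiring, sub_ns, instance,
                        enclosing=name, collector=self.collector)
            for take_name, ch in zip(defn.takes, arg_channels):
                if ch is not None:
                    sub.channels[take_name] = ch
            sub.wire_statements(defn.body_statements)
            outputs = []
            for estmt in defn.emit_statements:
                em = _find_assignment(estmt.masked)
                if em != -1 and re.fullmatch(r"\s*\w+\s*", estmt.masked[:em]):
                    ename = estmt.masked[:em].strip()
                    ch = sub.wire_expr(estmt, estmt.text[em + 1 :].strip(),
                                       estmt.masked[em + 1 :].strip(),
                                       estmt.offset + em + 1,
                                       produced_names=[], need_value=True,
                                       emit_bind=True)
                else:
                    ename = None
                    ch = sub.wire_expr(estmt, estmt.text, estmt.masked, estmt.offset,
                                       produced_names=[], need_value=True,
                                       emit_bind=True)
                if ch is not None:
                    outputs.append((ename, ch))
            record = CallRecord(local_name=name, kind=kind, outputs=outputs, node_id=None)
        self.last_call[name] = record
        return record

    def _channel_from_arg(self, stmt: Statement, a_c: str, a_m: str,
                          off: int) -> Optional[Channel]:
        if re.fullmatch(r"\w+", a_m):
            return self.get_or_create(a_m)  # dangling allowed
        return self.wire_expr(stmt, a_c, a_m, off, produced_names=[], need_value=True)

    # -- emit references ---------------------------------------------------

    def resolve_emit_reference(self, stmt: Statement, name: str,
                               emit_name: Optional[str]) -> Optional[Channel]:
        record = self.last_call.get(name)
        if record is None:
            entry = self.namespace.get(name)
            if entry is not None and entry[0] in ("process", "subworkflow"):
                self.collector.add(Code.E_EMIT_NOT_CALLED,
                                   f"emit of '{name}' accessed but '{name}' has not been called",
                                   stmt.file.path, stmt.span, stmt.text.split("\n")[0])
            else:
                self.collector.add(Code.E_UNDEFINED_ELEMENT,
                                   f"'{name}' is not defined in any reachable file",
                                   stmt.file.path, stmt.span, stmt.text.split("\n")[0])
            return None
        if emit_name is not None:
            for en, ch in record.outputs:
                if en == emit_name:
                    return ch
            self.collector.add(Code.E_UNDEFINED_ELEMENT,
                               f"'{name}' declares no emit named '{emit_name}'",
                               stmt.file.path, stmt.span, stmt.text.split("\n")[0])
            return None
        return self._record_single_out(record, stmt)

    def _record_single_out(self, record: CallRecord, stmt: Statement) -> Optional[Channel]:
        if len(record.outputs) == 1:
            return record.outputs[0][1]
        if record.kind == "subworkflow":
            self.collector.add(Code.E_SUBWF_EMIT_COUNT,
                               f"subworkflow '{record.local_name}' emits "
                               f"{len(record.outputs)} values; exactly one is needed here",
                               stmt.file.path, stmt.span, stmt.text.split("\n")[0])
        else:
            self.collector.add(Code.E_EMIT_MULTIPLE,
                               f"'{record.local_name}.out' provides {len(record.outputs)} "
                               f"channels where one is expected",
                               stmt.file.path, stmt.span, stmt.text.split("\n")[0])
        return None

    # -- operations --------------------------------------------------------

    def wire_expr(self, stmt: Statement, c_expr: str, m_expr: str, off: int,
                  produced_names: list[str], need_value: bool,
                  emit_bind: bool = False) -> Optional[Channel]:
        """Wire one (non-pipe) expression; returns its value channel if any."""
        segs = _split_segments(m_expr)
        seg_m = [m_expr[s:e] for s, e in segs]
        seg_c = [c_expr[s:e] for s, e in segs]

        root_channels: list[Channel] = []
        chain_start = 1
        label_parts: list[str] = []
        is_factory = False

        first = seg_m[0].strip()
        fname, fargs, _ = _parse_segment(seg_m[0])
        if fname in ("Channel", "channel") and len(segs) >= 2:
            gname, gargs, _ = _parse_segment(seg_m[1])
            is_factory = True
            chain_start = 2
            label_parts.append(f"Channel.{gname}")
        elif fname and fargs is not None and self.namespace.get(fname, ("",))[0] in ("process", "subworkflow"):
            record = self.wire_call(stmt, seg_c[0], seg_m[0], off + segs[0][0])
            if record is None:
                return None
            ch = self._record_single_out(record, stmt)
            if ch is None:
                return None
            root_channels.append(ch)
        elif len(segs) >= 2 and seg_m[1].strip() == "out" and re.fullmatch(r"\w+", first):
            emit_name = None
            chain_start = 2
            if len(segs) >= 3:
                nm, nargs, nrest = _parse_segment(seg_m[2])
                if nm and nargs is None and "{" not in seg_m[2] and nm not in OPERATORS:
                    emit_name = nm
                    chain_start = 3
            ch = self.resolve_emit_reference(stmt, first, emit_name)
            if ch is None:
                return None
            root_channels.append(ch)
        elif re.fullmatch(r"\w+", first):
            if len(segs) == 1:
                if emit_bind or first in self.channels:
                    return self.get_or_create(first) if not emit_bind else \
                        self.channels.get(first, self.get_or_create(first))
                if produced_names:
                    # bare alias: target names the same channel (no node)
                    ch = self.get_or_create(first)
                    for nm in produced_names:
                        if self.namespace.get(nm) is None and nm not in self.channels:
                            self.channels[nm] = ch
                    return ch
                return None
            root_channels.append(self.get_or_create(first))
        else:
            # literal / closure / arithmetic root: structurally opaque
            if not produced_names and not need_value:
                return None
            root_channels = []

        # walk the operator chain
        set_targets: list[str] = []
        for k in range(chain_start, len(segs)):
            name, args_span, rest = _parse_segment(seg_m[k])
            if name is None:
                continue
            if name in ("set", "into"):
                tgt = re.findall(r"\w+", seg_c[k][len(name):])
                set_targets.extend(tgt)
                label_parts.append(name)
                continue
            if name not in OPERATORS and name != "out":
                log.warning("unknown operator '%s' treated as channel operator (%s:%s)",
                            name, stmt.file.path, stmt.span[0])
            label_parts.append(name)
            if name in CHANNEL_ARG_OPERATORS and args_span is not None:
                a_m = seg_m[k][args_span[0]:args_span[1]]
                a_c = seg_c[k][args_span[0]:args_span[1]]
                for s, e in top_level_split(a_m, ","):
                    arg_m = a_m[s:e].strip()
                    arg_c = a_c[s:e].strip()
                    if re.fullmatch(r"\w+", arg_m):
                        if arg_m in self.channels:
                            root_channels.append(self.channels[arg_m])
                        else:
                            root_channels.append(self.get_or_create(arg_m))
                    elif ".out" in arg_m:
                        sub = self.wire_expr(stmt, arg_c, arg_m,
                                             off + segs[k][0] + args_span[0] + s,
                                             produced_names=[], need_value=True)
                        if sub is not None:
                            root_channels.append(sub)

        chain = [p for p in label_parts if not p.startswith("Channel.")]
        has_node = is_factory or bool(chain)
        if not has_node:
            # pure reference (e.g. `x = P.out` or emit binding)
            ch = root_channels[0] if root_channels else None
            if ch is not None and produced_names:
                for nm in produced_names:
                    if self.namespace.get(nm) is None and nm not in self.channels:
                        self.channels[nm] = ch
            return ch

        label = ".".join(label_parts) if label_parts else "="
        node = self.new_op_node(stmt, label, chain)
        if is_factory:
            pass  # factories consume nothing
        for ch in root_channels:
            if ch is not None:
                self.consume(ch, node)

        produced = list(produced_names) + set_targets
        out_ch: Optional[Channel] = None
        for nm in produced:
            ch = self.produce(nm, node, stmt)
            if out_ch is None:
                out_ch = ch
        if out_ch is None and need_value:
            out_ch = self.wiring.new_channel(f"{node.id}.val", "<anon>")
            out_ch.producers.append(node.id)
            node.produced.append(out_ch)
        return out_ch

    # -- pipe chains -------------------------------------------------------

    def wire_pipe(self, stmt: Statement, c_expr: str, m_expr: str, off: int,
                  produced_names: list[str]) -> Optional[Channel]:
        """Expand ``a | P | map{...}`` left-to-right into calls and operations."""
        stages = top_level_split(m_expr, "|")
        s0, e0 = stages[0]
        first_m = m_expr[s0:e0].strip()
        first_c = c_expr[s0:e0].strip()

        current: Optional[Channel] = None
        if re.fullmatch(r"\w+", first_m):
            entry = self.namespace.get(first_m)
            if first_m in self.channels:
                current = self.channels[first_m]
            elif entry is not None and entry[0] in ("process", "subworkflow"):
                record = self.last_call.get(first_m)
                if record is None:
                    self.collector.add(Code.E_EMIT_NOT_CALLED,
                                       f"emit of '{first_m}' accessed but '{first_m}' has not been called",
                                       stmt.file.path, stmt.span, stmt.text.split("\n")[0])
                    return None
                current = self._record_single_out(record, stmt)
                if current is None:
                    return None
            else:
                self.collector.add(Code.E_PIPE_FIRST_UNKNOWN,
                                   f"first element '{first_m}' of the pipe does not exist",
                                   stmt.file.path, stmt.span, stmt.text.split("\n")[0])
                return None
        else:
            current = self.wire_expr(stmt, first_c, first_m, off + s0,
                                     produced_names=[], need_value=True)
            if current is None:
                self.collector.add(Code.E_PIPE_FIRST_UNKNOWN,
                                   f"first element of the pipe could not be resolved",
                                   stmt.file.path, stmt.span, stmt.text.split("\n")[0])
                return None

        pending_chain: list[str] = []
        pending_sets: list[str] = []
        pending_extra: list[Channel] = []

        def flush(produce: list[str], need_value: bool) -> Optional[Channel]:
            nonlocal current, pending_chain, pending_sets, pending_extra
            if not pending_chain:
                return current
            node = self.new_op_node(stmt, ".".join(pending_chain), list(pending_chain))
            if current is not None:
                self.consume(current, node)
            for extra in pending_extra:
                self.consume(extra, node)
            out: Optional[Channel] = None
            for nm in produce + pending_sets:
                ch = self.produce(nm, node, stmt)
                if out is None:
                    out = ch
            if out is None and need_value:
                out = self.wiring.new_channel(f"{node.id}.val", "<anon>")
                out.producers.append(node.id)
                node.produced.append(out)
            pending_chain = []
            pending_sets = []
            pending_extra = []
            current = out
            return out

        for si in range(1, len(stages)):
            s, e = stages[si]
            st_m = m_expr[s:e].strip()
            st_c = c_expr[s:e].strip()
            name, args_span, rest = _parse_segment(st_m)
            if name is None:
                continue
            entry = self.namespace.get(name)
            if entry is not None and entry[0] in ("process", "subworkflow"):
                flush([], need_value=True)
                record = self._wire_pipe_call(stmt, name, entry, current)
                if record is None:
                    return None
                if si == len(stages) - 1:
                    if produced_names:
                        ch = self._record_single_out(record, stmt)
                        if ch is not None:
                            for nm in produced_names:
                                if self.namespace.get(nm) is None and nm not in self.channels:
                                    self.channels[nm] = ch
                    return None
                current = self._record_single_out(record, stmt)
                if current is None:
                    return None
            elif name in ("set", "into"):
                tgt = re.findall(r"\w+", st_c[len(name):])
                pending_sets.extend(tgt)
                pending_chain.append(name)
            elif name in OPERATORS:
                pending_chain.append(name)
                if name in CHANNEL_ARG_OPERATORS and args_span is not None:
                    a_m = st_m[args_span[0]:args_span[1]]
                    for as_, ae in top_level_split(a_m, ","):
                        arg = a_m[as_:ae].strip()
                        if re.fullmatch(r"\w+", arg):
                            pending_extra.append(self.get_or_create(arg))
            else:
                self.collector.add(Code.U_PIPE_UNKNOWN,
                                   f"unknown element '{name}' used in a pipe operator",
                                   stmt.file.path, stmt.span, stmt.text.split("\n")[0])
                return None

        return flush(list(produced_names), need_value=False)

    def _wire_pipe_call(self, stmt: Statement, name: str, entry,
                        arg: Optional[Channel]) -> Optional[CallRecord]:
        kind, defn = entry
        expected = defn.arity
        n_args = 1 if arg is not None else 0
        if n_args != expected:
            self.collector.add(
                Code.E_ARITY,
                f"call to {kind} '{name}' has {n_args} argument(s), expected {expected}",
                stmt.file.path, stmt.span, stmt.text.split("\n")[0])
            return None
        line, col = stmt.span
        if kind == "process":
            nid = self.wiring.next_id(self.id + "/", name)
            node = Node(id=nid, label=name, kind="process",
                        span=(stmt.file.path, line, col), enclosing=self.enclosing)
            self.wiring.nodes.append(node)
            if arg is not None:
                self.consume(arg, node)
            outputs: list[Tuple[Optional[str], Channel]] = []
            for i, od in enumerate(defn.output_decls):
                label = f"{name}.out.{od.emit_name}" if od.emit_name else f"{name}.out"
                och = self.wiring.new_channel(f"{nid}.out.{i}", label)
                och.producers.append(nid)
                node.produced.append(och)
                outputs.append((od.emit_name, och))
            record = CallRecord(local_name=name, kind=kind, outputs=outputs, node_id=nid)
            self.wiring.calls.append(CallSite(
                callee_name=name, callee_kind=kind,
                args=[arg.label if arg else ""],
                enclosing_workflow=self.enclosing, span=(stmt.file.path, line, col),
                instance_id=nid))
            self.last_call[name] = record
            return record
        # subworkflow in a pipe
        instance = self.wiring.next_id(self.id + "/", name)
        self.wiring.calls.append(CallSite(
            callee_name=name, callee_kind=kind, args=[arg.label if arg else ""],
            enclosing_workflow=self.enclosing, span=(stmt.file.path, line, col),
            instance_id=instance))
        sub_ns = self.project.namespaces.get(defn.file, self.namespace)
        sub = Scope(self.project, self.wiring, sub_ns, instance,
                    enclosing=name, collector=self.collector)
        for take_name, ch in zip(defn.takes, [arg]):
            if ch is not None:
                sub.channels[take_name] = ch
        sub.wire_statements(defn.body_statements)
        outputs = []
        for estmt in defn.emit_statements:
            em = _find_assignment(estmt.masked)
            if em != -1 and re.fullmatch(r"\s*\w+\s*", estmt.masked[:em]):
                ename = estmt.masked[:em].strip()
                ch = sub.wire_expr(estmt, estmt.text[em + 1 :].strip(),
                                   estmt.masked[em + 1 :].strip(),
                                   estmt.offset + em + 1, produced_names=[],
                                   need_value=True, emit_bind=True)
            else:
                ename = None
                ch = sub.wire_expr(estmt, estmt.text, estmt.masked, estmt.offset,
                                   produced_names=[], need_value=True, emit_bind=True)
            if ch is not None:
                outputs.append((ename, ch))
        record = CallRecord(local_name=name, kind=kind, outputs=outputs, node_id=None)
        self.last_call[name] = record
        return record


# spec-facing wrappers -------------------------------------------------------

def parse_workflow_body(statements: list[Statement], scope: Scope):
    """Wire a statement list; returns the (calls, operations) it created."""
    n_calls = len(scope.wiring.calls)
    n_ops = len(scope.wiring.operations)
    scope.wire_statements(statements)
    return scope.wiring.calls[n_calls:], scope.wiring.operations[n_ops:]


def expand_pipe_chains(stmt: Statement, scope: Scope):
    return scope.wire_pipe(stmt, stmt.text, stmt.masked, stmt.offset, produced_names=[])


def resolve_emit_reference(expr: str, scope: Scope, stmt: Statement):
    m = re.fullmatch(r"\s*(\w+)\.out(?:\.(\w+))?\s*", expr)
    if not m:
        return None
    return scope.resolve_emit_reference(stmt, m.group(1), m.group(2))


def bind_channels(scope: Scope) -> dict[str, Tuple[list[str], list[str]]]:
    """The scope's channel table: name -> (producer ids, consumer ids)."""
    return {name: (list(ch.producers), list(ch.consumers))
            for name, ch in scope.channels.items()}


# ---------------------------------------------------------------------------
# project loading

@dataclass
class WorkflowProject:
    root: Path
    main_path: str
    files: dict[str, NextflowFile] = field(default_factory=dict)
    elements: dict[str, FileElements] = field(default_factory=dict)
    namespaces: dict[str, dict] = field(default_factory=dict)
    dsl: Optional[DslVersion] = None
    diagnostics: list[Diagnostic] = field(default_factory=list)
    wiring: Optional[Wiring] = None
    config_source: Optional[str] = None
    readme_source: Optional[str] = None
    phase: str = "init"

    @property
    def ok(self) -> bool:
        return not self.diagnostics


def _file_namespace(project: WorkflowProject, rel: str, collector: Collector) -> dict:
    """Name -> (kind, def) visible inside *rel*: own defs plus include items."""
    fe = project.elements[rel]
    ns: dict = {}
    for p in fe.processes:
        ns[p.name] = ("process", p)
    for w in fe.workflows:
        ns[w.name] = ("subworkflow", w)
    for f in fe.functions:
        ns[f.name] = ("function", f)
    for inc in fe.includes:
        if inc.resolved_path is None or inc.resolved_path not in project.elements:
            continue
        target = project.elements[inc.resolved_path]
        defs: dict = {}
        for p in target.processes:
            defs[p.name] = ("process", p)
        for w in target.workflows:
            defs[w.name] = ("subworkflow", w)
        for f in target.functions:
            defs[f.name] = ("function", f)
        for name, alias in inc.items:
            if name in defs:
                ns[alias or name] = defs[name]
            else:
                collector.add(Code.E_UNDEFINED_ELEMENT,
                              f"'{name}' is expected to be defined in "
                              f"'{inc.resolved_path}' but is not",
                              inc.file, inc.span)
    return ns


def load_project(main_file: Path, config_file: Optional[Path] = None) -> WorkflowProject:
    """Run preprocessing, extraction and wiring with per-phase stops."""
    main_file = Path(main_file)
    root = main_file.parent
    project = WorkflowProject(root=root, main_path=main_file.name)
    collector = Collector()

    # phase 1: preprocess the main file, identify the DSL
    main_nf = NextflowFile.from_path(main_file, main_file.name)
    project.files[main_nf.path] = main_nf
    main_nf.check_syntax(collector)
    if config_file is None:
        candidate = root / "nextflow.config"
        config_file = candidate if candidate.is_file() else None
    if config_file is not None:
        project.config_source = Path(config_file).read_text(encoding="utf-8")
    for rn in ("README.md", "README.rst", "README.txt", "README"):
        if (root / rn).is_file():
            project.readme_source = (root / rn).read_text(encoding="utf-8")
            break
    project.dsl = detect_dsl_version(main_nf, project.config_source, collector)
    if collector:
        project.diagnostics = collector.items
        project.phase = "preprocess"
        return project

    # phase 2: extract every reachable file
    project.elements[main_nf.path] = parse_file(main_nf, collector)
    if project.dsl.value == "DSL2":
        queue = [main_nf.path]
        seen = {main_nf.path}
        while queue:
            rel = queue.pop(0)
            for inc in project.elements[rel].includes:
                _resolve_include(inc, root, rel, collector)
                tgt = inc.resolved_path
                if tgt is None or tgt in seen:
                    continue
                seen.add(tgt)
                nf = NextflowFile.from_path(root / tgt, tgt)
                project.files[tgt] = nf
                nf.check_syntax(collector)
                project.elements[tgt] = parse_file(nf, collector)
                queue.append(tgt)
        for rel in project.elements:
            project.namespaces[rel] = _file_namespace(project, rel, collector)
    else:
        project.namespaces[main_nf.path] = _file_namespace(project, main_nf.path, collector)
    if collector:
        project.diagnostics = collector.items
        project.phase = "extract"
        return project

    # phase 3: wire from the entry point
    wiring = Wiring()
    project.wiring = wiring
    if project.dsl.value == "DSL2":
        fe = project.elements[main_nf.path]
        entry = fe.anonymous
        if entry is None:
            if len(fe.workflows) == 1:
                entry = fe.workflows[0]
            else:
                collector.add(Code.E_UNDEFINED_ELEMENT,
                              "no entry workflow: the main file has no anonymous "
                              "workflow block and not exactly one named workflow",
                              main_nf.path)
        if entry is not None:
            scope = Scope(project, wiring, project.namespaces[main_nf.path],
                          "main", enclosing=entry.name or "<entry>",
                          collector=collector)
            scope.wire_statements(entry.body_statements)
    else:
        _wire_dsl1(project, wiring, collector)
    project.diagnostics = collector.items
    project.phase = "wire" if collector else "done"
    return project


def _wire_dsl1(project: WorkflowProject, wiring: Wiring, collector: Collector) -> None:
    """DSL1: the single file is the scope; processes wire via from/into."""
    fe = project.elements[project.main_path]
    nf = fe.file
    scope = Scope(project, wiring, project.namespaces[project.main_path],
                  "main", enclosing="<file>", collector=collector)
    for kind, obj in fe.items:
        if kind == "statement":
            scope.wire_statement(obj)
        elif kind == "process":
            pd: ProcessDef = obj
            nid = wiring.next_id("main/", pd.name)
            node = Node(id=nid, label=pd.name, kind="process",
                        span=(pd.file, pd.span[0], 1), enclosing="<file>")
            wiring.nodes.append(node)
            for d in pd.input_decls:
                if d.from_channel:
                    scope.consume(scope.get_or_create(d.from_channel), node)
            for od in pd.output_decls:
                for name in od.into_channels:
                    entry = scope.namespace.get(name)
                    if entry is not None:
                        collector.add(Code.E_NAME_COLLISION,
                                      f"channel '{name}' collides with the {entry[0]} "
                                      f"of the same name", pd.file, (pd.span[0], 1),
                                      od.raw)
                        continue
                    ch = scope.get_or_create(name)
                    ch.producers.append(node.id)
                    node.produced.append(ch)
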