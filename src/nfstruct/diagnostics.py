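"""Error catalogue, diagnostic records and the project-level validation pass.

A Nextflow project that cannot be analysed statically produces one or more
:class:`Diagnostic` findings instead of a graph.  The catalogue distinguishes
*errors* (faults or ambiguities in the workflow code itself) from *unsupported*
patterns (constructs this analyser deliberately does not model).  Both stop
graph construction; the severity lets a user tell a broken workflow apart from
a tool limitation.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Optional, Tuple


class Severity(str, enum.Enum):
    ERROR = "error"
    UNSUPPORTED = "unsupported"


class Code(str, enum.Enum):
    """The fixed catalogue of detectable findings (14 classes)."""

    # Patterns outside the analyser's modelling scope
    U_PIPE_UNKNOWN = "U_PIPE_UNKNOWN"
    U_TERNARY_TUPLE = "U_TERNARY_TUPLE"
    U_TUPLE_CALL = "U_TUPLE_CALL"
    # Errors or ambiguities in the workflow code
    E_ARITY = "E_ARITY"
    E_NAME_COLLISION = "E_NAME_COLLISION"
    E_EMIT_MULTIPLE = "E_EMIT_MULTIPLE"
    E_EMIT_NOT_CALLED = "E_EMIT_NOT_CALLED"
    E_INCLUDE_MISSING = "E_INCLUDE_MISSING"
    E_INCLUDE_IN_WORKFLOW = "E_INCLUDE_IN_WORKFLOW"
    E_PIPE_FIRST_UNKNOWN = "E_PIPE_FIRST_UNKNOWN"
    E_SYNTAX = "E_SYNTAX"
    E_UNDEFINED_ELEMENT = "E_UNDEFINED_ELEMENT"
    E_SUBWF_EMIT_COUNT = "E_SUBWF_EMIT_COUNT"
    E_BAD_DEFINITION = "E_BAD_DEFINITION"


#: Codes that flag analyser scope limits rather than workflow faults.
UNSUPPORTED_CODES = frozenset({Code.U_PIPE_UNKNOWN, Code.U_TERNARY_TUPLE, Code.U_TUPLE_CALL})

#: Human description of each class, mirroring the published error inventory.
CATALOGUE: dict[Code, str] = {
    Code.U_PIPE_UNKNOWN: "Unknown element used in a pipe operator",
    Code.U_TERNARY_TUPLE: "Ternary conditional operator used with a tuple",
    Code.U_TUPLE_CALL: "Tuple associated with a call",
    Code.E_ARITY: "Incorrect number of parameters given for a process or a subworkflow call",
    Code.E_NAME_COLLISION: "Channel trying to be created with a name already given to an existing element",
    Code.E_EMIT_MULTIPLE: "Multiple channels are given by an emit even though only expecting one",
    Code.E_EMIT_NOT_CALLED: "Tried to access an emit even though the element its emitting has not been called",
    Code.E_INCLUDE_MISSING: "Tried to include a file which does not exist",
    Code.E_INCLUDE_IN_WORKFLOW: "An include was present in a main or subworkflow",
    Code.E_PIPE_FIRST_UNKNOWN: "In a pipe operator, the first element called does not exist",
    Code.E_SYNTAX: "Syntax error in the code (e.g., not the same number of opening and closing parentheses)",
    Code.E_UNDEFINED_ELEMENT: "Element (process or subworkflow) is expected to be defined in a file but is not",
    Code.E_SUBWF_EMIT_COUNT: "A subworkflow either emits nothing or too many values for use in an operation",
    Code.E_BAD_DEFINITION: "A subworkflow or process was defined badly (e.g., multiple input sections, multiple main sections...)",
}

_SNIPPET_LIMIT = 120


@dataclass
class Diagnostic:
    """One finding: a code, a message, and where in the source it was seen."""

    code: Code
    message: str
    file: str
    span: Optional[Tuple[int, int]] = None  # 1-based (line, column)
    snippet: str = ""

    @property
    def severity(self) -> Severity:
        return Severity.UNSUPPORTED if self.code in UNSUPPORTED_CODES else Severity.ERROR

    def to_dict(self) -> dict:
        return {
            "code": self.code.value,
            "severity": self.severity.value,
            "file": self.file,
            "line": self.span[0] if self.span else None,
            "column": self.span[1] if self.span else None,
            "message": self.message,
            "snippet": self.snippet,
        }


@dataclass
class Collector:
    """Accumulates diagnostics; nothing handed to :meth:`add` is ever dropped."""

    items: list[Diagnostic] = field(default_factory=list)

    def add(self, code: Code, message: str, file: str,
            span: Optional[Tuple[int, int]] = None, snippet: str = "") -> Diagnostic:
        d = Diagnostic(code=code, message=message, file=file, span=span, snippet=snippet)
        self.items.append(d)
        return d

    def __len__(self) -> int:
        return len(self.items)

    def __bool__(self) -> bool:
        return bool(self.items)


def format_diagnostic(d: Diagnostic) -> str:
    """One-line ``severity code file:line message`` plus an indented snippet."""
    loc = d.file if d.span is None else f"{d.file}:{d.span[0]}"
    head = f"{d.severity.value} {d.code.value} {loc} {d.message}"
    snippet = d.snippet.strip()
    if not snippet:
        return head
    if len(snippet) > _SNIPPET_LIMIT:
        snippet = snippet[: _SNIPPET_LIMIT - 1] + "…"
    return head + "\n    " + snippet


def validate_project(project) -> list[Diagnostic]:
    """Return all diagnostics of *project* in source order.

    The project has already been loaded (preprocessing and extraction
    attempted, wiring attempted if those phases were clean); analysis stops at
    the first phase that produced findings, and every finding of that phase is
    reported.  An empty list means the structure graphs can be built.
    """
    def key(d: Diagnostic):
        return (d.file, d.span if d.span is not None else (1 << 30, 0))

    return sorted(project.diagnostics, key=key)


def diagnostics_to_json(diags: list[Diagnostic]) -> str:
    return json.dumps([d.to_dict() for d in diags], indent=2) + "\n"
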