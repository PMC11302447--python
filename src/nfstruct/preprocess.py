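"""Source cleaning, bracket tallying and DSL-version identification.

Nextflow files are Groovy-flavoured text; recovering workflow structure does
not need a full Groovy grammar, only a faithful lexical pass.  A single-pass
state machine walks every character once, tracking whether it sits in code, a
line comment, a block comment, a single/double/triple-quoted string or a shell
block.  Two views of each file are produced:

``cleaned_source``
    comments replaced by equal-length whitespace (newlines kept), strings and
    script bodies untouched — the text later phases slice literals from.
``masked_source``
    additionally blanks the *contents* of string literals — the text all
    structural scanning (brackets, keywords, statement splitting) runs on, so
    braces or keywords inside strings can never confuse the analysis.

Both views preserve every byte offset of the original, so any later finding
maps straight back to a (line, column) in the file the user wrote.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Tuple

from .diagnostics import Code, Collector

_CODE, _LINE, _BLOCK, _SQ, _DQ, _TSQ, _TDQ = range(7)


def _scan(raw: str) -> Tuple[str, str, Optional[int]]:
    """Run the lexical state machine.

    Returns ``(cleaned, masked, unterminated_block_offset)``.
    """
    cleaned = list(raw)
    masked = list(raw)
    n = len(raw)
    i = 0
    state = _CODE
    block_start: Optional[int] = None

    def blank(idx: int, both: bool) -> None:
        if raw[idx] != "\n":
            cleaned[idx] = " " if both else cleaned[idx]
            masked[idx] = " "

    while i < n:
        c = raw[i]
        if state == _CODE:
            if c == "/" and raw[i + 1 : i + 2] == "/":
                state = _LINE
                blank(i, True)
            elif c == "/" and raw[i + 1 : i + 2] == "*":
                state = _BLOCK
                block_start = i
                blank(i, True)
            elif c == '"':
                if raw[i : i + 3] == '"""':
                    state = _TDQ
                    i += 2
                else:
                    state = _DQ
            elif c == "'":
                if raw[i : i + 3] == "'''":
                    state = _TSQ
                    i += 2
                else:
                    state = _SQ
        elif state == _LINE:
            if c == "\n":
                state = _CODE
            else:
                blank(i, True)
        elif state == _BLOCK:
            if c == "*" and raw[i + 1 : i + 2] == "/":
                blank(i, True)
                blank(i + 1, True)
                i += 1
                state = _CODE
                block_start = None
            else:
                blank(i, True)
        elif state in (_SQ, _DQ):
            quote = "'" if state == _SQ else '"'
            if c == "\\" and i + 1 < n:
                blank(i, False)
                blank(i + 1, False)
                i += 1
            elif c == quote:
                state = _CODE
            elif c == "\n":
                # single-quoted strings do not span lines; recover
                state = _CODE
            else:
                blank(i, False)
        else:  # _TSQ, _TDQ
            quote = "'''" if state == _TSQ else '"""'
            if c == "\\" and i + 1 < n:
                blank(i, False)
                blank(i + 1, False)
                i += 1
            elif raw[i : i + 3] == quote:
                i += 2
                state = _CODE
            else:
                blank(i, False)
        i += 1

    unterminated = block_start if state == _BLOCK else None
    return "".join(cleaned), "".join(masked), unterminated


def strip_comments(raw_source: str) -> str:
    """Replace comment spans with equal-length whitespace.

    Line comments (``// …``) and block comments (``/* … */``) are blanked;
    newlines inside block comments are kept so the output has exactly the same
    number of lines as the input.  Comment markers inside string literals or
    triple-quoted script bodies are left untouched.
    """
    cleaned, _, _ = _scan(raw_source)
    return cleaned


class LineIndex:
    """Maps a character offset to a 1-based (line, column)."""

    def __init__(self, text: str):
        self._starts = [0]
        for m in re.finditer("\n", text):
            self._starts.append(m.end())
        self._len = len(text)

    def locate(self, offset: int) -> Tuple[int, int]:
        offset = max(0, min(offset, self._len))
        line = bisect.bisect_right(self._starts, offset) - 1
        return line + 1, offset - self._starts[line] + 1


@dataclass
class BalanceReport:
    """Per-delimiter open/close tallies plus the first imbalance, if any."""

    counts: dict  # pair -> (n_open, n_close)
    first_imbalance: Optional[int]  # character offset, None when balanced

    @property
    def balanced(self) -> bool:
        return self.first_imbalance is None and all(o == c for o, c in self.counts.values())


_OPEN = {"{": "{}", "(": "()", "[": "[]"}
_CLOSE = {"}": "{}", ")": "()", "]": "[]"}


def verify_bracket_balance(masked_source: str) -> BalanceReport:
    """Tally ``{}``, ``()`` and ``[]`` on string-masked, comment-free text.

    Balanced means every opener has a matching closer of the same kind and
    nesting never goes negative.  ``first_imbalance`` points at the earliest
    offending delimiter (an unmatched opener or a stray closer).
    """
    counts = {"{}": [0, 0], "()": [0, 0], "[]": [0, 0]}
    stack: list[Tuple[str, int]] = []
    first: Optional[int] = None
    for i, c in enumerate(masked_source):
        if c in _OPEN:
            counts[_OPEN[c]][0] += 1
            stack.append((c, i))
        elif c in _CLOSE:
            counts[_CLOSE[c]][1] += 1
            if stack and _OPEN[stack[-1][0]] == _CLOSE[c]:
                stack.pop()
            elif first is None:
                first = stack[-1][1] if stack else i
    if first is None and stack:
        first = stack[0][1]
    return BalanceReport(counts={k: tuple(v) for k, v in counts.items()}, first_imbalance=first)


@dataclass
class NextflowFile:
    """One source file with its cleaned/masked views and position index."""

    path: str  # project-relative
    raw_source: str
    cleaned_source: str = ""
    masked_source: str = ""
    line_index: LineIndex = None  # type: ignore[assignment]
    unterminated_comment: Optional[int] = field(default=None, repr=False)

    @classmethod
    def from_text(cls, path: str, raw: str) -> "NextflowFile":
        cleaned, masked, unterminated = _scan(raw)
        return cls(path=path, raw_source=raw, cleaned_source=cleaned,
                   masked_source=masked, line_index=LineIndex(raw),
                   unterminated_comment=unterminated)

    @classmethod
    def from_path(cls, path: Path, rel: str) -> "NextflowFile":
        return cls.from_text(rel, path.read_text(encoding="utf-8"))

    def locate(self, offset: int) -> Tuple[int, int]:
        return self.line_index.locate(offset)

    def check_syntax(self, collector: Collector) -> bool:
        """Record unterminated-comment and bracket-imbalance findings."""
        ok = True
        if self.unterminated_comment is not None:
            collector.add(Code.E_SYNTAX, "unterminated block comment", self.path,
                          self.locate(self.unterminated_comment))
            ok = False
        report = verify_bracket_balance(self.masked_source)
        if not report.balanced:
            span = self.locate(report.first_imbalance) if report.first_imbalance is not None else None
            tallies = ", ".join(f"{k}: {o} open / {c} close" for k, (o, c) in report.counts.items())
            collector.add(Code.E_SYNTAX, f"unbalanced delimiters ({tallies})", self.path, span)
            ok = False
        return ok


@dataclass
class DslVersion:
    value: str  # "DSL1" | "DSL2"
    evidence: str

    def __eq__(self, other):
        if isinstance(other, DslVersion):
            return self.value == other.value
        return self.value == other


_DSL2_DECL = re.compile(r"nextflow\.(?:enable|preview)\.dsl\s*=\s*2\b")
_DSL1_DECL = re.compile(r"nextflow\.(?:enable|preview)\.dsl\s*=\s*1\b")
_WORKFLOW_BLOCK = re.compile(r"(?:^|\n)\s*workflow(?:\s+\w+)?\s*\{")
_INCLUDE = re.compile(r"(?:^|\n)\s*include\s*\{")


def detect_dsl_version(main_file: NextflowFile, config_source: Optional[str] = None,
                       collector: Optional[Collector] = None) -> DslVersion:
    """Identify the Nextflow language version of a project.

    DSL2 when an explicit ``nextflow.enable.dsl = 2`` declaration appears in
    the main file or config, or when the main file has a ``workflow`` block or
    ``include`` directive; DSL1 otherwise (a bare file of processes is the
    DSL1 idiom).  An explicit DSL1 declaration combined with DSL2 constructs
    is contradictory and diagnosed as a syntax error.
    """
    masked = main_file.masked_source
    config_masked = strip_comments(config_source) if config_source else ""
    has_dsl2_constructs = bool(_WORKFLOW_BLOCK.search(masked) or _INCLUDE.search(masked))

    if _DSL1_DECL.search(masked) or _DSL1_DECL.search(config_masked):
        if has_dsl2_constructs:
            if collector is not None:
                collector.add(Code.E_SYNTAX,
                              "explicit DSL1 declaration contradicts workflow/include constructs",
                              main_file.path)
        return DslVersion("DSL1", "explicit DSL1 declaration")
    if _DSL2_DECL.search(masked):
        return DslVersion("DSL2", "explicit DSL2 declaration in main file")
    if config_masked and _DSL2_DECL.search(config_masked):
        return DslVersion("DSL2", "explicit DSL2 declaration in nextflow.config")
    if has_dsl2_constructs:
        return DslVersion("DSL2", "workflow block or include directive in main file")
    return DslVersion("DSL1", "no DSL2 signal; bare-process default")
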