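"""Synthetic Nextflow projects with known ground-truth structure.

The generator samples a random but well-formed wiring of channel factories,
operator chains, process calls (plain and piped, optionally across included
module files, optionally inside a subworkflow, optionally under conditional
branches) and renders it both as Nextflow source text and as the ground-truth
specification graph the analyser is expected to recover.  ``inject_error``
applies the minimal mutation that triggers exactly one catalogue code, giving
a fault-injection corpus for the diagnostics.

Process bodies are trivial (``echo``) on purpose: the corpus exercises
structure, not science.  Everything is a pure function of the arguments —
identical seeds give byte-identical projects.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx

from .diagnostics import Code
from .graph_build import SPECIFICATION, StructureGraph
from .preprocess import NextflowFile
from .extract import find_matching

_CHAIN_OPS = ["map", "filter", "flatten", "collect", "unique", "first"]
_FACTORIES = [("of", "(1, 2, 3)"), ("fromPath", "('data/*.csv')"),
              ("value", "(1)"), ("fromList", "(['a', 'b'])")]


@dataclass
class Fixture:
    """A generated project plus everything needed to check the analysis."""

    files: dict[str, str]
    truth_graph: StructureGraph
    truth_manifest: dict[str, int]
    expected_diagnostics: list[Code]
    seed: int
    dsl: str
    meta: dict = field(default_factory=dict)


class _Truth:
    """Ground-truth accumulator mirroring the analyser's graph conventions."""

    def __init__(self) -> None:
        self.g = nx.MultiDiGraph()
        self.channels: dict[str, dict] = {}
        self._n = 0

    def node(self, label: str, kind: str) -> str:
        nid = f"t{self._n}"
        self._n += 1
        self.g.add_node(nid, label=label, kind=kind)
        return nid

    def chan(self, key: str, label: str) -> str:
        if key not in self.channels:
            self.channels[key] = {"label": label, "producers": [], "consumers": []}
        return key

    def produce(self, key: str, label: str, node: str) -> None:
        self.chan(key, label)
        self.channels[key]["producers"].append(node)

    def consume(self, key: str, node: str) -> None:
        self.chan(key, self.channels.get(key, {}).get("label", key))
        self.channels[key]["consumers"].append(node)

    def finish(self) -> StructureGraph:
        for ch in self.channels.values():
            for p in ch["producers"]:
                for c in ch["consumers"]:
                    self.g.add_edge(p, c, label=ch["label"])
        return StructureGraph(level=SPECIFICATION, g=self.g)


@dataclass
class _Source:
    """Something usable as an input: a named channel or an emit reference."""

    expr: str  # how consuming code spells it
    key: str  # truth channel key
    named: bool  # plain channel name (usable as a DSL1 `from` / pipe head)
    has_producer: bool = True  # False for dangling inputs


@dataclass
class _ProcPlan:
    name: str
    n_in: int
    emits: list[Optional[str]]  # one entry per output declaration
    module: Optional[str] = None
    alias: Optional[str] = None

    @property
    def local(self) -> str:
        return self.alias or self.name

    def out_expr(self, i: int) -> str:
        e = self.emits[i]
        return f"{self.local}.out.{e}" if e else f"{self.local}.out"

    def out_label(self, i: int) -> str:
        e = self.emits[i]
        return f"{self.local}.out.{e}" if e else f"{self.local}.out"


def _proc_def_text(p: _ProcPlan, dsl1_from: Optional[list[str]] = None,
                   dsl1_into: Optional[list[str]] = None) -> str:
    lines = [f"process {p.name} {{", "    input:"]
    for i in range(p.n_in):
        if dsl1_from is not None:
            lines.append(f"    val x{i} from {dsl1_from[i]}")
        else:
            lines.append(f"    val x{i}")
    lines.append("")
    lines.append("    output:")
    for i, emit in enumerate(p.emits):
        if dsl1_into is not None:
            lines.append(f"    file 'out_{i}.txt' into {dsl1_into[i]}")
        elif emit:
            lines.append(f"    path 'out_{i}.txt', emit: {emit}")
        else:
            lines.append(f"    path 'out_{i}.txt'")
    lines += ["", "    script:", '    """', f"    echo {p.name}", '    """', "}"]
    return "\n".join(lines)


def generate_workflow_fixture(n_processes: int, n_operations: int, dsl: str = "DSL2",
                              p_branch: float = 0.0, p_multifile: float = 0.0,
                              seed: int = 0) -> Fixture:
    """Sample one clean project with its ground truth (deterministic in *seed*)."""
    if n_processes < 0 or n_operations < 0:
        raise ValueError("element counts must be non-negative")
    if not (0.0 <= p_branch <= 1.0 and 0.0 <= p_multifile <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if dsl not in ("DSL1", "DSL2"):
        raise ValueError("dsl must be 'DSL1' or 'DSL2'")
    rng = random.Random(seed)
    if dsl == "DSL1":
        return _generate_dsl1(n_processes, n_operations, p_branch, rng, seed)
    return _generate_dsl2(n_processes, n_operations, p_branch, p_multifile, rng, seed)


# ---------------------------------------------------------------------------
# DSL2 generation

def _generate_dsl2(n_proc: int, n_ops: int, p_branch: float, p_multi: float,
                   rng: random.Random, seed: int) -> Fixture:
    truth = _Truth()
    manifest = {"processes": 0, "subworkflows": 0, "includes": 0,
                "calls": 0, "operations": 0}
    meta: dict = {}

    procs = []
    for i in range(n_proc):
        n_out = 2 if rng.random() < 0.3 else 1
        if n_out == 2:
            emits: list[Optional[str]] = [f"out_{chr(97 + i)}_{j}" for j in range(2)]
        else:
            emits = [f"out_{chr(97 + i)}_0"] if rng.random() < 0.5 else [None]
        procs.append(_ProcPlan(name=f"PROC_{i + 1}", n_in=rng.randint(1, 2), emits=emits))

    use_sub = n_proc >= 2 and rng.random() < 0.4
    sub_procs: list[_ProcPlan] = []
    if use_sub:
        k = min(rng.randint(1, 2), n_proc - 1)
        sub_procs = procs[-k:]
    entry_procs = [p for p in procs if p not in sub_procs]

    # module placement + aliases
    for p in procs:
        if rng.random() < p_multi:
            p.module = f"modules/mod_{rng.randint(1, 2)}.nf"
            if rng.random() < 0.3:
                p.alias = p.name + "_AS"

    ch_counter = [0]
    dang_counter = [0]

    def new_name(prefix: str = "ch") -> str:
        ch_counter[0] += 1
        return f"{prefix}_{ch_counter[0]}"

    def closure() -> str:
        return "{ it }"

    n_start = max(1, round(0.4 * n_ops)) if n_ops > 0 else 0
    n_follow = max(0, n_ops - n_start)
    sub_follow = 1 if use_sub and n_follow > 0 else 0
    n_follow -= sub_follow

    # ---- entry body ------------------------------------------------------
    avail: list[_Source] = []
    entry: list[str] = []

    def emit_factory() -> None:
        name = new_name()
        fn, args = rng.choice(_FACTORIES)
        chained = rng.random() < 0.2
        chain_txt = f".map {closure()}" if chained else ""
        entry.append(f"{name} = Channel.{fn}{args}{chain_txt}")
        label = f"Channel.{fn}" + (".map" if chained else "")
        node = truth.node(label, "starting_op")
        truth.produce(f"main:{name}", name, node)
        avail.append(_Source(expr=name, key=f"main:{name}", named=True))
        manifest["operations"] += 1
        if "safe_channel" not in meta:
            meta["safe_channel"] = name

    def pick(named_only: bool = False) -> _Source:
        pool = [s for s in avail if s.named and s.has_producer] if named_only else avail
        if not pool:
            dang_counter[0] += 1
            name = f"dang_{dang_counter[0]}"
            return _Source(expr=name, key=f"main:{name}", named=True,
                           has_producer=False)
        return rng.choice(pool)

    def emit_op(lines: list[str], scope: str, sources: list[_Source],
                prefix: str = "ch") -> None:
        """One following operation (or a conditional pair) in *lines*."""
        manifest["operations"] += 1
        style = rng.random()
        if rng.random() < p_branch:
            src = rng.choice(sources) if sources else pick()
            name = new_name(prefix)
            lines.append(f"if (params.flag_{ch_counter[0]}) {{")
            lines.append(f"    {name} = {src.expr}.map {closure()}")
            lines.append("} else {")
            lines.append(f"    {name} = {src.expr}.filter {closure()}")
            lines.append("}")
            for op in ("map", "filter"):
                node = truth.node(op, "following_op")
                truth.consume(src.key, node)
                truth.produce(f"{scope}:{name}", name, node)
            manifest["operations"] += 1  # the second branch node
            avail.append(_Source(expr=name, key=f"{scope}:{name}", named=True))
            return
        src = rng.choice(sources) if sources else pick()
        if style < 0.15:  # sink
            lines.append(f"{src.expr}.view()")
            node = truth.node("view", "following_op")
            truth.consume(src.key, node)
            return
        name = new_name(prefix)
        if style < 0.35 and len([s for s in sources or avail if s is not src]) >= 1:
            pool = [s for s in (sources or avail) if s is not src] or (sources or avail)
            other = rng.choice(pool)
            lines.append(f"{name} = {src.expr}.mix({other.expr})")
            node = truth.node("mix", "following_op")
            truth.consume(src.key, node)
            truth.consume(other.key, node)
            truth.produce(f"{scope}:{name}", name, node)
        elif style < 0.55:
            op = rng.choice(_CHAIN_OPS)
            lines.append(f"{src.expr}.{op} {closure()}.set {{ {name} }}")
            node = truth.node(f"{op}.set", "following_op")
            truth.consume(src.key, node)
            truth.produce(f"{scope}:{name}", name, node)
        elif style < 0.75 and src.named:
            lines.append(f"{name} = {src.expr} | map {closure()} | filter {closure()}")
            node = truth.node("map.filter", "following_op")
            truth.consume(src.key, node)
            truth.produce(f"{scope}:{name}", name, node)
        else:
            ops = [rng.choice(_CHAIN_OPS) for _ in range(rng.randint(1, 2))]
            chain_txt = "".join(f".{o} {closure()}" for o in ops)
            lines.append(f"{name} = {src.expr}{chain_txt}")
            node = truth.node(".".join(ops), "following_op")
            truth.consume(src.key, node)
            truth.produce(f"{scope}:{name}", name, node)
        avail.append(_Source(expr=name, key=f"{scope}:{name}", named=True))

    def emit_call(p: _ProcPlan, lines: list[str], scope: str,
                  sources: Optional[list[_Source]] = None) -> str:
        """Call *p* once; returns the truth node id."""
        manifest["calls"] += 1
        pipeable = any(s.named and s.has_producer for s in avail)
        use_pipe = p.n_in == 1 and pipeable and rng.random() < 0.3
        args = []
        for _ in range(p.n_in):
            s = pick(named_only=use_pipe) if sources is None else rng.choice(sources)
            args.append(s)
        node = truth.node(p.local, "process")
        if use_pipe and args[0].named and args[0].has_producer:
            lines.append(f"{args[0].expr} | {p.local}")
        else:
            lines.append(f"{p.local}({', '.join(a.expr for a in args)})")
        for a in args:
            truth.consume(a.key, node)
        for i in range(len(p.emits)):
            key = f"{node}.out.{i}"
            truth.produce(key, p.out_label(i), node)
            avail.append(_Source(expr=p.out_expr(i), key=key, named=False))
        if "element_name" not in meta:
            meta["element_name"] = p.local
            meta["element_arity"] = p.n_in
        return node

    for _ in range(n_start):
        emit_factory()

    actions: list = ["op"] * n_follow + [("call", p) for p in entry_procs]
    if use_sub:
        actions.append(("subcall",))
    rng.shuffle(actions)

    # ---- subworkflow body (built at its single call site) ----------------
    sub_name = "SUB_1"
    sub_def_lines: list[str] = []

    def emit_subworkflow_call() -> None:
        nonlocal sub_def_lines
        manifest["calls"] += 1
        src = pick()
        take_src = _Source(expr="tk_1", key=src.key, named=True)
        body: list[str] = []
        local_sources: list[_Source] = [take_src]
        if sub_follow:
            name = new_name("s_ch")
            op = rng.choice(_CHAIN_OPS)
            body.append(f"{name} = {take_src.expr}.{op} {closure()}")
            node = truth.node(op, "following_op")
            truth.consume(take_src.key, node)
            truth.produce(f"sub:{name}", name, node)
            local_sources.append(_Source(expr=name, key=f"sub:{name}", named=True))
            manifest["operations"] += 1
        last = None
        for p in sub_procs:
            manifest["calls"] += 1
            args = [rng.choice(local_sources) for _ in range(p.n_in)]
            node = truth.node(p.local, "process")
            body.append(f"{p.local}({', '.join(a.expr for a in args)})")
            for a in args:
                truth.consume(a.key, node)
            for i in range(len(p.emits)):
                key = f"{node}.out.{i}"
                truth.produce(key, p.out_label(i), node)
                local_sources.append(_Source(expr=p.out_expr(i), key=key, named=False))
            last = (p, node)
        # emit: bind the last process's first output
        p, node = last
        emit_expr = p.out_expr(0)
        sub_def_lines = (
            [f"workflow {sub_name} {{", "    take:", "    tk_1", "", "    main:"]
            + [f"    {l}" for l in body]
            + ["", "    emit:", f"    em_1 = {emit_expr}", "}"]
        )
        entry.append(f"{sub_name}({src.expr})")
        avail.append(_Source(expr=f"{sub_name}.out.em_1", key=f"{node}.out.0",
                             named=False))
        if "element_name" not in meta:
            meta["element_name"] = sub_name
            meta["element_arity"] = 1

    for act in actions:
        if act == "op":
            emit_op(entry, "main", [])
        elif act[0] == "call":
            emit_call(act[1], entry, "main")
        else:
            emit_subworkflow_call()

    if use_sub:
        manifest["subworkflows"] = 1

    # optional never-called definition: retained in the model, no node
    extra_def = None
    if n_proc > 0 and rng.random() < 0.2:
        extra_def = _ProcPlan(name="PROC_SPARE", n_in=1, emits=[None])
    manifest["processes"] = n_proc + (1 if extra_def else 0)

    # ---- assemble files --------------------------------------------------
    modules: dict[str, list[_ProcPlan]] = {}
    for p in procs:
        if p.module:
            modules.setdefault(p.module, []).append(p)

    main_parts = ["nextflow.enable.dsl = 2", ""]
    for mod_path, plist in sorted(modules.items()):
        items = "; ".join(p.name if not p.alias else f"{p.name} as {p.alias}"
                          for p in plist)
        rel = "./" + mod_path[: -len(".nf")]
        main_parts.append(f"include {{ {items} }} from '{rel}'")
        manifest["includes"] += 1
    if modules:
        main_parts.append("")
    for p in procs:
        if not p.module:
            main_parts.append(_proc_def_text(p))
            main_parts.append("")
    if extra_def:
        main_parts.append(_proc_def_text(extra_def))
        main_parts.append("")
    if use_sub and sub_def_lines:
        main_parts.extend(sub_def_lines)
        main_parts.append("")
    main_parts.append("workflow {")
    main_parts.extend(f"    {l}" for l in entry)
    main_parts.append("}")
    files = {"main.nf": "\n".join(main_parts) + "\n"}
    for mod_path, plist in sorted(modules.items()):
        files[mod_path] = "\n\n".join(_proc_def_text(p) for p in plist) + "\n"
    if rng.random() < 0.3:
        files["nextflow.config"] = (
            "manifest {\n"
            f"    name = 'fixture-{seed}'\n"
            "    author = 'Fixture Author'\n"
            "    description = 'Synthetic workflow fixture'\n"
            "}\n")

    meta.setdefault("safe_channel", None)
    meta.setdefault("element_name", None)
    return Fixture(files=files, truth_graph=truth.finish(),
                   truth_manifest=manifest, expected_diagnostics=[],
                   seed=seed, dsl="DSL2", meta=meta)


# ---------------------------------------------------------------------------
# DSL1 generation

def _generate_dsl1(n_proc: int, n_ops: int, p_branch: float,
                   rng: random.Random, seed: int) -> Fixture:
    truth = _Truth()
    manifest = {"processes": n_proc, "subworkflows": 0, "includes": 0,
                "calls": 0, "operations": 0}
    meta: dict = {}
    lines: list[str] = []
    avail: list[str] = []  # DSL1 queue channels: single consumer
    ch_counter = [0]

    def new_name() -> str:
        ch_counter[0] += 1
        return f"ch_{ch_counter[0]}"

    def emit_factory() -> None:
        name = new_name()
        fn, args = rng.choice(_FACTORIES)
        lines.append(f"{name} = Channel.{fn}{args}")
        node = truth.node(f"Channel.{fn}", "starting_op")
        truth.produce(f"main:{name}", name, node)
        avail.append(name)
        manifest["operations"] += 1
        meta.setdefault("safe_channel", name)

    def take_source() -> str:
        if not avail:
            emit_factory()
        i = rng.randrange(len(avail))
        return avail.pop(i)

    n_start = max(1, round(0.4 * n_ops)) if n_ops > 0 else 0
    n_follow = max(0, n_ops - n_start)
    for _ in range(n_start):
        emit_factory()

    procs = []
    for i in range(n_proc):
        procs.append(_ProcPlan(name=f"PROC_{i + 1}", n_in=rng.randint(1, 2),
                               emits=[None] * rng.randint(1, 2)))
        meta.setdefault("element_name", procs[-1].name)

    actions: list = ["op"] * n_follow + [("proc", p) for p in procs]
    rng.shuffle(actions)
    proc_defs: list[str] = []

    for act in actions:
        if act == "op":
            manifest["operations"] += 1
            style = rng.random()
            src = take_source()
            if style < 0.2:
                lines.append(f"{src}.view()")
                node = truth.node("view", "following_op")
                truth.consume(f"main:{src}", node)
            elif style < 0.45:
                a, b = new_name(), new_name()
                lines.append(f"{src}.into {{ {a}; {b} }}")
                node = truth.node("into", "following_op")
                truth.consume(f"main:{src}", node)
                for nm in (a, b):
                    truth.produce(f"main:{nm}", nm, node)
                    avail.append(nm)
            elif style < 0.7:
                name = new_name()
                op = rng.choice(_CHAIN_OPS)
                lines.append(f"{src}.{op} {{ it }}.set {{ {name} }}")
                node = truth.node(f"{op}.set", "following_op")
                truth.consume(f"main:{src}", node)
                truth.produce(f"main:{name}", name, node)
                avail.append(name)
            else:
                name = new_name()
                op = rng.choice(_CHAIN_OPS)
                lines.append(f"{name} = {src}.{op} {{ it }}")
                node = truth.node(op, "following_op")
                truth.consume(f"main:{src}", node)
                truth.produce(f"main:{name}", name, node)
                avail.append(name)
        else:
            p: _ProcPlan = act[1]
            froms = [take_source() for _ in range(p.n_in)]
            intos = [new_name() for _ in p.emits]
            proc_defs.append(_proc_def_text(p, dsl1_from=froms, dsl1_into=intos))
            node = truth.node(p.name, "process")
            for f in froms:
                truth.consume(f"main:{f}", node)
            for nm in intos:
                truth.produce(f"main:{nm}", nm, node)
                avail.append(nm)

    body = lines + [""] + proc_defs if proc_defs else lines
    text = "\n".join(body) + "\n" if body else "// empty workflow\n"
    meta.setdefault("safe_channel", None)
    meta.setdefault("element_name", None)
    return Fixture(files={"main.nf": text}, truth_graph=truth.finish(),
                   truth_manifest=manifest, expected_diagnostics=[],
                   seed=seed, dsl="DSL1", meta=meta)


# ---------------------------------------------------------------------------
# emission and fault injection

def emit_nextflow_source(fixture: Fixture, out_dir: Path) -> list[Path]:
    """Write the fixture's files under *out_dir*; refuses to overwrite."""
    out_dir = Path(out_dir)
    written = []
    for rel, text in fixture.files.items():
        dest = out_dir / rel
        if dest.exists() and dest.read_text(encoding="utf-8") != text:
            raise FileExistsError(f"refusing to overwrite existing '{dest}'")
        dest.parent.mkdir(parents=True, exist_ok=True)
        dest.write_text(text, encoding="utf-8")
        written.append(dest)
    return written


_DSL1_INJECTABLE = {Code.E_SYNTAX, Code.E_NAME_COLLISION, Code.E_BAD_DEFINITION}

_BAD_PROCESS_DEF = """
process INJ_BAD {
    input:
    val a
    input:
    val b

    output:
    path 'x.txt'

    script:
    \"\"\"
    echo bad
    \"\"\"
}
"""

_MULTI_OUT_DEF = """
process INJ_MULTI {
    input:
    val x

    output:
    path 'a.txt', emit: first_out
    path 'b.txt', emit: second_out

    script:
    \"\"\"
    echo multi
    \"\"\"
}
"""

_UNCALLED_DEF = """
process INJ_UNCALLED {
    input:
    val x

    output:
    path 'u.txt'

    script:
    \"\"\"
    echo uncalled
    \"\"\"
}
"""

_TWO_EMIT_SUB_DEF = """
workflow INJ_SUB {
    take:
    inj_tk

    main:
    inj_mid = inj_tk.map { it }

    emit:
    first_e = inj_mid
    second_e = inj_mid
}
"""


def _append_to_entry(main_text: str, lines: list[str]) -> str:
    """Insert statements at the end of the anonymous workflow body."""
    nf = NextflowFile.from_text("main.nf", main_text)
    m = re.search(r"(?m)^workflow\s*\{", nf.masked_source)
    if m is None:
        raise ValueError("fixture has no anonymous entry workflow")
    open_idx = nf.masked_source.index("{", m.start())
    close = find_matching(nf.masked_source, open_idx)
    insert = "".join(f"    {l}\n" for l in lines)
    return main_text[:close] + insert + main_text[close:]


def inject_error(fixture: Fixture, code: Code, seed: int = 0) -> Fixture:
    """Minimal mutation of a clean fixture that triggers exactly *code*."""
    if fixture.expected_diagnostics:
        raise ValueError("inject_error requires a clean fixture")
    code = Code(code)
    if fixture.dsl == "DSL1" and code not in _DSL1_INJECTABLE:
        raise ValueError(f"{code.value} is not applicable to DSL1 fixtures")
    files = dict(fixture.files)
    main = files["main.nf"]
    safe = fixture.meta.get("safe_channel")
    elem = fixture.meta.get("element_name")

    def need(value, what: str):
        if not value:
            raise ValueError(f"fixture lacks a {what} required to inject {code.value}")
        return value

    if code == Code.E_SYNTAX:
        files["main.nf"] = main + "inj_broken = (1\n"
    elif code == Code.E_BAD_DEFINITION:
        files["main.nf"] = main + _BAD_PROCESS_DEF
    elif code == Code.E_NAME_COLLISION:
        stmt = f"{need(elem, 'named element')} = Channel.of(1)"
        if fixture.dsl == "DSL1":
            files["main.nf"] = main + stmt + "\n"
        else:
            files["main.nf"] = _append_to_entry(main, [stmt])
    elif code == Code.E_INCLUDE_MISSING:
        lines = main.split("\n")
        lines.insert(1, "include { INJ_GHOST } from './modules/inj_missing'")
        files["main.nf"] = "\n".join(lines)
    elif code == Code.E_INCLUDE_IN_WORKFLOW:
        files["main.nf"] = _append_to_entry(
            main, ["include { INJ_X } from './inj_nowhere'"])
    elif code == Code.E_ARITY:
        s = need(safe, "producing channel")
        e = need(elem, "named element")
        files["main.nf"] = _append_to_entry(main, [f"{e}({s}, {s}, {s})"])
    elif code == Code.E_EMIT_MULTIPLE:
        s = need(safe, "producing channel")
        files["main.nf"] = _append_to_entry(
            main + _MULTI_OUT_DEF,
            [f"INJ_MULTI({s})", "inj_bad = INJ_MULTI.out.map { it }"])
    elif code == Code.E_EMIT_NOT_CALLED:
        files["main.nf"] = _append_to_entry(
            main + _UNCALLED_DEF, ["inj_bad = INJ_UNCALLED.out.map { it }"])
    elif code == Code.E_SUBWF_EMIT_COUNT:
        s = need(safe, "producing channel")
        files["main.nf"] = _append_to_entry(
            main + _TWO_EMIT_SUB_DEF,
            [f"INJ_SUB({s})", "inj_bad = INJ_SUB.out.map { it }"])
    elif code == Code.E_PIPE_FIRST_UNKNOWN:
        files["main.nf"] = _append_to_entry(main, ["inj_ghost_src | map { it }"])
    elif code == Code.U_PIPE_UNKNOWN:
        s = need(safe, "producing channel")
        files["main.nf"] = _append_to_entry(main, [s + " | inj_frobnicate { it }"])
    elif code == Code.E_UNDEFINED_ELEMENT:
        s = need(safe, "producing channel")
        files["main.nf"] = _append_to_entry(main, [f"INJ_GHOST_PROC({s})"])
    elif code == Code.U_TERNARY_TUPLE:
        files["main.nf"] = _append_to_entry(
            main, ["(inj_a, inj_b) = params.inj_flag ? [1, 2] : [3, 4]"])
    elif code == Code.U_TUPLE_CALL:
        s = need(safe, "producing channel")
        e = need(elem, "named element")
        files["main.nf"] = _append_to_entry(main, [f"(inj_a, inj_b) = {e}({s})"])
    else:  # pragma: no cover - exhaustive above
        raise ValueError(f"unknown code {code}")

    return Fixture(files=files, truth_graph=fixture.truth_graph,
                   truth_manifest=fixture.truth_manifest,
                   expected_diagnostics=[code], seed=seed, dsl=fixture.dsl,
                   meta=dict(fixture.meta))


def fixture_truth_json(fixture: Fixture) -> dict:
    """Serializable ground truth (graph, manifest, expected diagnostics)."""
    g = fixture.truth_graph.g
    return {
        "seed": fixture.seed,
        "dsl": fixture.dsl,
        "manifest": fixture.truth_manifest,
        "expected_diagnostics": [c.value for c in fixture.expected_diagnostics],
        "graph": {
            "nodes": [{"id": n, "label": d.get("label", ""), "kind": d.get("kind", "")}
                      for n, d in g.nodes(data=True)],
            "edges": [{"src": u, "dst": v, "label": d.get("label", "")}
                      for u, v, d in g.edges(data=True)],
        },
    }
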