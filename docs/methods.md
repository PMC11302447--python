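# Methods

## Scope and overall procedure

`nfstruct` recovers the structure of a Nextflow workflow from source text
alone, in three phases:

1. **Workflow analysis.**  The main `.nf` file is cleaned and checked
   (comments blanked, brackets tallied, string literals masked), the DSL
   version identified, and — for DSL2 — every transitively included file is
   cleaned and scanned the same way.  Processes, named/anonymous workflows,
   functions and include directives are extracted per file.
2. **Structure reconstruction.**  Starting from the entry workflow, each
   statement is classified (channel factory, operator chain, process or
   subworkflow call, pipe chain, conditional, inert) and wired into a flat
   node/channel model; the specification graph is transcribed from it.
3. **Structure analysis.**  The two contracted graphs, the metrics report,
   the Mermaid/DOT/PNG serializations and the RO-Crate document are derived
   from the specification graph and the project model.

Any diagnostic raised in a phase stops the pipeline before the next phase;
all findings of the stopping phase are reported together, so a user sees
every same-phase problem at once rather than one per run.

## Lexical model

Full Groovy parsing is out of proportion to the structural facts needed, so
the front end is a single-pass character state machine (states: code, line
comment, block comment, single/double/triple-quoted string).  It produces two
aligned views of each file: `cleaned_source` (comments replaced by
equal-length whitespace — byte offsets, and hence line/column positions for
diagnostics, are preserved) and `masked_source` (string contents additionally
blanked, so braces, keywords or `//` inside strings and `"""` script bodies
can never confuse structural scanning).  Bracket tallying and all construct
recognition run on the masked view; literal content (include paths, manifest
values) is sliced from the cleaned view.

DSL detection: explicit `nextflow.enable.dsl`/`nextflow.preview.dsl`
declarations in the main file or `nextflow.config` win; otherwise a
`workflow` block or `include` directive implies DSL2; otherwise DSL1 (a bare
file of processes is the DSL1 idiom; an empty file also defaults to DSL1).
An explicit DSL1 declaration combined with DSL2 constructs is diagnosed
rather than guessed.  `nextflow.config` is consulted only for the DSL
declaration and the `manifest` block; profiles and params are ignored.

## Graph semantics

- **Nodes** are process call instances and operations.  A chained expression
  (`x.map{...}.filter{...}`) is one operation; consecutive operator stages of
  a pipe likewise collapse into one operation node.  A process called twice
  (or under two include aliases) yields two distinct instances — merging them
  would fabricate joins that do not exist in any execution state.
- **Edges**: every channel contributes its full producer × consumer bipartite
  edge set, labelled with the channel name (emit references are labelled
  `NAME.out[.emit]`).  Channels consumed but never produced (e.g. driven by
  `params` the analyser cannot see) become dangling inputs: their consumers
  simply have no in-edge, and such operations still count as *following*
  because they have declared inputs.
- **Conditionals**: all branches of `if`/`else` are extracted and merged into
  the same scope, which is also the mechanism by which cycles can appear in
  the specification graph.
- **Subworkflows** are flattened at their call site: the body is wired in a
  fresh instance namespace with `take:` names bound to the caller's argument
  channels and `emit:` bindings exposing inner channels to the caller.
  Function definitions never become nodes; calls to them are opaque.
- Only elements reachable from the entry point (the anonymous `workflow {}`
  block, or the single named workflow if no anonymous one exists) produce
  nodes; unreachable definitions stay in the project model.

The operator vocabulary is a single editable registry (the documented channel
operators: `map`, `filter`, `mix`, `join`, `groupTuple`, `set`, `into`, …).
An unknown method on a channel expression is treated as an operator with a
logged warning — except inside pipe chains, where an unknown stage is
reported as an unsupported pattern, because pipe stages must resolve to
something callable for the rewrite to be meaningful.

## Contraction

"Connect two kept nodes if a path exists between them" admits two readings.
The default is *removed-internal* contraction: an edge u → v exists iff some
directed path u → … → v has all internal vertices removed.  This keeps the
simplified graphs minimal (no shortcut edge between nodes already mediated by
a kept node) while provably preserving reachability between kept nodes: any
original path decomposes at its kept vertices into removed-internal segments.
The literal transitive-closure reading is implemented behind the `--closure`
flag.  Parallel edges collapse and labels are dropped at the simplified
levels; a self-loop survives only for an original self-loop or a cycle
through removed nodes returning to the same kept node.

## Diagnostics

The catalogue has exactly 14 classes: three *unsupported* patterns (unknown
pipe element, ternary assigned to a tuple, tuple destructuring of a call) and
eleven *errors* (arity mismatch, name collision, emit misuse ×3, include
faults ×2, unresolvable pipe head, syntax, undefined element, bad
definition).  The severity split lets users distinguish analyser limits from
code faults; both stop the analysis.  Every diagnostic carries file, line and
column where determinable, and a source snippet.  In pipes an unresolvable
first element is an error even though elsewhere unproduced channels are
tolerated as dangling inputs: a pipe head must be an existing value for the
left-to-right rewrite to apply.

## Metrics

Per graph level: node/edge counts, per-kind node counts, sources (in-degree
0) and sinks (out-degree 0), the number of simple source-to-sink paths
(≥ 1 edge, counted over node sequences, capped at 10⁶ with an explicit
`path_cap_hit` flag since path counts explode combinatorially), the longest
path in edges, weak components, degree maxima and a cycle flag.  On cyclic
graphs the longest path is computed on the condensation (each strongly
connected component one step) because the plain longest path is ill-defined
under cycles.  Reports are validated pydantic models (all counts ≥ 0); the
JSON Schema ships under `src/nfstruct/schemas/`.

## Serialization and RO-Crate

Mermaid and DOT outputs order nodes by id and edges by (src, dst, label), so
repeated runs are byte-identical and diffable.  PNG rendering shells out to
graphviz `dot` when present and degrades to a warning otherwise.  The
RO-Crate is a base-profile-conformant JSON-LD document (metadata descriptor,
root dataset, the main file typed `ComputationalWorkflow` with the Nextflow
language entity, one `File` entity per project file, name/description/author
recovered from the config `manifest` block or a README title) plus a clearly
namespaced `nfstruct:` extension entity listing processes, subworkflows and
graph files — conformance first, extension documented.  No timestamps are
embedded, keeping the crate deterministic.

## Synthetic corpus

The fixture generator emulates the project shapes the analyser targets:
DSL1 single-file workflows (processes wired by `from`/`into` named channels,
`.set{}`/`.into{}` forks) and DSL2 projects (include directives with aliases
across module files, an optional subworkflow with `take:`/`main:`/`emit:`
sections, plain and piped calls, named emits, operator chains, conditional
branches producing the same channel from two alternatives).  Defaults used
throughout the conformance runs: fixtures of up to 6 processes and 8
operations with branch probability 0.3 and module-split probability up to 1.0
— comfortably covering the construct mix while keeping each project small
enough that 500 round trips run in seconds.  Process bodies are a trivial
`echo`: structure, not science, is under test.  Generation is a pure function
of its arguments, and the generator records ground truth (graph, element
manifest, expected diagnostics) as it emits code.

`inject_error` applies the minimal mutation triggering exactly one catalogue
code (unbalance a parenthesis, add surplus call arguments, assign a channel
to an element's name, include a nonexistent file, reference an uncalled
element's emit, …).  Include-, call-, emit- and pipe-related codes require
DSL2 and are rejected on DSL1 fixtures.

What passing on this corpus does **not** show: real-world workflows use
Groovy constructs the generator never emits (computed include paths, dynamic
channel expressions, `params`-driven wiring, template scripts), so corpus
conformance bounds correctness of the modelled constructs, not coverage of
the full language.

## Numerical and procedural choices

- Statement splitting is line-based with bracket-depth continuation; `else`
  continuation and leading `.`/`|` continuation lines are honoured.
- Include paths resolve relative to the including file, `.nf` appended when
  missing; no remote/registry resolution.
- `NAME.out` resolves to the most recent call of `NAME` in scope; `.out` on a
  multi-output element in a single-channel context is an error
  (`E_EMIT_MULTIPLE` for processes, `E_SUBWF_EMIT_COUNT` for subworkflows —
  the zero-output case is folded into the same classes).
- Node ids are `scope-path/NAME#k` slugs with a per-name instance counter;
  display labels are the bare local names, so aliased instances render under
  their alias.
- Edge labels for anonymous intermediate channels (inside pipes) are the
  placeholder `<anon>`.

## Known limitations

- No Groovy expression evaluation: closures, `params.*`, string
  interpolation and computed paths are opaque; wiring that depends on them
  appears as dangling inputs or is missed.
- DSL1 support covers the common idiom (top-level operators plus
  `from`/`into` process wiring); exotic DSL1 forms (multi-`into` output
  lists, `when:`-dependent wiring) are not modelled.
- The entry-point rule (anonymous workflow, else the single named workflow)
  cannot disambiguate projects with several named workflows and no anonymous
  block; these are reported as missing an entry element.
- `batch` mode expects one workflow per subdirectory with `main.nf` (or a
  unique `.nf` file) at its root.
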