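# nfstruct

Static reconstruction, linting and export of Nextflow workflow structure.

Nextflow workflows shared on GitHub or WorkflowHub are hard to reuse in part
or to repurpose without first understanding their structure — which processes
exist, which channels connect them, and in what order data flows.  Nextflow
itself only shows a *trace* graph after a run, which requires working inputs
and configuration and reflects a single execution state.  `nfstruct` analyses
the **source code alone** (DSL1 and DSL2, no execution) and reconstructs:

- the **specification graph** — every process call instance and every
  *operation* (a group of chained channel operators) as nodes, every channel
  as labelled edges oriented along the data flow.  Because all conditional
  branches are represented together, this graph may contain cycles;
- the **dependency graph** — the specification graph with *following*
  operations (operations with at least one input) removed, connectivity
  preserved;
- the **process dependency graph** — only the processes and their
  inter-dependencies;
- a **diagnostic report** covering 14 classes of structural code faults
  (wrong call arity, channel/element name collisions, missing include files,
  emit misuse, bracket imbalance, …) with file and line positions;
- per-graph **metrics** (node/edge counts, source-to-sink path counts,
  longest path, degrees, cycles) as validated JSON;
- **Mermaid** and **DOT** serializations (optionally PNG via graphviz), and an
  **RO-Crate** JSON-LD description of the project.

## The model

A workflow is a directed multigraph G = (V, E).  V contains one node per
process call instance and one node per operation; an operation is *starting*
when it consumes no channel (typically a channel factory such as
`Channel.fromPath(...)`) and *following* otherwise.  For every channel with
producer set P and consumer set C, E contains the full bipartite set
P × C of labelled edges, so the graph unifies all execution states.
Subworkflow calls are flattened: their internal nodes are inlined and their
`take:`/`emit:` channels spliced onto the caller's channels.

The simplified levels are computed by *contraction*: keeping a node subset K
(processes and starting operations for the dependency graph; processes only
for the process graph), the contracted graph has an edge u → v, u,v ∈ K, iff
G contains a directed path u → … → v whose internal vertices are all removed.
This preserves reachability between kept nodes exactly without adding
shortcut edges (`--closure` switches to the literal transitive-closure
reading).

## Worked example

A small DSL2 project, `demo/main.nf`:

```nextflow
nextflow.enable.dsl = 2

include { FASTQC; TRIM as TRIM_READS } from './modules/qc'

process ASSEMBLE {
    input:
    val reads

    output:
    path 'contigs.fa', emit: contigs

    script:
    """
    echo assemble
    """
}

workflow {
    reads = Channel.fromPath('data/*.fastq')
    FASTQC(reads)
    trimmed = reads | TRIM_READS | map { it }
    ASSEMBLE(trimmed)
    ASSEMBLE.out.contigs.view()
}
```

with `FASTQC` and `TRIM` defined in `demo/modules/qc.nf`.  Then

```sh
nfstruct analyze demo/main.nf --out demo_out --labels --rocrate
```

exits 0 and writes `spec.mmd` containing:

```
flowchart TD
    n0["ASSEMBLE"]
    n1["FASTQC"]
    n2["TRIM_READS"]
    n3(["Channel.fromPath"])
    n4(("map"))
    n5(("view"))
    n0 -->|"ASSEMBLE.out.contigs"| n5
    n2 -->|"TRIM_READS.out"| n4
    n3 -->|"reads"| n1
    n3 -->|"reads"| n2
    n4 -->|"trimmed"| n0
```

Rectangles are processes (the aliased include is a distinct instance named
`TRIM_READS`), the stadium node is the starting operation, circles are
following operations, and edge labels are channel names — note the pipe chain
`reads | TRIM_READS | map { it }` was expanded into a call plus one
operation.  `proc.dot` holds the process dependency graph, contracted to
`TRIM_READS -> ASSEMBLE` (FASTQC feeds nothing downstream).
`metrics.json` reports for the specification level:

```
"n_nodes": 6, "n_edges": 5, "n_processes": 3,
"n_operations_starting": 1, "n_operations_following": 2,
"n_simple_paths_source_to_sink": 2, "longest_path_len": 4, "has_cycle": false
```

i.e. two source-to-sink paths (one through the assembler to `view`, one
ending at `FASTQC`) and a longest chain of 4 edges.  With a broken workflow —
say an extra argument in the `ASSEMBLE` call — the tool instead stops before
graph construction, exits 1, writes `diagnostics.json`, and prints every
finding of the failing phase:

```
error E_ARITY main.nf:22 call to process 'ASSEMBLE' has 2 argument(s), expected 1
    ASSEMBLE(trimmed, reads)
error E_EMIT_NOT_CALLED main.nf:23 emit of 'ASSEMBLE' accessed but 'ASSEMBLE' has not been called
    ASSEMBLE.out.contigs.view()
```

Other entry points: `nfstruct batch <dir>` analyses one workflow per
subdirectory and writes a summary table; `nfstruct fixtures generate`
produces synthetic projects with known ground truth (optionally with an
injected fault) for testing.

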