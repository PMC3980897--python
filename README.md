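# enroute

Path extraction from biological pathway maps for exploring heterogeneous
experimental datasets — as a headless library and CLI.

## The problem

Pathway maps (KEGG, WikiPathways) are hand-curated diagrams of molecular
interactions whose layout itself carries meaning. Modern studies attach
hundreds of samples and several data types to every gene in such a map —
mRNA expression (numerical), copy-number status (five ordered levels:
homozygous deletion, heterozygous deletion, normal, low gain, high gain),
and mutation status (binary). Coloring nodes in place cannot show that
much data; a plain table loses the topology. This package implements the
dual-view resolution of that conflict:

1. **Pathway overview** — the map in its original geometry. Each node is
   filled with a diverging blue-white-red color for the mean of its
   mapped values, mean(v(r, s)) over all mapped rows r and samples s
   (pathway nodes often stand for whole gene families, so several data
   rows map to one node), carries a green bar scaled by the standard
   deviation, and a marker when data is missing. A selected path is
   wrapped in a continuous corridor whose edge routes dodge non-path
   nodes and whose node interiors are cut out.
2. **Linear path view** — the selected path extracted top-down, one block
   of data rows per node at uniform row height, with joining/leaving
   branches collapsed into countable abstract nodes, and per-sample bar
   charts, copy-number bars, histograms and mutation matrices next to
   each node.

Paths are selected either iteratively (extend node by node, optionally
*forcing* edges the database lacks) or by start/stop: all simple paths
s ⇝ t with at most `max_len` edges are enumerated, sorted by length and
then lexicographically, with the shortest pre-selected. Branch switching
replaces the path above/below an anchor with a chosen branch, following
it until a dead end or the next branching point.

Everything is deterministic: same inputs and seed give byte-identical
SVG, JSON and TSV outputs.

## Worked example

Generate a synthetic study (pathway + coupled mRNA/CNV/mutation matrices
+ sample groups), enumerate paths, and render both views:

```sh
enroute simulate --seed 7 --out demo --n-samples 12
enroute paths --pathway demo/pathway.kgml --start n001 --end n006
```

```json
{
  "start": "n001",
  "end": "n006",
  "status": "ok",
  "selected_index": 0,
  "paths": [
    ["n001", "n007", "n008", "n006"],
    ["n001", "n002", "n003", "n004", "n005", "n006"],
    ...
  ]
}
```

Four alternatives exist between the chosen endpoints; the 4-node route is
shortest and selected by default. Now run the full pipeline from a config:

```yaml
# demo/run.yaml
pathway: pathway.kgml
grouping: groups.tsv
datasets:
- {id: mrna, file: mrna.tsv, dtype: numerical, color_tag: "#7fd4d4"}
- {id: cnv, file: cnv.tsv, dtype: ordinal_cnv, color_tag: "#7fa8d4"}
- {id: mutation, file: mutation.tsv, dtype: binary, color_tag: "#d4b8e8"}
selection: {start: n001, end: n006}
overview_dataset: mrna
```

```sh
enroute run --config demo/run.yaml --out demo/out
```

```json
{
  "nodes": 25,
  "edges": 33,
  "path_len": 4,
  "rows_mapped": 7,
  "spec_json": "demo/out/spec.json",
  "overview_svg": "demo/out/overview.svg",
  "enroute_svg": "demo/out/enroute.svg"
}
```

The pathway has 25 nodes and 33 edges; the selected 4-node path maps onto
7 data rows (one node represents several genes). `overview.svg` shows the
map with on-node means and the corridor-highlighted alternatives;
`enroute.svg` shows the extracted path with per-sample expression bars,
signed copy-number bars, and the mutation matrix per sample group.

Other subcommands: `extract` (linearize a path, with optional
`--switch anchor:head:leaving` branch switches, to JSON),
`render-overview`, `render-path`. Exit codes: 0 ok, 2 usage, 3 data
error, 4 no path.

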