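# Methods

## Problem and model

Pathway maps (KEGG, WikiPathways) are hand-curated node-link diagrams with
fixed, meaningful layouts. Joint analysis of such a map with large,
heterogeneous omics datasets runs into a scale conflict: on-node color
coding preserves the layout but cannot show hundreds of samples, while
tabular views scale but lose the topology. The approach implemented here
resolves the conflict by temporal separation: the whole map is kept in its
original geometry as an overview (with only aggregate on-node mapping),
and a single user-selected path is extracted into a linear top-down view
where per-sample detail is drawn next to each node.

The pathway is modelled as an attributed directed graph. Nodes carry a
kind (gene, compound, map link, or group), a pixel-space bounding box
(center-anchored, origin top-left, y down — the KGML convention, GPML
coordinates adopted unchanged), and an ordered list of namespace-qualified
member gene identifiers. One node frequently stands for a whole protein
family ("multi-mapping"), and a group node ("complex node") aggregates
several subnodes. Edges are typed (activation, inhibition, binding,
conversion, other) and may be undirected (GPML interactions without an
arrowhead); path logic uses only direction, never the type — biological
cascades routinely run through inhibitory links, so inhibition edges are
traversable like any other.

## Path selection

Two selection styles, freely combinable:

* **Iterative** — `extend_path` grows a path by one adjacent node at
  either end; `force_edge` bridges nodes the database does not connect
  (incomplete or outdated maps) and records the injected pair so it can
  be rendered dashed. Paths are always simple; a repeated node is
  rejected. True cycles therefore cannot be selected; this is a
  documented limitation.
* **Start-stop** — `find_alternatives` enumerates *all* simple paths
  between two nodes, bounded by `max_len` edges (default 20) and
  truncated to `max_paths` alternatives (default 64, truncation
  reported). Bounded exhaustive enumeration was chosen over a k-shortest
  algorithm because every alternative must be presentable, not only the
  shortest. Results are sorted by (length, lexicographic node-id
  sequence), so the default selection is a shortest path and the whole
  ordering is independent of node insertion order. Enumeration is
  delegated to `networkx.all_simple_paths` over a directed view in which
  undirected edges appear in both orientations; the test suite checks it
  against an independently written exhaustive DFS.

## Linearization and branches

The extracted path is ordered top-down. For every path node, off-path
in-neighbors form its *joining* branches and off-path out-neighbors its
*leaving* branches; each direction is collapsed into one expandable
abstract node reporting the branch count (heads ordered by label then id
for reproducibility). The path's own predecessor/successor never counts
as a branch. At most one abstract branch is expanded at a time; expansion
only toggles rendering state.

Branch *switching* replaces the path segment below (leaving) or above
(joining) the anchor with a walk starting at the chosen head. The walk
appends the unique eligible continuation — a successor (or predecessor,
for joining) not already on the path — and stops as soon as a node has
zero (dead end) or two or more such continuations (a new branching
point). Eligibility excluding on-path nodes guarantees termination and
simplicity. Forced edges outside the retained segment are discarded.

## Data model and statistics

Three dataset types cover a typical cancer study: numerical matrices
(e.g. mRNA expression), ordinal copy-number status on the five-level
scale homozygous deletion / heterozygous deletion / normal / low gain /
high gain (integer codes −2..2), and binary status (e.g. mutated or
not). Matrices are genes × samples TSVs; empty cells are missing. Sample
groups are ordered, may overlap, and all samples of one group come from
a single dataset.

Node summaries aggregate the multiset {value(row, sample)} of all mapped
rows crossed with the selected samples. Choices made where the contract
was open:

* **Population standard deviation** (ddof = 0): stable for single-sample
  groups; configurable in principle but not expected to matter at the
  sample sizes involved.
* **Ordinal means** use the integer codes −2..2; the five-category
  counts are reported alongside so no information is lost.
* **Missing values are excluded, never imputed.** Any missing mapped
  cell — or a node with no mapped row at all — sets the `has_missing`
  flag that drives the lower-left marker in the overview.
* **Quantitative copy-number thresholds** default to t_low = 0.3 and
  t_high = 1.0 on a log2-ratio-like scale, boundaries closed above
  (value = t_high is a high gain); both are config-exposed since no
  canonical values exist.
* **Identifier aliasing** is explicit and offline: an optional
  two-column TSV maps member ids to dataset row ids; without it, ids
  must match exactly. Real pathway databases use one of many gene
  aliases, so silent fuzzy matching was deliberately avoided.

## Rendering

All SVG output is byte-deterministic (fixed element order, fixed two-
decimal float formatting, no timestamps); the writer is a small internal
string builder.

**Overview.** Nodes are drawn at their original boxes, filled with a
diverging blue-white-red map (white = neutral middle, exact at vmid;
piecewise-linear RGB interpolation; symmetric range from the dataset's
maximum absolute value). Binary data uses a two-color gray-to-red ramp
on the mutated fraction. The standard deviation appears as a green
bottom bar normalised by the pathway-wide maximum std (the scale is a
design choice; the data defines no natural one).

**Corridor.** Selected paths are wrapped in a continuous filled outline:
the union of the member boxes inflated by `radius` (rounded corners) and
strokes of width 2·radius along the routed edges, with the exact member
boxes cut out (even-odd fill) so on-node colors stay legible. This
geometric union replaces a potential-field set-outline algorithm with
identical contracts (continuous outline, node cut-outs, obstacle-avoiding
routes) and is exactly testable with polygon predicates.

**Edge routing.** A path edge is a straight center-to-center segment
when that segment stays at least `margin` away from every non-path leaf
node box (tangency counts as blocked). Otherwise a shortest orthogonal
detour is found by Dijkstra on a visibility grid built from the box
edges pushed out by twice the margin; ties break on coordinates, so the
route is deterministic. Corridor routes are computed with an effective
clearance of `margin + radius` so the buffered band still clears every
obstacle by `margin`. If no clear route exists the straight segment is
returned with a warning (degraded mode). Group nodes are containers
whose boxes hull their children; they are not routing obstacles — a path
through a group member could otherwise never be routed — only leaf
glyphs occlude.

**Linear view.** Each path node gets a block of data rows at a uniform
row height (at least `min_node_height`), stacked top-down with
alternating background shades (two grays, config-exposed) and connected
to its node glyph by a ribbon. Six cell encodings by type and column
style: per-sample vertical bars with a left-to-right gradient (numerical
detailed; the gradient makes adjacent bar borders visible without
outlines; bars grow up/down from the zero line, so a zero value is a
zero-height bar); a horizontal mean bar with std error bars (numerical
abstract); signed category bars — long dark red up for high gain, short
light red up for low gain, nothing for normal, short light blue down and
long dark blue down for deletions, long:short = 2:1 (copy number
detailed; quantitative values are binned through the same thresholds); a
five-bin horizontal histogram in the same colors (copy number abstract);
a fixed-row-count cell matrix filled column-major, red = mutated
(binary detailed, 3 rows by default); and a two-bin histogram (binary
abstract). Detailed column width is proportional to group size; all
abstract columns share one fixed width and per-row baseline so values
can be compared along the path. A set of highlighted sample ids is
outlined in every group and data type in which those samples occur.

## Synthetic study generator

The generator emulates the structure, not the content, of a real study.
The pathway is a directed backbone chain (default 6 nodes) with a planted
two-node parallel branch (guaranteeing at least two alternatives between
the designated start and end), one backbone node carrying 16 member genes
(the complex-node multi-mapping case), one group node with 3 subnode
children, random extra nodes/edges up to the configured sizes (default
24 nodes, 32 edges), and non-overlapping boxes on a jittered grid.

Omics defaults: four sample groups of 30 samples each; copy-number
categories drawn per group, with a gain-heavy distribution
(0.05/0.10/0.35/0.30/0.20 over codes −2..2) in the designated amplified
group and a normal-heavy one (0.05/0.15/0.60/0.15/0.05) elsewhere;
expression = per-group shift (0, 0.4, −0.4, 0.8) + ρ·(copy-number code)
+ unit Gaussian noise with ρ = 1 by default, so amplified samples also
express higher — the coupling an analyst hunts for; mutation status
Bernoulli(0.1); 2% missing cells per matrix. A seed fully determines all
outputs byte-for-byte.

What the generator does **not** emulate: real pathway topology
statistics, hand-drawn layout conventions, LOH/ploidy structure in copy
number, co-mutation patterns, batch effects, or realistic expression
covariance. Passing tests therefore demonstrate correctness of the
mechanics (parsing, enumeration, statistics, geometry, encoding counts),
not biological fidelity.

## Numerical choices and problem sizes

Tie-breaks are everywhere lexicographic on node ids/labels for
reproducibility. Enumeration carries a hard internal cap (20 000 raw
paths) before sorting to bound memory on dense maps; hitting it is
reported as truncation. Degenerate inputs: empty member lists, empty
resolved-row sets, all-missing blocks and single-sample groups all yield
flagged summaries rather than NaNs.

Verification sweeps use 200 seeded random graphs (≤ 12 nodes) against
the exhaustive-DFS oracle, 200 random studies for geometry safety via
exact polygon predicates, 100 datasets for brute-force statistics
agreement (1e-12), 100 KGML round-trips, 50 rendered studies for element
accounting, and parameter recovery at 1000 samples per group (empirical
category fractions within three binomial standard errors). The
acceptance script runs the same pipeline once at 1000 samples/group and
a 50-graph oracle sweep.

## Known limitations

* Non-simple paths (true cycles) cannot be selected.
* Preview mode lists immediate neighbors only, not transitive
  continuations.
* The orthogonal router optimises within its visibility grid; routes are
  shortest on that grid, not globally shortest smooth curves, and the
  degraded straight-segment fallback can overlap obstacles (it warns).
* On-node averages are computed for one explicitly chosen dataset at a
  time; datasets are never pooled.
* Cross-pathway paths and interactive features (tooltips, brushing,
  embedded-pathway navigation) are out of scope; expansion and highlight
  state are inputs, not interactions.
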