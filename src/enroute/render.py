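"""Deterministic SVG rendering of the pathway overview and the linear view.

Two pictures are produced.  The *overview* draws the pathway map in its
original geometry with on-node data mapping: each node is filled with a
diverging blue-white-red color for the mean of its mapped values (gray-red
for binary data), carries a green bottom bar for the standard deviation,
and a small lower-left marker when data is missing; selected paths are
wrapped in a continuous corridor whose edge routes avoid non-path nodes
and whose node interiors are cut out so the on-node colors stay legible.

The *linear view* shows an extracted path top-down with one block of data
rows per node (uniform row height), ribbons tying each node to its rows,
alternating background shades per node, abstract branch nodes on the
left, and six per-cell encodings depending on data type and column style:
vertical per-sample bars (numerical, detailed), a horizontal mean bar
with error bars (numerical, abstract), signed category bars (copy number,
detailed), a five-bin histogram (copy number, abstract), a cell matrix
(binary, detailed), and a two-bin histogram (binary, abstract).

All output is byte-deterministic: fixed element order, fixed float
formatting, no timestamps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, box as shapely_box
from shapely.ops import unary_union

from .data import (
    CNV_DISPLAY_ORDER,
    CnvCategory,
    OmicsDataset,
    SampleGrouping,
    categorize_cnv,
    node_summary,
    resolve_mappings,
)
from .linearize import LinearPathSpec
from .model import PathwayGraph
from .paths import PathAlternatives, SelectedPath

log = logging.getLogger(__name__)


# -- configuration -----------------------------------------------------------


@dataclass(frozen=True)
class RenderConfig:
    """All tunable rendering knobs (pixels unless stated otherwise)."""

    row_height: float = 14.0
    min_node_height: float = 22.0
    node_gap: float = 10.0
    corridor_radius: float = 10.0
    route_margin: float = 5.0
    abstract_width: float = 60.0
    bar_width: float = 4.0
    binary_rows: int = 3
    binary_cell: float = 5.0
    column_gap: float = 6.0
    dataset_gap: float = 14.0
    caption_height: float = 16.0
    node_glyph_width: float = 84.0
    branch_area_width: float = 76.0
    ribbon_gap: float = 26.0
    shade_light: str = "#f0f0f0"
    shade_dark: str = "#e1e1e1"
    low_color: str = "#2166ac"
    mid_color: str = "#ffffff"
    high_color: str = "#b2182b"
    binary_base: str = "#c8c8c8"
    binary_hit: str = "#d7191c"
    missing_fill: str = "#eeeeee"
    variance_color: str = "#2ca02c"
    bar_color: str = "#4878a8"
    bar_color_dark: str = "#32567c"
    cnv_colors: tuple[str, str, str, str] = ("#a50026", "#f4a582", "#92c5de", "#053061")
    # (high_gain, low_gain, het_del, hom_del); normal draws no bar
    t_low: float = 0.3
    t_high: float = 1.0
    column_styles: tuple[tuple[str, str], ...] = ()
    # ((dataset_id, "detailed"|"abstract"), ...); default is detailed

    def style_for(self, dataset_id: str) -> str:
        for ds, style in self.column_styles:
            if ds == dataset_id:
                return style
        return "detailed"

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RenderConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown render config keys: {sorted(unknown)}")
        cleaned = dict(mapping)
        if "column_styles" in cleaned:
            cleaned["column_styles"] = tuple(tuple(p) for p in cleaned["column_styles"])
        if "cnv_colors" in cleaned:
            cleaned["cnv_colors"] = tuple(cleaned["cnv_colors"])
        return cls(**cleaned)


# -- color mapping -----------------------------------------------------------


@dataclass(frozen=True)
class DivergingColorSpec:
    """Piecewise-linear diverging color map anchored at a neutral middle."""

    low_color: tuple[int, int, int]
    mid_color: tuple[int, int, int]
    high_color: tuple[int, int, int]
    vmin: float
    vmid: float
    vmax: float

    def __post_init__(self) -> None:
        if not (self.vmin < self.vmid < self.vmax):
            raise ValueError("need vmin < vmid < vmax")


def hex_to_rgb(color: str) -> tuple[int, int, int]:
    color = color.lstrip("#")
    return (int(color[0:2], 16), int(color[2:4], 16), int(color[4:6], 16))


def rgb_to_hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def diverging_color(value: float, spec: DivergingColorSpec) -> str:
    """Map a value onto the diverging color ramp (clamped to [vmin, vmax]).

    The middle value maps exactly onto the middle color; interpolation is
    channel-wise linear in RGB on either side.
    """
    v = min(max(value, spec.vmin), spec.vmax)
    if v >= spec.vmid:
        t = (v - spec.vmid) / (spec.vmax - spec.vmid)
        a, b = spec.mid_color, spec.high_color
    else:
        t = (spec.vmid - v) / (spec.vmid - spec.vmin)
        a, b = spec.mid_color, spec.low_color
    rgb = tuple(int(round(a[i] + t * (b[i] - a[i]))) for i in range(3))
    return rgb_to_hex(rgb)  # type: ignore[arg-type]


def symmetric_spec(dataset: OmicsDataset, config: RenderConfig) -> DivergingColorSpec:
    """Diverging spec with a symmetric range around zero for a dataset."""
    values = dataset.values.to_numpy(dtype=float)
    finite = values[~np.isnan(values)]
    vmax = float(np.abs(finite).max()) if finite.size else 1.0
    vmax = max(vmax, 1e-9)
    return DivergingColorSpec(
        hex_to_rgb(config.low_color), hex_to_rgb(config.mid_color),
        hex_to_rgb(config.high_color), -vmax, 0.0, vmax,
    )


# -- SVG writing -------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{float(x):.2f}"


class SvgCanvas:
    """Minimal deterministic SVG 1.1 writer (fixed attribute order)."""

    def __init__(self, width: float, height: float) -> None:
        self.width = width
        self.height = height
        self.defs: list[str] = []
        self.body: list[str] = []

    def element(self, tag: str, attrs: list[tuple[str, str]], text: str | None = None) -> None:
        parts = "".join(f' {k}="{v}"' for k, v in attrs)
        if text is None:
            self.body.append(f"<{tag}{parts}/>")
        else:
            self.body.append(f"<{tag}{parts}>{_escape(text)}</{tag}>")

    def rect(self, x: float, y: float, w: float, h: float, fill: str, **extra: str) -> None:
        attrs = [("x", _fmt(x)), ("y", _fmt(y)), ("width", _fmt(w)),
                 ("height", _fmt(h)), ("fill", fill)]
        attrs += sorted(extra.items())
        self.element("rect", attrs)

    def line(self, x1: float, y1: float, x2: float, y2: float, stroke: str, **extra: str) -> None:
        attrs = [("x1", _fmt(x1)), ("y1", _fmt(y1)), ("x2", _fmt(x2)),
                 ("y2", _fmt(y2)), ("stroke", stroke)]
        attrs += sorted(extra.items())
        self.element("line", attrs)

    def polyline(self, points: list[tuple[float, float]], stroke: str, **extra: str) -> None:
        pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in points)
        attrs = [("points", pts), ("fill", "none"), ("stroke", stroke)]
        attrs += sorted(extra.items())
        self.element("polyline", attrs)

    def path(self, d: str, fill: str, **extra: str) -> None:
        attrs = [("d", d), ("fill", fill)]
        attrs += sorted(extra.items())
        self.element("path", attrs)

    def text(self, x: float, y: float, content: str, size: float = 8.0, **extra: str) -> None:
        attrs = [("x", _fmt(x)), ("y", _fmt(y)), ("font-size", _fmt(size)),
                 ("font-family", "sans-serif")]
        attrs += sorted(extra.items())
        self.element("text", attrs, text=content)

    def linear_gradient(self, gradient_id: str, stops: list[tuple[float, str]]) -> None:
        body = "".join(
            f'<stop offset="{_fmt(off)}" stop-color="{color}"/>' for off, color in stops
        )
        self.defs.append(
            f'<linearGradient id="{gradient_id}" x1="0" y1="0" x2="1" y2="0">{body}</linearGradient>'
        )

    def to_string(self) -> str:
        head = (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{_fmt(self.width)}" height="{_fmt(self.height)}" '
            f'viewBox="0 0 {_fmt(self.width)} {_fmt(self.height)}">'
        )
        defs = f"<defs>{''.join(self.defs)}</defs>" if self.defs else ""
        return head + defs + "\n" + "\n".join(self.body) + "\n</svg>\n"


def _escape(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


# -- edge routing and corridor ----------------------------------------------


def _inflated_box(node, pad: float):
    x0, y0, x1, y1 = node.box_corners
    return shapely_box(x0 - pad, y0 - pad, x1 + pad, y1 + pad)


def route_edge(
    graph: PathwayGraph,
    a: str,
    b: str,
    path_nodes: set[str],
    margin: float,
) -> list[tuple[float, float]]:
    """Route a path edge from box center to box center, dodging obstacles.

    The straight segment is returned when it stays at least ``margin``
    away from every non-path node's bounding box (touching the inflated
    box counts as blocked).  Otherwise orthogonal detours around the
    blocking boxes are generated and the shortest candidate that clears
    all obstacles is returned.  When no clear route exists within the
    image, the straight segment is returned with a warning (degraded
    mode).

    Group nodes are containers whose box hulls their children; only leaf
    node glyphs (gene/compound/map-link) act as obstacles, otherwise a
    path through a group member could never be routed.
    """
    na, nb = graph.nodes[a], graph.nodes[b]
    pa = (na.bbox[0], na.bbox[1])
    pb = (nb.bbox[0], nb.bbox[1])
    obstacles = [
        graph.nodes[nid] for nid in sorted(graph.nodes)
        if nid not in path_nodes and nid not in (a, b)
        and graph.nodes[nid].kind != "group"
    ]
    inflated = [(_inflated_box(n, margin), n) for n in obstacles]

    straight = [pa, pb]
    seg = LineString(straight)
    if not any(seg.intersects(geom) for geom, _ in inflated):
        return straight

    route = _orthogonal_route(pa, pb, [n.box_corners for n in obstacles], margin)
    if route is not None:
        return route
    log.warning("route %s->%s: no clear detour found, returning straight segment", a, b)
    return straight


def _orthogonal_route(pa, pb, obstacle_corners, margin):
    """Shortest orthogonal detour via Dijkstra on a visibility grid.

    Grid coordinates are the endpoints plus the obstacle box edges pushed
    out by twice the margin; grid segments touching any margin-inflated
    box (closed, so tangency blocks) are unusable.  Ties are broken by
    coordinate, making the result deterministic.
    """
    import heapq

    pad = 2 * margin
    boxes = [(x0 - margin, y0 - margin, x1 + margin, y1 + margin)
             for x0, y0, x1, y1 in obstacle_corners]
    xs = {pa[0], pb[0]}
    ys = {pa[1], pb[1]}
    for x0, y0, x1, y1 in obstacle_corners:
        xs.update((x0 - pad, x1 + pad))
        ys.update((y0 - pad, y1 + pad))
    xs = sorted(xs)
    ys = sorted(ys)
    xi = {x: i for i, x in enumerate(xs)}
    yi = {y: j for j, y in enumerate(ys)}

    def blocked(p, q) -> bool:
        (px, py), (qx, qy) = p, q
        lo_x, hi_x = min(px, qx), max(px, qx)
        lo_y, hi_y = min(py, qy), max(py, qy)
        for bx0, by0, bx1, by1 in boxes:
            if hi_x >= bx0 and lo_x <= bx1 and hi_y >= by0 and lo_y <= by1:
                return True
        return False

    start = (xi[pa[0]], yi[pa[1]])
    goal = (xi[pb[0]], yi[pb[1]])
    dist: dict[tuple[int, int], float] = {start: 0.0}
    prev: dict[tuple[int, int], tuple[int, int]] = {}
    heap = [(0.0, start)]
    while heap:
        d, node = heapq.heappop(heap)
        if node == goal:
            break
        if d > dist.get(node, math.inf):
            continue
        i, j = node
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if not (0 <= ni < len(xs) and 0 <= nj < len(ys)):
                continue
            p, q = (xs[i], ys[j]), (xs[ni], ys[nj])
            # segments incident to an endpoint may graze that endpoint's
            # own box; obstacles never contain the endpoints, so only the
            # obstacle test applies
            if blocked(p, q):
                continue
            nd = d + abs(q[0] - p[0]) + abs(q[1] - p[1])
            key = (ni, nj)
            if nd < dist.get(key, math.inf) - 1e-12:
                dist[key] = nd
                prev[key] = node
                heapq.heappush(heap, (nd, key))
    if goal not in dist:
        return None
    chain = [goal]
    while chain[-1] != start:
        chain.append(prev[chain[-1]])
    points = [(xs[i], ys[j]) for i, j in reversed(chain)]
    # drop collinear intermediates
    simplified = [points[0]]
    for k in range(1, len(points) - 1):
        q, p, r = simplified[-1], points[k], points[k + 1]
        if (q[0] == p[0] == r[0]) or (q[1] == p[1] == r[1]):
            continue
        simplified.append(p)
    simplified.append(points[-1])
    return simplified


@dataclass
class CorridorGeometry:
    """A continuous corridor wrapping a path, with node interiors cut out."""

    member_boxes: list  # shapely boxes of path nodes (exact bboxes)
    edge_routes: list[list[tuple[float, float]]]
    outline: object  # shapely (Multi)Polygon of the filled corridor band
    holes: list  # shapely boxes excluded from the fill

    @property
    def filled(self):
        """Outline minus the node-interior holes (even-odd fill result)."""
        return self.outline.difference(unary_union(self.holes))


def corridor(
    graph: PathwayGraph,
    path: SelectedPath,
    radius: float,
    margin: float,
) -> CorridorGeometry:
    """Build the corridor geometry highlighting a selected path.

    The corridor is the union of rounded rectangles (member boxes inflated
    by ``radius``) and strokes of width ``2*radius`` along the routed
    edges; the exact member boxes are cut out so on-node color coding
    underneath stays unobscured.  Edge routes are computed with an
    effective clearance of ``margin + radius`` so the buffered band still
    clears every non-path box by ``margin``.
    """
    members = set(path.nodes)
    boxes = [shapely_box(*graph.nodes[n].box_corners) for n in path.nodes]
    routes = []
    for u, v in zip(path.nodes, path.nodes[1:]):
        routes.append(route_edge(graph, u, v, members, margin + radius))
    shapes = [b.buffer(radius, quad_segs=8) for b in boxes]
    shapes += [LineString(r).buffer(radius, quad_segs=8) for r in routes if len(r) >= 2]
    outline = unary_union(shapes)
    return CorridorGeometry(member_boxes=boxes, edge_routes=routes,
                            outline=outline, holes=list(boxes))


def _ring_to_path(coords) -> str:
    pts = list(coords)
    d = f"M {_fmt(pts[0][0])} {_fmt(pts[0][1])}"
    for x, y in pts[1:]:
        d += f" L {_fmt(x)} {_fmt(y)}"
    return d + " Z"


def corridor_svg_path(geometry: CorridorGeometry) -> str:
    """SVG path data for the corridor (outer rings + hole rings, even-odd)."""
    outline = geometry.outline
    polygons = [outline] if outline.geom_type == "Polygon" else list(outline.geoms)
    parts: list[str] = []
    for poly in polygons:
        parts.append(_ring_to_path(poly.exterior.coords))
        for interior in poly.interiors:
            parts.append(_ring_to_path(interior.coords))
    for hole in geometry.holes:
        parts.append(_ring_to_path(hole.exterior.coords))
    return " ".join(parts)


# -- pathway overview --------------------------------------------------------

_ALTERNATIVE_PALETTE = ("#ff7f00", "#6a3d9a", "#33a02c", "#1f78b4", "#e31a1c",
                        "#b15928", "#a6cee3", "#fb9a99")


def render_overview(
    graph: PathwayGraph,
    dataset: OmicsDataset,
    grouping: SampleGrouping | None = None,
    selection: PathAlternatives | SelectedPath | None = None,
    config: RenderConfig = RenderConfig(),
    alias_table: dict[str, str] | None = None,
) -> str:
    """Render the annotated pathway overview as an SVG string.

    Every node is drawn at its original bounding box, filled with the
    diverging color of its mapped mean (gray-red for binary data), with a
    green bottom bar scaled by its standard deviation relative to the
    pathway-wide maximum, and a small lower-left marker when values are
    missing.  Selected paths are overlaid as corridors, one color per
    alternative with the selected one emphasized; forced edges are drawn
    dashed.
    """
    if grouping is not None:
        grouping.validate(dataset)
    spec = symmetric_spec(dataset, config)

    summaries = {
        node_id: node_summary(graph.nodes[node_id], dataset,
                              alias_table=alias_table, graph=graph)
        for node_id in sorted(graph.nodes)
    }
    stds = [s.std for s in summaries.values() if s.std is not None]
    std_max = max(stds) if stds else 0.0

    canvas = SvgCanvas(graph.image_size[0], graph.image_size[1])
    canvas.rect(0, 0, graph.image_size[0], graph.image_size[1], "#ffffff")

    # corridors under the node rects would be hidden; the cut-out holes
    # keep node interiors visible, so corridors are drawn first and the
    # node fills re-drawn inside the holes afterwards (paint order below).
    paths_to_draw: list[tuple[SelectedPath, str, float]] = []
    if isinstance(selection, SelectedPath):
        paths_to_draw = [(selection, _ALTERNATIVE_PALETTE[0], 0.45)]
    elif isinstance(selection, PathAlternatives) and selection.paths:
        for i, alt in enumerate(selection.paths):
            if i == selection.selected_index:
                continue
            color = _ALTERNATIVE_PALETTE[(i + 1) % len(_ALTERNATIVE_PALETTE)]
            paths_to_draw.append((alt, color, 0.25))
        paths_to_draw.append((selection.selected, _ALTERNATIVE_PALETTE[0], 0.5))

    for sel_path, color, opacity in paths_to_draw:
        geometry = corridor(graph, sel_path, config.corridor_radius, config.route_margin)
        canvas.path(corridor_svg_path(geometry), color, **{
            "class": "corridor", "fill-opacity": _fmt(opacity),
            "fill-rule": "evenodd", "stroke": color, "stroke-width": "1.00",
        })
        for u, v in sorted(sel_path.forced_edges):
            nu, nv = graph.nodes[u], graph.nodes[v]
            canvas.line(nu.bbox[0], nu.bbox[1], nv.bbox[0], nv.bbox[1], color,
                        **{"class": "forced", "stroke-dasharray": "5,3",
                           "stroke-width": "2.00"})

    for node_id in sorted(graph.nodes):
        node = graph.nodes[node_id]
        summary = summaries[node_id]
        x0, y0, x1, y1 = node.box_corners
        if summary.mean is None:
            fill = config.missing_fill
        elif dataset.dtype == "binary":
            base, hit = hex_to_rgb(config.binary_base), hex_to_rgb(config.binary_hit)
            t = summary.mutated_fraction
            fill = rgb_to_hex(tuple(int(round(base[i] + t * (hit[i] - base[i])))
                                    for i in range(3)))  # type: ignore[arg-type]
        else:
            fill = diverging_color(summary.mean, spec)
        canvas.rect(x0, y0, node.bbox[2], node.bbox[3], fill,
                    **{"class": "nodebox", "stroke": "#555555", "stroke-width": "0.50"})
        if summary.std is not None and std_max > 0 and summary.std > 0:
            bar_w = node.bbox[2] * (summary.std / std_max)
            canvas.rect(x0, y1 - 3, bar_w, 3, config.variance_color,
                        **{"class": "stdbar"})
        if summary.has_missing:
            canvas.rect(x0, y1 - 4, 4, 4, "#666666", **{"class": "missmark"})
        if node.label:
            canvas.text(node.bbox[0], node.bbox[1] + 3, node.label, size=7.0,
                        **{"text-anchor": "middle"})
    return canvas.to_string()


# -- linear layout -----------------------------------------------------------


@dataclass(frozen=True)
class NodeBlock:
    node_id: str
    y_top: float
    y_bottom: float
    rows: tuple[str, ...]
    shade: str  # "light" | "dark"


@dataclass(frozen=True)
class ColumnSlot:
    dataset_id: str
    group_label: str
    x_left: float
    width: float
    style: str  # "detailed" | "abstract"
    dtype: str
    samples: tuple[str, ...]


@dataclass(frozen=True)
class BranchSlot:
    anchor: str
    direction: str
    y_center: float
    n_heads: int
    expanded: bool
    heads: tuple[str, ...]


@dataclass(frozen=True)
class LinearLayout:
    """Geometry of the linear view: node blocks, columns, branch slots."""

    row_height: float
    nodes: tuple[NodeBlock, ...]
    columns: tuple[ColumnSlot, ...]
    branch_slots: tuple[BranchSlot, ...]
    width: float
    height: float
    node_x: float
    node_width: float
    data_x0: float


def layout_linear(
    spec: LinearPathSpec,
    datasets: dict[str, OmicsDataset],
    groupings: dict[str, SampleGrouping],
    config: RenderConfig = RenderConfig(),
    alias_table: dict[str, str] | None = None,
    graph: PathwayGraph | None = None,
) -> LinearLayout:
    """Compute the top-down geometry of a linearized path.

    Each path node gets a block tall enough for all of its mapped data
    rows at the uniform row height (at least ``min_node_height``); blocks
    are stacked in path order with a fixed gap and alternate between two
    background shades.  Detailed columns are as wide as their sample
    count demands (width proportional to group size); abstract columns
    all share the fixed ``abstract_width``.
    """
    if graph is None:
        raise ValueError("layout_linear needs the pathway graph to resolve rows")

    node_rows: list[tuple[str, ...]] = []
    for node_id in spec.path.nodes:
        node = graph.nodes[node_id]
        rows: list[str] = []
        for dataset_id in sorted(datasets):
            for row_id in resolve_mappings(node, datasets[dataset_id], alias_table, graph):
                if row_id not in rows:
                    rows.append(row_id)
        node_rows.append(tuple(rows))

    y = config.caption_height + config.node_gap
    blocks: list[NodeBlock] = []
    shades = ("light", "dark")
    for i, node_id in enumerate(spec.path.nodes):
        rows = node_rows[i]
        height = max(config.min_node_height, len(rows) * config.row_height)
        blocks.append(NodeBlock(node_id, y, y + height, rows, shades[i % 2]))
        y += height + config.node_gap

    node_x = config.branch_area_width
    data_x0 = node_x + config.node_glyph_width + config.ribbon_gap
    x = data_x0
    columns: list[ColumnSlot] = []
    for dataset_id in sorted(datasets):
        dataset = datasets[dataset_id]
        grouping = groupings.get(dataset_id)
        if grouping is None:
            continue
        style = config.style_for(dataset_id)
        for label, samples in grouping.groups:
            if style == "abstract":
                width = config.abstract_width
            elif dataset.dtype == "binary":
                n_cols = math.ceil(len(samples) / config.binary_rows)
                width = max(n_cols * config.binary_cell, config.binary_cell)
            else:
                width = max(len(samples) * config.bar_width, config.bar_width)
            columns.append(ColumnSlot(dataset_id, label, x, width, style,
                                      dataset.dtype, tuple(samples)))
            x += width + config.column_gap
        x += config.dataset_gap

    branch_slots: list[BranchSlot] = []
    block_of = {b.node_id: b for b in blocks}
    for branch in spec.branches:
        block = block_of[branch.anchor]
        offset = -config.row_height / 2 if branch.direction == "joining" else config.row_height / 2
        y_center = (block.y_top + block.y_bottom) / 2 + offset
        branch_slots.append(BranchSlot(branch.anchor, branch.direction, y_center,
                                       len(branch.heads), branch.expanded, branch.heads))

    width = x + 10.0
    height = y + config.caption_height + 10.0
    return LinearLayout(
        row_height=config.row_height, nodes=tuple(blocks), columns=tuple(columns),
        branch_slots=tuple(branch_slots), width=width, height=height,
        node_x=node_x, node_width=config.node_glyph_width, data_x0=data_x0,
    )


# -- linear view rendering ---------------------------------------------------


def _cnv_category_of(value: float, dataset: OmicsDataset, config: RenderConfig):
    if np.isnan(value):
        return None
    if dataset.dtype == "ordinal_cnv":
        return CnvCategory(int(value))
    return categorize_cnv(value, config.t_low, config.t_high)


def _cnv_bar(category: CnvCategory, half: float, config: RenderConfig):
    """(signed length, color) of a copy-number bar; None for normal."""
    long, short = 0.9 * half, 0.45 * half
    high, low, het, hom = config.cnv_colors
    table = {
        CnvCategory.high_gain: (-long, high),
        CnvCategory.low_gain: (-short, low),
        CnvCategory.het_del: (short, het),
        CnvCategory.hom_del: (long, hom),
    }
    return table.get(category)


def render_enroute(
    layout: LinearLayout,
    datasets: dict[str, OmicsDataset],
    groupings: dict[str, SampleGrouping],
    highlights: set[str] | None = None,
    config: RenderConfig = RenderConfig(),
    graph: PathwayGraph | None = None,
    spec: LinearPathSpec | None = None,
) -> str:
    """Render the linear path view with all six data encodings.

    ``highlights`` is a set of sample ids outlined wherever they occur,
    across groups and data types, which is how a selection made in one
    group (say, high copy number) can be traced into another (say, the
    expression bars).
    """
    highlights = highlights or set()
    canvas = SvgCanvas(layout.width, layout.height)
    canvas.rect(0, 0, layout.width, layout.height, "#ffffff")
    canvas.linear_gradient("bargrad", [(0.0, config.bar_color_dark), (1.0, config.bar_color)])

    specs = {ds_id: symmetric_spec(ds, config) for ds_id, ds in datasets.items()
             if ds.dtype == "numerical"}
    data_width = max((c.x_left + c.width for c in layout.columns), default=layout.data_x0)

    shade_fill = {"light": config.shade_light, "dark": config.shade_dark}
    for block in layout.nodes:
        canvas.rect(layout.data_x0 - 4, block.y_top, data_width - layout.data_x0 + 8,
                    block.y_bottom - block.y_top, shade_fill[block.shade],
                    **{"class": "rowshade"})

    # group captions, top and bottom, on the dataset's color tag
    for column in layout.columns:
        tag = datasets[column.dataset_id].color_tag
        for cy in (0.0, layout.height - config.caption_height):
            canvas.rect(column.x_left, cy, column.width, config.caption_height, tag,
                        **{"class": "caption"})
            canvas.text(column.x_left + column.width / 2, cy + config.caption_height - 4,
                        column.group_label, size=7.0, **{"text-anchor": "middle"})

    # node glyphs + ribbons
    for block in layout.nodes:
        y_mid = (block.y_top + block.y_bottom) / 2
        canvas.rect(layout.node_x, y_mid - 9, layout.node_width, 18, "#dce6f2",
                    **{"class": "pathnode", "stroke": "#44546a", "stroke-width": "0.80"})
        label = graph.nodes[block.node_id].label if graph else block.node_id
        canvas.text(layout.node_x + layout.node_width / 2, y_mid + 3, label,
                    size=8.0, **{"text-anchor": "middle"})
        x0 = layout.node_x + layout.node_width
        d = (f"M {_fmt(x0)} {_fmt(y_mid - 7)} L {_fmt(layout.data_x0 - 4)} {_fmt(block.y_top)} "
             f"L {_fmt(layout.data_x0 - 4)} {_fmt(block.y_bottom)} L {_fmt(x0)} {_fmt(y_mid + 7)} Z")
        canvas.path(d, "#b0b8c8", **{"class": "ribbon", "fill-opacity": "0.55"})

    # path spine between consecutive node glyphs
    spine_x = layout.node_x + layout.node_width / 2
    for upper, lower in zip(layout.nodes, layout.nodes[1:]):
        y0 = (upper.y_top + upper.y_bottom) / 2 + 9
        y1 = (lower.y_top + lower.y_bottom) / 2 - 9
        forced = spec is not None and (upper.node_id, lower.node_id) in spec.path.forced_edges
        extra = {"class": "spine", "stroke-width": "1.60"}
        if forced:
            extra["stroke-dasharray"] = "5,3"
        canvas.line(spine_x, y0, spine_x, y1, "#44546a", **extra)

    # abstract branch nodes on the left of the path axis
    for slot in layout.branch_slots:
        bx = 8.0
        glyph_fill = "#f4e8d0" if slot.direction == "joining" else "#d8ecd8"
        canvas.rect(bx, slot.y_center - 7, layout.node_x - 16, 14, glyph_fill,
                    **{"class": "branchnode", "stroke": "#777777", "stroke-width": "0.60"})
        arrow = "→" if slot.direction == "joining" else "←"
        canvas.text(bx + 4, slot.y_center + 3,
                    f"{slot.n_heads} {arrow}", size=7.0)
        if slot.expanded:
            for k, head in enumerate(slot.heads):
                hy = slot.y_center + 16 + k * 12
                label = graph.nodes[head].label if graph else head
                canvas.rect(bx, hy - 6, layout.node_x - 16, 11, "#ffffff",
                            **{"class": "branchhead", "stroke": "#999999",
                               "stroke-width": "0.50"})
                canvas.text(bx + 4, hy + 3, label, size=6.5)

    # data cells
    for block in layout.nodes:
        for j, row_id in enumerate(block.rows):
            y_row = block.y_top + j * layout.row_height
            for column in layout.columns:
                dataset = datasets[column.dataset_id]
                if row_id not in dataset.values.index:
                    continue
                _draw_cell(canvas, dataset, row_id, column, y_row, layout.row_height,
                           specs.get(column.dataset_id), highlights, config)
    return canvas.to_string()


def _draw_cell(canvas, dataset, row_id, column, y_row, row_h, color_spec,
               highlights, config) -> None:
    values = dataset.values.loc[row_id, list(column.samples)].to_numpy(dtype=float)
    half = row_h / 2
    baseline = y_row + half
    if column.style == "detailed":
        if dataset.dtype == "numerical":
            vmax = color_spec.vmax if color_spec else 1.0
            for k, (sample, value) in enumerate(zip(column.samples, values)):
                if np.isnan(value):
                    continue
                h = abs(value) / vmax * (half - 1)
                y0 = baseline - h if value >= 0 else baseline
                extra = {"class": "bar"}
                if sample in highlights:
                    extra.update({"stroke": "#000000", "stroke-width": "0.80"})
                canvas.rect(column.x_left + k * config.bar_width, y0,
                            config.bar_width * 0.9, h, "url(#bargrad)", **extra)
        elif dataset.dtype == "ordinal_cnv":
            for k, (sample, value) in enumerate(zip(column.samples, values)):
                category = _cnv_category_of(value, dataset, config)
                if category is None:
                    continue
                bar = _cnv_bar(category, half, config)
                if bar is None:
                    continue  # normal copy number: no bar
                signed, color = bar
                y0 = baseline + min(0.0, signed)
                extra = {"class": "cnvbar"}
                if sample in highlights:
                    extra.update({"stroke": "#000000", "stroke-width": "0.80"})
                canvas.rect(column.x_left + k * config.bar_width, y0,
                            config.bar_width * 0.9, abs(signed), color, **extra)
        else:  # binary matrix, column-major fill with a fixed row count
            cell = config.binary_cell
            for k, (sample, value) in enumerate(zip(column.samples, values)):
                col_i, row_i = divmod(k, config.binary_rows)
                if np.isnan(value):
                    fill = config.missing_fill
                elif value >= 0.5:
                    fill = config.binary_hit
                else:
                    fill = config.binary_base
                extra = {"class": "mcell"}
                if sample in highlights:
                    extra.update({"stroke": "#000000", "stroke-width": "0.80"})
                canvas.rect(column.x_left + col_i * cell, y_row + 1 + row_i * (cell - 1),
                            cell - 0.6, cell - 1.6, fill, **extra)
    else:  # abstract
        present = values[~np.isnan(values)]
        if present.size == 0:
            return
        zero_x = column.x_left + column.width / 2
        if dataset.dtype == "numerical":
            vmax = color_spec.vmax if color_spec else 1.0
            mean = float(present.mean())
            std = float(present.std(ddof=0))
            scale = (column.width / 2 - 2) / vmax
            x0 = zero_x + min(0.0, mean) * scale
            canvas.rect(x0, baseline - 3, abs(mean) * scale, 6, config.bar_color,
                        **{"class": "abar"})
            lo, hi = (mean - std) * scale + zero_x, (mean + std) * scale + zero_x
            canvas.line(lo, baseline, hi, baseline, "#333333",
                        **{"class": "errbar", "stroke-width": "0.80"})
            for xe in (lo, hi):
                canvas.line(xe, baseline - 3, xe, baseline + 3, "#333333",
                            **{"class": "errtick", "stroke-width": "0.80"})
        elif dataset.dtype == "ordinal_cnv":
            counts = [int(np.count_nonzero(present == float(c.value)))
                      for c in CNV_DISPLAY_ORDER]
            total = max(sum(counts), 1)
            bin_h = (row_h - 2) / len(counts)
            high, low, het, hom = config.cnv_colors
            colors = {CnvCategory.high_gain: high, CnvCategory.low_gain: low,
                      CnvCategory.normal: "#bbbbbb", CnvCategory.het_del: het,
                      CnvCategory.hom_del: hom}
            for i, (category, count) in enumerate(zip(CNV_DISPLAY_ORDER, counts)):
                if count == 0:
                    continue
                length = count / total * (column.width - 4)
                canvas.rect(column.x_left + 2, y_row + 1 + i * bin_h, length,
                            bin_h * 0.85, colors[category], **{"class": "cnvhist"})
        else:  # binary two-bin histogram
            mutated = int(np.count_nonzero(present >= 0.5))
            non = int(present.size - mutated)
            total = max(mutated + non, 1)
            bin_h = (row_h - 2) / 2
            for i, (count, color) in enumerate(((mutated, config.binary_hit),
                                                (non, config.binary_base))):
                if count == 0:
                    continue
                length = count / total * (column.width - 4)
                canvas.rect(column.x_left + 2, y_row + 1 + i * bin_h, length,
                            bin_h * 0.85, color, **{"class": "binhist"})
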