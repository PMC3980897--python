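"""Rendering: colors, edge routing, corridor geometry, layouts, SVG."""

import math
import re

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, box as shapely_box

from enroute.data import OmicsDataset, SampleGrouping
from enroute.linearize import compute_branches
from enroute.paths import SelectedPath
from enroute.render import (
    DivergingColorSpec,
    RenderConfig,
    corridor,
    diverging_color,
    hex_to_rgb,
    layout_linear,
    render_enroute,
    render_overview,
    route_edge,
    symmetric_spec,
)

from conftest import build_graph, small_dataset

SPEC = DivergingColorSpec(hex_to_rgb("#2166ac"), hex_to_rgb("#ffffff"),
                          hex_to_rgb("#b2182b"), -2.0, 0.0, 2.0)


class TestDivergingColor:
    def test_middle_maps_to_mid_color_exactly(self):
        assert diverging_color(0.0, SPEC) == "#ffffff"

    def test_extremes_map_to_end_colors(self):
        assert diverging_color(2.0, SPEC) == "#b2182b"
        assert diverging_color(-2.0, SPEC) == "#2166ac"
        # clamped beyond the range
        assert diverging_color(99.0, SPEC) == "#b2182b"

    def test_halfway_is_channelwise_midpoint(self):
        mid = hex_to_rgb(diverging_color(1.0, SPEC))
        expected = tuple(round((255 + c) / 2) for c in hex_to_rgb("#b2182b"))
        assert mid == expected

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DivergingColorSpec((0, 0, 0), (1, 1, 1), (2, 2, 2), 1.0, 0.0, 2.0)


def _clearance(points, graph, path_nodes, margin):
    """Min distance from the polyline to any non-path leaf box."""
    line = LineString(points)
    dist = math.inf
    for nid, node in graph.nodes.items():
        if nid in path_nodes or node.kind == "group":
            continue
        dist = min(dist, line.distance(shapely_box(*node.box_corners)))
    return dist


class TestRouteEdge:
    def test_no_blockers_straight_segment(self):
        g = build_graph(["A", "B"], [("A", "B")])
        route = route_edge(g, "A", "B", {"A", "B"}, margin=5.0)
        assert len(route) == 2

    def test_central_blocker_detoured_with_clearance(self):
        # C sits exactly on the straight A-B segment
        g = build_graph(["A", "C", "B"], [("A", "B")], grid_cols=3)
        route = route_edge(g, "A", "B", {"A", "B"}, margin=5.0)
        assert len(route) >= 4
        assert _clearance(route, g, {"A", "B"}, 5.0) > 5.0

    def test_tangent_blocker_treated_as_blocked(self):
        # a box whose inflated boundary exactly touches the segment
        from enroute.model import PathwayNode, PathwayGraph, PathwayEdge
        nodes = {
            "A": PathwayNode("A", "gene", "A", (0.0, 0.0, 10.0, 10.0), ("symbol:A",)),
            "B": PathwayNode("B", "gene", "B", (200.0, 0.0, 10.0, 10.0), ("symbol:B",)),
            # top edge of the inflated box (margin 5) reaches y=0 exactly
            "T": PathwayNode("T", "gene", "T", (100.0, 15.0, 20.0, 20.0), ("symbol:T",)),
        }
        g = PathwayGraph("t", "t", (300.0, 100.0), nodes, [PathwayEdge("A", "B")])
        route = route_edge(g, "A", "B", {"A", "B"}, margin=5.0)
        assert len(route) >= 4  # detour, not the straight tangent segment

    def test_blocked_route_emits_warning_in_degraded_mode(self, caplog):
        from enroute.model import PathwayNode, PathwayGraph, PathwayEdge
        # obstacles completely surround B: no clear orthogonal detour
        nodes = {
            "A": PathwayNode("A", "gene", "A", (50.0, 50.0, 10.0, 10.0), ("symbol:A",)),
            "B": PathwayNode("B", "gene", "B", (52.0, 80.0, 10.0, 10.0), ("symbol:B",)),
        }
        for i, (dx, dy) in enumerate([(-14, 0), (14, 0), (0, -14), (0, 14)]):
            nid = f"w{i}"
            nodes[nid] = PathwayNode(nid, "gene", nid,
                                     (52.0 + dx * 1.0, 80.0 + dy, 12.0, 12.0),
                                     (f"symbol:{nid}",))
        g = PathwayGraph("t", "t", (200.0, 200.0), nodes, [PathwayEdge("A", "B")])
        with caplog.at_level("WARNING"):
            route = route_edge(g, "A", "B", {"A", "B"}, margin=6.0)
        assert route[0] == (50.0, 50.0) and route[-1] == (52.0, 80.0)


class TestCorridor:
    def test_single_node_rounded_rect_with_hole(self):
        g = build_graph(["A"], [])
        geom = corridor(g, SelectedPath("test", ("A",)), radius=10.0, margin=5.0)
        filled = geom.filled
        assert filled.geom_type == "Polygon"
        assert len(filled.interiors) == 1  # the node cut-out

    def test_two_adjacent_nodes_simply_connected_two_holes(self):
        g = build_graph(["A", "B"], [("A", "B")], grid_cols=2)
        geom = corridor(g, SelectedPath("test", ("A", "B")), radius=10.0, margin=5.0)
        filled = geom.filled
        assert filled.geom_type == "Polygon"  # one connected band
        assert len(filled.interiors) == 2

    def test_blocker_on_path_edge_is_avoided(self):
        # caspase-cascade style: the straight CASP9-CASP3 edge would cross
        # CASP7, which is not on the path
        g = build_graph(["CASP9", "CASP7", "CASP3"], [("CASP9", "CASP3")],
                        grid_cols=3)
        path = SelectedPath("test", ("CASP9", "CASP3"))
        geom = corridor(g, path, radius=10.0, margin=5.0)
        blocker = shapely_box(*g.nodes["CASP7"].box_corners).buffer(5.0, join_style="mitre")
        assert not geom.filled.intersects(blocker)

    def test_union_matches_shapely_oracle(self):
        from shapely.ops import unary_union
        g = build_graph(["A", "B"], [("A", "B")], grid_cols=2)
        geom = corridor(g, SelectedPath("test", ("A", "B")), radius=8.0, margin=4.0)
        oracle = unary_union(
            [shapely_box(*g.nodes[n].box_corners).buffer(8.0, quad_segs=8)
             for n in ("A", "B")]
            + [LineString(r).buffer(8.0, quad_segs=8) for r in geom.edge_routes]
        )
        assert geom.outline.symmetric_difference(oracle).area < 1e-6


def _mini_study():
    genes = ["symbol:gA", "symbol:gB"]
    samples = [f"s{i}" for i in range(6)]
    rng = np.random.default_rng(7)
    mrna = OmicsDataset("mrna", "numerical",
                        pd.DataFrame(rng.normal(size=(2, 6)), index=genes, columns=samples),
                        color_tag="#7fd4d4")
    mut = OmicsDataset("mut", "binary",
                       pd.DataFrame(rng.integers(0, 2, size=(2, 6)).astype(float),
                                    index=genes, columns=samples),
                       color_tag="#d4b8e8")
    groups = [("left", samples[:3]), ("right", samples[3:])]
    groupings = {"mrna": SampleGrouping("mrna", [(l, list(s)) for l, s in groups]),
                 "mut": SampleGrouping("mut", [(l, list(s)) for l, s in groups])}
    g = build_graph(["A", "B", "C"], [("A", "B"), ("B", "C")],
                    members={"A": ("symbol:gA",), "B": ("symbol:gB",),
                             "C": ("symbol:gA", "symbol:gB")})
    return g, {"mrna": mrna, "mut": mut}, groupings


class TestLayoutLinear:
    def test_three_nodes_alternating_shades(self):
        g, datasets, groupings = _mini_study()
        spec = compute_branches(g, SelectedPath("test", ("A", "B", "C")))
        layout = layout_linear(spec, datasets, groupings, graph=g)
        assert [b.shade for b in layout.nodes] == ["light", "dark", "light"]
        # blocks ordered top-down and disjoint
        for upper, lower in zip(layout.nodes, layout.nodes[1:]):
            assert upper.y_bottom < lower.y_top

    def test_sixteen_row_block_height(self):
        members = tuple(f"symbol:m{i:02d}" for i in range(16))
        g = build_graph(["X", "Y"], [("X", "Y")], members={"X": members})
        values = pd.DataFrame(np.zeros((17, 2)),
                              index=list(members) + ["symbol:Y"], columns=["s1", "s2"])
        ds = OmicsDataset("d", "numerical", values)
        grouping = {"d": SampleGrouping("d", [("all", ["s1", "s2"])])}
        spec = compute_branches(g, SelectedPath("test", ("X", "Y")))
        config = RenderConfig(row_height=14.0)
        layout = layout_linear(spec, {"d": ds}, grouping, config, graph=g)
        block = layout.nodes[0]
        assert len(block.rows) == 16
        assert block.y_bottom - block.y_top == pytest.approx(16 * 14.0)

    def test_detailed_column_width_proportional_to_group_size(self):
        genes = ["symbol:gA"]
        samples = [f"s{i}" for i in range(40)]
        ds = OmicsDataset("d", "numerical",
                          pd.DataFrame(np.zeros((1, 40)), index=genes, columns=samples))
        grouping = {"d": SampleGrouping("d", [("small", samples[:10]),
                                              ("large", samples[10:])])}
        g = build_graph(["A"], [], members={"A": ("symbol:gA",)})
        spec = compute_branches(g, SelectedPath("test", ("A",)))
        layout = layout_linear(spec, {"d": ds}, grouping, graph=g)
        widths = {c.group_label: c.width for c in layout.columns}
        assert widths["large"] / widths["small"] == pytest.approx(3.0)

    def test_abstract_columns_share_fixed_width(self):
        g, datasets, groupings = _mini_study()
        config = RenderConfig(column_styles=(("mrna", "abstract"), ("mut", "abstract")))
        spec = compute_branches(g, SelectedPath("test", ("A", "B")))
        layout = layout_linear(spec, datasets, groupings, config, graph=g)
        assert {c.width for c in layout.columns} == {config.abstract_width}


class TestRenderOverview:
    def test_constant_data_renders_white_nodes_without_variance_bars(self):
        g, _, _ = _mini_study()
        values = pd.DataFrame(np.zeros((2, 3)), index=["symbol:gA", "symbol:gB"],
                              columns=["s1", "s2", "s3"])
        ds = OmicsDataset("d", "numerical", values)
        svg = render_overview(g, ds)
        assert 'class="stdbar"' not in svg
        assert svg.count('fill="#ffffff"') >= len(g.nodes)

    def test_single_node_extreme_value_is_saturated_red(self):
        g = build_graph(["A"], [], members={"A": ("symbol:gA",)})
        ds = OmicsDataset("d", "numerical",
                          pd.DataFrame([[3.0]], index=["symbol:gA"], columns=["s1"]))
        svg = render_overview(g, ds)
        config = RenderConfig()
        assert f'fill="{config.high_color}"' in svg

    def test_node_fills_equal_color_recomputation(self):
        g, datasets, groupings = _mini_study()
        ds = datasets["mrna"]
        svg = render_overview(g, ds, groupings["mrna"])
        spec = symmetric_spec(ds, RenderConfig())
        from enroute.data import node_summary
        for nid in g.nodes:
            expected = diverging_color(node_summary(g.nodes[nid], ds, graph=g).mean, spec)
            pattern = f'fill="{expected}"[^/]*class="nodebox"'
            assert re.search(pattern, svg), f"node {nid} fill mismatch"

    def test_missing_marker_for_unmapped_node(self):
        g = build_graph(["A"], [], members={"A": ("symbol:absent",)})
        ds = OmicsDataset("d", "numerical",
                          pd.DataFrame([[1.0]], index=["symbol:other"], columns=["s1"]))
        svg = render_overview(g, ds)
        assert 'class="missmark"' in svg

    def test_forced_edges_drawn_dashed(self):
        g = build_graph(["A", "B"], [], grid_cols=2)
        path = SelectedPath("test", ("A", "B"), frozenset({("A", "B")}))
        ds = OmicsDataset("d", "numerical",
                          pd.DataFrame([[1.0]], index=["symbol:A"], columns=["s1"]))
        svg = render_overview(g, ds, selection=path)
        assert "stroke-dasharray" in svg


class TestRenderEnroute:
    def _render(self, highlights=None, config=RenderConfig()):
        g, datasets, groupings = _mini_study()
        spec = compute_branches(g, SelectedPath("test", ("A", "B", "C")))
        layout = layout_linear(spec, datasets, groupings, config, graph=g)
        svg = render_enroute(layout, datasets, groupings, highlights, config,
                             graph=g, spec=spec)
        return g, datasets, layout, svg

    def test_bar_count_equals_non_missing_samples(self):
        g, datasets, layout, svg = self._render()
        mrna = datasets["mrna"]
        expected = 0
        for block in layout.nodes:
            for row in block.rows:
                if row in mrna.values.index:
                    expected += int((~mrna.values.loc[row].isna()).sum())
        assert svg.count('class="bar"') == expected

    def test_binary_matrix_cell_count(self):
        g, datasets, layout, svg = self._render()
        mut = datasets["mut"]
        expected = sum(
            len(mut.values.columns)
            for block in layout.nodes for row in block.rows
            if row in mut.values.index
        )
        assert svg.count('class="mcell"') == expected

    def test_cnv_detailed_draws_no_bar_for_normal(self):
        genes = ["symbol:gA"]
        values = pd.DataFrame([[2.0, 0.0, -2.0]], index=genes,
                              columns=["s1", "s2", "s3"])
        ds = OmicsDataset("cnv", "ordinal_cnv", values)
        grouping = {"cnv": SampleGrouping("cnv", [("all", ["s1", "s2", "s3"])])}
        g = build_graph(["A"], [], members={"A": ("symbol:gA",)})
        spec = compute_branches(g, SelectedPath("test", ("A",)))
        config = RenderConfig()
        layout = layout_linear(spec, {"cnv": ds}, grouping, config, graph=g)
        svg = render_enroute(layout, {"cnv": ds}, grouping, None, config, graph=g)
        assert svg.count('class="cnvbar"') == 2  # normal sample draws nothing
        high, low, het, hom = config.cnv_colors
        assert f'fill="{high}"' in svg and f'fill="{hom}"' in svg

    def test_zero_value_draws_zero_height_bar(self):
        ds = OmicsDataset("d", "numerical",
                          pd.DataFrame([[0.0]], index=["symbol:gA"], columns=["s1"]))
        grouping = {"d": SampleGrouping("d", [("one", ["s1"])])}
        g = build_graph(["A"], [], members={"A": ("symbol:gA",)})
        spec = compute_branches(g, SelectedPath("test", ("A",)))
        layout = layout_linear(spec, {"d": ds}, grouping, graph=g)
        svg = render_enroute(layout, {"d": ds}, grouping, graph=g)
        match = re.search(r'height="([0-9.]+)" fill="url\(#bargrad\)"[^/]*class="bar"', svg)
        assert match and float(match.group(1)) == 0.0

    def test_highlighted_samples_outlined(self):
        g, datasets, layout, svg = self._render(highlights={"s1"})
        assert 'stroke="#000000"' in svg

    def test_abstract_columns_share_baseline_offset(self):
        config = RenderConfig(column_styles=(("mrna", "abstract"), ("mut", "abstract")))
        g, datasets, layout, svg = self._render(config=config)
        offsets = {c.width / 2 for c in layout.columns}
        assert len(offsets) == 1  # identical per-row baseline offset

    def test_byte_identical_determinism(self):
        _, _, _, svg1 = self._render()
        _, _, _, svg2 = self._render()
        assert svg1 == svg2

    def test_unknown_dtype_rejected(self):
        with pytest.raises(ValueError):
            OmicsDataset("x", "wat", pd.DataFrame([[1.0]], index=["g"], columns=["s"]))
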