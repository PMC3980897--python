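"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from enroute.data import OmicsDataset, SampleGrouping
from enroute.model import PathwayEdge, PathwayGraph, PathwayNode


def build_graph(node_ids, edges, kinds=None, members=None, grid_cols=5,
                cell=(100.0, 60.0), box=(46.0, 17.0), children=None,
                pathway_id="test") -> PathwayGraph:
    """Construct a PathwayGraph with nodes laid on a regular grid.

    ``edges`` are (source, target) or (source, target, relation, directed)
    tuples.  ``members`` maps node id -> member tuple (default one
    ``symbol:<id>`` member per gene node).
    """
    kinds = kinds or {}
    members = members or {}
    children = children or {}
    nodes = {}
    for i, nid in enumerate(node_ids):
        r, c = divmod(i, grid_cols)
        x = 60.0 + c * cell[0]
        y = 60.0 + r * cell[1]
        kind = kinds.get(nid, "gene")
        node_members = members.get(nid)
        if node_members is None:
            node_members = (f"symbol:{nid}",) if kind == "gene" else ()
        nodes[nid] = PathwayNode(nid, kind, nid, (x, y, box[0], box[1]),
                                 members=tuple(node_members),
                                 children=tuple(children.get(nid, ())))
    edge_objs = []
    for e in edges:
        if len(e) == 2:
            edge_objs.append(PathwayEdge(e[0], e[1]))
        else:
            edge_objs.append(PathwayEdge(e[0], e[1], e[2], e[3]))
    ncols = min(grid_cols, max(1, len(node_ids)))
    nrows = (len(node_ids) + grid_cols - 1) // grid_cols
    g = PathwayGraph(pathway_id, "test pathway",
                     (120.0 + ncols * cell[0], 120.0 + nrows * cell[1]),
                     nodes, edge_objs)
    g.validate()
    return g


def random_graph(rng: np.random.Generator, n_nodes: int, n_edges: int,
                 p_undirected: float = 0.15) -> PathwayGraph:
    """Random connected-ish digraph for oracle sweeps."""
    node_ids = [f"r{i:02d}" for i in range(n_nodes)]
    n_edges = min(n_edges, n_nodes * (n_nodes - 1) // 2)
    edges = set()
    # spanning chain keeps things reachable
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        edges.add((node_ids[j], node_ids[i]))
    while len(edges) < max(n_edges, n_nodes - 1):
        u = node_ids[int(rng.integers(0, n_nodes))]
        v = node_ids[int(rng.integers(0, n_nodes))]
        if u != v:
            edges.add((u, v))
    edge_list = []
    for u, v in sorted(edges):
        directed = rng.random() >= p_undirected
        edge_list.append((u, v, "other", directed))
    return build_graph(node_ids, edge_list, grid_cols=4)


def dfs_simple_paths(graph: PathwayGraph, start: str, end: str,
                     max_len: int = 50) -> set[tuple[str, ...]]:
    """Exhaustive recursive enumeration of simple paths (test oracle).

    Independent of the production implementation: works directly off the
    edge list via PathwayGraph.is_successor semantics.
    """
    succ: dict[str, set[str]] = {nid: set() for nid in graph.nodes}
    for e in graph.edges:
        succ[e.source].add(e.target)
        if not e.directed:
            succ[e.target].add(e.source)
    found: set[tuple[str, ...]] = set()

    def walk(current: str, trail: list[str]) -> None:
        if len(trail) - 1 > max_len:
            return
        if current == end:
            found.add(tuple(trail))
            return
        for nxt in succ[current]:
            if nxt not in trail:
                walk(nxt, trail + [nxt])

    walk(start, [start])
    return found


def bfs_distance(graph: PathwayGraph, start: str, end: str) -> int | None:
    """Unweighted shortest-path edge count (test oracle)."""
    succ: dict[str, set[str]] = {nid: set() for nid in graph.nodes}
    for e in graph.edges:
        succ[e.source].add(e.target)
        if not e.directed:
            succ[e.target].add(e.source)
    frontier, dist, seen = [start], 0, {start}
    while frontier:
        if end in frontier:
            return dist
        nxt = []
        for u in frontier:
            for v in succ[u]:
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
        dist += 1
    return None


@pytest.fixture
def diamond():
    """A->B->D, A->C->D."""
    return build_graph(["A", "B", "C", "D"],
                       [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")])


@pytest.fixture
def cascade():
    """Receptor-cascade replica: a path with branches.

    EGFR's successors are the path continuation plus PLCG1 and SHC2; the
    SHC2 branch runs SHC2 -> GRB2 -> SOS -> HRAS, and HRAS has two leaving
    branches (RAF1, RALGDS) so a branch switch must stop there.
    """
    nodes = ["EGFR", "MID1", "MID2", "MTOR", "PLCG1", "SHC2",
             "GRB2", "SOS", "HRAS", "RAF1", "RALGDS"]
    edges = [("EGFR", "MID1"), ("MID1", "MID2"), ("MID2", "MTOR"),
             ("EGFR", "PLCG1"), ("EGFR", "SHC2"),
             ("SHC2", "GRB2"), ("GRB2", "SOS"), ("SOS", "HRAS"),
             ("HRAS", "RAF1"), ("HRAS", "RALGDS")]
    return build_graph(nodes, edges, grid_cols=4)


def small_dataset(dtype: str = "numerical", dataset_id: str = "ds") -> OmicsDataset:
    data = {
        "numerical": [[1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, np.nan]],
        "ordinal_cnv": [[2.0, 0.0, -2.0, 1.0], [0.0, 0.0, -1.0, np.nan]],
        "binary": [[1.0, 0.0, 0.0, 1.0], [0.0, 1.0, np.nan, 0.0]],
    }[dtype]
    values = pd.DataFrame(data, index=["symbol:g1", "symbol:g2"],
                          columns=["s1", "s2", "s3", "s4"])
    return OmicsDataset(dataset_id, dtype, values)


@pytest.fixture
def grouping():
    return SampleGrouping("ds", [("grpA", ["s1", "s2"]), ("grpB", ["s3", "s4"])])
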