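"""Path selection over pathway graphs.

Two complementary selection styles are supported.  The *iterative* style
grows a path one node at a time in either direction (:func:`extend_path`),
optionally injecting edges the database lacks (:func:`force_edge`).  The
*start-stop* style enumerates every simple alternative route between two
chosen nodes (:func:`find_alternatives`) so the analyst can flip through
them; the shortest route is pre-selected.

All selected paths are simple (no repeated node).  Undirected edges are
traversable in both directions; directed edges only along their arrow,
regardless of whether they encode activation or inhibition — biological
cascades routinely run through inhibitory links.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx

from .model import PathwayGraph

DEFAULT_MAX_LEN = 20
DEFAULT_MAX_PATHS = 64
# hard cap on raw enumeration before sorting, to bound memory on dense maps
_ENUMERATION_CAP = 20000


@dataclass(frozen=True)
class SelectedPath:
    """An ordered simple path plus any user-forced edges.

    ``forced_edges`` records consecutive pairs that are *not* connected in
    the underlying graph; renderers draw them dashed.
    """

    graph_ref: str
    nodes: tuple[str, ...]
    forced_edges: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if len(self.nodes) < 1:
            raise ValueError("a path needs at least one node")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("path repeats a node (must be simple)")

    def validate(self, graph: PathwayGraph) -> None:
        for node_id in self.nodes:
            if node_id not in graph.nodes:
                raise ValueError(f"path node {node_id} missing from graph")
        for u, v in zip(self.nodes, self.nodes[1:]):
            if not graph.is_successor(u, v) and (u, v) not in self.forced_edges:
                raise ValueError(f"consecutive pair ({u},{v}) is not connected")

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class PathAlternatives:
    """All simple routes between a start and an end node.

    ``paths[0]`` is a shortest route (ties broken lexicographically on the
    node-id sequence).  ``status`` is ``"ok"``, ``"truncated"`` when the
    enumeration hit ``max_paths``/``max_len``, or ``"no_path"``.
    """

    start: str
    end: str
    paths: tuple[SelectedPath, ...]
    selected_index: int = 0
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.paths:
            if not (0 <= self.selected_index < len(self.paths)):
                raise ValueError("selected_index out of range")
            for p in self.paths:
                if p.nodes[0] != self.start or p.nodes[-1] != self.end:
                    raise ValueError("alternative does not run start->end")

    @property
    def selected(self) -> SelectedPath:
        if not self.paths:
            raise ValueError("no path between start and end")
        return self.paths[self.selected_index]


class PathError(ValueError):
    pass


def _check_adjacent(graph: PathwayGraph, terminal: str, node_id: str, end: str) -> None:
    ok = graph.is_successor(node_id, terminal) if end == "head" else graph.is_successor(terminal, node_id)
    if not ok:
        raise PathError(f"{node_id} is not connected to {terminal} ({end} extension)")


def extend_path(graph: PathwayGraph, path: SelectedPath, node_id: str, end: str) -> SelectedPath:
    """Grow the path by one adjacent node at its head or tail.

    Head extension requires an edge node->first (or undirected), tail
    extension first requires last->node.  The input path is unchanged.
    """
    if end not in ("head", "tail"):
        raise ValueError("end must be 'head' or 'tail'")
    if node_id not in graph.nodes:
        raise PathError(f"unknown node {node_id!r}")
    if node_id in path.nodes:
        raise PathError(f"adding {node_id} would create a cycle")
    terminal = path.nodes[0] if end == "head" else path.nodes[-1]
    _check_adjacent(graph, terminal, node_id, end)
    nodes = (node_id,) + path.nodes if end == "head" else path.nodes + (node_id,)
    return replace(path, nodes=nodes)


def force_edge(graph: PathwayGraph, path: SelectedPath, node_id: str, end: str) -> SelectedPath:
    """Extend the path across an edge absent from the pathway database.

    Pathway maps are sometimes incomplete or outdated; force mode bridges
    such gaps with a user-injected edge, recorded in ``forced_edges`` so it
    can be rendered distinctly.  Forcing across an edge that *does* exist
    simply behaves like :func:`extend_path`.
    """
    if end not in ("head", "tail"):
        raise ValueError("end must be 'head' or 'tail'")
    if node_id not in graph.nodes:
        raise PathError(f"unknown node {node_id!r}")
    if node_id in path.nodes:
        raise PathError(f"adding {node_id} would create a cycle")
    terminal = path.nodes[0] if end == "head" else path.nodes[-1]
    exists = graph.is_successor(node_id, terminal) if end == "head" else graph.is_successor(terminal, node_id)
    if exists:
        return extend_path(graph, path, node_id, end)
    pair = (node_id, terminal) if end == "head" else (terminal, node_id)
    nodes = (node_id,) + path.nodes if end == "head" else path.nodes + (node_id,)
    return replace(path, nodes=nodes, forced_edges=path.forced_edges | {pair})


def find_alternatives(
    graph: PathwayGraph,
    start: str,
    end: str,
    max_paths: int = DEFAULT_MAX_PATHS,
    max_len: int = DEFAULT_MAX_LEN,
) -> PathAlternatives:
    """Enumerate all simple paths from start to end.

    ``max_len`` bounds the number of edges per path; enumeration beyond
    ``max_paths`` alternatives is truncated (``status="truncated"``).
    Alternatives are sorted by (length, lexicographic node-id sequence),
    so ``paths[0]`` is a shortest path and the whole ordering is invariant
    under the graph's node-insertion order.
    """
    if start == end:
        raise PathError("start and end must differ")
    for node_id in (start, end):
        if node_id not in graph.nodes:
            raise PathError(f"unknown node {node_id!r}")
    g = graph.to_networkx()
    raw: list[tuple[str, ...]] = []
    truncated = False
    try:
        for nodes in nx.all_simple_paths(g, start, end, cutoff=max_len):
            raw.append(tuple(nodes))
            if len(raw) >= _ENUMERATION_CAP:
                truncated = True
                break
    except nx.NetworkXNoPath:
        pass
    if not raw:
        return PathAlternatives(start=start, end=end, paths=(), status="no_path")
    raw.sort(key=lambda nodes: (len(nodes), nodes))
    if len(raw) > max_paths:
        raw = raw[:max_paths]
        truncated = True
    paths = tuple(SelectedPath(graph.pathway_id, nodes) for nodes in raw)
    return PathAlternatives(start=start, end=end, paths=paths,
                            status="truncated" if truncated else "ok")


def select_alternative(alts: PathAlternatives, index: int) -> PathAlternatives:
    """Return the alternatives with a different route selected."""
    if not (0 <= index < len(alts.paths)):
        raise PathError(f"alternative index {index} out of range")
    if index == alts.selected_index:
        return alts
    return replace(alts, selected_index=index)


def step_alternative(alts: PathAlternatives, step: int = 1) -> PathAlternatives:
    """Cyclic next/previous over the alternatives (mouse-wheel semantics)."""
    if not alts.paths:
        raise PathError("no path between start and end")
    return select_alternative(alts, (alts.selected_index + step) % len(alts.paths))


def preview_extensions(graph: PathwayGraph, path: SelectedPath) -> dict[str, list[tuple[str, object]]]:
    """Immediate continuation candidates at both ends of a path.

    ``tail`` lists successors of the last node, ``head`` predecessors of
    the first, each excluding nodes already on the path; both in the
    deterministic order of :meth:`PathwayGraph.neighbors`.
    """
    path.validate(graph)
    on_path = set(path.nodes)
    tail = [(n, e) for n, e in graph.neighbors(path.nodes[-1], "out") if n not in on_path]
    head = [(n, e) for n, e in graph.neighbors(path.nodes[0], "in") if n not in on_path]
    return {"head": head, "tail": tail}
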