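"""Linearization of a selected path with branch abstraction.

The extracted path is shown top-down; to preserve some of the topology
around it, off-path neighbors are summarised as *branches*: flow either
joins the path at a node (an in-neighbor off the path) or leaves it (an
out-neighbor off the path).  All joining branches of one path node collapse
into a single expandable abstract node, and likewise all leaving branches,
so the linear representation stays compact while still reporting how many
routes enter and exit at each step.

Branch *switching* replaces the part of the path above (joining) or below
(leaving) the anchor node with the selected branch, following it until the
route becomes ambiguous — a node with two or more eligible continuations —
or dead-ends.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .model import PathwayGraph
from .paths import SelectedPath


@dataclass(frozen=True)
class AbstractBranch:
    """All branches of one direction at one path node, collapsed.

    ``heads`` are the first nodes of each branch, ordered by (label, id)
    for reproducible rendering; the abstract node reports ``len(heads)``.
    """

    anchor: str
    direction: str  # "joining" | "leaving"
    heads: tuple[str, ...]
    expanded: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("joining", "leaving"):
            raise ValueError("direction must be 'joining' or 'leaving'")
        if not self.heads:
            raise ValueError("an abstract branch needs >= 1 head")


@dataclass(frozen=True)
class LinearPathSpec:
    """A path plus its abstracted branches, in top-down order."""

    path: SelectedPath
    branches: tuple[AbstractBranch, ...]

    def branch_at(self, anchor: str, direction: str) -> AbstractBranch | None:
        for branch in self.branches:
            if branch.anchor == anchor and branch.direction == direction:
                return branch
        return None


def _head_order(graph: PathwayGraph, heads: set[str]) -> tuple[str, ...]:
    return tuple(sorted(heads, key=lambda n: (graph.nodes[n].label, n)))


def compute_branches(graph: PathwayGraph, path: SelectedPath) -> LinearPathSpec:
    """Find the joining and leaving branches at every path node.

    For a node at position *i*, joining heads are its in-neighbors that are
    neither on the path nor its path predecessor; leaving heads its
    out-neighbors that are neither on the path nor its path successor.  At
    most one joining and one leaving abstract branch exist per node.
    """
    path.validate(graph)
    on_path = set(path.nodes)
    branches: list[AbstractBranch] = []
    for i, node_id in enumerate(path.nodes):
        joining = {n for n, _ in graph.neighbors(node_id, "in") if n not in on_path}
        leaving = {n for n, _ in graph.neighbors(node_id, "out") if n not in on_path}
        if joining:
            branches.append(AbstractBranch(node_id, "joining", _head_order(graph, joining)))
        if leaving:
            branches.append(AbstractBranch(node_id, "leaving", _head_order(graph, leaving)))
    return LinearPathSpec(path=path, branches=tuple(branches))


def _walk(graph: PathwayGraph, head: str, blocked: set[str], direction: str) -> list[str]:
    """Follow a branch until it becomes ambiguous or dead-ends.

    At each step the eligible continuations are the successors (leaving) or
    predecessors (joining) not yet on the path; the walk appends the node
    and continues only while exactly one continuation exists.  Interior
    nodes of the result therefore each had a unique continuation at walk
    time, and termination is guaranteed because ``blocked`` only grows.
    """
    walked = [head]
    taken = set(blocked) | {head}
    current = head
    while True:
        neigh_dir = "out" if direction == "leaving" else "in"
        continuations = [n for n, _ in graph.neighbors(current, neigh_dir) if n not in taken]
        if len(continuations) != 1:
            break
        current = continuations[0]
        walked.append(current)
        taken.add(current)
    return walked


def switch_branch(
    graph: PathwayGraph,
    path: SelectedPath,
    anchor: str,
    head: str,
    direction: str,
) -> SelectedPath:
    """Replace part of the path with the branch starting at ``head``.

    A leaving branch replaces everything below the anchor, a joining branch
    everything above it.  The branch is followed until a node with zero or
    several eligible continuations is reached (dead end / new branching
    point).  Forced edges outside the retained segment are discarded.
    """
    spec = compute_branches(graph, path)
    branch = spec.branch_at(anchor, direction)
    if branch is None or head not in branch.heads:
        raise ValueError(f"({anchor}, {head}, {direction}) is not a registered branch")
    idx = path.nodes.index(anchor)
    if direction == "leaving":
        kept = path.nodes[: idx + 1]
        walked = _walk(graph, head, set(kept), "leaving")
        nodes = kept + tuple(walked)
    else:
        kept = path.nodes[idx:]
        walked = _walk(graph, head, set(kept), "joining")
        nodes = tuple(reversed(walked)) + kept
    kept_pairs = set(zip(nodes, nodes[1:]))
    forced = frozenset(pair for pair in path.forced_edges if pair in kept_pairs)
    new_path = replace(path, nodes=nodes, forced_edges=forced)
    new_path.validate(graph)
    return new_path


def expand_branch(spec: LinearPathSpec, anchor: str, direction: str) -> LinearPathSpec:
    """Expand one abstract branch node; any other expansion collapses.

    Expanded heads are rendered with data previews while the remaining
    branches are de-emphasized, so at most one branch is expanded at a
    time.
    """
    if spec.branch_at(anchor, direction) is None:
        raise ValueError(f"no {direction} branch at {anchor}")
    branches = tuple(
        replace(b, expanded=(b.anchor == anchor and b.direction == direction))
        for b in spec.branches
    )
    return replace(spec, branches=branches)


def collapse_branches(spec: LinearPathSpec) -> LinearPathSpec:
    """Collapse every branch (undo of :func:`expand_branch`)."""
    return replace(spec, branches=tuple(replace(b, expanded=False) for b in spec.branches))
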