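"""Attributed pathway-graph model and KGML/GPML parsers.

Pathway maps from KEGG (KGML) and WikiPathways (GPML) are hand-curated
node-link diagrams whose XML descriptions carry both the topology and the
pixel geometry of every node.  Both formats are parsed into a single
:class:`PathwayGraph` that preserves the original map geometry: nodes keep
their center-anchored bounding boxes in image coordinates (origin top-left,
y increasing downward), so anything rendered on top of the graph lines up
with the published map.

A KGML-dialect writer is provided so synthetic pathways can round-trip
through the parser; the dialect adds two attributes plain KGML lacks
(``image-width``/``image-height`` on the pathway element, ``directed`` on
relations) and is otherwise ordinary KGML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from lxml import etree

log = logging.getLogger(__name__)

NODE_KINDS = ("gene", "compound", "map_link", "group")
EDGE_RELATIONS = ("activation", "inhibition", "binding", "conversion", "other")

# KEGG organism prefixes that denote Entrez gene ids in entry names.
_ENTREZ_PREFIXES = {"hsa", "mmu", "rno", "dme", "cel", "sce", "dre"}


@dataclass(frozen=True)
class PathwayNode:
    """A node of a pathway map.

    ``bbox`` is (x_center, y_center, width, height) in image pixels.
    ``members`` lists the namespace-qualified gene identifiers the node
    stands for; pathway nodes frequently represent whole protein families,
    so several data rows may map onto one node (multi-mapping).
    ``children`` is non-empty only for ``kind="group"`` — a complex node
    composed of multiple subnodes.
    """

    node_id: str
    kind: str
    label: str
    bbox: tuple[float, float, float, float]
    members: tuple[str, ...] = ()
    children: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        x, y, w, h = self.bbox
        if not (w > 0 and h > 0):
            raise ValueError(f"node {self.node_id}: bbox must have positive size")
        if self.kind in ("compound", "map_link") and self.members:
            raise ValueError(f"node {self.node_id}: {self.kind} nodes carry no members")
        if self.kind == "gene" and not self.members:
            raise ValueError(f"node {self.node_id}: gene node needs >= 1 member")
        if self.children and self.kind != "group":
            raise ValueError(f"node {self.node_id}: only group nodes have children")

    @property
    def box_corners(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the bounding box."""
        x, y, w, h = self.bbox
        return (x - w / 2, y - h / 2, x + w / 2, y + h / 2)


@dataclass(frozen=True)
class PathwayEdge:
    """A typed link between two pathway nodes.

    Undirected edges (``directed=False``) are stored once and traversable
    both ways.
    """

    source: str
    target: str
    relation: str = "other"
    directed: bool = True

    def __post_init__(self) -> None:
        if self.relation not in EDGE_RELATIONS:
            raise ValueError(f"unknown edge relation {self.relation!r}")


@dataclass
class PathwayGraph:
    """A pathway map: nodes with geometry plus typed edges."""

    pathway_id: str
    title: str
    image_size: tuple[float, float]
    nodes: dict[str, PathwayNode] = field(default_factory=dict)
    edges: list[PathwayEdge] = field(default_factory=list)
    source_format: str = "kgml"

    def validate(self) -> None:
        seen_children: set[str] = set()
        for node in self.nodes.values():
            for child in node.children:
                if child not in self.nodes:
                    raise ValueError(f"group {node.node_id}: unknown child {child}")
                if child in seen_children:
                    raise ValueError(f"node {child} is a child of two groups")
                seen_children.add(child)
        for edge in self.edges:
            for endpoint in (edge.source, edge.target):
                if endpoint not in self.nodes:
                    raise ValueError(f"edge endpoint {endpoint} is not a node")

    # -- traversal ---------------------------------------------------------

    def neighbors(self, node_id: str, direction: str = "out") -> list[tuple[str, PathwayEdge]]:
        """Adjacent (node_id, edge) pairs in a stable order.

        ``out`` follows directed edges from the node plus undirected
        incident edges; ``in`` is symmetric; ``both`` is their union.
        Ordering is deterministic (by the opposite node id, then relation).
        """
        if node_id not in self.nodes:
            raise KeyError(f"unknown node {node_id!r}")
        if direction not in ("out", "in", "both"):
            raise ValueError(f"direction must be out/in/both, got {direction!r}")
        found: list[tuple[str, PathwayEdge]] = []
        for edge in self.edges:
            if not edge.directed:
                # undirected: traversable both ways from either endpoint
                if edge.source == node_id:
                    pair = (edge.target, edge)
                elif edge.target == node_id:
                    pair = (edge.source, edge)
                else:
                    continue
                found.append(pair)
            elif direction in ("out", "both") and edge.source == node_id:
                found.append((edge.target, edge))
            elif direction in ("in", "both") and edge.target == node_id:
                found.append((edge.source, edge))
        uniq: list[tuple[str, PathwayEdge]] = []
        for pair in found:
            if pair not in uniq:
                uniq.append(pair)
        uniq.sort(key=lambda p: (p[0], p[1].relation, p[1].source, p[1].target))
        return uniq

    def to_networkx(self):
        """Directed view of the graph: undirected edges appear both ways."""
        import networkx as nx

        g = nx.DiGraph()
        for node_id in sorted(self.nodes):
            g.add_node(node_id)
        for edge in self.edges:
            g.add_edge(edge.source, edge.target, relation=edge.relation)
            if not edge.directed:
                g.add_edge(edge.target, edge.source, relation=edge.relation)
        return g

    def is_successor(self, u: str, v: str) -> bool:
        """True when v can be reached from u over one edge."""
        for edge in self.edges:
            if edge.source == u and edge.target == v:
                return True
            if not edge.directed and edge.source == v and edge.target == u:
                return True
        return False

    def find_edge(self, u: str, v: str) -> PathwayEdge | None:
        for edge in self.edges:
            if edge.source == u and edge.target == v:
                return edge
            if not edge.directed and edge.source == v and edge.target == u:
                return edge
        return None


def neighbors(graph: PathwayGraph, node_id: str, direction: str = "out"):
    """Module-level alias for :meth:`PathwayGraph.neighbors`."""
    return graph.neighbors(node_id, direction)


class PathwayParseError(ValueError):
    pass


def _parse_xml(xml_document) -> etree._Element:
    if isinstance(xml_document, (str, bytes)):
        text = xml_document
        if isinstance(text, str) and "\n" not in text and text.endswith((".xml", ".kgml", ".gpml")):
            try:
                return etree.parse(text).getroot()
            except (OSError, etree.XMLSyntaxError) as exc:
                raise PathwayParseError(str(exc)) from exc
        try:
            if isinstance(text, str):
                text = text.encode("utf-8")
            return etree.fromstring(text)
        except etree.XMLSyntaxError as exc:
            raise PathwayParseError(f"malformed XML at line {exc.lineno}: {exc.msg}") from exc
    if hasattr(xml_document, "read"):
        try:
            return etree.parse(xml_document).getroot()
        except etree.XMLSyntaxError as exc:
            raise PathwayParseError(f"malformed XML at line {exc.lineno}: {exc.msg}") from exc
    raise TypeError("xml_document must be a string, bytes, path or file object")


def _qualify_member(token: str) -> str:
    """Map a KGML name token onto a namespace-qualified member id."""
    if ":" in token:
        prefix, rest = token.split(":", 1)
        if prefix in _ENTREZ_PREFIXES:
            return f"entrez:{rest}"
        return token
    return f"symbol:{token}"


def _unqualify_member(member: str) -> str:
    if member.startswith("entrez:"):
        return "hsa:" + member.split(":", 1)[1]
    if member.startswith("symbol:"):
        return member.split(":", 1)[1]
    return member


_KGML_SUBTYPE_TO_RELATION = {
    "activation": "activation",
    "expression": "activation",
    "inhibition": "inhibition",
    "repression": "inhibition",
    "binding/association": "binding",
    "binding": "binding",
    "conversion": "conversion",
}


def parse_kgml(xml_document) -> PathwayGraph:
    """Parse a KGML document (or the fixture dialect) into a PathwayGraph.

    One node is created per entry of type gene/ortholog/compound/map/group;
    entry names with several space-separated identifiers become the members
    list; relations and reaction substrate/product pairs become edges.
    Coordinates are copied verbatim (KGML graphics are center-anchored).
    Entries without graphics are skipped with a warning; relations that
    reference a missing entry are dropped with a warning.
    """
    root = _parse_xml(xml_document)
    if etree.QName(root).localname != "pathway":
        raise PathwayParseError("root element is not <pathway>")

    graph = PathwayGraph(
        pathway_id=root.get("name", ""),
        title=root.get("title", ""),
        image_size=(0.0, 0.0),
        source_format="kgml",
    )

    kind_map = {"gene": "gene", "ortholog": "gene", "compound": "compound",
                "map": "map_link", "group": "group"}
    group_children: dict[str, list[str]] = {}

    for entry in root.findall("entry"):
        entry_id = entry.get("id")
        entry_type = entry.get("type", "")
        kind = kind_map.get(entry_type)
        if kind is None:
            log.warning("entry %s: unsupported type %r skipped", entry_id, entry_type)
            continue
        graphics = entry.find("graphics")
        if graphics is None or graphics.get("x") is None:
            log.warning("entry %s: no graphics, node skipped", entry_id)
            continue
        bbox = (
            float(graphics.get("x")),
            float(graphics.get("y")),
            float(graphics.get("width", 46)),
            float(graphics.get("height", 17)),
        )
        label = (graphics.get("name") or entry.get("name", "")).split(",")[0].strip()
        members: tuple[str, ...] = ()
        if kind == "gene":
            tokens = [t for t in entry.get("name", "").split() if t and t != "undefined"]
            members = tuple(_qualify_member(t) for t in tokens)
            if not members:
                members = (f"symbol:{label or entry_id}",)
        children = tuple(c.get("id") for c in entry.findall("component"))
        if kind == "group":
            group_children[entry_id] = list(children)
        graph.nodes[entry_id] = PathwayNode(
            node_id=entry_id, kind=kind, label=label, bbox=bbox,
            members=members, children=children if kind == "group" else (),
        )

    for relation in root.findall("relation"):
        e1, e2 = relation.get("entry1"), relation.get("entry2")
        if e1 not in graph.nodes or e2 not in graph.nodes:
            log.warning("relation %s->%s references a missing entry, dropped", e1, e2)
            continue
        rel = "other"
        if relation.get("type") == "ECrel":
            rel = "conversion"
        for subtype in relation.findall("subtype"):
            mapped = _KGML_SUBTYPE_TO_RELATION.get(subtype.get("name", ""))
            if mapped:
                rel = mapped
                break
        directed = relation.get("directed", "true") != "false"
        graph.edges.append(PathwayEdge(source=e1, target=e2, relation=rel, directed=directed))

    # KGML reactions: the entry whose id matches the reaction id is the
    # enzyme; substrates feed into it, products flow out.
    for reaction in root.findall("reaction"):
        enzyme_id = reaction.get("id")
        if enzyme_id not in graph.nodes:
            log.warning("reaction %s: enzyme entry missing, dropped", enzyme_id)
            continue
        for substrate in reaction.findall("substrate"):
            sid = substrate.get("id")
            if sid in graph.nodes:
                graph.edges.append(PathwayEdge(sid, enzyme_id, "conversion", True))
            else:
                log.warning("reaction %s: substrate %s missing, edge dropped", enzyme_id, sid)
        for product in reaction.findall("product"):
            pid = product.get("id")
            if pid in graph.nodes:
                graph.edges.append(PathwayEdge(enzyme_id, pid, "conversion", True))
            else:
                log.warning("reaction %s: product %s missing, edge dropped", enzyme_id, pid)

    iw = root.get("image-width")
    ih = root.get("image-height")
    if iw is not None and ih is not None:
        graph.image_size = (float(iw), float(ih))
    else:
        graph.image_size = _extent(graph)
    graph.validate()
    return graph


def _extent(graph: PathwayGraph) -> tuple[float, float]:
    if not graph.nodes:
        return (0.0, 0.0)
    xs = [n.box_corners[2] for n in graph.nodes.values()]
    ys = [n.box_corners[3] for n in graph.nodes.values()]
    return (max(xs) + 10.0, max(ys) + 10.0)


def _num(x: float) -> str:
    """Format a coordinate so that float(_num(x)) == x."""
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


_RELATION_TO_KGML = {
    "activation": ("PPrel", "activation"),
    "inhibition": ("PPrel", "inhibition"),
    "binding": ("PPrel", "binding/association"),
    "conversion": ("ECrel", "conversion"),
    "other": ("PPrel", None),
}

_KIND_TO_KGML = {"gene": "gene", "compound": "compound", "map_link": "map", "group": "group"}


def write_kgml(graph: PathwayGraph) -> str:
    """Serialise a PathwayGraph as KGML-dialect XML.

    Round-trip contract: ``parse_kgml(write_kgml(g))`` is isomorphic to
    ``g`` — same node ids, members, bounding boxes and edge multiset.
    """
    root = etree.Element("pathway")
    root.set("name", graph.pathway_id)
    root.set("title", graph.title)
    root.set("image-width", _num(graph.image_size[0]))
    root.set("image-height", _num(graph.image_size[1]))

    for node_id in sorted(graph.nodes, key=str):
        node = graph.nodes[node_id]
        entry = etree.SubElement(root, "entry")
        entry.set("id", node.node_id)
        if node.kind == "gene":
            entry.set("name", " ".join(_unqualify_member(m) for m in node.members))
        elif node.kind == "map_link":
            entry.set("name", f"path:{node.label}")
        else:
            entry.set("name", node.label or "undefined")
        entry.set("type", _KIND_TO_KGML[node.kind])
        graphics = etree.SubElement(entry, "graphics")
        graphics.set("name", node.label)
        graphics.set("x", _num(node.bbox[0]))
        graphics.set("y", _num(node.bbox[1]))
        graphics.set("width", _num(node.bbox[2]))
        graphics.set("height", _num(node.bbox[3]))
        graphics.set("type", "rectangle")
        for child in node.children:
            etree.SubElement(entry, "component").set("id", child)

    for edge in graph.edges:
        kgml_type, subtype = _RELATION_TO_KGML[edge.relation]
        relation = etree.SubElement(root, "relation")
        relation.set("entry1", edge.source)
        relation.set("entry2", edge.target)
        relation.set("type", kgml_type)
        if not edge.directed:
            relation.set("directed", "false")
        if subtype is not None:
            etree.SubElement(relation, "subtype").set("name", subtype)

    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode("utf-8")


# -- GPML --------------------------------------------------------------------

_GPML_DB_TO_NAMESPACE = {
    "entrez gene": "entrez",
    "ensembl": "ensembl",
    "uniprot": "uniprot",
    "uniprot-trembl": "uniprot",
    "hgnc": "symbol",
}

_ARROW_TO_RELATION = {
    "Arrow": ("activation", True),
    "mim-stimulation": ("activation", True),
    "mim-conversion": ("conversion", True),
    "mim-catalysis": ("conversion", True),
    "TBar": ("inhibition", True),
    "mim-inhibition": ("inhibition", True),
    "mim-binding": ("binding", True),
}


def parse_gpml(xml_document) -> PathwayGraph:
    """Parse a WikiPathways GPML document into a PathwayGraph.

    DataNodes of type GeneProduct/Protein become gene nodes, Metabolites
    become compounds, Pathway nodes become map links, and Groups become
    group nodes whose bounding box hulls their children.  Interactions are
    resolved through anchors where possible; unresolvable endpoints drop
    the interaction with a warning.  A GeneProduct without an Xref falls
    back to ``symbol:<label>`` members.
    """
    root = _parse_xml(xml_document)
    if etree.QName(root).localname != "Pathway":
        raise PathwayParseError("root element is not <Pathway>")
    ns = etree.QName(root).namespace

    def tag(name: str) -> str:
        return f"{{{ns}}}{name}" if ns else name

    graph = PathwayGraph(
        pathway_id=root.get("Name", ""),
        title=root.get("Name", ""),
        image_size=(0.0, 0.0),
        source_format="gpml",
    )
    gfx = root.find(tag("Graphics"))
    if gfx is not None and gfx.get("BoardWidth"):
        graph.image_size = (float(gfx.get("BoardWidth")), float(gfx.get("BoardHeight", 0)))

    graphid_to_node: dict[str, str] = {}
    group_members: dict[str, list[str]] = {}

    type_map = {"GeneProduct": "gene", "Protein": "gene", "Rna": "gene",
                "Metabolite": "compound", "Pathway": "map_link"}
    counter = 0
    for dn in root.findall(tag("DataNode")):
        kind = type_map.get(dn.get("Type", "GeneProduct"))
        if kind is None:
            log.warning("DataNode %r: unsupported type skipped", dn.get("TextLabel"))
            continue
        node_gfx = dn.find(tag("Graphics"))
        if node_gfx is None or node_gfx.get("CenterX") is None:
            log.warning("DataNode %r: no graphics, skipped", dn.get("TextLabel"))
            continue
        counter += 1
        node_id = dn.get("GraphId") or f"dn{counter}"
        label = dn.get("TextLabel", "")
        bbox = (
            float(node_gfx.get("CenterX")),
            float(node_gfx.get("CenterY")),
            float(node_gfx.get("Width", 80)),
            float(node_gfx.get("Height", 20)),
        )
        members: tuple[str, ...] = ()
        if kind == "gene":
            xref = dn.find(tag("Xref"))
            if xref is not None and xref.get("ID"):
                db = (xref.get("Database") or "").strip().lower()
                namespace = _GPML_DB_TO_NAMESPACE.get(db, db or "symbol")
                members = (f"{namespace}:{xref.get('ID')}",)
            else:
                members = (f"symbol:{label}",)
        graph.nodes[node_id] = PathwayNode(node_id, kind, label, bbox, members)
        graphid_to_node[node_id] = node_id
        group_ref = dn.get("GroupRef")
        if group_ref:
            group_members.setdefault(group_ref, []).append(node_id)

    for grp in root.findall(tag("Group")):
        gid = grp.get("GroupId") or grp.get("GraphId")
        children = group_members.get(gid, [])
        if not children:
            continue
        corners = [graph.nodes[c].box_corners for c in children]
        x0 = min(c[0] for c in corners)
        y0 = min(c[1] for c in corners)
        x1 = max(c[2] for c in corners)
        y1 = max(c[3] for c in corners)
        node_id = grp.get("GraphId") or gid
        graph.nodes[node_id] = PathwayNode(
            node_id, "group", gid or "group",
            ((x0 + x1) / 2, (y0 + y1) / 2, max(x1 - x0, 1.0), max(y1 - y0, 1.0)),
            children=tuple(children),
        )
        if grp.get("GraphId"):
            graphid_to_node[grp.get("GraphId")] = node_id
        graphid_to_node[gid] = node_id

    # Anchors sit on interactions; an endpoint referencing an anchor is
    # resolved to the host interaction's opposite-end data node.
    anchor_host: dict[str, etree._Element] = {}
    for interaction in root.findall(tag("Interaction")):
        igfx = interaction.find(tag("Graphics"))
        if igfx is None:
            continue
        for anchor in igfx.findall(tag("Anchor")):
            if anchor.get("GraphId"):
                anchor_host[anchor.get("GraphId")] = igfx

    def resolve(ref: str | None, depth: int = 0) -> str | None:
        if ref is None or depth > 4:
            return None
        if ref in graphid_to_node:
            return graphid_to_node[ref]
        host = anchor_host.get(ref)
        if host is not None:
            points = host.findall(tag("Point"))
            for point in reversed(points):
                hit = resolve(point.get("GraphRef"), depth + 1)
                if hit is not None:
                    return hit
        return None

    for interaction in root.findall(tag("Interaction")):
        igfx = interaction.find(tag("Graphics"))
        if igfx is None:
            continue
        points = igfx.findall(tag("Point"))
        if len(points) < 2:
            continue
        source = resolve(points[0].get("GraphRef"))
        target = resolve(points[-1].get("GraphRef"))
        if source is None or target is None or source == target:
            log.warning("interaction with unresolvable endpoint dropped")
            continue
        arrow = points[-1].get("ArrowHead") or points[0].get("ArrowHead")
        if arrow in _ARROW_TO_RELATION:
            relation, directed = _ARROW_TO_RELATION[arrow]
        elif arrow:
            relation, directed = "other", True
        else:
            relation, directed = "other", False
        graph.edges.append(PathwayEdge(source, target, relation, directed))

    if graph.image_size == (0.0, 0.0):
        graph.image_size = _extent(graph)
    graph.validate()
    return graph


def graphs_isomorphic(a: PathwayGraph, b: PathwayGraph) -> bool:
    """Structural equality: ids, kinds, members, bboxes, children, edge multiset."""
    if set(a.nodes) != set(b.nodes):
        return False
    for node_id, node in a.nodes.items():
        other = b.nodes[node_id]
        if (node.kind, node.members, node.bbox, node.children) != (
            other.kind, other.members, other.bbox, other.children
        ):
            return False
    def key(e: PathwayEdge):
        return (e.source, e.target, e.relation, e.directed)
    return sorted(map(key, a.edges)) == sorted(map(key, b.edges))
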