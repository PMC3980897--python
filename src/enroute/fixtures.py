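"""Seeded generators of synthetic pathways and omics matrices.

The generators emulate the structure of the data a pathway-centric cancer
study works with, so the whole pipeline can be exercised without any
database download:

* a connected directed pathway graph in the KGML dialect, with a planted
  diamond motif (guaranteeing at least two alternative routes between a
  designated start and end node), one complex node carrying many member
  genes (multi-mapping), one group node with subnode children, and
  non-overlapping bounding boxes laid out on a jittered grid;
* matched mRNA (numerical), copy-number (five-level ordinal) and mutation
  (binary) matrices over named sample groups, with an amplification
  coupling: a gene's expression is shifted by ``rho`` times its copy-number
  code, so samples with a copy-number gain also show raised expression —
  the classic CNV↔expression correlation an analyst looks for.

A given seed fully determines every output, byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import OmicsDataset, SampleGrouping
from .model import PathwayEdge, PathwayGraph, PathwayNode, write_kgml

_GRID_CELL = (100.0, 60.0)
_NODE_BOX = (46.0, 17.0)
_JITTER = 10.0


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic study; the seed determines all randomness."""

    seed: int = 0
    n_nodes: int = 24
    n_edges: int = 32
    backbone_len: int = 6
    complex_members: int = 16     # member genes of the planted complex node
    group_children: int = 3       # subnodes of the planted group node
    multi_mapping_probs: tuple[tuple[int, float], ...] = (
        (1, 0.70), (2, 0.15), (3, 0.10), (4, 0.05),
    )
    group_labels: tuple[str, ...] = ("ovary", "lung", "breast", "liver")
    n_samples: int = 30           # per group
    mean_shifts: tuple[float, ...] = (0.0, 0.4, -0.4, 0.8)
    amplified_group: str = "ovary"
    cnv_probs_amplified: tuple[float, ...] = (0.05, 0.10, 0.35, 0.30, 0.20)
    cnv_probs_background: tuple[float, ...] = (0.05, 0.15, 0.60, 0.15, 0.05)
    # category probabilities in code order (-2, -1, 0, 1, 2)
    mutation_rates: tuple[float, ...] = (0.10, 0.10, 0.10, 0.10)
    rho: float = 1.0              # expression shift per copy-number code unit
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        for probs in (self.cnv_probs_amplified, self.cnv_probs_background):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("CNV category probabilities must sum to 1")
        if abs(sum(p for _, p in self.multi_mapping_probs) - 1.0) > 1e-9:
            raise ValueError("multi-mapping probabilities must sum to 1")
        if self.n_edges < self.n_nodes - 1:
            raise ValueError("need n_edges >= n_nodes - 1 for connectivity")
        if len(self.mean_shifts) != len(self.group_labels):
            raise ValueError("one mean shift per group required")
        if len(self.mutation_rates) != len(self.group_labels):
            raise ValueError("one mutation rate per group required")

    @property
    def start_node(self) -> str:
        return "n001"

    @property
    def end_node(self) -> str:
        return f"n{self.backbone_len:03d}"


def _node_id(i: int) -> str:
    return f"n{i:03d}"


def make_pathway(config: FixtureConfig) -> PathwayGraph:
    """Generate a connected pathway graph with planted motifs.

    Topology: a directed backbone chain ``n001 -> ... -> n<B>`` (the
    designated start-to-end route), a parallel two-node branch off the
    start re-joining at the fourth backbone node (the planted diamond,
    guaranteeing alternatives), one backbone node with
    ``complex_members`` member genes, one group node whose children sit
    off the backbone, plus randomly attached extra nodes and edges up to
    the configured sizes.  Boxes are laid on a jittered grid so none
    overlap; an infeasible request raises with a hint.
    """
    rng = np.random.default_rng(config.seed)
    B = config.backbone_len
    if config.n_nodes < B + 2 + config.group_children:
        raise ValueError("n_nodes too small for backbone + diamond + group children")
    if B < 4:
        raise ValueError("backbone_len must be >= 4 to plant the diamond")

    gene_counter = 0

    def members_for(n: int) -> tuple[str, ...]:
        nonlocal gene_counter
        out = tuple(f"symbol:G{gene_counter + k:03d}" for k in range(n))
        gene_counter += n
        return out

    sizes = [s for s, _ in config.multi_mapping_probs]
    probs = [p for _, p in config.multi_mapping_probs]

    node_ids = [_node_id(i + 1) for i in range(config.n_nodes)]
    backbone = node_ids[:B]
    diamond = node_ids[B:B + 2]
    children = node_ids[B + 2:B + 2 + config.group_children]
    extras = node_ids[B + 2 + config.group_children:]

    member_count: dict[str, int] = {}
    for nid in node_ids:
        member_count[nid] = int(rng.choice(sizes, p=probs))
    member_count[backbone[1]] = config.complex_members  # the Fig-11-style node

    edges: list[PathwayEdge] = []
    for u, v in zip(backbone, backbone[1:]):
        edges.append(PathwayEdge(u, v, "activation", True))
    # diamond: start -> d1 -> d2 -> backbone[3]
    edges.append(PathwayEdge(backbone[0], diamond[0], "activation", True))
    edges.append(PathwayEdge(diamond[0], diamond[1], "activation", True))
    edges.append(PathwayEdge(diamond[1], backbone[3], "activation", True))
    # group children hang off the middle of the backbone
    anchor = backbone[B // 2]
    for child in children:
        edges.append(PathwayEdge(anchor, child, "binding", True))
    # extra nodes attach to a random earlier node (keeps the graph connected)
    placed = backbone + diamond + children
    for nid in extras:
        host = placed[int(rng.integers(0, len(placed)))]
        if rng.random() < 0.5:
            edges.append(PathwayEdge(host, nid, "other", True))
        else:
            edges.append(PathwayEdge(nid, host, "other", True))
        placed.append(nid)

    existing = {(e.source, e.target) for e in edges}
    attempts = 0
    while len(edges) < config.n_edges and attempts < 20 * config.n_edges:
        attempts += 1
        u = node_ids[int(rng.integers(0, len(node_ids)))]
        v = node_ids[int(rng.integers(0, len(node_ids)))]
        if u == v or (u, v) in existing or (v, u) in existing:
            continue
        relation = ("activation", "inhibition", "other")[int(rng.integers(0, 3))]
        edges.append(PathwayEdge(u, v, relation, True))
        existing.add((u, v))

    # jittered grid placement; group children get consecutive cells so the
    # group hull stays compact
    n_cells = config.n_nodes
    ncols = max(4, math.ceil(math.sqrt(n_cells * 1.6)))
    nrows = math.ceil(n_cells / ncols)
    cw, ch = _GRID_CELL
    bw, bh = _NODE_BOX
    if cw - bw <= 2 * _JITTER or ch - bh <= 2 * _JITTER:
        raise ValueError("overlap-free placement infeasible; use a larger grid cell")
    nodes: dict[str, PathwayNode] = {}
    for i, nid in enumerate(node_ids):
        r, c = divmod(i, ncols)
        x = 40.0 + c * cw + cw / 2 + float(rng.uniform(-_JITTER, _JITTER))
        y = 40.0 + r * ch + ch / 2 + float(rng.uniform(-_JITTER, _JITTER))
        nodes[nid] = PathwayNode(nid, "gene", f"GENE{i + 1}", (x, y, bw, bh),
                                 members=members_for(member_count[nid]))

    # the group node hulls its children
    corners = [nodes[c].box_corners for c in children]
    gx0 = min(c[0] for c in corners) - 4
    gy0 = min(c[1] for c in corners) - 4
    gx1 = max(c[2] for c in corners) + 4
    gy1 = max(c[3] for c in corners) + 4
    group_id = "grp001"
    nodes[group_id] = PathwayNode(
        group_id, "group", "COMPLEX1",
        ((gx0 + gx1) / 2, (gy0 + gy1) / 2, gx1 - gx0, gy1 - gy0),
        children=tuple(children),
    )
    edges.append(PathwayEdge(anchor, group_id, "binding", True))

    image_size = (40.0 * 2 + ncols * cw, 40.0 * 2 + nrows * ch)
    graph = PathwayGraph(
        pathway_id=f"synthetic{config.seed:04d}", title="synthetic pathway",
        image_size=image_size, nodes=nodes, edges=edges, source_format="kgml",
    )
    graph.validate()
    return graph


def all_member_genes(graph: PathwayGraph) -> list[str]:
    """Distinct member gene ids over all gene nodes, in node-id order."""
    genes: list[str] = []
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        if node.kind != "gene":
            continue
        for member in node.members:
            if member not in genes:
                genes.append(member)
    return genes


def make_omics(
    graph: PathwayGraph, config: FixtureConfig
) -> tuple[OmicsDataset, OmicsDataset, OmicsDataset, dict[str, SampleGrouping]]:
    """Generate coupled mRNA / copy-number / mutation matrices.

    One row per distinct member gene.  Copy-number categories are sampled
    per group from the configured probabilities (the amplified group uses
    the gain-heavy set); expression is the group's mean shift plus
    ``rho`` times the copy-number code plus unit Gaussian noise; mutation
    status is Bernoulli per gene and group.  Missing cells are injected
    at ``missing_rate`` independently per matrix.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = all_member_genes(graph)
    samples: list[str] = []
    sample_group: list[str] = []
    for label in config.group_labels:
        for i in range(config.n_samples):
            samples.append(f"{label}_{i:04d}")
            sample_group.append(label)

    n_genes, n_samples = len(genes), len(samples)
    cnv_codes = np.zeros((n_genes, n_samples))
    codes = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    for j, label in enumerate(sample_group):
        probs = (config.cnv_probs_amplified if label == config.amplified_group
                 else config.cnv_probs_background)
        cnv_codes[:, j] = rng.choice(codes, size=n_genes, p=probs)

    shift_of = dict(zip(config.group_labels, config.mean_shifts))
    shifts = np.array([shift_of[label] for label in sample_group])
    mrna = shifts[None, :] + config.rho * cnv_codes + rng.standard_normal((n_genes, n_samples))

    rate_of = dict(zip(config.group_labels, config.mutation_rates))
    rates = np.array([rate_of[label] for label in sample_group])
    mutation = (rng.random((n_genes, n_samples)) < rates[None, :]).astype(float)

    def inject_missing(matrix: np.ndarray) -> np.ndarray:
        mask = rng.random(matrix.shape) < config.missing_rate
        out = matrix.copy()
        out[mask] = np.nan
        return out

    frames = {
        "mrna": inject_missing(mrna),
        "cnv": inject_missing(cnv_codes),
        "mutation": inject_missing(mutation),
    }
    mk = lambda name, dtype, tag: OmicsDataset(  # noqa: E731
        dataset_id=name, dtype=dtype,
        values=pd.DataFrame(frames[name], index=genes, columns=samples),
        color_tag=tag,
    )
    mrna_ds = mk("mrna", "numerical", "#7fd4d4")
    cnv_ds = mk("cnv", "ordinal_cnv", "#7fa8d4")
    mut_ds = mk("mutation", "binary", "#d4b8e8")

    groups = [(label, [s for s, g in zip(samples, sample_group) if g == label])
              for label in config.group_labels]
    groupings = {
        name: SampleGrouping(name, [(label, list(members)) for label, members in groups])
        for name in ("mrna", "cnv", "mutation")
    }
    return mrna_ds, cnv_ds, mut_ds, groupings


def _matrix_tsv(dataset: OmicsDataset, integer: bool) -> str:
    frame = dataset.values
    lines = ["gene\t" + "\t".join(frame.columns)]
    for row_id in frame.index:
        cells = []
        for value in frame.loc[row_id].to_numpy(dtype=float):
            if np.isnan(value):
                cells.append("")
            elif integer:
                cells.append(str(int(value)))
            else:
                cells.append(f"{value:.6f}")
        lines.append(row_id + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


def _grouping_tsv(groupings: dict[str, SampleGrouping]) -> str:
    lines = ["dataset_id\tgroup_label\tsample_id"]
    for dataset_id in sorted(groupings):
        for label, samples in groupings[dataset_id].groups:
            for sample in samples:
                lines.append(f"{dataset_id}\t{label}\t{sample}")
    return "\n".join(lines) + "\n"


def write_fixture_dir(config: FixtureConfig, outdir) -> dict[str, str]:
    """Write the full synthetic study to a directory; returns file paths.

    Files: ``pathway.kgml``, ``mrna.tsv``, ``cnv.tsv``, ``mutation.tsv``,
    ``groups.tsv``, ``config.yaml``.  Identical config => identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph = make_pathway(config)
    mrna, cnv, mutation, groupings = make_omics(graph, config)

    files = {
        "pathway.kgml": write_kgml(graph),
        "mrna.tsv": _matrix_tsv(mrna, integer=False),
        "cnv.tsv": _matrix_tsv(cnv, integer=True),
        "mutation.tsv": _matrix_tsv(mutation, integer=True),
        "groups.tsv": _grouping_tsv(groupings),
        "config.yaml": yaml.safe_dump({
            "seed": config.seed,
            "start": config.start_node,
            "end": config.end_node,
            "datasets": [
                {"id": "mrna", "file": "mrna.tsv", "dtype": "numerical",
                 "color_tag": mrna.color_tag},
                {"id": "cnv", "file": "cnv.tsv", "dtype": "ordinal_cnv",
                 "color_tag": cnv.color_tag},
                {"id": "mutation", "file": "mutation.tsv", "dtype": "binary",
                 "color_tag": mutation.color_tag},
            ],
            "grouping": "groups.tsv",
            "pathway": "pathway.kgml",
        }, sort_keys=True),
    }
    written = {}
    for name, content in files.items():
        path = outdir / name
        path.write_text(content)
        written[name] = str(path)
    return written
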