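"""Omics matrices, sample groupings, and on-node summary statistics.

Three data types are handled, matching the heterogeneity of a typical
cancer study: numerical (e.g. mRNA expression), ordinal copy-number status
on the five-level scale (homozygous deletion, heterozygous deletion,
normal, low gain, high gain, coded -2..2), and binary status (e.g. whether
a gene is mutated).  A matrix is genes x samples; samples are organised
into named, possibly overlapping groups, all drawn from a single dataset.

Mapping a pathway node onto a dataset can yield several rows at once
(multi-mapping): a node often stands for a whole protein family, and a
complex (group) node contributes the rows of all its subnodes.  Summaries
therefore aggregate over the full multiset of (row, sample) values, with
missing cells excluded rather than imputed.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PathwayGraph, PathwayNode

DTYPES = ("numerical", "ordinal_cnv", "binary")


class CnvCategory(enum.IntEnum):
    """Five-level copy-number scale, totally ordered by copy count."""

    hom_del = -2
    het_del = -1
    normal = 0
    low_gain = 1
    high_gain = 2


#: Order used for stacked bars and histograms (highest gain first).
CNV_DISPLAY_ORDER = (
    CnvCategory.high_gain,
    CnvCategory.low_gain,
    CnvCategory.normal,
    CnvCategory.het_del,
    CnvCategory.hom_del,
)


@dataclass
class OmicsDataset:
    """A typed gene x sample matrix.

    ``values`` is a float DataFrame (rows = genes, columns = samples) with
    NaN for missing cells.  Ordinal CNV values are stored as their integer
    codes -2..2; binary values as 0/1.
    """

    dataset_id: str
    dtype: str
    values: pd.DataFrame
    color_tag: str = "#888888"

    def __post_init__(self) -> None:
        if self.dtype not in DTYPES:
            raise ValueError(f"unknown dtype {self.dtype!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene id(s): {dupes}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        flat = self.values.to_numpy(dtype=float).ravel()
        finite = flat[~np.isnan(flat)]
        if self.dtype == "binary" and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("binary dataset values must be 0/1 or missing")
        if self.dtype == "ordinal_cnv" and not np.isin(finite, (-2.0, -1.0, 0.0, 1.0, 2.0)).all():
            raise ValueError("ordinal CNV values must be coded -2..2 or missing")
        if self.dtype == "numerical" and not np.isfinite(finite).all():
            raise ValueError("numerical dataset contains non-finite values")

    @property
    def rows(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SampleGrouping:
    """Ordered, possibly overlapping sample groups of one dataset."""

    dataset_id: str
    groups: list[tuple[str, list[str]]] = field(default_factory=list)

    def labels(self) -> list[str]:
        return [label for label, _ in self.groups]

    def samples_of(self, group_label: str) -> list[str]:
        for label, samples in self.groups:
            if label == group_label:
                return list(samples)
        raise KeyError(f"unknown group {group_label!r}")

    def validate(self, dataset: OmicsDataset) -> None:
        known = set(dataset.samples)
        for label, samples in self.groups:
            missing = [s for s in samples if s not in known]
            if missing:
                raise ValueError(f"group {label!r}: samples not in dataset: {missing}")


@dataclass(frozen=True)
class NodeSummary:
    """Aggregate of the values mapped onto one node.

    ``mean``/``std`` are None when no non-missing value maps to the node
    (the renderer then shows the missing-data marker instead of a color).
    ``std`` is the population standard deviation.  ``category_counts``
    (ordinal only) counts non-missing cells per CNV category;
    ``mutated_fraction`` (binary only) is the share of 1s.
    """

    mean: float | None
    std: float | None
    n_rows: int
    n_samples: int
    n_values: int
    has_missing: bool
    category_counts: dict[CnvCategory, int] | None = None
    mutated_fraction: float | None = None


class DataError(ValueError):
    pass


def read_matrix(tsv, dtype: str, dataset_id: str, color_tag: str = "#888888") -> OmicsDataset:
    """Read a gene x sample TSV into a typed dataset.

    The header row holds sample ids, the first column gene ids; empty
    cells are missing.  Binary cells must be 0/1, ordinal CNV cells must be
    the integer codes -2..2 (mapped onto the five categories).
    """
    if isinstance(tsv, str) and "\n" in tsv:
        tsv = io.StringIO(tsv)
    try:
        frame = pd.read_csv(tsv, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise DataError(f"cannot read matrix TSV: {exc}") from exc
    frame.index = frame.index.astype(str)
    if frame.index.has_duplicates:
        dupes = sorted(set(frame.index[frame.index.duplicated()]))
        raise DataError(f"duplicate gene id(s): {dupes}")
    values = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for col in frame.columns:
        for row in frame.index:
            cell = frame.at[row, col].strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                values.at[row, col] = np.nan
                continue
            try:
                values.at[row, col] = float(cell)
            except ValueError as exc:
                raise DataError(f"non-numeric cell at row {row!r}, column {col!r}: {cell!r}") from exc
    try:
        return OmicsDataset(dataset_id=dataset_id, dtype=dtype, values=values, color_tag=color_tag)
    except ValueError as exc:
        raise DataError(str(exc)) from exc


def read_grouping(tsv) -> dict[str, SampleGrouping]:
    """Read a grouping TSV (columns: dataset_id, group_label, sample_id)."""
    if isinstance(tsv, str) and "\n" in tsv:
        tsv = io.StringIO(tsv)
    frame = pd.read_csv(tsv, sep="\t", dtype=str)
    required = {"dataset_id", "group_label", "sample_id"}
    if not required.issubset(frame.columns):
        raise DataError(f"grouping TSV needs columns {sorted(required)}")
    groupings: dict[str, SampleGrouping] = {}
    for _, row in frame.iterrows():
        grouping = groupings.setdefault(row["dataset_id"], SampleGrouping(row["dataset_id"]))
        for label, samples in grouping.groups:
            if label == row["group_label"]:
                samples.append(row["sample_id"])
                break
        else:
            grouping.groups.append((row["group_label"], [row["sample_id"]]))
    return groupings


def read_alias_table(tsv) -> dict[str, str]:
    """Two-column TSV mapping member ids to dataset row ids (no header)."""
    if isinstance(tsv, str) and "\n" in tsv:
        tsv = io.StringIO(tsv)
    frame = pd.read_csv(tsv, sep="\t", dtype=str, header=None, names=["member_id", "row_id"])
    return dict(zip(frame["member_id"], frame["row_id"]))


def resolve_mappings(
    node: PathwayNode,
    dataset: OmicsDataset,
    alias_table: dict[str, str] | None = None,
    graph: PathwayGraph | None = None,
) -> list[str]:
    """Dataset rows a node maps onto, in member order.

    Gene nodes map through their members (after optional alias
    translation); group nodes concatenate their children's rows in
    child-major order, deduplicated; compounds and map links map to
    nothing.  An empty result is valid — it triggers the missing-data
    marker downstream.
    """
    alias = alias_table or {}
    known = set(dataset.rows)

    def rows_for(members) -> list[str]:
        hits = []
        for member in members:
            row_id = alias.get(member, member)
            if row_id in known:
                hits.append(row_id)
        return hits

    if node.kind == "gene":
        out: list[str] = []
        for row_id in rows_for(node.members):
            if row_id not in out:
                out.append(row_id)
        return out
    if node.kind == "group":
        if graph is None:
            raise DataError("resolving a group node requires the graph")
        out = []
        for child_id in node.children:
            child = graph.nodes[child_id]
            for row_id in resolve_mappings(child, dataset, alias_table, graph):
                if row_id not in out:
                    out.append(row_id)
        return out
    return []


def _block(dataset: OmicsDataset, rows: list[str], samples: list[str]) -> np.ndarray:
    if not rows or not samples:
        return np.empty((0, 0))
    return dataset.values.loc[rows, samples].to_numpy(dtype=float)


def node_summary(
    node: PathwayNode,
    dataset: OmicsDataset,
    grouping: SampleGrouping | None = None,
    group_label: str | None = None,
    alias_table: dict[str, str] | None = None,
    graph: PathwayGraph | None = None,
) -> NodeSummary:
    """Summarise the values mapped onto a node.

    The mean and population standard deviation run over the multiset
    {value(row, sample)} of all mapped rows crossed with the selected
    samples (one group when ``group_label`` is given, otherwise every
    dataset column), excluding missing cells.  Ordinal CNV values enter
    the mean through their integer codes and are additionally counted per
    category; binary data reports the mutated fraction (its mean).
    """
    rows = resolve_mappings(node, dataset, alias_table, graph)
    if group_label is not None:
        if grouping is None:
            raise DataError("group_label given without a grouping")
        samples = grouping.samples_of(group_label)
    else:
        samples = dataset.samples
    block = _block(dataset, rows, samples)
    flat = block.ravel()
    present = flat[~np.isnan(flat)]
    n_cells = len(rows) * len(samples)
    has_missing = (len(present) < n_cells) or n_cells == 0

    category_counts = None
    if dataset.dtype == "ordinal_cnv":
        category_counts = {
            cat: int(np.count_nonzero(present == float(cat.value))) for cat in CnvCategory
        }
    if present.size == 0:
        return NodeSummary(None, None, len(rows), len(samples), 0, True,
                           category_counts=category_counts,
                           mutated_fraction=None)
    mean = float(present.mean())
    std = float(present.std(ddof=0))
    mutated = mean if dataset.dtype == "binary" else None
    return NodeSummary(mean, std, len(rows), len(samples), int(present.size),
                       has_missing, category_counts=category_counts,
                       mutated_fraction=mutated)


def group_summary(
    node: PathwayNode,
    dataset: OmicsDataset,
    grouping: SampleGrouping,
    group_label: str,
    alias_table: dict[str, str] | None = None,
    graph: PathwayGraph | None = None,
) -> NodeSummary:
    """:func:`node_summary` restricted to one sample group."""
    return node_summary(node, dataset, grouping, group_label, alias_table, graph)


def categorize_cnv(value: float, t_low: float = 0.3, t_high: float = 1.0) -> CnvCategory | None:
    """Bin a quantitative copy-number value onto the five-level scale.

    Thresholds are symmetric around zero on a log2-ratio-like scale:
    ``|value| < t_low`` is normal, ``t_low <= |value| < t_high`` a low
    gain / heterozygous deletion, ``|value| >= t_high`` a high gain /
    homozygous deletion (boundaries closed above).  Non-finite values are
    missing (None).
    """
    if not (t_high > t_low > 0):
        raise ValueError("need t_high > t_low > 0")
    if not np.isfinite(value):
        return None
    if value >= t_high:
        return CnvCategory.high_gain
    if value >= t_low:
        return CnvCategory.low_gain
    if value > -t_low:
        return CnvCategory.normal
    if value > -t_high:
        return CnvCategory.het_del
    return CnvCategory.hom_del


def branch_preview(
    head_node: PathwayNode,
    datasets: dict[str, OmicsDataset],
    groupings: dict[str, SampleGrouping],
    alias_table: dict[str, str] | None = None,
    graph: PathwayGraph | None = None,
) -> dict[str, dict[str, object]]:
    """Per-group preview values for an (expanded) branch head node.

    Numerical datasets preview as the per-group mean, ordinal CNV as the
    per-group category counts in display order (a stacked-bar spec), and
    binary as (mutated, non-mutated) counts.  A head with no mapped rows
    yields an empty preview with the missing marker flagged.
    """
    preview: dict[str, dict[str, object]] = {}
    for dataset_id in sorted(datasets):
        dataset = datasets[dataset_id]
        grouping = groupings.get(dataset_id)
        if grouping is None:
            continue
        rows = resolve_mappings(head_node, dataset, alias_table, graph)
        per_group: dict[str, object] = {}
        for label, _ in grouping.groups:
            summary = group_summary(head_node, dataset, grouping, label, alias_table, graph)
            if not rows or summary.n_values == 0:
                per_group[label] = None
            elif dataset.dtype == "numerical":
                per_group[label] = summary.mean
            elif dataset.dtype == "ordinal_cnv":
                per_group[label] = tuple(summary.category_counts[c] for c in CNV_DISPLAY_ORDER)
            else:
                mutated = int(round(summary.mutated_fraction * summary.n_values))
                per_group[label] = (mutated, summary.n_values - mutated)
        preview[dataset_id] = {"dtype": dataset.dtype, "groups": per_group,
                               "missing": not rows}
    return preview
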