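"""Relatedness network over sample groups from pairwise DMP counts.

Nodes are diagnosis groups; an edge connects a pair whose DMP count falls in
one of the binned intervals — {0}, [1, 999], [1000, 4999], [5000, 9999],
[10000, 14999] by default.  Fewer differential probes means a stronger
similarity, so the zero-count bin is the strongest connection.  Pairs at or
above the last bin's upper end get no edge; groups left without any edge are
annotated with their closest possible connection (the minimum-count partner
and the exact count, all partners kept on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .dmp import PairwiseDMPCounts

__all__ = [
    "BinScheme",
    "RelatednessGraph",
    "DEFAULT_BINS",
    "build_network",
    "annotate_closest",
    "nearest_entity",
    "edge_list",
]


@dataclass(frozen=True)
class BinScheme:
    """Ordered, disjoint integer count intervals [lo, hi] with labels.

    Counts above the last interval are unbinned: the pair gets no edge.
    """

    intervals: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        prev_hi = -1
        for lo, hi, _label in self.intervals:
            if lo > hi:
                raise ValueError(f"bin [{lo},{hi}] is empty")
            if lo <= prev_hi:
                raise ValueError("bins must be ordered and non-overlapping")
            prev_hi = hi

    def label_for(self, count: int) -> str | None:
        """Bin label for a DMP count, or None when the count is unbinned."""
        if count < 0:
            raise ValueError("counts must be >= 0")
        for lo, hi, label in self.intervals:
            if lo <= count <= hi:
                return label
        return None

    @property
    def max_binned(self) -> int:
        return self.intervals[-1][1]


DEFAULT_BINS = BinScheme(intervals=(
    (0, 0, "0 CpGs"),
    (1, 999, "1-999 CpGs"),
    (1000, 4999, "1,000-4,999 CpGs"),
    (5000, 9999, "5,000-9,999 CpGs"),
    (10000, 14999, "10,000-14,999 CpGs"),
))


@dataclass(frozen=True)
class RelatednessGraph:
    """Binned relatedness network plus closest-connection annotations."""

    graph: nx.Graph
    bins: BinScheme
    closest_connections: tuple[tuple[str, str, int], ...] = field(default=())

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, dict]]:
        return list(self.graph.edges(data=True))

    def isolated_nodes(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.degree(n) == 0]


def build_network(
    counts: PairwiseDMPCounts,
    bins: BinScheme = DEFAULT_BINS,
    sample_counts: dict[str, int] | None = None,
) -> RelatednessGraph:
    """One node per group; one edge per pair whose count falls in a bin.

    Each edge carries the exact DMP count and its bin label.
    """
    c = counts.counts
    if not c.index.equals(c.columns):
        raise ValueError("count matrix must be square with matching labels")
    if not (c.to_numpy() == c.to_numpy().T).all():
        raise ValueError("count matrix must be symmetric")
    g = nx.Graph()
    for label in c.index:
        g.add_node(label, group_label=label,
                   n_samples=int(sample_counts.get(label, 0)) if sample_counts else 0)
    labels = list(c.index)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            count = int(c.loc[a, b])
            bin_label = bins.label_for(count)
            if bin_label is not None:
                g.add_edge(a, b, dmp_count=count, bin_label=bin_label,
                           is_closest_annotation=False)
    return RelatednessGraph(graph=g, bins=bins)


def annotate_closest(
    graph: RelatednessGraph, counts: PairwiseDMPCounts
) -> RelatednessGraph:
    """Record, for every node with no binned edge, its minimum-count partner(s)
    with the exact DMP count; ties keep all tied partners."""
    closest: list[tuple[str, str, int]] = []
    c = counts.counts
    for node in graph.isolated_nodes():
        row = c.loc[node].drop(node)
        min_count = int(row.min())
        for partner in row.index[row == min_count]:
            closest.append((node, str(partner), min_count))
    g = graph.graph.copy()
    for node, partner, count in closest:
        if not g.has_edge(node, partner):
            g.add_edge(node, partner, dmp_count=count,
                       bin_label="closest-connection", is_closest_annotation=True)
    return RelatednessGraph(
        graph=g, bins=graph.bins,
        closest_connections=tuple(closest),
    )


def nearest_entity(counts: PairwiseDMPCounts, group: str) -> tuple[str, int]:
    """The group with the fewest DMPs against ``group``; ties break by label."""
    c = counts.counts
    if group not in c.index:
        raise ValueError(f"unknown group {group!r}")
    row = c.loc[group].drop(group)
    min_count = int(row.min())
    tied = sorted(str(x) for x in row.index[row == min_count])
    return tied[0], min_count


def edge_list(graph: RelatednessGraph) -> pd.DataFrame:
    """Flat edge table: group_a, group_b, count, bin, is_closest_annotation."""
    rows = [
        {
            "group_a": a,
            "group_b": b,
            "dmp_count": attrs["dmp_count"],
            "bin_label": attrs["bin_label"],
            "is_closest_annotation": attrs.get("is_closest_annotation", False),
        }
        for a, b, attrs in sorted(graph.graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=[
        "group_a", "group_b", "dmp_count", "bin_label", "is_closest_annotation"
    ])
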