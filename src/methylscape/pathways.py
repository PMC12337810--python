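"""Direction-labelled gene lists from differentially methylated TSS probes,
and hypergeometric over-representation against a gene-set collection.

TSS probes hypermethylated in the lesion (delta > 0 in lesion-vs-normal
orientation) mark their gene as inhibited; hypomethylated TSS probes mark it
activated.  A gene with conflicting TSS probes is assigned by the sign of its
mean delta and logged as conflicting.  The orientation of the contrast must
be explicit: callers state which group is the baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dmp import DMPSet, bh_adjust
from .io import GeneSetCollection, ProbeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "DirectionalGeneLists",
    "dmps_to_gene_lists",
    "hypergeometric_enrich",
    "tss_universe",
]


@dataclass(frozen=True)
class DirectionalGeneLists:
    """Genes called activated (hypomethylated TSS) or inhibited (hypermethylated
    TSS) in the lesion, with the universe of all genes carrying a TSS probe."""

    activated: frozenset
    inhibited: frozenset
    universe: frozenset
    source_pair: tuple[str, str]
    conflicting: frozenset = field(default=frozenset())

    def __post_init__(self) -> None:
        if not self.activated <= self.universe or not self.inhibited <= self.universe:
            raise ValueError("gene lists must be subsets of the universe")
        if self.activated & self.inhibited:
            raise ValueError("a gene cannot be both activated and inhibited")


def tss_universe(annotation: ProbeAnnotation) -> frozenset:
    """All genes with at least one TSS-flagged probe on the array."""
    ann = annotation.data
    genes = ann.loc[ann["tss_flag"] & (ann["gene_symbol"] != ""), "gene_symbol"]
    return frozenset(genes)


def dmps_to_gene_lists(
    dmps: DMPSet,
    annotation: ProbeAnnotation,
    lesion_is_group_b: bool = True,
) -> DirectionalGeneLists:
    """Map a DMP set to activated/inhibited gene lists via TSS probes.

    ``dmps.deltas`` is group_b - group_a; ``lesion_is_group_b`` states the
    contrast orientation (True: group_b is the lesion, group_a the normal
    baseline).  Positive lesion-orientation delta = hypermethylated in lesion
    = inhibited gene; negative = activated.  Multi-probe genes with mixed
    signs are resolved by the sign of the mean delta and logged.
    """
    ann = annotation.indexed()
    missing = [p for p in dmps.probe_ids if p not in ann.index]
    if missing:
        raise ValueError(f"annotation missing {len(missing)} DMP probes, e.g. {missing[:3]}")
    deltas = dmps.deltas if lesion_is_group_b else -dmps.deltas
    sub = ann.loc[list(dmps.probe_ids)]
    tss = sub["tss_flag"] & (sub["gene_symbol"] != "")
    per_probe = pd.DataFrame({
        "gene": sub.loc[tss, "gene_symbol"],
        "delta": deltas.loc[sub.index[tss]].to_numpy(),
    })
    activated, inhibited, conflicting = set(), set(), set()
    for gene, grp in per_probe.groupby("gene"):
        signs = np.sign(grp["delta"].to_numpy())
        if len(set(signs[signs != 0])) > 1:
            conflicting.add(gene)
        mean_delta = grp["delta"].mean()
        if mean_delta > 0:
            inhibited.add(gene)
        elif mean_delta < 0:
            activated.add(gene)
        else:
            conflicting.add(gene)   # perfectly cancelling probes: no direction
    if conflicting:
        logger.info("%d genes had conflicting TSS probe directions", len(conflicting))
    universe = tss_universe(annotation)
    return DirectionalGeneLists(
        activated=frozenset(activated) & universe,
        inhibited=frozenset(inhibited) & universe,
        universe=universe,
        source_pair=(dmps.group_a, dmps.group_b),
        conflicting=frozenset(conflicting),
    )


def hypergeometric_enrich(
    query: frozenset | set,
    universe: frozenset | set,
    collection: GeneSetCollection,
    direction: str = "",
) -> pd.DataFrame:
    """One-sided (upper tail, observed included) hypergeometric test per set.

    Sets are intersected with the universe before testing; the universe
    defines the sampling margin.  Returns a table with overlap, sizes, p and
    BH q; empty for an empty query (with a warning).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query) & universe
    if not query:
        logger.warning("empty query gene list; no enrichment computed")
        return pd.DataFrame(columns=[
            "gene_set", "overlap", "set_size", "query_size", "universe_size",
            "p", "q", "direction",
        ])
    rows = []
    n_universe, n_query = len(universe), len(query)
    for name, members in collection.sets.items():
        in_universe = frozenset(members) & universe
        if not in_universe:
            continue
        overlap = len(in_universe & query)
        # P(X >= overlap), X ~ Hypergeom(N=universe, K=set, n=query)
        p = float(hypergeom.sf(overlap - 1, n_universe, len(in_universe), n_query))
        rows.append({
            "gene_set": name,
            "overlap": overlap,
            "set_size": len(in_universe),
            "query_size": n_query,
            "universe_size": n_universe,
            "p": min(p, 1.0),
            "direction": direction,
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
    return table
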