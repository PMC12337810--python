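"""Validated in-memory containers and readers/writers for every format the pipeline touches.

Matrices are oriented probes-in-rows, samples-in-columns, matching the export
convention of methylation array processing tools.  Readers reject malformed
input rather than silently coercing it; write->read round trips are identity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "DetectionPMatrix",
    "SampleSheet",
    "ProbeAnnotation",
    "GeneSetCollection",
    "read_beta_matrix",
    "read_detection_p",
    "write_matrix",
    "read_sample_sheet",
    "read_probe_annotation",
    "read_gmt",
    "write_gmt",
    "write_graphml",
    "read_graphml",
]

SAMPLE_SHEET_COLUMNS = ["sample_id", "group_label", "material", "grade", "mutation_status"]
ANNOTATION_COLUMNS = ["probe_id", "chromosome", "position", "gene_symbol", "tss_flag"]

# probes with more than this fraction of missing betas are dropped at load
MAX_MISSING_FRACTION = 0.10


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _check_unique(ids, kind: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate {kind} ids: {dups}")


@dataclass(frozen=True)
class BetaMatrix:
    """Probe x sample methylation fractions, all finite values in [0, 1].

    ``data`` is a float DataFrame indexed by probe id with sample-id columns.
    NaN marks an explicitly missing entry.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1) | np.isinf(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"beta value out of [0,1] at probe {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}: {vals[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def select_probes(self, probes) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[list(probes)])

    def select_samples(self, samples) -> "BetaMatrix":
        return BetaMatrix(self.data[list(samples)])


@dataclass(frozen=True)
class DetectionPMatrix:
    """Per-probe, per-sample detection p-values, same axes as a BetaMatrix."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy(dtype=float)
        if np.isnan(vals).any() or ((vals < 0) | (vals > 1)).any():
            raise FormatError("detection p-values must be finite and in [0,1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def matches(self, beta: BetaMatrix) -> bool:
        return self.data.index.equals(beta.data.index) and self.data.columns.equals(
            beta.data.columns
        )


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata: diagnosis group, material, grade, mutation status."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        _check_unique(self.data["sample_id"], "sample")
        if (self.data["group_label"].astype(str).str.len() == 0).any():
            raise FormatError("empty group_label in sample sheet")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.data["sample_id"])

    def groups(self) -> dict[str, list[str]]:
        """Mapping group label -> sample ids, in sheet order."""
        out: dict[str, list[str]] = {}
        for sid, grp in zip(self.data["sample_id"], self.data["group_label"]):
            out.setdefault(str(grp), []).append(str(sid))
        return out

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"].astype(str), self.data["group_label"].astype(str)))


@dataclass(frozen=True)
class ProbeAnnotation:
    """Manifest-style probe annotation: locus, gene symbol, TSS-region flag.

    Coordinates are 1-based, matching array manifest convention.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"probe annotation missing columns: {missing}")
        _check_unique(self.data["probe_id"], "probe")
        if (self.data["position"].astype(int) < 1).any():
            raise FormatError("positions must be >= 1 (1-based)")

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.data["probe_id"])

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("probe_id")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with free-text descriptions; no set may be empty."""

    sets: Mapping[str, frozenset]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


# ---------------------------------------------------------------------------
# matrix TSV


def _read_matrix_tsv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.name is None and df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    # detect transposed input: probe-id-looking column headers (e.g. cg000…)
    if len(df.columns) and all(str(c).startswith("cg") for c in df.columns) and not all(
        str(i).startswith("cg") for i in df.index
    ):
        raise FormatError(
            f"{path}: header looks like probe ids; matrix must be probes-in-rows"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    # "NA" (and friends) are legitimate missing markers; anything else
    # non-numeric is an error
    na_mask = df.isna() | df.isin(["NA", "NaN", "nan", ""])
    bad = numeric.isna() & ~na_mask
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell {df.iat[i, j]!r} at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return numeric.astype(float)


def read_beta_matrix(path, max_missing_fraction: float = MAX_MISSING_FRACTION) -> BetaMatrix:
    """Read a probes x samples beta-value TSV.

    Probes with more than ``max_missing_fraction`` missing entries are dropped
    (with a logged count); any present value outside [0, 1] is rejected with
    the probe and sample named in the error.
    """
    df = _read_matrix_tsv(path)
    frac_missing = df.isna().mean(axis=1)
    drop = frac_missing > max_missing_fraction
    if drop.any():
        logger.info("dropping %d probes with >%d%% missing betas",
                    int(drop.sum()), int(100 * max_missing_fraction))
        df = df.loc[~drop]
    return BetaMatrix(df)


def read_detection_p(path) -> DetectionPMatrix:
    return DetectionPMatrix(_read_matrix_tsv(path))


def write_matrix(data: pd.DataFrame | BetaMatrix | DetectionPMatrix, path,
                 index_label: str = "probe_id") -> None:
    """Write a probes x samples matrix as TSV with full float precision."""
    if isinstance(data, (BetaMatrix, DetectionPMatrix)):
        data = data.data
    data.to_csv(path, sep="\t", index_label=index_label, float_format="%.17g")


# ---------------------------------------------------------------------------
# sample sheet / annotation CSV


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str).fillna("NA")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, index=False)


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, dtype={"probe_id": str, "chromosome": str, "gene_symbol": str})
    df["gene_symbol"] = df["gene_symbol"].fillna("")
    df["tss_flag"] = df["tss_flag"].astype(bool)
    df["position"] = df["position"].astype(int)
    return ProbeAnnotation(df)


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    annotation.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: name TAB description TAB member TAB member…

    Duplicate members within one line are collapsed; an empty file yields an
    empty collection; a line with fewer than three fields is rejected with its
    line number.
    """
    sets: dict[str, frozenset] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = frozenset(members)
            desc[name] = description
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# GraphML (relatedness network)


def write_graphml(graph: nx.Graph, path) -> None:
    """Serialize a relatedness graph to GraphML.

    Nodes carry group label and sample-count attributes; edges carry the exact
    DMP count, the bin label, and an ``is_closest_annotation`` flag separating
    real binned edges from closest-connection annotations on isolated groups.
    """
    out = nx.Graph()
    for node, attrs in graph.nodes(data=True):
        out.add_node(str(node), **{k: v for k, v in attrs.items()})
    for u, v, attrs in graph.edges(data=True):
        a = dict(attrs)
        a.setdefault("is_closest_annotation", False)
        out.add_edge(str(u), str(v), **a)
    nx.write_graphml(out, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# JSON helpers (ground truth, reports)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
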