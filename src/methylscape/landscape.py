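"""Methylation landscapes: t-SNE embedding, hierarchical clustering,
agglomerative consensus clustering, and the consensus-degree group comparison.

All clustering runs on 1 - Pearson correlation distance with average linkage,
over the top-variance probe subset selected upstream.  Consensus clustering
resamples samples (without replacement, default 80%), re-clusters each draw,
cuts at k, and records for every sample pair the fraction of co-draws in
which the pair co-clustered.  Because the correlation distance between two
samples over the fixed probe set does not depend on which other samples were
drawn, the full distance matrix is computed once and indexed per resample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .dmp import bh_adjust
from .io import BetaMatrix, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "Embedding",
    "Dendrogram",
    "ConsensusMatrix",
    "tsne_embed",
    "hierarchical_cluster",
    "consensus_cluster",
    "consensus_degree_test",
    "correlation_distance",
    "knn_label_purity",
]


@dataclass(frozen=True)
class Embedding:
    """2-D sample coordinates plus the parameters that produced them."""

    coords: pd.DataFrame                 # index sample_id, columns x, y
    perplexity: float
    seed: int
    n_iter: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.coords.to_numpy()).all():
            raise ValueError("non-finite embedding coordinates")


@dataclass(frozen=True)
class Dendrogram:
    """Sample merge tree (scipy linkage matrix) with its distance/linkage names."""

    linkage: np.ndarray
    sample_ids: tuple[str, ...]
    distance: str
    method: str

    def cut(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=list(self.sample_ids), name="cluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.sample_ids[node.id]
            left, right = walk(node.left), walk(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


@dataclass(frozen=True)
class ConsensusMatrix:
    """Sample x sample co-clustering frequency over resampled clusterings.

    Entries are co-cluster count / co-draw count; pairs never drawn together
    are NaN (flagged missing, not 0).  Symmetric with unit diagonal.
    """

    values: pd.DataFrame
    B: int
    subsample_fraction: float
    k: int

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index


def correlation_distance(data: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between samples (columns) of a probes x samples
    matrix.  Constant samples (zero variance) are rejected."""
    x = data.to_numpy(dtype=float).T        # samples x probes
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = data.columns[sd == 0].tolist()[:5]
        raise ValueError(f"constant samples have undefined correlation: {bad}")
    corr = np.corrcoef(x)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    dist = (dist + dist.T) / 2.0
    return pd.DataFrame(dist, index=data.columns, columns=data.columns)


def tsne_embed(
    matrix: BetaMatrix | pd.DataFrame,
    perplexity: float = 30.0,
    seed: int = 0,
    n_iter: int = 1000,
    pca_components: int = 50,
) -> Embedding:
    """t-SNE of samples from a probes x samples matrix.

    Samples are first reduced to ``pca_components`` principal components for
    stability, then embedded in 2-D.  Deterministic for a fixed seed.
    """
    data = matrix.data if isinstance(matrix, BetaMatrix) else matrix
    n = data.shape[1]
    if n <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} samples; need "
            f"n_samples > 3*perplexity — lower --perplexity to < {n / 3:.0f}"
        )
    x = data.to_numpy(dtype=float).T
    n_comp = min(pca_components, *x.shape)
    x = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        max_iter=n_iter,
        init="pca",
    ).fit_transform(x)
    coords = pd.DataFrame(emb, index=data.columns, columns=["x", "y"])
    return Embedding(coords=coords, perplexity=perplexity, seed=seed, n_iter=n_iter)


def hierarchical_cluster(
    matrix: BetaMatrix | pd.DataFrame,
    distance: str = "correlation",
    method: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of samples; default 1-Pearson, average linkage."""
    data = matrix.data if isinstance(matrix, BetaMatrix) else matrix
    if data.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if data.isna().to_numpy().any():
        raise ValueError("NaNs in matrix; filter or impute first")
    if distance == "correlation":
        dmat = correlation_distance(data)
        condensed = squareform(dmat.to_numpy(), checks=False)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(data.to_numpy(dtype=float).T)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    linkage = hierarchy.linkage(condensed, method=method)
    return Dendrogram(
        linkage=linkage,
        sample_ids=tuple(data.columns),
        distance=distance,
        method=method,
    )


def consensus_cluster(
    matrix: BetaMatrix | pd.DataFrame,
    B: int = 500,
    subsample_fraction: float = 0.8,
    k: int = 4,
    seed: int = 0,
    distance: str = "correlation",
    method: str = "average",
) -> ConsensusMatrix:
    """Consensus matrix over B subsampled hierarchical clusterings cut at k."""
    data = matrix.data if isinstance(matrix, BetaMatrix) else matrix
    n = data.shape[1]
    if B < 10:
        raise ValueError("B must be >= 10")
    if not 0.5 < subsample_fraction < 1.0:
        raise ValueError("subsample_fraction must be in (0.5, 1)")
    m = int(round(subsample_fraction * n))
    if k > m:
        raise ValueError(f"k={k} exceeds subsample size {m}")
    dist_full = (
        correlation_distance(data).to_numpy()
        if distance == "correlation"
        else None
    )
    rng = np.random.default_rng(seed)
    co_cluster = np.zeros((n, n))
    co_draw = np.zeros((n, n))
    x_t = data.to_numpy(dtype=float).T
    for _ in range(B):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        if dist_full is not None:
            sub = dist_full[np.ix_(idx, idx)]
            condensed = squareform(sub, checks=False)
        else:
            from scipy.spatial.distance import pdist

            condensed = pdist(x_t[idx])
        labels = hierarchy.fcluster(hierarchy.linkage(condensed, method=method),
                                    t=k, criterion="maxclust")
        same = labels[:, None] == labels[None, :]
        co_draw[np.ix_(idx, idx)] += 1
        co_cluster[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore"):
        consensus = np.where(co_draw > 0, co_cluster / np.where(co_draw > 0, co_draw, 1), np.nan)
    never = int(np.isnan(consensus[np.triu_indices(n, 1)]).sum())
    if never:
        logger.warning("%d sample pairs never co-drawn; reported as missing", never)
    np.fill_diagonal(consensus, 1.0)
    values = pd.DataFrame(consensus, index=data.columns, columns=data.columns)
    return ConsensusMatrix(values=values, B=B, subsample_fraction=subsample_fraction, k=k)


def consensus_degree_test(
    consensus: ConsensusMatrix,
    sheet: SampleSheet,
    reference_groups: list[str] | str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare within-reference consensus against reference-vs-other consensus.

    For each non-reference group g, the distribution of consensus values
    among reference samples (upper triangle only) is compared with the
    consensus values between reference samples and members of g, using a
    two-sided Mann-Whitney test; q-values are BH-adjusted across groups.
    Groups with < 2 samples are skipped with a warning.
    """
    if isinstance(reference_groups, str):
        reference_groups = [reference_groups]
    groups = sheet.groups()
    for g in reference_groups:
        if g not in groups:
            raise ValueError(f"reference group {g!r} not in sample sheet")
    ids = consensus.sample_ids
    ref_samples = [s for g in reference_groups for s in groups[g] if s in ids]
    if len(ref_samples) < 2:
        raise ValueError("reference group(s) need >= 2 samples in the consensus matrix")
    vals = consensus.values
    ref_idx = [ids.get_loc(s) for s in ref_samples]
    arr = vals.to_numpy()
    iu = np.triu_indices(len(ref_idx), 1)
    within = arr[np.ix_(ref_idx, ref_idx)][iu]
    within = within[~np.isnan(within)]

    rows = []
    for g, samples in groups.items():
        if g in reference_groups:
            continue
        present = [s for s in samples if s in ids]
        if len(present) < 2:
            logger.warning("group %r has < 2 samples; skipped", g)
            continue
        g_idx = [ids.get_loc(s) for s in present]
        between = arr[np.ix_(ref_idx, g_idx)].ravel()
        between = between[~np.isnan(between)]
        if np.array_equal(np.unique(within), np.unique(between)) and (
            len(np.unique(np.concatenate([within, between]))) == 1
        ):
            stat, p = np.nan, 1.0     # identical constant distributions
        else:
            stat, p = mannwhitneyu(within, between, alternative="two-sided")
        rows.append({"group": g, "n_within": len(within), "n_between": len(between),
                     "statistic": stat, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["q"] < alpha
    return table


def knn_label_purity(embedding: Embedding, labels: dict[str, str] | pd.Series, k: int = 5) -> float:
    """Fraction of samples whose k nearest embedded neighbours vote their own
    label.  A quantitative stand-in for reading group proximity off a t-SNE."""
    coords = embedding.coords.to_numpy()
    ids = list(embedding.coords.index)
    lab = pd.Series(labels)
    y = lab.loc[ids].to_numpy()
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    correct = 0
    for i in range(len(ids)):
        nn = np.argpartition(d[i], k)[:k]
        votes = pd.Series(y[nn]).value_counts()
        top = votes.index[votes == votes.max()]
        if y[i] in top:
            correct += 1
    return correct / len(ids)
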