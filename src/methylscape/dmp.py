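"""Moderated two-group differential methylation with empirical-Bayes shrinkage.

For each probe the two-group pooled variance s_g^2 (d = n_a + n_b - 2 df) is
shrunk toward a prior variance s0^2 estimated from the whole ensemble of
per-probe variances:

    s_shrunk^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)
    t_g = (mean_b - mean_a) / (s_shrunk * sqrt(1/n_a + 1/n_b))

with p-values from a t distribution on d0 + d degrees of freedom.  The prior
(d0, s0^2) is fitted by the method of moments on log variances: under the
model, log s_g^2 follows a scaled F distribution, so the mean and variance of
log s_g^2 identify s0^2 and d0 through digamma/trigamma functions.  d0 is the
weight of the prior in pseudo-observations; d0 -> 0 recovers the ordinary
pooled t, d0 -> inf shrinks every probe to the common variance.

A probe is called differentially methylated when its BH-adjusted p-value is
below 0.01 and its absolute effect exceeds 0.3.  On the default beta scale
the effect ("logFC" in array-tool convention) is the group delta-beta, so the
0.3 threshold reads as a 30-percentage-point methylation difference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import BetaMatrix, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "DMPStats",
    "DMPSet",
    "PairwiseDMPCounts",
    "moderated_t",
    "bh_adjust",
    "call_dmps",
    "pairwise_dmp_counts",
    "fit_variance_prior",
]

DEFAULT_P_ADJ_MAX = 0.01
DEFAULT_ABS_LFC_MIN = 0.3
_MIN_PROBES_FOR_PRIOR = 50


@dataclass(frozen=True)
class DMPStats:
    """Per-probe moderated test results for one two-group contrast."""

    table: pd.DataFrame          # columns: delta, var_shrunk, t, df, p, p_adj
    group_a: str
    group_b: str
    d0: float                    # prior degrees of freedom (inf = total shrinkage)
    s0_sq: float                 # prior variance

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class DMPSet:
    """Probes passing both the significance and effect-size thresholds."""

    group_a: str
    group_b: str
    probe_ids: frozenset
    deltas: pd.Series            # delta (group_b - group_a) for each member
    p_adj_max: float
    abs_lfc_min: float

    def __len__(self) -> int:
        return len(self.probe_ids)


@dataclass(frozen=True)
class PairwiseDMPCounts:
    """Symmetric group x group matrix of DMP counts over all unordered pairs."""

    counts: pd.DataFrame
    dmp_sets: dict[tuple[str, str], DMPSet]

    @property
    def group_labels(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_pairs(self) -> int:
        return len(self.dmp_sets)

    def count(self, a: str, b: str) -> int:
        return int(self.counts.loc[a, b])


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    trigamma is strictly decreasing and convex on (0, inf); the iteration
    below converges monotonically from the closed-form large/small-x limits.
    """
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x          # good start: trigamma(y) ~ 1/y + 1/(2y^2)
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif / y) < 1e-10):
            break
    return y


def fit_variance_prior(variances: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from the ensemble of per-probe
    pooled variances, each on ``df`` residual degrees of freedom.

    Works on z = log(s_g^2): E[z] and Var[z] are closed forms in digamma and
    trigamma of d0/2 and df/2.  Returns d0 = inf when the observed spread of
    log variances does not exceed the pure-sampling spread trigamma(df/2)
    (no evidence of variance heterogeneity -> complete shrinkage).
    """
    variances = np.asarray(variances, dtype=float)
    ok = variances > 0
    if ok.sum() < 2:
        raise ValueError("cannot fit a variance prior from < 2 positive variances")
    z = np.log(variances[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = float(2.0 * _trigamma_inverse(e_var))
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(
    matrix: BetaMatrix | pd.DataFrame,
    group_a_samples: list[str],
    group_b_samples: list[str],
    group_a: str = "A",
    group_b: str = "B",
    shrink: bool = True,
) -> DMPStats:
    """Moderated two-sample t test of group_b vs group_a for every probe.

    ``delta`` is mean(group_b) - mean(group_a) on the matrix's scale.  With
    ``shrink=False`` (or when the prior cannot be fitted) the statistic
    reduces exactly to the ordinary pooled two-sample t.
    """
    data = matrix.data if isinstance(matrix, BetaMatrix) else matrix
    for name, cols in ((group_a, group_a_samples), (group_b, group_b_samples)):
        if len(cols) < 2:
            raise ValueError(f"group {name!r} has {len(cols)} samples; need >= 2")
        missing = set(cols) - set(data.columns)
        if missing:
            raise ValueError(f"samples not in matrix: {sorted(missing)[:5]}")
    a = data[list(group_a_samples)].to_numpy(dtype=float)
    b = data[list(group_b_samples)].to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values in selected columns")
    n_a, n_b = a.shape[1], b.shape[1]
    d = n_a + n_b - 2
    delta = b.mean(axis=1) - a.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s_sq = ss / d

    d0, s0_sq = 0.0, 0.0
    if shrink:
        if len(s_sq) < _MIN_PROBES_FOR_PRIOR:
            logger.warning(
                "only %d probes; variance-prior fit unreliable, falling back to "
                "no shrinkage", len(s_sq))
        elif not (s_sq > 0).any():
            logger.warning("zero within-group variance everywhere; falling back to "
                           "exact-equality calls")
        else:
            d0, s0_sq = fit_variance_prior(s_sq, d)

    if d0 == 0.0:
        var_shrunk = s_sq
        df_total = float(d)
    elif np.isinf(d0):
        var_shrunk = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        var_shrunk = (d0 * s0_sq + d * s_sq) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(var_shrunk * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
        # zero delta and zero variance -> t = 0; nonzero delta with zero
        # variance -> infinite evidence
        t = np.where((se == 0) & (delta != 0), np.sign(delta) * np.inf, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)

    table = pd.DataFrame(
        {
            "delta": delta,
            "var_shrunk": var_shrunk,
            "t": t,
            "df": df_total,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=data.index,
    )
    return DMPStats(table=table, group_a=group_a, group_b=group_b, d0=d0, s0_sq=s0_sq)


def bh_adjust(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min over j >= i of min(1, m * p_(j) / j), on the sorted scale;
    order-preserving and always >= the raw p-value.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0,1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_dmps(
    stats_: DMPStats,
    p_adj_max: float = DEFAULT_P_ADJ_MAX,
    abs_lfc_min: float = DEFAULT_ABS_LFC_MIN,
) -> DMPSet:
    """Dual-threshold call: adjusted p < p_adj_max AND |delta| > abs_lfc_min."""
    t = stats_.table
    mask = (t["p_adj"] < p_adj_max) & (t["delta"].abs() > abs_lfc_min)
    members = t.index[mask]
    return DMPSet(
        group_a=stats_.group_a,
        group_b=stats_.group_b,
        probe_ids=frozenset(members),
        deltas=t.loc[members, "delta"],
        p_adj_max=p_adj_max,
        abs_lfc_min=abs_lfc_min,
    )


def pairwise_dmp_counts(
    matrix: BetaMatrix | pd.DataFrame,
    sheet: SampleSheet,
    p_adj_max: float = DEFAULT_P_ADJ_MAX,
    abs_lfc_min: float = DEFAULT_ABS_LFC_MIN,
    shrink: bool = True,
) -> PairwiseDMPCounts:
    """DMP counts for every unordered pair of sample-sheet groups.

    Groups with fewer than 2 samples present in the matrix are skipped with
    a warning.  G groups yield G*(G-1)/2 evaluated pairs.
    """
    data = matrix.data if isinstance(matrix, BetaMatrix) else matrix
    groups = {
        g: [s for s in samples if s in data.columns]
        for g, samples in sheet.groups().items()
    }
    usable = {g: s for g, s in groups.items() if len(s) >= 2}
    skipped = sorted(set(groups) - set(usable))
    if skipped:
        logger.warning("skipping groups with < 2 samples: %s", skipped)
    labels = list(usable)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups with >= 2 samples")
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    dmp_sets: dict[tuple[str, str], DMPSet] = {}
    for ga, gb in itertools.combinations(labels, 2):
        st = moderated_t(data, usable[ga], usable[gb], ga, gb, shrink=shrink)
        dmps = call_dmps(st, p_adj_max=p_adj_max, abs_lfc_min=abs_lfc_min)
        dmp_sets[(ga, gb)] = dmps
        counts.loc[ga, gb] = counts.loc[gb, ga] = len(dmps)
    return PairwiseDMPCounts(counts=counts, dmp_sets=dmp_sets)
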