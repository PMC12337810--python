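"""Reference-based cell-type decomposition of methylation-derived activity.

Promoter methylation is converted to a gene-activity surrogate (activity =
1 - mean TSS beta, a monotone methylation-to-expression proxy), then each
sample's activity vector is decomposed on a cell-type signature matrix by
least squares under nonnegativity and sum-to-one constraints:

    min_f || S f - a ||^2   s.t.  f >= 0,  sum(f) = 1

Two solvers are provided and must agree: the default augments the system
with a heavily weighted sum-to-one row and solves NNLS (then renormalises
the tiny residual slack); the exact alternative is a KKT active-set solver
for the equality-constrained problem.  Group comparisons of the estimated
fractions follow a Shapiro-Wilk normality gate: unpaired t-test when both
groups look normal, Mann-Whitney otherwise, with the conventional
significance-star categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import mannwhitneyu, shapiro, ttest_ind

from .io import BetaMatrix, ProbeAnnotation, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "FractionEstimate",
    "gene_activity_from_beta",
    "estimate_fractions",
    "compare_fractions",
    "simplex_lsq_active_set",
]

_SUM_WEIGHT = 1e4    # weight of the sum-to-one row in the augmented NNLS


@dataclass(frozen=True)
class FractionEstimate:
    """Per-sample cell-type fractions (rows sum to 1) and residual norms."""

    fractions: pd.DataFrame      # samples x cell types
    residuals: pd.Series         # per-sample ||S f - a||

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy()
        if (f < -1e-12).any():
            raise ValueError("negative fractions")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("fraction rows must sum to 1")


def gene_activity_from_beta(
    beta: BetaMatrix, annotation: ProbeAnnotation
) -> pd.DataFrame:
    """Gene activity = 1 - mean beta over the gene's TSS probes, in [0, 1].

    Genes without any TSS probe in the matrix are omitted (logged).
    """
    ann = annotation.indexed()
    common = beta.probe_ids.intersection(ann.index)
    sub = ann.loc[common]
    tss = sub.index[sub["tss_flag"] & (sub["gene_symbol"] != "")]
    if len(tss) == 0:
        raise ValueError("no TSS-flagged probes with gene symbols in matrix")
    gene_of = sub.loc[tss, "gene_symbol"]
    mean_beta = beta.data.loc[tss].groupby(gene_of).mean()
    n_total_genes = sub.loc[sub["gene_symbol"] != "", "gene_symbol"].nunique()
    omitted = n_total_genes - len(mean_beta)
    if omitted:
        logger.info("%d genes had no TSS probes and were omitted", omitted)
    activity = 1.0 - mean_beta
    activity.index.name = "gene"
    return activity


def simplex_lsq_active_set(S: np.ndarray, a: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Exact min ||S f - a|| s.t. f >= 0, sum f = 1 by KKT active-set iteration.

    On the working set of free coordinates the equality-constrained problem
    is solved through its KKT system; coordinates that go negative are
    clamped to zero, and a zero coordinate re-enters when its Lagrange
    multiplier says the objective would improve.  Terminates because the
    objective strictly decreases between distinct working sets.
    """
    S = np.asarray(S, dtype=float)
    a = np.asarray(a, dtype=float)
    k = S.shape[1]
    free = np.ones(k, dtype=bool)
    for _ in range(4 ** k + 16):
        idx = np.flatnonzero(free)
        Sf = S[:, idx]
        # KKT: [2 S'S, 1; 1', 0] [f; lam] = [2 S'a; 1]
        G = 2.0 * Sf.T @ Sf
        kkt = np.zeros((len(idx) + 1, len(idx) + 1))
        kkt[: len(idx), : len(idx)] = G
        kkt[: len(idx), -1] = 1.0
        kkt[-1, : len(idx)] = 1.0
        rhs = np.concatenate([2.0 * Sf.T @ a, [1.0]])
        sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
        f_free, lam = sol[:-1], sol[-1]
        if (f_free < -tol).any():
            drop = idx[np.argmin(f_free)]
            free[drop] = False
            if not free.any():
                raise RuntimeError("active-set solver eliminated all coordinates")
            continue
        f = np.zeros(k)
        f[idx] = np.clip(f_free, 0.0, None)
        # multipliers of clamped coordinates: mu_j = 2 s_j'(S f - a) + lam
        grad = 2.0 * S.T @ (S @ f - a) + lam
        clamped = np.flatnonzero(~free)
        if len(clamped) == 0 or (grad[clamped] >= -1e-9).all():
            return f / f.sum()
        free[clamped[np.argmin(grad[clamped])]] = True
    raise RuntimeError("active-set solver failed to converge")


def _augmented_nnls(S: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, float]:
    k = S.shape[1]
    S_aug = np.vstack([S, _SUM_WEIGHT * np.ones((1, k))])
    a_aug = np.concatenate([a, [_SUM_WEIGHT]])
    f, _ = nnls(S_aug, a_aug)
    total = f.sum()
    if total <= 0:
        raise RuntimeError("NNLS returned an all-zero fraction vector")
    f = f / total
    return f, float(np.linalg.norm(S @ f - a))


def estimate_fractions(
    activity: pd.DataFrame,
    signature: pd.DataFrame,
    method: str = "nnls",
) -> FractionEstimate:
    """Per-sample constrained least-squares fractions on the shared features.

    ``activity`` is features x samples, ``signature`` features x cell types;
    features are intersected by id and must outnumber the cell types.
    ``method`` is "nnls" (augmented sum-to-one NNLS, default) or
    "active-set" (exact KKT solver); both agree to ~1e-6.
    """
    common = activity.index.intersection(signature.index)
    k = signature.shape[1]
    if len(common) < k:
        raise ValueError(
            f"only {len(common)} shared features for {k} cell types; need >= {k}"
        )
    S = signature.loc[common].to_numpy(dtype=float)
    A = activity.loc[common].to_numpy(dtype=float)
    if not np.isfinite(A).all() or (A < 0).any():
        raise ValueError("activity must be finite and nonnegative")
    solver = {
        "nnls": lambda a: _augmented_nnls(S, a),
        "active-set": lambda a: (
            (f := simplex_lsq_active_set(S, a)), float(np.linalg.norm(S @ f - a))
        ),
    }.get(method)
    if solver is None:
        raise ValueError(f"unknown method {method!r}")
    fracs, resids = [], []
    for j in range(A.shape[1]):
        f, r = solver(A[:, j])
        fracs.append(f)
        resids.append(r)
    fractions = pd.DataFrame(
        np.vstack(fracs), index=activity.columns, columns=signature.columns
    )
    residuals = pd.Series(resids, index=activity.columns, name="residual")
    return FractionEstimate(fractions=fractions, residuals=residuals)


def _stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_fractions(
    fractions: FractionEstimate,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per cell type: Shapiro-Wilk gate, then unpaired t-test (both groups
    normal) or Mann-Whitney; reports the test used, statistic, two-sided p,
    and the significance-star category."""
    groups = sheet.groups()
    for g in (group_a, group_b):
        if g not in groups:
            raise ValueError(f"group {g!r} not in sample sheet")
    ids = fractions.fractions.index
    a_ids = [s for s in groups[group_a] if s in ids]
    b_ids = [s for s in groups[group_b] if s in ids]
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError("both groups need >= 3 samples with estimated fractions")
    rows = []
    for cell_type in fractions.fractions.columns:
        x = fractions.fractions.loc[a_ids, cell_type].to_numpy()
        y = fractions.fractions.loc[b_ids, cell_type].to_numpy()
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
            test, stat, p = "degenerate", np.nan, 1.0
        else:
            normal = all(
                np.ptp(v) > 0 and shapiro(v).pvalue > normality_alpha for v in (x, y)
            )
            if normal:
                res = ttest_ind(x, y, equal_var=False)
                test, stat, p = "t-test", float(res.statistic), float(res.pvalue)
            else:
                res = mannwhitneyu(x, y, alternative="two-sided")
                test, stat, p = "mann-whitney", float(res.statistic), float(res.pvalue)
        rows.append({
            "cell_type": cell_type,
            "group_a": group_a, "group_b": group_b,
            "n_a": len(a_ids), "n_b": len(b_ids),
            "test": test, "statistic": stat, "p": p, "stars": _stars(p),
        })
    return pd.DataFrame(rows)
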