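"""Sample QC, probe filtering, M-value transform, and top-variance CpG selection.

A sample is excluded when the fraction of its probes with detection p above
the threshold exceeds the configured cap (default 0.10; the oldest cohort
sample in the motivating study failed at 14%).  The feature space of every
landscape is the k probes with the largest across-sample standard deviation
of beta values (default k = 10,000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix, DetectionPMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "ProbeSubset",
    "sample_qc",
    "beta_to_m",
    "m_to_beta",
    "filter_probes",
    "select_top_sd",
]

DEFAULT_DETP_THRESHOLD = 0.01
DEFAULT_MAX_FAIL_FRACTION = 0.10
SEX_CHROMOSOMES = ("chrX", "chrY", "X", "Y")


@dataclass(frozen=True)
class QCReport:
    """Per-sample detection-p failure fractions and the exclusion decision."""

    fail_fraction: pd.Series          # sample id -> fraction of failing probes
    excluded: tuple[str, ...]
    p_threshold: float
    max_fail_fraction: float

    def to_jsonable(self) -> dict:
        return {
            "p_threshold": self.p_threshold,
            "max_fail_fraction": self.max_fail_fraction,
            "fail_fraction": {k: float(v) for k, v in self.fail_fraction.items()},
            "excluded": list(self.excluded),
        }


@dataclass(frozen=True)
class ProbeSubset:
    """Ordered probe selection with the per-probe selection statistic (SD)."""

    probe_ids: tuple[str, ...]
    sd: pd.Series

    def __len__(self) -> int:
        return len(self.probe_ids)


def sample_qc(
    detp: DetectionPMatrix,
    p_threshold: float = DEFAULT_DETP_THRESHOLD,
    max_fail_fraction: float = DEFAULT_MAX_FAIL_FRACTION,
) -> QCReport:
    """Flag samples whose failing-probe fraction exceeds ``max_fail_fraction``.

    A probe fails in a sample when its detection p-value is strictly greater
    than ``p_threshold``.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0,1)")
    if not 0.0 < max_fail_fraction < 1.0:
        raise ValueError("max_fail_fraction must be in (0,1)")
    if detp.data.size == 0:
        raise ValueError("empty detection-p matrix")
    frac = (detp.data > p_threshold).mean(axis=0)
    excluded = tuple(frac.index[frac > max_fail_fraction])
    if excluded:
        logger.info("QC excluding %d samples: %s", len(excluded), list(excluded))
    return QCReport(
        fail_fraction=frac.astype(float),
        excluded=excluded,
        p_threshold=p_threshold,
        max_fail_fraction=max_fail_fraction,
    )


def beta_to_m(beta: BetaMatrix, epsilon: float = 1e-3) -> pd.DataFrame:
    """M-value (logit2) transform: m = log2(beta / (1 - beta)).

    Betas are clipped to [epsilon, 1 - epsilon] first so the result is finite
    everywhere; away from the clip region the transform is exactly invertible.
    """
    if not 0.0 < epsilon < 0.1:
        raise ValueError("epsilon must be in (0, 0.1)")
    b = np.clip(beta.values, epsilon, 1.0 - epsilon)
    m = np.log2(b / (1.0 - b))
    return pd.DataFrame(m, index=beta.probe_ids, columns=beta.sample_ids)


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse M-value transform: beta = 2^m / (1 + 2^m)."""
    arr = m.to_numpy(dtype=float)
    return pd.DataFrame(1.0 / (1.0 + 2.0 ** (-arr)), index=m.index, columns=m.columns)


def filter_probes(
    beta: BetaMatrix,
    annotation: ProbeAnnotation,
    policy: tuple[str, ...] = ("sex_chromosomes",),
    max_missing_fraction: float = 0.10,
) -> BetaMatrix:
    """Drop probes per policy; recognised filters are ``sex_chromosomes`` and
    ``missingness``.  Filters are set operations, so they commute."""
    unknown = set(policy) - {"sex_chromosomes", "missingness"}
    if unknown:
        raise ValueError(f"unknown probe filters: {sorted(unknown)}")
    ann = annotation.indexed()
    missing_ann = beta.probe_ids.difference(ann.index)
    if len(missing_ann):
        raise ValueError(
            f"annotation missing {len(missing_ann)} probes present in matrix, "
            f"e.g. {list(missing_ann[:3])}"
        )
    keep = pd.Series(True, index=beta.probe_ids)
    if "sex_chromosomes" in policy:
        sex = ann.loc[beta.probe_ids, "chromosome"].isin(SEX_CHROMOSOMES)
        logger.info("probe filter sex_chromosomes: dropping %d probes", int(sex.sum()))
        keep &= ~sex
    if "missingness" in policy:
        frac_na = beta.data.isna().mean(axis=1)
        miss = frac_na > max_missing_fraction
        logger.info("probe filter missingness: dropping %d probes", int(miss.sum()))
        keep &= ~miss
    return BetaMatrix(beta.data.loc[keep])


def select_top_sd(matrix: BetaMatrix | pd.DataFrame, k: int) -> ProbeSubset:
    """The k probes with the largest across-sample standard deviation.

    Ordered by SD descending; ties broken lexicographically by probe id for
    determinism.  Asking for more probes than exist returns all of them with
    a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    data = matrix.data if isinstance(matrix, BetaMatrix) else matrix
    sd = data.std(axis=1, ddof=1)
    if k > len(sd):
        logger.warning("k=%d exceeds %d probes; returning all", k, len(sd))
        k = len(sd)
    order = sd.to_frame("sd").reset_index(names="probe_id")
    order = order.sort_values(["sd", "probe_id"], ascending=[False, True], kind="mergesort")
    chosen = order.head(k)
    return ProbeSubset(
        probe_ids=tuple(chosen["probe_id"]),
        sd=pd.Series(chosen["sd"].to_numpy(), index=chosen["probe_id"].to_numpy()),
    )
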