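"""Synthetic EPIC-like methylation cohorts with planted ground truth.

The generator emulates the features of array beta matrices that the pipeline
exercises: a bimodal marginal beta distribution (most CpGs are either near-
fully methylated or near-fully unmethylated), per-group methylation
signatures that create cluster structure, per-pair planted differential
probes with a known beta-scale effect size, detection-p failures for
designated bad samples, and known cell-type mixtures for the deconvolution
stage.  Every output is reproducible for a fixed seed.

Planting model: each probe has a cohort-wide base mean drawn from a 50/50
mixture of Beta(2,18) (unmethylated mode) and Beta(18,2) (methylated mode).
A group's signature probes, and the second group of a planted pair, have
their group mean shifted by ``delta`` on the beta scale, in the direction
that keeps the mean inside [0.01, 0.99]; configurations where neither
direction fits are rejected.  Per-sample noise is Gaussian on the logit2
(M-value) scale around the group mean, so observed betas stay in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    BetaMatrix,
    DetectionPMatrix,
    ProbeAnnotation,
    SampleSheet,
)

__all__ = [
    "GroupSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_reference_signature",
    "generate_mixtures",
    "study_cohort_config",
    "STUDY_GROUP_SIZES",
]

MEAN_FLOOR, MEAN_CEIL = 0.01, 0.99


@dataclass(frozen=True)
class GroupSpec:
    """One diagnosis group of the synthetic cohort.

    ``signature_probes`` probes (chosen disjointly per group) are shifted by
    ``signature_delta`` in this group only, giving the group its own
    methylation identity.  ``share_signature_with`` copies another group's
    signature instead (fully, or a leading fraction of it), which is how
    "sibling" entities with zero or few mutual differential probes are
    planted.
    """

    label: str
    n_samples: int
    signature_probes: int = 0
    signature_delta: float = 0.0
    share_signature_with: str | None = None
    share_fraction: float = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_probes: int
    groups: Sequence[GroupSpec]
    planted_dmps: Mapping[tuple[str, str], tuple[int, float]] = field(default_factory=dict)
    base_modes: tuple[tuple[float, float], tuple[float, float]] = ((2.0, 18.0), (18.0, 2.0))
    noise_sd: float = 0.5
    bad_samples: Sequence[tuple[str, float]] = ()
    detp_fail_threshold: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        for sid, frac in self.bad_samples:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"bad-sample fail fraction {frac} for {sid} not in [0,1]")
        for (a, b), (n, delta) in self.planted_dmps.items():
            if a not in labels or b not in labels:
                raise ValueError(f"planted pair ({a},{b}) names unknown group")
            if not 0.0 <= delta <= 1.0:
                raise ValueError(f"delta {delta} not in [0,1]")
            if n > self.n_probes:
                raise ValueError("cannot plant more probes than exist")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return sum(g.n_samples for g in self.groups)

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.groups]


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for a synthetic cohort.

    ``dmp_probes_per_pair`` lists, for every unordered group pair, exactly the
    probes whose group means differ (the exhaustive mean-difference scan of
    the planted design).  ``group_means`` holds the noise-free group-level
    beta means (groups x probes) from which that scan is computed.
    """

    dmp_probes_per_pair: dict[tuple[str, str], frozenset]
    cluster_assignment: dict[str, str]
    group_means: pd.DataFrame
    true_fractions: pd.DataFrame | None = None

    def to_jsonable(self) -> dict:
        return {
            "dmp_probes_per_pair": {
                f"{a}|{b}": sorted(probes)
                for (a, b), probes in self.dmp_probes_per_pair.items()
            },
            "cluster_assignment": dict(self.cluster_assignment),
            "true_fractions": (
                None if self.true_fractions is None
                else self.true_fractions.to_dict(orient="index")
            ),
        }


def _sigmoid2(m: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + 2.0 ** (-m))


def _logit2(beta: np.ndarray) -> np.ndarray:
    return np.log2(beta / (1.0 - beta))


def _shift_mean(base: np.ndarray, delta: float) -> np.ndarray:
    """Shift means by +delta where it fits in [MEAN_FLOOR, MEAN_CEIL], else -delta."""
    up_ok = base + delta <= MEAN_CEIL
    down_ok = base - delta >= MEAN_FLOOR
    if not np.all(up_ok | down_ok):
        raise ValueError(f"delta {delta} pushes some probe means outside ({MEAN_FLOOR},{MEAN_CEIL})")
    return np.where(up_ok, base + delta, base - delta)


def generate_cohort(config: SyntheticConfig) -> tuple[
    BetaMatrix, DetectionPMatrix, SampleSheet, ProbeAnnotation, GroundTruth
]:
    """Generate a full synthetic cohort with planted group structure.

    Returns the beta matrix, detection-p matrix, sample sheet, probe
    annotation (with chromosome, position, gene symbol and TSS flag), and the
    ground truth against which downstream stages are scored.
    """
    rng = np.random.default_rng(config.seed)
    n_probes = config.n_probes
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    labels = config.labels

    # bimodal base means, clipped away from 0/1 so logit noise stays sane
    (a0, b0), (a1, b1) = config.base_modes
    mode = rng.random(n_probes) < 0.5
    base = np.where(mode, rng.beta(a0, b0, n_probes), rng.beta(a1, b1, n_probes))
    base = np.clip(base, MEAN_FLOOR, MEAN_CEIL)

    # group-level mean matrix (groups x probes), starting from the shared base
    group_means = {lab: base.copy() for lab in labels}

    # disjoint signature probe pools, assigned group by group
    available = rng.permutation(n_probes)
    cursor = 0
    signature_sets: dict[str, np.ndarray] = {}
    for spec in config.groups:
        if spec.share_signature_with is not None:
            continue
        if spec.signature_probes:
            take = available[cursor : cursor + spec.signature_probes]
            if len(take) < spec.signature_probes:
                raise ValueError("not enough probes for requested signatures")
            cursor += spec.signature_probes
            signature_sets[spec.label] = take
            group_means[spec.label][take] = _shift_mean(base[take], spec.signature_delta)
    for spec in config.groups:
        if spec.share_signature_with is None:
            continue
        donor = spec.share_signature_with
        if donor not in signature_sets:
            raise ValueError(f"{spec.label} shares signature with {donor}, which has none")
        donor_probes = signature_sets[donor]
        k = int(round(spec.share_fraction * len(donor_probes)))
        shared = donor_probes[:k]
        group_means[spec.label][shared] = group_means[donor][shared]
        own = np.array([], dtype=int)
        if spec.signature_probes:
            own = available[cursor : cursor + spec.signature_probes]
            cursor += spec.signature_probes
            group_means[spec.label][own] = _shift_mean(base[own], spec.signature_delta)
        signature_sets[spec.label] = np.concatenate([shared, own])

    # per-pair planted probes: shift the SECOND group of the pair only
    planted_probe_sets: dict[tuple[str, str], np.ndarray] = {}
    for (ga, gb), (n, delta) in config.planted_dmps.items():
        take = available[cursor : cursor + n]
        if len(take) < n:
            raise ValueError("not enough unplanted probes left for planted pair")
        cursor += n
        group_means[gb][take] = _shift_mean(group_means[gb][take], delta)
        planted_probe_sets[(ga, gb)] = take

    # samples
    sample_ids: list[str] = []
    sample_groups: list[str] = []
    columns = []
    for spec in config.groups:
        m_mean = _logit2(np.clip(group_means[spec.label], 1e-6, 1 - 1e-6))
        for i in range(spec.n_samples):
            sid = f"{spec.label}_{i + 1:02d}"
            sample_ids.append(sid)
            sample_groups.append(spec.label)
            noise = rng.normal(0.0, config.noise_sd, n_probes) if config.noise_sd > 0 else 0.0
            columns.append(_sigmoid2(m_mean + noise))
    beta = pd.DataFrame(
        np.column_stack(columns), index=probe_ids, columns=sample_ids
    )

    # detection p-values: clean samples all pass; bad samples fail at exactly
    # round(fail_fraction * n_probes) randomly chosen probes
    detp = pd.DataFrame(
        rng.uniform(0.0, config.detp_fail_threshold / 2, size=(n_probes, len(sample_ids))),
        index=probe_ids,
        columns=sample_ids,
    )
    for sid, frac in config.bad_samples:
        if sid not in detp.columns:
            raise ValueError(f"bad sample {sid!r} not in cohort")
        n_fail = int(round(frac * n_probes))
        fail_idx = rng.choice(n_probes, size=n_fail, replace=False)
        detp.iloc[fail_idx, detp.columns.get_loc(sid)] = rng.uniform(
            config.detp_fail_threshold + 1e-6, 1.0, n_fail
        )

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "group_label": sample_groups,
        "material": "FFPE",
        "grade": "NA",
        "mutation_status": "NA",
    }))

    annotation = _make_annotation(probe_ids, rng)

    means_df = pd.DataFrame(
        np.vstack([group_means[lab] for lab in labels]), index=labels, columns=probe_ids
    )
    truth_pairs: dict[tuple[str, str], frozenset] = {}
    for i, ga in enumerate(labels):
        for gb in labels[i + 1:]:
            diff = np.abs(group_means[ga] - group_means[gb]) > 1e-12
            truth_pairs[(ga, gb)] = frozenset(np.asarray(probe_ids)[diff])
    truth = GroundTruth(
        dmp_probes_per_pair=truth_pairs,
        cluster_assignment=dict(zip(sample_ids, sample_groups)),
        group_means=means_df,
    )
    return BetaMatrix(beta), DetectionPMatrix(detp), sheet, annotation, truth


def _make_annotation(probe_ids: list[str], rng: np.random.Generator) -> ProbeAnnotation:
    """Manifest-like annotation: autosomes plus a small sex-chromosome tail,
    ~60% of probes in TSS regions, 2 TSS probes per gene on average."""
    n = len(probe_ids)
    chroms = [f"chr{c}" for c in list(range(1, 23)) + ["X", "Y"]]
    probs = np.array([0.98 / 22] * 22 + [0.015, 0.005])
    chrom = rng.choice(chroms, size=n, p=probs)
    position = rng.integers(1, 250_000_000, size=n)
    tss_flag = rng.random(n) < 0.6
    gene_symbol = np.array([""] * n, dtype=object)
    tss_idx = np.flatnonzero(tss_flag)
    n_genes = max(1, len(tss_idx) // 2)
    genes = [f"GENE{g:05d}" for g in range(n_genes)]
    gene_symbol[tss_idx] = rng.choice(genes, size=len(tss_idx))
    return ProbeAnnotation(pd.DataFrame({
        "probe_id": probe_ids,
        "chromosome": chrom,
        "position": position,
        "gene_symbol": gene_symbol,
        "tss_flag": tss_flag,
    }))


# ---------------------------------------------------------------------------
# deconvolution test bed


def generate_reference_signature(
    n_cell_types: int, n_markers_per_type: int, seed: int = 0
) -> pd.DataFrame:
    """Block-dominant cell-type signature: each type owns ``n_markers_per_type``
    markers whose reference value is at least 3x that of every other type."""
    if n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    if n_markers_per_type < 1:
        raise ValueError("need at least 1 marker per type")
    rng = np.random.default_rng(seed)
    n_markers = n_cell_types * n_markers_per_type
    background = rng.uniform(0.1, 1.0, size=(n_markers, n_cell_types))
    values = background.copy()
    for t in range(n_cell_types):
        rows = slice(t * n_markers_per_type, (t + 1) * n_markers_per_type)
        off_max = np.delete(background[rows], t, axis=1).max(axis=1)
        values[rows, t] = off_max * rng.uniform(3.0, 6.0, n_markers_per_type)
    return pd.DataFrame(
        values,
        index=[f"M{i:04d}" for i in range(n_markers)],
        columns=[f"type_{t + 1}" for t in range(n_cell_types)],
    )


def generate_mixtures(
    signature: pd.DataFrame,
    fractions: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mix signature columns by known fractions: activity = S @ f.T + noise.

    ``fractions`` is samples x cell types with nonnegative rows summing to 1;
    the result is features x samples.
    """
    f = fractions.to_numpy(dtype=float)
    if (f < 0).any():
        raise ValueError("fractions must be nonnegative")
    if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("fraction rows must sum to 1")
    if list(fractions.columns) != list(signature.columns):
        raise ValueError("fraction columns must match signature cell types")
    rng = np.random.default_rng(seed)
    activity = signature.to_numpy() @ f.T
    if noise_sd > 0:
        activity = activity + rng.normal(0.0, noise_sd, activity.shape)
    activity = np.clip(activity, 0.0, None)
    return pd.DataFrame(activity, index=signature.index, columns=fractions.index)


# ---------------------------------------------------------------------------
# study-scale default cohort

# 23 diagnosis groups with the published cohort sizes (430 samples):
# pancreatic, hepatic, and ovarian entities plus normal tissues.
STUDY_GROUP_SIZES: dict[str, int] = {
    "MCN-P": 14, "MCN-L": 6,
    "PDAC": 26, "ITPN-P": 9, "PanIN": 27, "iIPMN": 20, "gIPMN": 33,
    "ACC": 13, "SPN": 12, "PB": 13, "NEC": 10, "NET": 38, "normal-pancreas": 9,
    "HCC": 19, "iCCA": 45, "iIPNB": 8, "iITPN": 8, "normal-bile-duct": 50,
    "HGSOC": 16, "PMOC": 16, "mBOT": 10, "normal-ovary": 16, "fallopian-tube": 12,
}


def study_cohort_config(
    n_probes: int = 20_000,
    signature_probes: int = 300,
    signature_delta: float = 0.30,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SyntheticConfig:
    """Default synthetic cohort mirroring the 23-entity, 430-sample study.

    Every entity gets its own disjoint methylation signature except:
    the hepatic mucinous cystic neoplasm (MCN-L) shares the pancreatic one's
    (MCN-P) signature completely — the planted "sibling" pair with zero true
    differential probes — and the mucinous borderline ovarian tumor (mBOT)
    shares 60% of it, making it the nearest non-sibling neighbor.
    """
    groups = []
    for label, n in STUDY_GROUP_SIZES.items():
        if label == "MCN-L":
            groups.append(GroupSpec(label, n, share_signature_with="MCN-P",
                                    share_fraction=1.0))
        elif label == "mBOT":
            groups.append(GroupSpec(label, n, signature_probes=signature_probes * 2 // 5,
                                    signature_delta=signature_delta,
                                    share_signature_with="MCN-P", share_fraction=0.6))
        else:
            groups.append(GroupSpec(label, n, signature_probes=signature_probes,
                                    signature_delta=signature_delta))
    # MCN-P must be defined before its dependents; dict order already ensures it
    return SyntheticConfig(
        n_probes=n_probes, groups=groups, noise_sd=noise_sd, seed=seed,
    )
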