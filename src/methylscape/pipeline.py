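"""End-to-end orchestration of the methylation-landscape stages.

A run directory is populated stage by stage (simulate -> qc -> landscape ->
dmp -> network -> pathways -> deconv) with a machine-readable manifest
recording parameters and seeds.  Stages are resumable: an existing stage
output is reused unless ``force`` is set, and identical config + seeds give
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deconvolution, dmp, io, landscape, network, pathways, qc, simulate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "load_config"]

STAGES = ("simulate", "qc", "landscape", "dmp", "network", "pathways", "deconv")


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str
    seed: int = 0
    # synthetic cohort
    n_probes: int = 20_000
    signature_probes: int = 300
    signature_delta: float = 0.30
    noise_sd: float = 0.5
    # qc
    detp_threshold: float = 0.01
    max_fail_fraction: float = 0.10
    top_k: int = 10_000
    drop_sex_chromosomes: bool = True
    # landscape
    perplexity: float = 30.0
    tsne_iterations: int = 1000
    consensus_B: int = 200
    consensus_subsample: float = 0.8
    consensus_k: int | None = None
    reference_groups: tuple[str, ...] = ("MCN-P", "MCN-L")
    # dmp
    p_adj_max: float = 0.01
    abs_lfc_min: float = 0.3
    # pathways / deconvolution
    lesion_group: str = "MCN-P"
    baseline_group: str = "normal-pancreas"
    n_cell_types: int = 4
    n_markers_per_type: int = 25
    mixture_noise_sd: float = 0.02

    def validate(self) -> None:
        if not 0 < self.detp_threshold < 1:
            raise ValueError("detp_threshold must be in (0,1)")
        if not 0 < self.max_fail_fraction < 1:
            raise ValueError("max_fail_fraction must be in (0,1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0.5 < self.consensus_subsample < 1:
            raise ValueError("consensus_subsample must be in (0.5, 1)")

    def param_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "reference_groups" in raw:
        raw["reference_groups"] = tuple(raw["reference_groups"])
    return PipelineConfig(**raw)


def _stage_done(out: Path, stage: str) -> bool:
    return (out / stage / ".done").exists()


def _mark_done(out: Path, stage: str) -> None:
    (out / stage / ".done").write_text("ok\n")


def run_all(config: PipelineConfig, force: bool = False,
            stages: tuple[str, ...] = STAGES) -> Path:
    """Run the configured stages into the run directory; returns its path.

    Any stage failure propagates with the stage name prefixed.  Completed
    stages (``.done`` sentinel present) are skipped unless ``force``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "parameters": dataclasses.asdict(config),
        "stages_run": [],
    }
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if _stage_done(out, stage) and not force:
            logger.info("stage %s already complete; skipping", stage)
            continue
        (out / stage).mkdir(exist_ok=True)
        try:
            _RUNNERS[stage](config, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        _mark_done(out, stage)
        manifest["stages_run"].append(stage)
    io.write_json(manifest, out / "manifest.json")
    return out


# ---------------------------------------------------------------------------
# stage runners — each reads its inputs from the run directory and writes its
# outputs back, so stages can be re-run independently


def _require(out: Path, stage: str) -> Path:
    if not _stage_done(out, stage):
        raise FileNotFoundError(
            f"missing dependency: stage {stage!r} has not been run in {out}"
        )
    return out / stage


def _run_simulate(cfg: PipelineConfig, out: Path) -> None:
    sim_cfg = simulate.study_cohort_config(
        n_probes=cfg.n_probes,
        signature_probes=cfg.signature_probes,
        signature_delta=cfg.signature_delta,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
    )
    beta, detp, sheet, ann, truth = simulate.generate_cohort(sim_cfg)
    d = out / "simulate"
    io.write_matrix(beta, d / "beta.tsv")
    io.write_matrix(detp, d / "detection_p.tsv")
    io.write_sample_sheet(sheet, d / "sample_sheet.csv")
    io.write_probe_annotation(ann, d / "annotation.csv")
    io.write_json(truth.to_jsonable(), d / "ground_truth.json")


def _load_inputs(out: Path):
    d = _require(out, "simulate")
    beta = io.read_beta_matrix(d / "beta.tsv")
    detp = io.read_detection_p(d / "detection_p.tsv")
    sheet = io.read_sample_sheet(d / "sample_sheet.csv")
    ann = io.read_probe_annotation(d / "annotation.csv")
    return beta, detp, sheet, ann


def _run_qc(cfg: PipelineConfig, out: Path) -> None:
    beta, detp, sheet, ann = _load_inputs(out)
    report = qc.sample_qc(detp, cfg.detp_threshold, cfg.max_fail_fraction)
    keep = [s for s in beta.sample_ids if s not in report.excluded]
    beta_kept = beta.select_samples(keep)
    policy = ("sex_chromosomes",) if cfg.drop_sex_chromosomes else ()
    beta_filt = qc.filter_probes(beta_kept, ann, policy=policy)
    subset = qc.select_top_sd(beta_filt, cfg.top_k)
    d = out / "qc"
    io.write_json(report.to_jsonable(), d / "qc_report.json")
    io.write_matrix(beta_filt.select_probes(subset.probe_ids), d / "beta_topk.tsv")
    subset.sd.rename("sd").to_csv(d / "top_sd_probes.csv", index_label="probe_id")


def _qc_matrix(out: Path) -> io.BetaMatrix:
    return io.read_beta_matrix(_require(out, "qc") / "beta_topk.tsv")


def _run_landscape(cfg: PipelineConfig, out: Path) -> None:
    beta = _qc_matrix(out)
    _, _, sheet, _ = _load_inputs(out)
    sheet_kept = io.SampleSheet(
        sheet.data[sheet.data["sample_id"].isin(beta.sample_ids)].reset_index(drop=True)
    )
    groups = sheet_kept.groups()
    k = cfg.consensus_k or len(groups)
    emb = landscape.tsne_embed(beta, perplexity=cfg.perplexity, seed=cfg.seed,
                               n_iter=cfg.tsne_iterations)
    dendro = landscape.hierarchical_cluster(beta)
    cons = landscape.consensus_cluster(
        beta, B=cfg.consensus_B, subsample_fraction=cfg.consensus_subsample,
        k=k, seed=cfg.seed,
    )
    refs = [g for g in cfg.reference_groups if g in groups]
    d = out / "landscape"
    coords = emb.coords.copy()
    coords["group"] = [sheet_kept.group_of()[s] for s in coords.index]
    coords.to_csv(d / "tsne.csv", index_label="sample_id")
    (d / "dendrogram.nwk").write_text(dendro.to_newick())
    cons.values.to_csv(d / "consensus.tsv", sep="\t", index_label="sample_id")
    if refs:
        table = landscape.consensus_degree_test(cons, sheet_kept, refs)
        table.to_csv(d / "consensus_degree_test.csv", index=False)


def _run_dmp(cfg: PipelineConfig, out: Path) -> None:
    beta, detp, sheet, ann = _load_inputs(out)
    report = io.read_json(_require(out, "qc") / "qc_report.json")
    keep = [s for s in beta.sample_ids if s not in set(report["excluded"])]
    beta_kept = beta.select_samples(keep)
    sheet_kept = io.SampleSheet(
        sheet.data[sheet.data["sample_id"].isin(keep)].reset_index(drop=True)
    )
    counts = dmp.pairwise_dmp_counts(
        beta_kept, sheet_kept, p_adj_max=cfg.p_adj_max, abs_lfc_min=cfg.abs_lfc_min
    )
    d = out / "dmp"
    counts.counts.to_csv(d / "pairwise_counts.tsv", sep="\t", index_label="group")
    for (ga, gb), dmps in counts.dmp_sets.items():
        if len(dmps) == 0:
            continue
        tab = pd.DataFrame({"probe_id": sorted(dmps.probe_ids)})
        tab["delta"] = dmps.deltas.loc[tab["probe_id"]].to_numpy()
        tab.to_csv(d / f"dmps_{ga}_vs_{gb}.tsv", sep="\t", index=False)


def _run_network(cfg: PipelineConfig, out: Path) -> None:
    counts_df = pd.read_csv(_require(out, "dmp") / "pairwise_counts.tsv",
                            sep="\t", index_col=0)
    counts = dmp.PairwiseDMPCounts(counts=counts_df, dmp_sets={})
    _, _, sheet, _ = _load_inputs(out)
    sizes = {g: len(s) for g, s in sheet.groups().items()}
    graph = network.build_network(counts, sample_counts=sizes)
    graph = network.annotate_closest(graph, counts)
    d = out / "network"
    io.write_graphml(graph.graph, d / "relatedness.graphml")
    network.edge_list(graph).to_csv(d / "edges.tsv", sep="\t", index=False)


def _run_pathways(cfg: PipelineConfig, out: Path) -> None:
    beta, detp, sheet, ann = _load_inputs(out)
    groups = sheet.groups()
    for g in (cfg.baseline_group, cfg.lesion_group):
        if g not in groups:
            raise ValueError(f"group {g!r} not in cohort")
    stats = dmp.moderated_t(
        beta, groups[cfg.baseline_group], groups[cfg.lesion_group],
        cfg.baseline_group, cfg.lesion_group,
    )
    dmps = dmp.call_dmps(stats, cfg.p_adj_max, cfg.abs_lfc_min)
    lists = pathways.dmps_to_gene_lists(dmps, ann, lesion_is_group_b=True)
    d = out / "pathways"
    rows = [{"gene": g, "direction": "activated"} for g in sorted(lists.activated)]
    rows += [{"gene": g, "direction": "inhibited"} for g in sorted(lists.inhibited)]
    pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(
        d / "gene_lists.csv", index=False
    )
    # synthetic gene-set collection built from the universe, for the worked run
    rng = np.random.default_rng(cfg.seed)
    universe = sorted(lists.universe)
    sets = {}
    for i in range(10):
        size = int(rng.integers(10, 40))
        sets[f"SET_{i:02d}"] = frozenset(rng.choice(universe, size=size, replace=False))
    collection = io.GeneSetCollection(sets=sets)
    for direction, query in (("activated", lists.activated), ("inhibited", lists.inhibited)):
        table = pathways.hypergeometric_enrich(query, lists.universe, collection,
                                               direction=direction)
        table.to_csv(d / f"enrichment_{direction}.csv", index=False)


def _run_deconv(cfg: PipelineConfig, out: Path) -> None:
    beta, detp, sheet, ann = _load_inputs(out)
    signature = simulate.generate_reference_signature(
        cfg.n_cell_types, cfg.n_markers_per_type, seed=cfg.seed
    )
    activity = deconvolution.gene_activity_from_beta(beta, ann)
    # align the synthetic signature onto observed genes so the worked run is
    # self-contained: signature markers are relabelled with cohort gene names
    genes = list(activity.index[: len(signature)])
    signature = signature.set_axis(genes, axis=0)
    est = deconvolution.estimate_fractions(activity, signature)
    d = out / "deconv"
    est.fractions.to_csv(d / "fractions.csv", index_label="sample_id")
    groups = sheet.groups()
    pairs = [(cfg.lesion_group, g) for g in ("gIPMN", "iIPMN") if g in groups]
    tables = []
    for ga, gb in pairs:
        tables.append(deconvolution.compare_fractions(est, sheet, ga, gb))
    if tables:
        pd.concat(tables, ignore_index=True).to_csv(d / "fraction_tests.csv", index=False)


_RUNNERS = {
    "simulate": _run_simulate,
    "qc": _run_qc,
    "landscape": _run_landscape,
    "dmp": _run_dmp,
    "network": _run_network,
    "pathways": _run_pathways,
    "deconv": _run_deconv,
}
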