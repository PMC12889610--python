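"""End-to-end orchestration of the single-cell proteomics pipeline.

Stage order: simulate (optional) → QC/input estimation → median
normalization → batch correction → imputation → reference label transfer →
clustering + enrichment annotation (first pass) → permeabilized-cluster
filtering → second clustering/annotation pass on the retained cells →
one-vs-rest differential abundance. Every stage draws its own sub-seed
deterministically from the global seed and the stage name, so a run is a
pure function of its configuration and stages stay reproducible when run
standalone on the previous stage's files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import annotation, diff_abundance, label_transfer, normalize, qc, quant_io
from .synthetic import (
    AcquisitionConfig,
    GroundTruthConfig,
    generate_reference,
    generate_truth,
    simulate_acquisition,
)

logger = logging.getLogger("scplex")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "stage_seed", "annotate_cells"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic sub-seed per stage (stable across platforms, < 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (synthetic or file-based inputs)."""

    seed: int = 17
    out_dir: str | None = None
    # synthetic generation (used when no input files are given)
    truth: dict[str, Any] = field(default_factory=dict)
    acquisition: dict[str, Any] = field(default_factory=dict)
    reference: dict[str, Any] = field(default_factory=dict)
    # file-based inputs
    quant_path: str | None = None
    meta_path: str | None = None
    design_path: str | None = None
    # stage parameters
    n_hvp: int = 600
    n_pcs: int = 30
    k_neighbors: int = 20
    snn_prune: float = 1 / 15
    resolution: float = 1.0
    transfer_k: int = 20
    n_hvg: int = 2000
    enrichment_alpha: float = 0.05
    min_obs_per_group: int = 10
    imputation_floor: float = 0.3
    max_input_ratio: float = 0.67
    permeabilization_p: float = 0.01

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls(**payload)


@dataclass
class RunReport:
    summary: dict[str, Any]
    tables: dict[str, pd.DataFrame]

    def to_json(self) -> str:
        return json.dumps(self.summary, indent=2, sort_keys=True)


def _log_stage(name: str, t0: float, **info: Any) -> None:
    desc = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, desc)


def annotate_cells(
    protein_log2: quant_io.QuantMatrix,
    scores: label_transfer.PredictionScores,
    n_hvp: int,
    n_pcs: int,
    k_neighbors: int,
    snn_prune: float,
    resolution: float,
    alpha: float,
    seed: int,
) -> tuple[annotation.ClusterAssignment, annotation.EnrichmentTable]:
    """One clustering + enrichment-annotation pass on a complete matrix."""
    hvp = label_transfer.select_hvf(protein_log2, min(n_hvp, protein_log2.values.shape[0]))
    emb = annotation.pca_embed(protein_log2, hvp, n_pcs=n_pcs, seed=seed)
    graph = annotation.snn_graph(emb, k_neighbors=k_neighbors, prune=snn_prune)
    clusters = annotation.louvain_cluster(graph, resolution=resolution, seed=seed)
    assign = annotation.ClusterAssignment(
        clusters=clusters, graph=graph, embedding=emb, resolution=resolution, seed=seed
    )
    sub_scores = label_transfer.PredictionScores(
        scores=scores.scores.loc[clusters.index], cutoff=scores.cutoff
    )
    enrich = annotation.cluster_enrichment(clusters, sub_scores, alpha=alpha)
    return assign, enrich


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline and return a machine-readable report."""
    tables: dict[str, pd.DataFrame] = {}
    summary: dict[str, Any] = {"seed": config.seed}

    # ------------------------------------------------------------------ data
    t0 = time.perf_counter()
    truth = None
    if config.quant_path is None:
        truth_cfg = GroundTruthConfig(
            **{"seed": stage_seed(config.seed, "truth"), **config.truth}
        )
        truth = generate_truth(truth_cfg)
        acq_cfg = AcquisitionConfig(
            **{
                "mode": "rtls",
                "seed": stage_seed(config.seed, "acquisition"),
                **config.acquisition,
            }
        )
        result = simulate_acquisition(truth, acq_cfg)
        qm, meta, designs = result.quant, result.sample_meta, truth.designs
        id_sets = result.id_sets
        reference = generate_reference(
            truth,
            seed=stage_seed(config.seed, "reference"),
            **config.reference,
        )
    else:
        if config.meta_path is None or config.design_path is None:
            raise ValueError("file-based runs need quant, meta and design paths")
        qm = quant_io.read_quant_table(config.quant_path, level="peptide")
        meta = quant_io.read_sample_meta(config.meta_path)
        designs = quant_io.read_plex_designs(config.design_path)
        id_sets = [set(qm.values.index[qm.values[c].notna()]) for c in qm.sample_ids]
        reference = None
    counts = quant_io.validate_design(designs, meta, qm, require_bridge=True)
    if counts["single_cell"] == 0:
        raise ValueError("design contains zero single-cell channels")
    summary["role_counts"] = counts
    _log_stage("data", t0, features=qm.values.shape[0], samples=qm.values.shape[1])

    # -------------------------------------------------------------------- qc
    t0 = time.perf_counter()
    chans = qc.channel_sums(qm, meta)
    folds = qc.fold_differences(chans)
    input_pg = qc.estimate_input(chans, designs)
    cell_ids = list(meta.index[meta["role"] == "single_cell"])
    cell_ids = [c for c in cell_ids if c in qm.sample_ids]
    comp = qc.completeness(qm, cell_ids)
    curve = qc.sensitivity_curve(id_sets, seed=stage_seed(config.seed, "qc"))
    tables["channel_summary"] = chans.table
    summary["fold_differences"] = folds
    summary["median_input_pg"] = float(np.median(input_pg.loc[[c for c in input_pg.index if c in cell_ids]]))
    summary["completeness_cells"] = comp
    summary["total_sensitivity"] = curve["total_sensitivity"]
    summary["mean_local_sensitivity"] = curve["mean_local_sensitivity"]
    _log_stage("qc", t0, completeness=round(comp, 3))

    # ------------------------------------------------------- normalize stack
    t0 = time.perf_counter()
    prot = quant_io.rollup_to_protein(qm) if qm.level == "peptide" else qm
    n_prot_per_cell = prot.mask.sum(axis=0)
    cells_lin = prot.subset_samples(cell_ids)
    log2 = cells_lin.to_log2()
    normed = normalize.median_normalize(log2)
    batches = meta.loc[cell_ids, "batch"]
    corrected, batch_model = normalize.combat_adjust(normed, batches)
    complete, imputed_mask = normalize.impute(
        corrected, min_observation_rate=config.imputation_floor,
        seed=stage_seed(config.seed, "impute"),
    )
    summary["n_proteins_quantified"] = int(complete.values.shape[0])
    summary["n_batches_corrected"] = len(batch_model.batches) - len(batch_model.skipped_batches)
    _log_stage("normalize", t0, proteins=complete.values.shape[0], cells=len(cell_ids))

    # ------------------------------------------------------------------- map
    t0 = time.perf_counter()
    if reference is None:
        raise ValueError("label transfer requires a reference (synthetic runs provide one)")
    hvp = label_transfer.select_hvf(complete, min(config.n_hvp, complete.values.shape[0]))
    ref_qm = quant_io.QuantMatrix(values=reference.values, level="protein", scale="log2")
    hvg = label_transfer.select_hvf(ref_qm, min(config.n_hvg, reference.values.shape[0]))
    shared, n_shared = label_transfer.feature_overlap(hvp, hvg)
    if n_shared == 0:
        raise ValueError("no overlap between highly variable proteins and reference genes")
    scores = label_transfer.transfer_labels(
        complete,
        reference,
        shared_features=shared,
        k=config.transfer_k,
        n_pcs=config.n_pcs,
        seed=stage_seed(config.seed, "map"),
    )
    tables["prediction_scores"] = scores.table()
    summary["n_shared_features"] = n_shared
    summary["prediction_cutoff"] = scores.cutoff
    summary["n_high_confidence"] = int(scores.high_confidence.sum())
    _log_stage("map", t0, shared=n_shared, cutoff=round(scores.cutoff, 3))

    # -------------------------------------------------- annotate pass 1 + QC
    t0 = time.perf_counter()
    assign1, enrich1 = annotate_cells(
        complete, scores, config.n_hvp, config.n_pcs, config.k_neighbors,
        config.snn_prune, config.resolution, config.enrichment_alpha,
        seed=stage_seed(config.seed, "annotate1"),
    )
    report = annotation.flag_permeabilized(
        assign1.clusters,
        enrich1.cell_labels,
        input_pg,
        n_prot_per_cell,
        scores=scores,
        max_input_ratio=config.max_input_ratio,
        p_threshold=config.permeabilization_p,
    )
    tables["enrichment_pass1"] = enrich1.table
    tables["permeabilization_report"] = report.pairs
    retained = [c for c in assign1.clusters.index if c not in set(report.flagged_cells)]
    summary["n_cells_flagged"] = int(len(report.flagged_cells))
    summary["n_cells_retained"] = len(retained)
    _log_stage("annotate1", t0, clusters=len(assign1.cluster_ids),
               flagged=len(report.flagged_cells))

    # -------------------------------------------------------- annotate pass 2
    t0 = time.perf_counter()
    complete2 = complete.subset_samples(retained)
    assign2, enrich2 = annotate_cells(
        complete2, scores, config.n_hvp, config.n_pcs, config.k_neighbors,
        config.snn_prune, config.resolution, config.enrichment_alpha,
        seed=stage_seed(config.seed, "annotate2"),
    )
    labels = enrich2.cell_labels
    tables["clusters"] = assign2.clusters.to_frame()
    tables["enrichment"] = enrich2.table
    tables["labels"] = labels.to_frame()
    label_counts = labels.value_counts().to_dict()
    summary["labels_per_type"] = {str(k): int(v) for k, v in label_counts.items()}
    summary["n_clusters"] = len(assign2.cluster_ids)
    _log_stage("annotate2", t0, clusters=len(assign2.cluster_ids))

    # -------------------------------------------------------------------- de
    t0 = time.perf_counter()
    de_input = corrected.subset_samples(retained)
    de = diff_abundance.differential_abundance(
        de_input.values, labels, min_obs_per_group=config.min_obs_per_group
    )
    tables["de_results"] = de
    sig = de[(de["p_bonf"] < 0.05) & (de["log2fc"] > 0)]
    summary["n_significant_markers"] = int(len(sig))
    _log_stage("de", t0, tested=int((~de["skipped"]).sum()))

    # ---------------------------------------------------------- truth checks
    if truth is not None:
        truth_types = truth.cells["cell_type"]
        ref_types = set(reference.labels.unique())
        eval_cells = [c for c in retained if truth_types.loc[c] in ref_types]
        acc = float((labels.loc[eval_cells] == truth_types.loc[eval_cells]).mean())
        perm_cells = set(truth.cells.index[truth.cells["permeabilized"]])
        flagged = set(report.flagged_cells)
        recall = len(perm_cells & flagged) / len(perm_cells) if perm_cells else float("nan")
        summary["annotation_accuracy"] = acc
        summary["permeabilized_flag_recall"] = recall
        summary["true_median_input_pg"] = float(truth.cells["input_pg"].median())
        tables["truth_cells"] = truth.cells

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t")
        (out / "run_report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        quant_io.write_quant_table(complete, out / "normalized_imputed.tsv")

    return RunReport(summary=summary, tables=tables)


def config_to_dict(config: RunConfig) -> dict[str, Any]:
    return dataclasses.asdict(config)
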