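"""End-to-end pipeline orchestration: preprocess -> score -> diff -> cluster.

Holds the run configuration, the single-shot pipeline runner with its JSON
run manifest, and the tau-sweep robustness report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import core, differential, io_formats, pathway_space, preprocess
from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything that affects a pipeline run, serializable to the manifest."""

    matrix_path: str
    gmt_path: str
    groups_path: str | None = None
    out_dir: str = "."
    unit: str = io_formats.COUNTS
    tau: float = 5.0
    fdr_threshold: float = 0.01
    test: str = differential.STUDENT
    weight_denominator: str = core.DENOM_NP_SQUARED
    min_genes: int = 1000
    min_cell_fraction: float = 0.10
    delog_base: float = 2.0
    delog_pseudocount: float = 1.0
    delog_target_unit: str = io_formats.TPM
    cluster: bool = False
    n_neighbors: int = 20
    resolution: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.tau <= 100:
            raise ParameterError(f"tau must be in (0, 100], got {self.tau}")
        if not 0 < self.fdr_threshold < 1:
            raise ParameterError("fdr_threshold must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    scores: core.PathwayScoreMatrix
    calls: list | None
    clusters: pathway_space.ClusterAssignment | None
    manifest: dict
    artifacts: dict = field(default_factory=dict)  # name -> path


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the fixed stage order and write all artifacts plus a manifest.

    Stages: read -> (de-log) -> cell filter -> gene filter -> (CPM) ->
    score -> differential calls (when groups are given) -> clustering
    (when requested). Writes scores.tsv, calls.tsv, clusters.tsv and
    manifest.json under ``config.out_dir``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {"config": config.to_dict(), "stages": {}}

    matrix = io_formats.read_matrix(config.matrix_path, unit_tag=config.unit)
    sets = io_formats.read_gmt(config.gmt_path)
    manifest["stages"]["input"] = {"n_genes": matrix.n_genes,
                                   "n_cells": matrix.n_cells,
                                   "n_gene_sets": len(sets)}

    matrix, reports = preprocess.preprocess_pipeline(
        matrix, min_genes=config.min_genes,
        min_cell_fraction=config.min_cell_fraction,
        delog_base=config.delog_base,
        delog_pseudocount=config.delog_pseudocount,
        delog_target_unit=config.delog_target_unit,
    )
    manifest["stages"]["preprocess"] = [r.to_dict() for r in reports]

    scores = core.score_collection(matrix, sets, tau=config.tau,
                                   weight_denominator=config.weight_denominator)
    manifest["stages"]["score"] = {
        "n_pathways": len(scores.pathways),
        "skipped_sets": scores.skipped,
        "per_set": {name: {"n_set": inf.n_set, "coverage": inf.coverage,
                           "genes_missing": len(inf.genes_missing)}
                    for name, inf in scores.info.items()},
    }
    artifacts = {}
    scores_path = os.path.join(config.out_dir, "scores.tsv")
    io_formats.write_scores(scores, scores_path)
    artifacts["scores"] = scores_path

    calls = None
    if config.groups_path:
        groups = io_formats.read_groups(config.groups_path)
        groups.validate_against(scores.frame.columns)
        calls = differential.pairwise_analysis(
            scores, groups, fdr_threshold=config.fdr_threshold, test=config.test)
        calls_path = os.path.join(config.out_dir, "calls.tsv")
        differential.calls_to_frame(calls).to_csv(calls_path, sep="\t", index=False,
                                                  float_format="%.17g")
        artifacts["calls"] = calls_path
        manifest["stages"]["differential"] = {
            "n_calls": len(calls),
            "n_significant": sum(c.direction != differential.NS for c in calls),
        }

    clusters = None
    if config.cluster:
        clusters = pathway_space.cluster_cells(
            scores, n_neighbors=config.n_neighbors,
            resolution=config.resolution, seed=config.seed)
        clusters_path = os.path.join(config.out_dir, "clusters.tsv")
        clusters.labels.rename("cluster").to_csv(clusters_path, sep="\t",
                                                 index_label="cell_id")
        artifacts["clusters"] = clusters_path
        manifest["stages"]["cluster"] = {"n_clusters": clusters.n_clusters}

    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    artifacts["manifest"] = manifest_path
    return RunResult(scores=scores, calls=calls, clusters=clusters,
                     manifest=manifest, artifacts=artifacts)


def tau_sweep(config: RunConfig, taus) -> pd.DataFrame:
    """Score + differential calls per tau; per-pathway call-agreement report.

    Returns a DataFrame indexed by pathway with one column of calls per tau
    (each call a tuple of (group, direction) pairs, "ns" entries included as
    such) and a boolean ``agree`` column marking pathways whose calls are
    identical across every tau.
    """
    taus = list(taus)
    if len(taus) < 2:
        raise ParameterError("tau_sweep needs >= 2 tau values")
    if not config.groups_path:
        raise ParameterError("tau_sweep requires a groups table")

    matrix = io_formats.read_matrix(config.matrix_path, unit_tag=config.unit)
    sets = io_formats.read_gmt(config.gmt_path)
    matrix, _ = preprocess.preprocess_pipeline(
        matrix, min_genes=config.min_genes,
        min_cell_fraction=config.min_cell_fraction,
        delog_base=config.delog_base,
        delog_pseudocount=config.delog_pseudocount,
        delog_target_unit=config.delog_target_unit,
    )
    groups = io_formats.read_groups(config.groups_path)

    per_tau = {}
    for tau in taus:
        scores = core.score_collection(matrix, sets, tau=tau,
                                       weight_denominator=config.weight_denominator)
        calls = differential.pairwise_analysis(
            scores, groups, fdr_threshold=config.fdr_threshold, test=config.test)
        signature = {}
        for c in calls:
            signature.setdefault(c.pathway, []).append((c.focal_group, c.direction))
        per_tau[tau] = {pw: tuple(sorted(sig)) for pw, sig in signature.items()}

    pathways = sorted(per_tau[taus[0]])
    report = pd.DataFrame(index=pathways)
    for tau in taus:
        report[f"tau_{tau:g}"] = [per_tau[tau].get(pw) for pw in pathways]
    first = report[f"tau_{taus[0]:g}"]
    report["agree"] = report[[f"tau_{t:g}" for t in taus]].eq(first, axis=0).all(axis=1)
    return report
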