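"""End-to-end orchestration: enrich -> join -> standardize -> cluster ->
rank -> dendrogram -> fork screen, as one reproducible run.

Every stage is a pure function of (config, seed, inputs); artifacts are
written as delimited text plus a JSON run report, so any stage can be re-run
from the saved output of the one before it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import cluster_rank, dendro, enrichment, forks, matrix_io
from .matrix_io import FeatureMatrix, GENE, METABOLITE

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One run's settings; defaults are the workflow's canonical ones
    (z > 5 enrichment, k = 3, top-29 panels, alpha = 0.05)."""

    compendium_path: str = "compendium.csv"
    library_tissue_path: str = "library_tissue.csv"
    matrix_path: str = "cohort.csv"
    condition_path: str = "sample_condition.csv"
    kind_path: str | None = None
    tissue: str = "liver"
    z_threshold: float = 5.0
    k: int = 3
    n_restarts: int = 50
    n_trees: int = 10_000
    top_n: int = 29
    hclust_metric: str = dendro.DEFAULT_METRIC
    hclust_linkage: str = dendro.DEFAULT_LINKAGE
    fork_roles: dict | None = None  # {"A": [...], "B": [...], "C": [...]}
    max_fork_candidates: int = 10  # cap on default (prioritized-metabolite) role size
    alpha: float = 0.05
    adjust: str = "benjamini-hochberg"
    sample_mode: str = "intersection"  # or "union"
    seed: int = 0
    out_dir: str = "forkscan_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunReport:
    """Bookkeeping for one pipeline run; counts mirror the emitted files."""

    stages: list[str] = field(default_factory=list)
    seed: int = 0
    n_compendium_genes: int = 0
    n_enriched_genes: int = 0
    n_joint_features: int = 0
    n_joint_samples: int = 0
    dropped_features: dict[str, list[str]] = field(default_factory=dict)
    cluster_sizes: dict[int, int] = field(default_factory=dict)
    out_of_bag_accuracy: dict[int, float] = field(default_factory=dict)
    top_panel: dict[int, list[str]] = field(default_factory=dict)
    n_triplets: int = 0
    n_significant_forks: int = 0

    def to_json(self, path) -> None:
        d = asdict(self)
        for key in ("cluster_sizes", "out_of_bag_accuracy", "top_panel"):
            d[key] = {str(k): v for k, v in d[key].items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def reconcile_samples(
    gene_m: FeatureMatrix, met_m: FeatureMatrix, mode: str = "intersection"
) -> FeatureMatrix:
    """Join gene and metabolite sub-matrices on their samples.

    ``intersection`` (default) keeps only samples present in both layers,
    giving complete joint feature vectors; ``union`` keeps every sample and
    carries missing gene values for samples with no transcriptome library.
    """
    gs, ms = list(gene_m.sample_ids), list(met_m.sample_ids)
    if mode == "intersection":
        shared = [s for s in gs if s in set(ms)]
        if not shared:
            raise ValueError("no shared samples between gene and metabolite matrices")
        g, m = gene_m.subset_samples(shared), met_m.subset_samples(shared)
    elif mode == "union":
        allsamp = gs + [s for s in ms if s not in set(gs)]
        gvals = gene_m.values.reindex(columns=allsamp)
        mvals = met_m.values.reindex(columns=allsamp)
        cond = pd.concat([gene_m.condition, met_m.condition])
        cond = cond[~cond.index.duplicated()].loc[allsamp]
        values = pd.concat([gvals, mvals])
        kind = pd.concat([gene_m.feature_kind, met_m.feature_kind])
        return FeatureMatrix(values, kind, cond)
    else:
        raise ValueError(f"mode must be intersection or union, got {mode!r}")
    values = pd.concat([g.values, m.values])
    kind = pd.concat([g.feature_kind, m.feature_kind])
    return FeatureMatrix(values, kind, g.condition)


def _stage(report: RunReport, name: str):
    report.stages.append(name)
    logger.info("pipeline stage: %s", name)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed)
    stage = "read-inputs"
    try:
        comp = enrichment.read_compendium(cfg.compendium_path, cfg.library_tissue_path)
        cohort = matrix_io.read_feature_matrix(cfg.matrix_path, cfg.condition_path, cfg.kind_path)
        _stage(report, stage)
        report.n_compendium_genes = len(comp.gene_ids)

        stage = "enrichment"
        scores = enrichment.enrichment_z(comp, cfg.tissue, threshold=cfg.z_threshold)
        enriched = enrichment.filter_enriched(scores, threshold=cfg.z_threshold)
        enrichment.write_scores(scores, out / "enrichment_scores.csv")
        enrichment.write_enriched_list(enriched, out / "enriched_genes.txt")
        report.n_enriched_genes = len(enriched)
        _stage(report, stage)

        stage = "join"
        gene_ids = [g for g in cohort.kind_ids(GENE) if g in set(enriched)]
        met_ids = cohort.kind_ids(METABOLITE)
        gene_m = cohort.subset_features(gene_ids)
        met_m = cohort.subset_features(met_ids)
        joint = reconcile_samples(gene_m, met_m, mode=cfg.sample_mode)
        _stage(report, stage)

        stage = "preprocess"
        before = set(joint.feature_ids)
        joint = matrix_io.impute_min(joint)
        report.dropped_features["all_missing"] = sorted(before - set(joint.feature_ids))
        joint = matrix_io.log_transform(joint)
        before = set(joint.feature_ids)
        std = matrix_io.zscore_standardize(joint)
        report.dropped_features["constant"] = sorted(before - set(std.feature_ids))
        report.n_joint_features, report.n_joint_samples = std.shape
        matrix_io.write_feature_matrix(std, out / "standardized_matrix.csv")
        _stage(report, stage)

        stage = "kmeans"
        model = cluster_rank.kmeans_partition(
            std, k=cfg.k, seed=cfg.seed, n_restarts=cfg.n_restarts
        )
        cluster_rank.write_assignment(model, out / "cluster_assignment.csv")
        coords, evr = cluster_rank.pca_project(std, n_components=min(2, min(std.shape)))
        coords.to_csv(out / "pc_coordinates.csv", index_label="feature_id")
        report.cluster_sizes = model.sizes()
        _stage(report, stage)

        stage = "rank"
        prioritized: dict[int, list[str]] = {}
        for ci in range(1, cfg.k + 1):
            panel = cluster_rank.rf_rank(
                std, model, ci, n_trees=cfg.n_trees, seed=cfg.seed + ci
            )
            cluster_rank.write_panel(panel, out / f"importance_cluster{ci}.csv")
            report.out_of_bag_accuracy[ci] = panel.out_of_bag_accuracy
            prioritized[ci] = cluster_rank.top_n(panel, cfg.top_n)
            report.top_panel[ci] = prioritized[ci]
        _stage(report, stage)

        stage = "dendro"
        for ci, ids in prioritized.items():
            if len(ids) < 2:
                continue
            tree = dendro.hclust_features(
                std.subset_features(ids), metric=cfg.hclust_metric, linkage=cfg.hclust_linkage
            )
            (out / f"dendrogram_cluster{ci}.nwk").write_text(dendro.to_newick(tree) + "\n")
            dendro.write_merge_table(tree, out / f"merge_table_cluster{ci}.csv")
        _stage(report, stage)

        stage = "forks"
        # forks use metabolites only, on the full metabolome sample set,
        # post-imputation raw abundances
        met_full = matrix_io.impute_min(met_m)
        if cfg.fork_roles:
            roles = {r: list(cfg.fork_roles[r]) for r in ("A", "B", "C")}
        else:
            # best panel rank across clusters, capped to keep the screen tractable
            best_rank: dict[str, int] = {}
            for ids in prioritized.values():
                for rank, f in enumerate(ids, start=1):
                    if f in set(met_full.feature_ids):
                        best_rank[f] = min(rank, best_rank.get(f, rank))
            pri_mets = sorted(best_rank, key=lambda f: (best_rank[f], f))
            pri_mets = pri_mets[: cfg.max_fork_candidates]
            roles = {"A": pri_mets, "B": pri_mets, "C": pri_mets}
        if min(len(v) for v in roles.values()) == 0 or len(set().union(*roles.values())) < 3:
            logger.warning("fork screen skipped: fewer than 3 candidate metabolites")
            fits = []
        else:
            triplets = forks.enumerate_triplets(roles["A"], roles["B"], roles["C"])
            fits = forks.screen_forks(met_full, triplets, alpha=cfg.alpha, adjust=cfg.adjust)
        forks.write_fork_table(fits, out / "fork_table.csv")
        report.n_triplets = len(fits)
        report.n_significant_forks = len(forks.significant_forks(fits, alpha=cfg.alpha))
        _stage(report, stage)

        report.to_json(out / "run_report.json")
        return report
    except Exception as exc:  # annotate with the failing stage; keep partial outputs
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
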