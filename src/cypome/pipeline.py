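"""End-to-end pipeline: annotation -> clusters -> enrichment -> paralogs
-> expression -> co-expression, with TSV/JSON reports and a run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    AnnotationCategory,
    GenomeAnnotation,
    category_counts,
    merge_annotations,
    read_gff3,
)
from .bootstrap import chi2_enrichment, clustering_bootstrap, coexpression_bootstrap
from .clusters import (
    ClusterParams,
    cluster_statistics,
    clusters_to_frame,
    detect_clusters,
    write_cluster_bed,
)
from .coexpression import cluster_profiles, correlation_distance, row_normalize
from .expression import (
    CountMatrix,
    category_average,
    compute_fpkm,
    expressed_set,
    expression_summary,
    pooled_quantile_levels,
    read_category_map,
    read_matrix_tsv,
    write_matrix_tsv,
)
from .paralogs import (
    eligible_clustered_genes,
    paralog_link_table,
    rank_paralogs,
    same_cluster_fraction,
)
from .similarity import read_blast_tab

log = logging.getLogger("cypome")

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_in_memory"]


@dataclass(slots=True)
class PipelineConfig:
    """Inputs and knobs of one pipeline run.

    File inputs: a background genome GFF3, a family GFF3, a BLAST-style
    tabular hit file, a fragment-count TSV with per-annotation exon
    lengths and per-experiment library sizes, and an experiment ->
    category map.
    """

    background_gff: str
    family_gff: str
    hits_tsv: str
    counts_tsv: str
    exon_lengths_tsv: str
    library_sizes_tsv: str
    categories_tsv: str
    outdir: str = "cypome_out"
    max_gap_bp: int = 200_000
    max_intervening: int = 8
    min_cluster_size: int = 2
    cut_r: float = 0.656
    quantile_probs: tuple[float, float] = (0.33, 0.66)
    n_iter: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "quantile_probs" in data:
            data["quantile_probs"] = tuple(data["quantile_probs"])
        return cls(**data)

    @property
    def cluster_params(self) -> ClusterParams:
        return ClusterParams(self.max_gap_bp, self.max_intervening, self.min_cluster_size)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage from files on disk and write the report bundle."""
    background = read_gff3(cfg.background_gff)
    family = read_gff3(cfg.family_gff)
    hits = read_blast_tab(cfg.hits_tsv)
    counts = read_matrix_tsv(cfg.counts_tsv)
    exon_lengths = pd.read_csv(cfg.exon_lengths_tsv, sep="\t", index_col=0).iloc[:, 0]
    library_sizes = pd.read_csv(cfg.library_sizes_tsv, sep="\t", index_col=0).iloc[:, 0]
    cm = CountMatrix(counts, exon_lengths, library_sizes)
    cmap = read_category_map(cfg.categories_tsv)
    merged = merge_annotations(background, family)
    return run_pipeline_in_memory(merged, hits, cm, cmap, cfg)


def run_pipeline_in_memory(
    merged: GenomeAnnotation,
    hits: pd.DataFrame,
    cm: CountMatrix,
    cmap: dict[str, str],
    cfg: PipelineConfig,
) -> dict:
    """Pipeline core on in-memory objects; returns the report dict and
    writes TSV/JSON outputs under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = cfg.cluster_params
    report: dict = {}

    fam_features = merged.family_features
    n_family = len(fam_features)
    log.info("annotation: %d features, %d family members", len(merged), n_family)
    fam_counts = category_counts(
        GenomeAnnotation(fam_features, merged.scaffold_order), by="category"
    )
    report["family_category_counts"] = fam_counts.to_dict()

    # physical clusters -----------------------------------------------------
    clustering = detect_clusters(merged, params)
    stats = cluster_statistics(clustering)
    clusters_to_frame(clustering).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    write_cluster_bed(clustering, outdir / "clusters.bed")
    report["clusters"] = {k: v for k, v in stats.items() if k != "per_scaffold"}
    log.info(
        "clusters: %d clusters, %d clustered / %d isolated",
        stats["n_clusters"], stats["n_clustered"], stats["n_isolated"],
    )

    boot = clustering_bootstrap(
        merged, n_features=n_family, params=params, n_iter=cfg.n_iter, seed=cfg.seed
    )
    report["clustering_bootstrap"] = boot.summary()
    log.info("clustering bootstrap: observed %.3f p %.5f", boot.observed, boot.p_value)

    # paralog proximity -----------------------------------------------------
    complete = {
        f.feature_id for f in fam_features if f.category is AnnotationCategory.GENE
    }
    rankings = rank_paralogs(hits, complete)
    eligible = eligible_clustered_genes(clustering, complete)
    fractions = {
        k: same_cluster_fraction(rankings, clustering, k, eligible) for k in (1, 2, 3)
    }
    report["paralog_same_cluster_fraction"] = fractions
    paralog_link_table(rankings, clustering, eligible).to_csv(
        outdir / "paralog_links.tsv", sep="\t", index=False
    )
    log.info("paralogs: %d eligible, fractions %s", len(eligible), fractions)

    # expression ------------------------------------------------------------
    fpkm = compute_fpkm(cm)
    write_matrix_tsv(fpkm, outdir / "fpkm.tsv")
    expressed = expressed_set(fpkm)
    report["n_expressed"] = len(expressed)
    report["fraction_expressed"] = len(expressed) / len(fpkm) if len(fpkm) else 0.0
    categories = {f.feature_id: f.category for f in fam_features}
    summary = expression_summary(fpkm, expressed, categories)
    summary.to_csv(outdir / "expression_summary.tsv", sep="\t", index=False)
    report["expression_summary"] = summary.to_dict(orient="records")

    avgs = category_average(fpkm, cmap)
    write_matrix_tsv(avgs, outdir / "category_averages.tsv")
    thresholds, levels = pooled_quantile_levels(fpkm, avgs, probs=cfg.quantile_probs)
    write_matrix_tsv(levels, outdir / "levels.tsv")
    report["level_thresholds"] = {"q33": thresholds.q33, "q66": thresholds.q66}
    log.info("expression: %d expressed, thresholds %.3g/%.3g",
             len(expressed), thresholds.q33, thresholds.q66)

    # chi-square enrichments ------------------------------------------------
    expressed_by_cat = (avgs.loc[sorted(expressed & set(avgs.index))] > 0).sum(axis=0)
    silent_by_cat = len(avgs) - expressed_by_cat
    try:
        stat, dof, p = chi2_enrichment(
            np.vstack([expressed_by_cat.to_numpy(), silent_by_cat.to_numpy()])
        )
        report["chi2_expressed_by_category"] = {"statistic": stat, "dof": dof, "p_value": p}
    except ValueError as exc:
        report["chi2_expressed_by_category"] = {"error": str(exc)}
    high_by_cat = (levels == "high").sum(axis=0)
    not_high = len(levels) - high_by_cat
    try:
        stat, dof, p = chi2_enrichment(
            np.vstack([high_by_cat.to_numpy(), not_high.to_numpy()])
        )
        report["chi2_high_by_category"] = {"statistic": stat, "dof": dof, "p_value": p}
    except ValueError as exc:
        report["chi2_high_by_category"] = {"error": str(exc)}

    # co-expression ---------------------------------------------------------
    expressed_ids = [i for i in avgs.index if i in expressed]
    coexp_report: dict = {}
    if len(expressed_ids) >= 2:
        profiles = avgs.loc[expressed_ids]
        dist = correlation_distance(profiles)
        expr_clusters = cluster_profiles(dist, cut_r=cfg.cut_r)
        labels_frame = pd.DataFrame(
            {"annotation": expressed_ids,
             "expression_cluster": [expr_clusters.labels[i] for i in expressed_ids]}
        )
        labels_frame.to_csv(outdir / "expression_clusters.tsv", sep="\t", index=False)
        write_matrix_tsv(row_normalize(profiles), outdir / "normalized_profiles.tsv")
        coexp_report["n_expression_clusters"] = expr_clusters.n_clusters
        coexp_report["cluster_sizes"] = expr_clusters.sizes().to_dict()
        try:
            co_boot = coexpression_bootstrap(
                clustering, expr_clusters.labels, n_iter=cfg.n_iter, seed=cfg.seed
            )
            coexp_report["bootstrap"] = co_boot.summary()
            log.info("coexpression: observed %.3f p %.5f", co_boot.observed, co_boot.p_value)
        except ValueError as exc:
            coexp_report["bootstrap"] = {"error": str(exc)}
    report["coexpression"] = coexp_report

    manifest = {
        "cypome_version": __version__,
        "seed": cfg.seed,
        "n_iter": cfg.n_iter,
        "cluster_params": {
            "max_gap_bp": params.max_gap_bp,
            "max_intervening": params.max_intervening,
            "min_cluster_size": params.min_cluster_size,
        },
        "cut_r": cfg.cut_r,
        "quantile_probs": list(cfg.quantile_probs),
        "n_features": len(merged),
        "n_family": n_family,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    return report
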