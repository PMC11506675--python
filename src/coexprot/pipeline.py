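"""End-to-end orchestration: quantification through network comparison."""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import compare as cmp
from . import coexpression as coex
from . import differential as diff
from . import explore
from . import io
from . import quantify as quant
from .config import RunConfig
from .matrix import AbundanceMatrix

logger = logging.getLogger(__name__)

_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@contextmanager
def _stage(name: str):
    logger.info("stage: %s", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[{name}] {exc}") from exc


@dataclass
class PipelineInputs:
    metadata_path: str | Path
    protein_path: str | Path | None = None
    peptide_path: str | Path | None = None
    annotation_path: str | Path | None = None
    ko_path: str | Path | None = None

    def __post_init__(self) -> None:
        if self.protein_path is None and self.peptide_path is None:
            raise ValueError("need a protein- or peptide-level input table")


@dataclass
class PipelineResult:
    matrix: AbundanceMatrix
    pca: explore.PCAResult
    clusters: explore.ClusterAssignment
    cluster_chi2: explore.Chi2Result | None
    anova: diff.AnovaResult
    dep_sets: dict[str, set[str]]
    networks: dict[str, coex.CoexpressionNetwork]
    overlap: cmp.OverlapResult
    enrichment: dict[str, pd.DataFrame]
    connectivity_change: pd.DataFrame
    dep_breakdown: pd.DataFrame
    node_delta: pd.DataFrame
    log: dict = field(default_factory=dict)


def _flat_cells(cellmeans) -> pd.DataFrame:
    out = cellmeans.values.copy()
    out.columns = [f"{c}_{d}_z{z}" for c, d, z in out.columns]
    out.index.name = "protein_id"
    return out


def run_pipeline(
    config: RunConfig,
    inputs: PipelineInputs,
    outdir: str | Path,
) -> PipelineResult:
    """Run every analysis stage and write all result tables.

    Stages: quantification (when the input is peptide-level), replicate
    averaging + PCA + clustering, per-protein Type III ANOVA with BH
    calling, per-condition co-expression networks, and the full set of
    network comparison statistics. A JSON run log records the seed,
    thresholds and per-stage counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": asdict(config)}

    with _stage("load"):
        if inputs.peptide_path is not None:
            peptides = quant.read_peptide_table(inputs.peptide_path, inputs.metadata_path)
            log["n_peptides_in"] = peptides.n_peptides
        else:
            peptides = None
            matrix = io.read_abundance_table(inputs.protein_path, inputs.metadata_path)
        annotation_map = (
            io.read_annotation(inputs.annotation_path)
            if inputs.annotation_path is not None else {}
        )

    if peptides is not None:
        with _stage("quantify"):
            matrix = quant.quantify_peptides(
                peptides,
                max_missing_frac=config.min_missing_frac,
                min_corr=config.min_pep_corr,
                normalize=True,
            )
            log["n_proteins_quantified"] = matrix.n_proteins
            io.write_abundance_table(matrix, outdir / "protein_abundances.tsv")
    else:
        with _stage("transform"):
            if config.log_transform and not matrix.log_scale:
                matrix = matrix.to_log2()

    annotation = io.annotate_proteins(matrix.protein_ids, annotation_map)

    with _stage("exploratory"):
        cellmeans = explore.compute_cell_means(matrix)
        _flat_cells(cellmeans).to_csv(outdir / "cell_means.tsv", sep="\t",
                                      na_rep=io.NA_TOKEN, float_format=_FMT)
        pca = explore.run_pca(cellmeans)
        pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t", float_format=_FMT)
        pca.loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t", float_format=_FMT)
        pca.variance_frac.to_csv(outdir / "pca_variance.tsv", sep="\t", float_format=_FMT)
        clusters = explore.cluster_proteins(
            cellmeans, k=config.k_clusters, seed=config.rng_seed,
            restarts=config.kmeans_restarts,
        )
        clusters.labels.rename("cluster").to_csv(outdir / "clusters.tsv", sep="\t")
        log["cluster_sizes"] = {int(k): int(v) for k, v in clusters.sizes().items()}
        cluster_chi2 = None
        if annotation_map:
            cluster_chi2 = explore.test_cluster_annotation_independence(clusters, annotation)
            cluster_chi2.table.to_csv(outdir / "cluster_annotation_table.tsv", sep="\t")
            (outdir / "cluster_annotation_chi2.json").write_text(json.dumps({
                "statistic": cluster_chi2.statistic, "df": cluster_chi2.df,
                "p": cluster_chi2.p, "p_reported": cmp.format_p(cluster_chi2.p),
            }, indent=2))

    with _stage("differential"):
        anova = diff.anova_table(matrix, alpha=config.alpha)
        dep_sets = diff.call_significant(anova)
        out = anova.table.copy()
        out["direction"] = out["protein_id"].map(anova.direction)
        out.to_csv(outdir / "anova.tsv", sep="\t", index=False,
                   na_rep=io.NA_TOKEN, float_format=_FMT)
        log["n_significant"] = {t: len(dep_sets[t]) for t in sorted(dep_sets)}

    with _stage("networks"):
        networks = {
            cond: coex.build_network(matrix, cond, alpha=config.alpha)
            for cond in ("WW", "WD")
        }
        for cond, net in networks.items():
            coex.write_edges(net, outdir / f"edges_{cond}.tsv")
        (outdir / "network_summary.json").write_text(json.dumps({
            cond: {
                "n_nodes": net.n_nodes, "n_edges": net.n_edges,
                "n_possible": net.n_possible, "density": net.density,
                "n_excluded_pairs": net.n_excluded_pairs,
                "n_zero_variance": net.n_zero_variance,
            } for cond, net in networks.items()
        }, indent=2))
        log["n_edges"] = {c: n.n_edges for c, n in networks.items()}

    with _stage("comparison"):
        net_ww, net_wd = networks["WW"], networks["WD"]
        overlap = cmp.overlap(net_ww, net_wd)
        (outdir / "overlap.json").write_text(json.dumps(overlap.to_dict(), indent=2))
        enrichment = {}
        for cond, net in networks.items():
            enr = cmp.term_pair_enrichment(net, annotation, alpha=config.alpha)
            enr.to_csv(outdir / f"term_enrichment_{cond}.tsv", sep="\t",
                       index=False, float_format=_FMT)
            enrichment[cond] = enr
        change = cmp.compare_term_pair_connectivity(
            net_ww, net_wd, annotation,
            yates=config.yates_correction, alpha=config.alpha,
        )
        change.to_csv(outdir / "connectivity_change.tsv", sep="\t",
                      index=False, float_format=_FMT)
        breakdown = cmp.edge_set_algebra(net_ww, net_wd, dep_sets["WD_affected"])
        breakdown.to_csv(outdir / "dep_edge_breakdown.tsv", sep="\t")
        delta = cmp.node_degree_delta(net_ww, net_wd, annotation)
        delta.to_csv(outdir / "node_delta.tsv", sep="\t", index=False)

    if inputs.ko_path is not None:
        with _stage("kegg"):
            ko_map = io.read_ko_map(inputs.ko_path)
            directions = diff.dep_directions(anova, dep_sets["WD_affected"])
            skipped = io.write_kegg_mapping(directions, ko_map, outdir / "kegg_mapping.tsv")
            log["kegg_skipped"] = skipped

    log["normalisation"] = "median-of-ratios stand-in (log scale)"
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))

    return PipelineResult(
        matrix=matrix, pca=pca, clusters=clusters, cluster_chi2=cluster_chi2,
        anova=anova, dep_sets=dep_sets, networks=networks, overlap=overlap,
        enrichment=enrichment, connectivity_change=change,
        dep_breakdown=breakdown, node_delta=delta, log=log,
    )
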