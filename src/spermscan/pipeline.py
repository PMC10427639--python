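"""End-to-end orchestration: simulate/load -> QC -> cluster -> DE ->
trajectory -> dosage, with stage-level logging and a JSON report.

Every stage writes its artifact as a plain CSV/TSV/MTX file so stages are
independently re-runnable; ``report.json`` aggregates the headline
numbers (QC summary, cluster sizes, enriched-gene counts by cluster and
chromosome, RNA-content comparisons, ratio/regime tables, pseudotime
order) stamped with the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import diffexpr, dosage, qc, trajectory
from .datatypes import ClusterAssignment, GeneAnnotation, UmiMatrix
from .io import read_10x_triplet, read_gene_annotation, write_10x_triplet
from .simulate import (SimulationConfig, default_marker_table,
                       default_testis_config, root_marker_gene,
                       simulate_counts)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a full run needs; defaults follow the analysis rules."""

    # input: either a simulation config or an on-disk triplet + annotation
    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    annotation_path: str | None = None
    marker_table_path: str | None = None
    out_dir: str = "spermscan_out"
    # thresholds
    min_genes: int = 200
    log2fc_cutoff: float = 1.0
    alpha: float = 0.05
    band_no_dc: tuple[float, float] = (0.4, 0.65)
    floor_silenced: float = 0.4
    # clustering
    k: int = 8
    n_components: int = 10
    n_top_genes: int = 1000
    kmeans_seed: int = 0
    sweep_k_range: tuple[int, int] | None = None
    # trajectory / stage order
    root_marker: str | None = None
    stage_order_source: str = "trajectory"  # or "marker_table"

    def config_hash(self) -> str:
        payload = asdict(self)
        if payload.get("simulation") is not None:
            sim = payload["simulation"]
            sim["class_factor"] = np.asarray(sim["class_factor"]).tolist()
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_full(cfg: RunConfig) -> dict:
    """Execute the whole pipeline; returns (and writes) the report dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.config_hash()}

    # ---- input -----------------------------------------------------------
    stage = "input"
    try:
        truth = None
        if cfg.simulation is not None:
            matrix, annotation, truth = simulate_counts(cfg.simulation)
            report["seed"] = cfg.simulation.seed
            write_10x_triplet(matrix, out / "simulated", annotation)
            truth.write_tsv(out / "simulated" / "truth.tsv")
        elif cfg.input_dir is not None:
            matrix = read_10x_triplet(cfg.input_dir)
            annotation = (read_gene_annotation(cfg.annotation_path)
                          if cfg.annotation_path is not None else None)
            report["seed"] = cfg.kmeans_seed
        else:
            raise ValueError("provide either a simulation config or input_dir")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage name must surface
        raise StageError(stage, exc) from exc

    # ---- qc --------------------------------------------------------------
    stage = "qc"
    try:
        filtered = qc.filter_cells_min_genes(matrix, cfg.min_genes)
        filtered = qc.filter_genes_expressed(filtered)
        summary = qc.qc_summary(filtered)
        report["qc"] = summary.to_dict()
        log.info("qc: %d cells, %d genes retained", summary.n_cells,
                 summary.n_genes)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- clustering ------------------------------------------------------
    stage = "cluster"
    try:
        norm = cl.normalize_log(filtered)
        emb = cl.pca_embed(norm, cfg.n_components, cfg.n_top_genes)
        clusters = cl.kmeans_cluster(emb, cfg.k, cfg.kmeans_seed)
        report["cluster_sizes"] = clusters.sizes().to_dict()
        if cfg.sweep_k_range is not None:
            lo, hi = cfg.sweep_k_range
            sweep = cl.sweep_k(emb, range(lo, hi + 1), cfg.kmeans_seed)
            report["sweep_cluster_sizes"] = {
                k: a.sizes().to_dict() for k, a in sweep.items()
            }
        pd.DataFrame({"barcode": filtered.barcodes,
                      "cluster": clusters.labels_for(filtered.barcodes)}
                     ).to_csv(out / "clusters.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- differential expression ----------------------------------------
    stage = "diffexpr"
    try:
        de = diffexpr.globally_distinguishing_de(
            filtered, clusters, cfg.log2fc_cutoff, cfg.alpha)
        de.to_csv(out / "de.csv", index=False)
        partition = diffexpr.enrichment_partition(de)
        report["enriched_per_cluster"] = (
            de[de["enriched"]].groupby("cluster").size().to_dict()
        )
        report["enrichment_partition"] = {
            "+".join(map(str, sorted(s))): n for s, n in partition.items()
        }
        if annotation is not None:
            by_chrom = diffexpr.enrichment_by_chromosome(de, annotation)
            by_chrom.to_csv(out / "enrichment_by_chromosome.csv")
            report["enrichment_by_chromosome"] = {
                str(c): row.to_dict() for c, row in by_chrom.iterrows()
            }
        marker_table = None
        if cfg.marker_table_path is not None:
            marker_table = pd.read_csv(cfg.marker_table_path, sep="\t")
        elif cfg.simulation is not None:
            marker_table = default_marker_table(cfg.simulation)
        if marker_table is not None and not marker_table.empty:
            report["cluster_annotation"] = {
                str(c): {"cell_type": t, "score": s}
                for c, (t, s) in diffexpr.annotate_clusters(de, marker_table).items()
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- trajectory ------------------------------------------------------
    stage = "trajectory"
    try:
        root_marker = cfg.root_marker
        if root_marker is None and cfg.simulation is not None:
            try:
                root_marker = root_marker_gene(cfg.simulation)
            except ValueError:
                root_marker = None  # config has no typed stem-cell marker
        traj = None
        if root_marker is not None:
            root = trajectory.select_root(norm, clusters, root_marker)
            traj = trajectory.pseudotime_mst(emb, clusters, root)
            pd.DataFrame({"barcode": traj.pseudotime.index,
                          "pseudotime": traj.pseudotime.values}
                         ).to_csv(out / "pseudotime.csv", index=False)
            report["trajectory"] = {
                "root_cluster": traj.root_cluster,
                "cluster_order": traj.cluster_order,
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage order -----------------------------------------------------
    stage = "stage_order"
    try:
        if cfg.stage_order_source == "trajectory" and traj is not None:
            stage_order = traj.cluster_order
        elif cfg.stage_order_source == "marker_table" and marker_table is not None:
            ann_map = diffexpr.annotate_clusters(de, marker_table)
            rank_of_type = dict(zip(marker_table["cell_type"],
                                    marker_table["stage_rank"]))
            stage_order = sorted(
                ann_map, key=lambda c: rank_of_type.get(ann_map[c][0], 1e9))
        else:
            stage_order = sorted(clusters.sizes().index)
        clusters.stage_order = [int(c) for c in stage_order]
        report["stage_order"] = clusters.stage_order
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- dosage ----------------------------------------------------------
    stage = "dosage"
    try:
        if annotation is None:
            raise ValueError("a gene annotation (gene -> chromosome arm) is "
                             "required for the dosage analysis")
        for_dosage = qc.filter_genes_cluster_expressed(filtered, clusters)
        content = dosage.rna_content_per_cell(for_dosage, annotation, clusters)
        content.to_csv(out / "content_per_cell.csv", index=False)
        tests = dosage.compare_content_consecutive(content, stage_order)
        tests.to_csv(out / "content_tests.csv", index=False)
        report["content_tests"] = tests.to_dict(orient="records")
        glc = dosage.gene_cluster_log_counts(for_dosage, clusters)
        ratios = []
        for cls in ("X", "Y"):
            ratios.append(dosage.xa_ratio_per_cluster(
                glc, annotation, cls, alpha=cfg.alpha,
                band_no_dc=cfg.band_no_dc,
                floor_silenced=cfg.floor_silenced))
        ratio_df = pd.concat(ratios, ignore_index=True)
        ratio_df.to_csv(out / "ratio_results.csv", index=False)
        report["ratio_results"] = ratio_df.to_dict(orient="records")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- ground-truth diagnostics (simulation runs only) -----------------
    if truth is not None:
        from scipy.stats import spearmanr
        from sklearn.metrics import adjusted_rand_score

        true_labels = truth.true_cluster.reindex(filtered.barcodes)
        report["ari_vs_truth"] = float(adjusted_rand_score(
            true_labels.to_numpy(int),
            clusters.labels_for(filtered.barcodes)))
        if traj is not None:
            ranks = truth.true_pseudorank.reindex(traj.pseudotime.index)
            rho = spearmanr(ranks.to_numpy(float),
                            traj.pseudotime.to_numpy(float)).statistic
            report["pseudotime_spearman_vs_truth"] = float(rho)

    report_path = out / "report.json"
    report_path.write_text(json.dumps(_jsonable(report), indent=2,
                                      sort_keys=True))
    log.info("report written to %s", report_path)
    return report
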