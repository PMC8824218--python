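"""End-to-end pipeline: QC -> normalize -> scale -> PCA -> integrate ->
cluster (three modality views) -> shared UMAP -> differential -> co-expression.

Outputs are a pure function of (inputs, resolved configuration, seeds); every
stage logs its input/output dimensions to a JSON-lines run log so e.g. the
row count of the stacked matrix entering the second PCA is auditable.
"""

from __future__ import annotations

import json
import logging
import os
import platform
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    ClusterAssignment,
    Embedding,
    build_knn_graph,
    leiden_cluster,
    merge_clusters,
    umap_embed,
)
from .coexpression import screen_pairs
from .config import resolve_config
from .differential import wilcoxon_de
from .io_screening import (
    CountMatrix,
    compute_gene_stats,
    drop_adts,
    read_counts,
    screen_genes,
    top_cv_features,
)
from .normalization import NormalizedMatrix, clr_transform, log_normalize, minmax_scale
from .reduction import LowDimRep, integrate, pca_reduce

logger = logging.getLogger("citemo")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class ResultBundle:
    config: dict
    rna_scaled: NormalizedMatrix
    adt_scaled: NormalizedMatrix
    reps: dict[str, LowDimRep]
    clusters: dict[str, ClusterAssignment]
    embedding: Embedding
    de_genes: pd.DataFrame
    de_adts: pd.DataFrame
    coexpression: pd.DataFrame
    log_records: list[dict] = field(default_factory=list)


def _resolve_k(value, explained_variance, elbow):
    if value == "auto":
        return elbow(explained_variance)
    return int(value)


def run_pipeline(
    config: dict | None = None,
    rna: CountMatrix | None = None,
    adt: CountMatrix | None = None,
    write: bool = True,
) -> ResultBundle:
    """Execute the full workflow.

    ``rna``/``adt`` may be passed in memory; otherwise they are read from
    the configured input paths.  With ``write`` the result bundle (CSV
    tables, figures, resolved config, run log) lands in ``output.dir``.
    """
    from .reduction import elbow_select

    cfg = resolve_config(config or {})
    records: list[dict] = []

    def log_stage(stage: str, **info):
        rec = {"stage": stage, **info}
        records.append(rec)
        logger.info("%s: %s", stage, info)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                return False

        return _Ctx()

    log_stage(
        "start",
        version=__version__,
        python=platform.python_version(),
        seed=cfg["seed"],
        preset=cfg["preset"],
    )

    with stage("read"):
        if rna is None:
            if cfg["io.rna_path"] is None:
                raise ValueError("no RNA input: set io.rna_path or pass a matrix")
            rna = read_counts(cfg["io.rna_path"], cfg["io.rna_format"], "rna",
                              cfg["io.orientation"])
        if adt is None:
            if cfg["io.adt_path"] is None:
                raise ValueError("no ADT input: set io.adt_path or pass a matrix")
            adt = read_counts(cfg["io.adt_path"], cfg["io.adt_format"], "adt",
                              cfg["io.orientation"])
        if rna.cell_barcodes != adt.cell_barcodes:
            raise ValueError("RNA and ADT matrices cover different cells/order")
        log_stage("read", rna_shape=list(rna.values.shape), adt_shape=list(adt.values.shape))

    with stage("qc"):
        stats = compute_gene_stats(rna)
        screened = screen_genes(rna, stats, cfg["qc.t_frac"], cfg["qc.sp_frac"])
        if cfg["qc.species_prefix"]:
            # union: the high-CV spiked-species genes are added back even if
            # the reliability screen dropped them
            cv_ids = top_cv_features(rna, cfg["qc.species_prefix"], cfg["qc.top_cv_n"])
            keep_ids = set(screened.feature_ids) | set(cv_ids)
            keep = np.array([f in keep_ids for f in rna.feature_ids])
            screened = rna.subset_features(keep)
        rna_qc = screened
        adt_qc = drop_adts(adt, cfg["qc.drop_adts"], cfg["qc.strict_adt_names"])
        log_stage("qc", genes_kept=rna_qc.n_features, adts_kept=adt_qc.n_features)

    with stage("normalize"):
        rna_norm = log_normalize(rna_qc)
        adt_norm = clr_transform(adt_qc, cfg["norm.clr_pseudocount"])
        rna_scaled = minmax_scale(rna_norm, literal_shift=cfg["norm.literal_eq5"])
        adt_scaled = minmax_scale(adt_norm, literal_shift=cfg["norm.literal_eq5"])
        log_stage("normalize", clr_pseudocount=cfg["norm.clr_pseudocount"],
                  literal_eq5=cfg["norm.literal_eq5"])

    with stage("reduce"):
        rna_full = pca_reduce(rna_scaled, "all", cfg["reduce.seed"])
        rna_k = _resolve_k(cfg["reduce.rna_k"], rna_full.explained_variance, elbow_select)
        rna_rep = rna_full.truncate(min(rna_k, rna_full.k))
        if cfg["reduce.passthrough"]:
            adt_rep = pca_reduce(adt_scaled, passthrough=True)
        else:
            adt_full = pca_reduce(adt_scaled, "all", cfg["reduce.seed"])
            adt_k = _resolve_k(cfg["reduce.adt_k"], adt_full.explained_variance, elbow_select)
            adt_rep = adt_full.truncate(min(adt_k, adt_full.k))
        log_stage("reduce", rna_k=rna_rep.k, adt_k=adt_rep.k,
                  adt_passthrough=cfg["reduce.passthrough"])

    with stage("integrate"):
        multi_rep = integrate(rna_rep, adt_rep, cfg["reduce.multimodal_k"],
                              cfg["reduce.seed"])
        log_stage("integrate", stacked_rows=rna_rep.k + adt_rep.k,
                  multimodal_k=multi_rep.k)

    reps = {"rna": rna_rep, "adt": adt_rep, "multimodal": multi_rep}
    clusters: dict[str, ClusterAssignment] = {}
    with stage("cluster"):
        for modality, rep in reps.items():
            graph = build_knn_graph(rep, cfg["cluster.k_neighbors"])
            asg = leiden_cluster(graph, cfg["cluster.resolution"], cfg["cluster.seed"],
                                 modality, rep.cell_barcodes)
            if modality == "multimodal" and cfg["cluster.merge"]:
                asg = merge_clusters(asg, [tuple(p) for p in cfg["cluster.merge"]])
            clusters[modality] = asg
            log_stage("cluster", modality=modality, n_clusters=asg.n_clusters,
                      k_neighbors=cfg["cluster.k_neighbors"],
                      resolution=cfg["cluster.resolution"], seed=cfg["cluster.seed"])

    with stage("umap"):
        embedding = umap_embed(multi_rep, cfg["umap.seed"], cfg["umap.n_neighbors"],
                               cfg["umap.min_dist"])
        log_stage("umap", seed=cfg["umap.seed"], n_neighbors=cfg["umap.n_neighbors"])

    with stage("differential"):
        de_genes = wilcoxon_de(rna_norm, clusters["multimodal"], cfg["de.min_cells"],
                               cfg["de.test"])
        de_adts = wilcoxon_de(adt_norm, clusters["multimodal"], cfg["de.min_cells"],
                              cfg["de.test"])
        log_stage("differential", gene_rows=len(de_genes), adt_rows=len(de_adts))

    with stage("coexpression"):
        coex = screen_pairs(adt_scaled, clusters["multimodal"], cfg["coex.theta"],
                            cfg["coex.epsilon"], cfg["coex.product_form"])
        log_stage("coexpression", rows=len(coex), theta=cfg["coex.theta"])

    bundle = ResultBundle(cfg, rna_scaled, adt_scaled, reps, clusters, embedding,
                          de_genes, de_adts, coex, records)
    if write:
        with stage("write"):
            write_bundle(bundle, cfg["output.dir"])
    return bundle


def write_bundle(bundle: ResultBundle, out_dir: str) -> None:
    """CSV tables, shared-UMAP figures, resolved config and run log."""
    os.makedirs(out_dir, exist_ok=True)
    barcodes = bundle.embedding.cell_barcodes
    for modality, asg in bundle.clusters.items():
        pd.DataFrame({"barcode": barcodes, "label": asg.labels}).to_csv(
            os.path.join(out_dir, f"clusters_{modality}.csv"), index=False
        )
    pd.DataFrame(
        {"barcode": barcodes,
         "x": bundle.embedding.coords[:, 0],
         "y": bundle.embedding.coords[:, 1]}
    ).to_csv(os.path.join(out_dir, "umap.csv"), index=False)
    bundle.de_genes.to_csv(os.path.join(out_dir, "de_genes.csv"), index=False)
    bundle.de_adts.to_csv(os.path.join(out_dir, "de_adts.csv"), index=False)
    bundle.coexpression.to_csv(os.path.join(out_dir, "coexpression.csv"), index=False)
    with open(os.path.join(out_dir, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(bundle.config, fh, sort_keys=True)
    with open(os.path.join(out_dir, "run_log.jsonl"), "w") as fh:
        for rec in bundle.log_records:
            fh.write(json.dumps(rec) + "\n")

    # one shared embedding, three cluster colourings
    coords = bundle.embedding.coords
    fig, axes = plt.subplots(1, 3, figsize=(13, 4), sharex=True, sharey=True)
    for ax, (modality, asg) in zip(axes, bundle.clusters.items()):
        ax.scatter(coords[:, 0], coords[:, 1], c=asg.labels, cmap="tab20", s=6,
                   linewidths=0)
        ax.set_title(f"{modality} ({asg.n_clusters} clusters)")
        ax.set_xlabel("UMAP1")
    axes[0].set_ylabel("UMAP2")
    fig.tight_layout()
    for ext in ("png", "svg"):
        fig.savefig(os.path.join(out_dir, f"umap_clusters.{ext}"), dpi=120)
    plt.close(fig)
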