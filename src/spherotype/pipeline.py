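"""Configuration-driven end-to-end orchestration of the analysis.

Stages run in the order QC -> normalization -> overdispersion feature
selection -> correlation distance + UMAP -> clustering (K-means and EM,
each in the variable-gene space and the embedded space) -> per-cluster
GSEA (one-vs-rest and pairwise) -> enrichment map + cross-method
concordance -> pairwise differential expression -> Venn/markers/key
genes. One master seed fans out deterministically to per-stage seeds so
inserting a stage does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import de as de_mod
from . import emap as emap_mod
from . import enrich as enrich_mod
from . import features as feat
from . import io_formats as iof

logger = logging.getLogger("spherotype")

__all__ = ["RunConfig", "RunSummary", "validate_config", "run_pipeline",
           "stage_seed", "load_config"]


@dataclass
class RunConfig:
    """All pipeline thresholds, each appearing exactly once.

    Defaults are the study values: QC at 1000 detected genes, top 6000
    overdispersed genes, 300 UMAP iterations, enrichment significance at
    FDR < 0.05 and p < 0.01, map links at Jaccard > 0.4, concordance at
    Jaccard >= 0.7, DE at |log2FC| > 1.5 (markers > 2) and p < 0.01.
    """

    counts_path: str | None = None
    counts_format: str = "dense"
    metadata_path: str | None = None
    gmt_path: str | None = None
    out_dir: str | None = None

    qc_min_genes: int = 1000
    features_top_n: int = 6000
    cluster_kmax: int = 8
    cluster_n_init: int = 25
    umap_n_iter: int = 300
    enrich_n_perm: int = 1000
    enrich_fdr: float = 0.05
    enrich_p: float = 0.01
    emap_link_threshold: float = 0.4
    concordance_threshold: float = 0.7
    de_n_perm: int = 1000
    de_lfc: float = 1.5
    de_marker_lfc: float = 2.0
    de_p: float = 0.01
    de_pseudocount: float = 1.0
    seed: int = 0


@dataclass
class RunSummary:
    n_genes_raw: int = 0
    n_cells_raw: int = 0
    n_genes_qc: int = 0
    n_cells_qc: int = 0
    n_genes_selected: int = 0
    variance_fraction: float = 0.0
    selected_k: dict[str, int] = field(default_factory=dict)
    cluster_sizes: dict[str, int] = field(default_factory=dict)
    time_composition: dict[str, dict[str, float]] = field(default_factory=dict)
    enriched_counts: dict[str, int] = field(default_factory=dict)
    n_map_collections: int = 0
    concordance_matches: int = 0
    n_de_significant: int = 0
    n_cluster_specific: int = 0
    n_core: int = 0
    n_markers: int = 0
    key_genes: list[str] = field(default_factory=list)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


_VALID_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _VALID_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return cfg


def validate_config(cfg: RunConfig) -> list[str]:
    """Return the full list of invariant violations (empty means ok)."""
    errs = []
    if cfg.qc_min_genes < 0:
        errs.append("qc_min_genes must be >= 0")
    if cfg.features_top_n < 1:
        errs.append("features_top_n must be >= 1")
    if cfg.cluster_kmax < 3:
        errs.append("cluster_kmax must be >= 3")
    if cfg.cluster_n_init < 1:
        errs.append("cluster_n_init must be >= 1")
    if cfg.umap_n_iter < 1:
        errs.append("umap_n_iter must be >= 1")
    if cfg.enrich_n_perm < 100:
        errs.append("enrich_n_perm must be >= 100")
    for name in ("enrich_fdr", "enrich_p", "de_p"):
        v = getattr(cfg, name)
        if not 0.0 < v <= 1.0:
            errs.append(f"{name} must be in (0, 1]")
    for name in ("emap_link_threshold", "concordance_threshold"):
        v = getattr(cfg, name)
        if not 0.0 <= v <= 1.0:
            errs.append(f"{name} must be in [0, 1]")
    if cfg.de_n_perm < 100:
        errs.append("de_n_perm must be >= 100")
    if cfg.de_lfc < 0 or cfg.de_marker_lfc < 0:
        errs.append("fold-change thresholds must be >= 0")
    if cfg.de_pseudocount <= 0:
        errs.append("de_pseudocount must be > 0")
    if cfg.counts_format not in ("dense", "mtx"):
        errs.append("counts_format must be dense or mtx")
    return errs


def _cells_of(labels: np.ndarray, cell_ids: list[str], k: int):
    return {c: [cid for cid, l in zip(cell_ids, labels) if l == c]
            for c in range(k)}


def run_pipeline(
    cfg: RunConfig,
    cm: iof.CountMatrix | None = None,
    gsc: iof.GeneSetCollection | None = None,
) -> RunSummary:
    """Execute the full analysis; returns the run summary.

    ``cm`` and ``gsc`` may be passed directly (programmatic use);
    otherwise they are read from the configured paths. Intermediates are
    written under ``cfg.out_dir`` when set.
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(seed=cfg.seed)
    t0 = time.time()

    def log_stage(stage: str, **fields) -> None:
        rec = {"stage": stage, "elapsed_s": round(time.time() - t0, 2)}
        rec.update(fields)
        logger.info(json.dumps(rec))

    # ---- input + QC -------------------------------------------------------
    if cm is None:
        if cfg.counts_path is None:
            raise ValueError("no counts provided")
        cm = iof.read_counts(cfg.counts_path, cfg.counts_format,
                             metadata=cfg.metadata_path)
    if gsc is None:
        if cfg.gmt_path is None:
            raise ValueError("no gene-set collection provided")
        gsc = iof.read_gmt(cfg.gmt_path)
    summary.n_genes_raw, summary.n_cells_raw = cm.n_genes, cm.n_cells
    cm = iof.filter_qc(cm, cfg.qc_min_genes)
    summary.n_genes_qc, summary.n_cells_qc = cm.n_genes, cm.n_cells
    log_stage("qc", genes=cm.n_genes, cells=cm.n_cells)

    # ---- features ---------------------------------------------------------
    em = feat.normalize(cm)
    scores = feat.overdispersion_scores(em)
    top = feat.select_top_genes(scores, cfg.features_top_n)
    summary.n_genes_selected = len(top)
    summary.variance_fraction = feat.variance_fraction(em, top)
    if out:
        sel = set(top)
        pd.DataFrame({
            "gene": scores.gene_ids, "mean": scores.mean,
            "variance": scores.variance, "score": scores.score,
            "rank": scores.rank,
            "selected": [g in sel for g in scores.gene_ids],
        }).to_csv(out / "features.tsv", sep="\t", index=False)
    log_stage("features", selected=len(top),
              variance_fraction=summary.variance_fraction)

    # ---- distance, embedding, clustering ---------------------------------
    dist = cl.correlation_distance_matrix(em, top)
    emb = cl.embed(dist, n_iter=cfg.umap_n_iter,
                   seed=stage_seed(cfg.seed, "umap"))
    idx = {g: i for i, g in enumerate(em.gene_ids)}
    var_points = em.values[[idx[g] for g in top], :].T  # cells x genes

    assignments: dict[str, cl.ClusterAssignment] = {}
    km_var = cl.kmeans_elbow(var_points, cfg.cluster_kmax, cfg.cluster_n_init,
                             stage_seed(cfg.seed, "kmeans_var"))
    km_var.space = "var"
    assignments["kmeans_var"] = km_var
    km_umap = cl.kmeans_elbow(emb.coords, cfg.cluster_kmax, cfg.cluster_n_init,
                              stage_seed(cfg.seed, "kmeans_umap"))
    km_umap.space = "umap"
    assignments["kmeans_umap"] = km_umap
    # mixture fitting in the gene space runs on principal components;
    # raw d >> n coordinates are not identifiable for a GMM
    em_var = cl.em_cluster(var_points, cfg.cluster_kmax,
                           stage_seed(cfg.seed, "em_var"),
                           pca_components=10)
    em_var.space = "var"
    assignments["em_var"] = em_var
    em_umap = cl.em_cluster(emb.coords, cfg.cluster_kmax,
                            stage_seed(cfg.seed, "em_umap"))
    em_umap.space = "umap"
    assignments["em_umap"] = em_umap
    summary.selected_k = {name: ca.k for name, ca in assignments.items()}

    # headline route: K-means in the variance space. The UMAP-space elbow
    # depends on how the embedding lays out well-separated islands, so the
    # full-space route is the more reproducible of the two K-means runs.
    main = assignments["kmeans_var"]
    summary.cluster_sizes = {
        str(c): int(n) for c, n in
        zip(*np.unique(main.label, return_counts=True))
    }
    comp = cl.cluster_time_composition(main, cm.timepoint)
    summary.time_composition = {
        str(c): {tp: float(v) for tp, v in row.items()}
        for c, row in comp.iterrows()
    }
    if out:
        rows = []
        for name, ca in assignments.items():
            for cid, l in zip(cm.cell_ids, ca.label):
                rows.append({"cell_id": cid, "method": ca.method,
                             "space": ca.space, "label": int(l)})
        pd.DataFrame(rows).to_csv(out / "labels.tsv", sep="\t", index=False)
        pd.DataFrame({"k": range(1, len(km_umap.sse_curve) + 1),
                      "sse": km_umap.sse_curve}).to_csv(
            out / "sse_curve.tsv", sep="\t", index=False)
        pd.DataFrame(emb.coords, index=cm.cell_ids,
                     columns=["umap1", "umap2"]).to_csv(
            out / "embedding.tsv", sep="\t")
    log_stage("cluster", selected_k=summary.selected_k)

    # ---- enrichment: one-vs-rest per cluster, all method/space routes -----
    pathway_sets: dict[str, dict[str, set[str]]] = {}
    enriched_main: dict[int, list[enrich_mod.EnrichmentResult]] = {}
    for name, ca in assignments.items():
        groups = _cells_of(ca.label, cm.cell_ids, ca.k)
        per_cluster: dict[str, set[str]] = {}
        for c, cells in groups.items():
            rest = [cid for cid in cm.cell_ids if cid not in set(cells)]
            if len(cells) < 3 or len(rest) < 3:
                per_cluster[str(c)] = set()  # too small for a two-class rank
                if name == "kmeans_var":
                    enriched_main[c] = []
                continue
            res = enrich_mod.gsea(
                em, cells, rest, gsc, n_perm=cfg.enrich_n_perm,
                seed=stage_seed(cfg.seed, f"gsea_{name}_{c}"))
            pos = enrich_mod.filter_enriched(res, cfg.enrich_fdr, cfg.enrich_p)
            per_cluster[str(c)] = {r.set_name for r in pos}
            if name == "kmeans_var":
                enriched_main[c] = pos
        pathway_sets[name] = per_cluster
    summary.enriched_counts = {
        c: len(s) for c, s in pathway_sets["kmeans_var"].items()
    }
    log_stage("enrich", counts=summary.enriched_counts)

    # ---- enrichment map + concordance -------------------------------------
    universe = set(em.gene_ids)
    all_pos = [r for res in enriched_main.values() for r in res]
    graph = None
    if all_pos:
        graph = emap_mod.build_enrichment_map(
            all_pos, universe, cfg.emap_link_threshold)
        emap_mod.name_collections(graph)
        summary.n_map_collections = len(graph.collections)
        if out:
            emap_mod.export_graph(graph, out / "enrichment_map.graphml")
    conc = emap_mod.cluster_concordance(pathway_sets,
                                        cfg.concordance_threshold)
    summary.concordance_matches = int(conc["matched"].sum())
    if out:
        conc.to_csv(out / "concordance.tsv", sep="\t", index=False)
    log_stage("emap", collections=summary.n_map_collections,
              concordance_matches=summary.concordance_matches)

    # ---- differential expression on the main route ------------------------
    if main.k >= 3:
        groups = _cells_of(main.label, cm.cell_ids, main.k)
        names = {c: str(c) for c in groups}
        pairwise = {}
        for a, b in combinations(sorted(groups), 2):
            comp_name = (names[a], names[b])
            pairwise[comp_name] = de_mod.differential_expression(
                cm, groups[a], groups[b], n_perm=cfg.de_n_perm,
                pseudocount=cfg.de_pseudocount,
                seed=stage_seed(cfg.seed, f"de_{a}_{b}"),
                lfc_min=cfg.de_lfc, p_max=cfg.de_p, comparison=comp_name)
        if main.k == 3:
            venn = de_mod.classify_de_venn(pairwise, cfg.de_lfc, cfg.de_p)
            markers = de_mod.marker_genes(pairwise, cfg.de_marker_lfc,
                                          cfg.de_p)
            summary.n_de_significant = len(venn.membership)
            summary.n_cluster_specific = sum(
                len(v) for v in venn.cluster_specific.values())
            summary.n_core = len(venn.core)
            summary.n_markers = sum(len(v) for v in markers.values())
            by_coll = {}
            if graph is not None:
                for cid, info in graph.collections.items():
                    members = set(info["members"])
                    by_coll[str(cid)] = [r for r in all_pos
                                         if r.set_name in members]
            kg = de_mod.key_genes(venn, by_coll)
            summary.key_genes = kg.key_genes
            if out:
                rows = [dataclasses.asdict(r) for recs in pairwise.values()
                        for r in recs]
                pd.DataFrame(rows).to_csv(out / "de.tsv", sep="\t",
                                          index=False)
                kg.table.to_csv(out / "key_genes.tsv", sep="\t", index=False)
        log_stage("de", n_significant=summary.n_de_significant)

    if out:
        (out / "summary.json").write_text(summary.to_json())
    return summary
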