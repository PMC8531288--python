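"""End-to-end staged analysis on synthetic data.

``run_pipeline`` wires the whole study together: simulate a staged
single-cell atlas, QC each compartment with its own criteria, log-normalize,
select HVGs, scale, embed and Leiden-cluster each compartment, derive the
cancer signature from tumor-vs-normal bulk DE at the configured gates, score
every epithelial cell, median-split into normal/cancer, locate the stem-like
cluster, trace BCSC proportions across stages with a Mann-Kendall trend on
per-stage score medians, stratify a survival cohort by signature expression
(KM + log-rank), and summarize cytokine-receptor cross-talk from the stem
cluster to the immune clusters. All outputs are deterministic CSV/JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import crosstalk as ct
from . import preprocess as pp
from . import qc, scoring, signatures, survival, trend
from .io import write_gmt, write_table
from .simulate import SimConfig, simulate_bulk, simulate_cohort, simulate_single_cell

logger = logging.getLogger("stemscore")


def run_pipeline(config: SimConfig | None = None, out_dir: str | Path = "pipeline_out",
                 seed: int = 0, n_hvgs: int = 3000, n_pcs: int = 50,
                 resolution: float = 0.4, k_neighbors: int = 20,
                 scale_factor: float = 1e4) -> dict:
    """Run the full analysis; returns the summary dict (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = replace(config if config is not None else SimConfig(), seed=seed)

    # ---- simulate & QC ----------------------------------------------------
    counts, cells, truth = simulate_single_cell(config)
    metrics = qc.compute_qc_metrics(counts, mito_prefix=config.mito_prefix)
    metrics = metrics.merge(cells, on="cell_id")
    kept_ids: list[str] = []
    qc_summary = {}
    for compartment, criteria in (("epithelial", qc.MOUSE_EPITHELIAL),
                                  ("immune", qc.MOUSE_IMMUNE)):
        sub = metrics[metrics["compartment"] == compartment]
        kept, removed = qc.filter_cells(sub, criteria)
        kept_ids.extend(kept)
        qc_summary[compartment] = {"n_input": len(sub), "n_kept": len(kept),
                                   "removed_per_criterion": removed}
    kept_ids = [c for c in counts.cell_ids if c in set(kept_ids)]  # matrix order
    write_table(metrics, out / "qc_metrics.csv")

    counts_f = counts.subset_cells(kept_ids)
    cells_f = cells.set_index("cell_id").loc[kept_ids].reset_index()
    norm = pp.lognormalize(counts_f, scale_factor=scale_factor)

    # ---- per-compartment embedding + clustering ---------------------------
    cluster_map: dict[str, str] = {}
    for compartment, prefix in (("epithelial", "E"), ("immune", "I")):
        ids = cells_f.loc[cells_f["compartment"] == compartment, "cell_id"].tolist()
        sub = norm.subset_cells(ids)
        hvgs = pp.select_hvgs(sub, n=n_hvgs)
        scaled, genes = pp.scale_genes(sub, hvgs)
        k = min(n_pcs, len(ids) - 1, len(genes))
        emb = pp.run_pca(scaled, n_components=k, seed=seed)
        labels = pp.cluster_cells(emb, resolution=resolution,
                                  k_neighbors=min(k_neighbors, len(ids) - 1),
                                  seed=seed)
        for cid, lab in zip(ids, labels):
            cluster_map[cid] = f"{prefix}{lab}"
    cells_f["cluster"] = cells_f["cell_id"].map(cluster_map)
    clusters = cells_f.set_index("cell_id")["cluster"]

    # ---- cancer signature from bulk DE ------------------------------------
    bulk, samples, bulk_truth = simulate_bulk(config)
    de = signatures.bulk_de(bulk, samples.set_index("sample_id")["group"])
    write_table(de, out / "bulk_de.csv")
    gates = signatures.DEGates()
    cancer_sig = signatures.build_signature(de, gates, name="cancer")
    write_gmt([cancer_sig], out / "cancer_signature.gmt")

    # ---- ER lineage on epithelial clusters --------------------------------
    epi_ids = cells_f.loc[cells_f["compartment"] == "epithelial", "cell_id"].tolist()
    norm_epi = norm.subset_cells(epi_ids)
    er_summary = {}
    if "Esr1" in norm.gene_ids:
        er_clusters, er_cells = signatures.classify_er_lineage(
            norm_epi, clusters.loc[epi_ids])
        cells_f["er_lineage"] = cells_f["cell_id"].map(er_cells)
        n_low = int((er_cells == "ERlow").sum())
        er_summary = {"cluster_labels": {str(k): v for k, v in er_clusters.items()},
                      "pct_erlow": 100.0 * n_low / len(er_cells)}

    # ---- scoring, median split, stem cluster, proportions ------------------
    # cancer score (bulk-derived signature) -> normal/cancer median split;
    # stemness score (curated stem-marker set, rank-ES) -> stem cluster
    scores = scoring.mean_difference_score(norm_epi, cancer_sig)
    write_table(scores, out / "cancer_scores.csv")
    labels = scoring.classify_by_median(scores)
    bcsc_set = [g for g in truth.markers[config.stem_type] if g in norm.gene_ids]
    stem_scores = scoring.rank_enrichment_score(norm_epi, bcsc_set, name="stemness")
    write_table(stem_scores, out / "stemness_scores.csv")
    ranking, stem_cluster, margin = scoring.identify_stem_cluster(
        stem_scores, clusters.loc[epi_ids])
    write_table(ranking, out / "cluster_score_ranking.csv")

    label_s = labels.set_index("cell_id")["label"]
    cells_f["cancer_label"] = cells_f["cell_id"].map(label_s)
    cancer_cells = label_s.index[label_s == "cancer"]
    is_bcsc = pd.Series(
        [(c in set(cancer_cells)) and clusters.get(c) == stem_cluster
         for c in cells_f["cell_id"]], index=cells_f.index)
    cells_f["is_bcsc"] = is_bcsc.to_numpy()
    write_table(cells_f, out / "cell_table.csv")

    stages = cells_f.set_index("cell_id")["stage"]
    bcsc_flags = cells_f.set_index("cell_id")["is_bcsc"].map(
        {True: "BCSC", False: "other"})
    props = scoring.proportion_dynamics(bcsc_flags, stages, list(cancer_cells))
    write_table(props, out / "bcsc_proportions.csv")

    imm = cells_f[cells_f["compartment"] == "immune"]
    imm_props = scoring.proportion_dynamics(
        imm.set_index("cell_id")["cluster"], stages, list(imm["cell_id"]))
    write_table(imm_props, out / "immune_proportions.csv")

    # ---- stage trend on score medians --------------------------------------
    epi_scores = scores.set_index("cell_id")["score"]
    tr = trend.grade_trend(epi_scores.loc[epi_ids],
                           stages.loc[epi_ids],
                           grade_order=sorted(stages.loc[epi_ids].unique()),
                           alternative="increasing")

    # ---- survival ----------------------------------------------------------
    cohort, expr, surv_sig, cohort_truth = simulate_cohort(seed=seed)
    strat = survival.stratify_by_signature(expr, surv_sig, cohort)
    write_table(strat, out / "cohort_groups.csv")
    for grp in ("high", "low"):
        curve = survival.km_curve(strat[strat["group"] == grp])
        write_table(curve, out / f"km_{grp}.csv")
    lr = survival.logrank_test(strat)

    # ---- cross-talk --------------------------------------------------------
    pairs = ct.default_pairs()
    resolvable = [p for p in pairs
                  if p.ligand in norm.gene_ids and p.receptor in norm.gene_ids]
    flags_df = pd.DataFrame()
    if resolvable:
        summary_df = ct.pair_expression_summary(norm, clusters, resolvable)
        write_table(summary_df, out / "crosstalk_summary.csv")
        immune_clusters = sorted(imm["cluster"].unique())
        flags_df = ct.flag_interactions(summary_df, resolvable,
                                        source_clusters=[stem_cluster],
                                        target_clusters=immune_clusters)
        write_table(flags_df, out / "crosstalk_flags.csv")

    summary = {
        "seed": seed,
        "n_cells_simulated": len(cells),
        "qc": qc_summary,
        "n_clusters": {p: int(len({v for v in cluster_map.values()
                                   if v.startswith(p)})) for p in ("E", "I")},
        "er": er_summary,
        "signature_size": {"up": len(cancer_sig.up_genes),
                           "down": len(cancer_sig.down_genes)},
        "stem_cluster": str(stem_cluster),
        "stem_cluster_margin": margin,
        "score_trend": {"S": tr.s, "var_S": tr.var_s, "z": tr.z,
                        "p_value": tr.p_value, "p_exact": tr.p_exact},
        "logrank": {"statistic": lr.statistic, "p_value": lr.p_value},
        "n_crosstalk_flags": int(len(flags_df)),
        "top_crosstalk": (flags_df.iloc[0][["pair", "source", "target"]].to_dict()
                          if len(flags_df) else None),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return summary
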