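"""Cytokine-receptor cross-talk between cell clusters.

For every ligand/receptor gene of a pair list, the per-cluster mean
log-normalized expression and fraction of expressing cells are summarized
(the numbers behind the usual dot plot). A (pair, source, target) triple is
flagged as a candidate interaction when the ligand is specifically high in
the source cluster and the receptor in the target cluster: each gene must
pass a fraction-expressing floor and a z-score of its cluster mean against
the across-cluster distribution of means. The interaction score is the sum
of the two z-scores. This thresholded rule is an explicit operationalization
of dot-plot inspection; both thresholds are configuration knobs.

A small editable TSV of pairs ships with the package (Cxcl1-Cxcr2 and
Cxcl16-Cxcr6 among others); it is a generic stand-in list, not a curated
repository.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io import NormalizedMatrix, ValidationError

logger = logging.getLogger("stemscore")


@dataclass(frozen=True)
class LigandReceptorPair:
    ligand: str
    receptor: str
    name: str

    def __post_init__(self) -> None:
        if self.ligand == self.receptor:
            raise ValidationError(f"pair {self.name}: ligand equals receptor")


def read_pairs(path) -> list[LigandReceptorPair]:
    """Read a ligand/receptor TSV with columns ligand, receptor[, name]."""
    df = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValidationError("pair table needs 'ligand' and 'receptor' columns")
    pairs = []
    for _, row in df.iterrows():
        name = row.get("name") if "name" in df.columns else None
        if not isinstance(name, str) or not name:
            name = f"{row['ligand']}-{row['receptor']}"
        pairs.append(LigandReceptorPair(str(row["ligand"]), str(row["receptor"]), name))
    return pairs


def default_pairs() -> list[LigandReceptorPair]:
    """The pair list shipped with the package."""
    with resources.as_file(
            resources.files("stemscore.data") / "cytokine_receptor_pairs.tsv") as p:
        return read_pairs(p)


def _resolve_pairs(pairs, gene_ids) -> list[LigandReceptorPair]:
    known = set(gene_ids)
    kept, dropped = [], []
    for p in pairs:
        (kept if p.ligand in known and p.receptor in known else dropped).append(p)
    if dropped:
        logger.warning("%d ligand-receptor pairs unresolvable against the gene "
                       "universe, dropped: %s", len(dropped),
                       [p.name for p in dropped[:5]])
    if not kept:
        raise ValidationError("no ligand-receptor pair resolvable against the matrix")
    return kept


def pair_expression_summary(norm: NormalizedMatrix, clusters: pd.Series,
                            pairs) -> pd.DataFrame:
    """Per (gene, cluster) mean expression and fraction of expressing cells
    for every gene that appears in a resolvable pair."""
    clusters = pd.Series(clusters)
    missing = set(norm.cell_ids) - set(clusters.index)
    if missing:
        raise ValidationError(f"{len(missing)} cells have no cluster assignment")
    pairs = _resolve_pairs(pairs, norm.gene_ids)
    genes = sorted({g for p in pairs for g in (p.ligand, p.receptor)})
    gidx = norm.gene_index(genes)
    cl = clusters.loc[list(norm.cell_ids)].to_numpy()
    rows = []
    for cluster in sorted(pd.unique(cl), key=str):
        mask = cl == cluster
        sub = norm.values[np.ix_(gidx, np.flatnonzero(mask))]
        means = sub.mean(axis=1)
        fracs = (sub > 0).mean(axis=1)
        for g, m, f in zip(genes, means, fracs):
            rows.append({"gene": g, "cluster": cluster,
                         "mean_expr": float(m), "frac_expr": float(f)})
    return pd.DataFrame(rows)


def _cluster_z(summary: pd.DataFrame) -> pd.DataFrame:
    """z-score of each gene's cluster mean against its across-cluster means."""
    def z(group: pd.DataFrame) -> pd.Series:
        m = group["mean_expr"]
        sd = m.std(ddof=1)
        return (m - m.mean()) / sd if sd > 0 else pd.Series(0.0, index=m.index)

    out = summary.copy()
    out["z"] = (summary.groupby("gene", group_keys=False)
                .apply(z, include_groups=False))
    return out


def flag_interactions(summary: pd.DataFrame, pairs, source_clusters,
                      target_clusters, min_fraction: float = 0.1,
                      min_z: float = 1.0) -> pd.DataFrame:
    """Flag (pair, source, target) triples with specific paired expression.

    A triple passes iff the ligand has frac_expr >= min_fraction and cluster-
    mean z >= min_z in the source cluster, and the receptor likewise in the
    target cluster. Output columns: pair, ligand, receptor, source, target,
    ligand_z, receptor_z, score (= ligand_z + receptor_z), sorted by score
    descending (ties by pair/source/target for determinism).
    """
    clusters = summary["cluster"].unique()
    if len(clusters) < 2:
        raise ValidationError("need >= 2 clusters for a cluster z-score")
    genes_needed = {g for p in pairs for g in (p.ligand, p.receptor)}
    missing = genes_needed - set(summary["gene"])
    if missing:
        raise ValidationError(f"summary lacks pair genes: {sorted(missing)[:5]}")
    withz = _cluster_z(summary).set_index(["gene", "cluster"])
    rows = []
    for p in pairs:
        for src in source_clusters:
            lig = withz.loc[(p.ligand, src)]
            lig_ok = lig["frac_expr"] >= min_fraction and lig["z"] >= min_z
            for tgt in target_clusters:
                rec = withz.loc[(p.receptor, tgt)]
                if lig_ok and rec["frac_expr"] >= min_fraction and rec["z"] >= min_z:
                    rows.append({"pair": p.name, "ligand": p.ligand,
                                 "receptor": p.receptor, "source": src,
                                 "target": tgt, "ligand_z": float(lig["z"]),
                                 "receptor_z": float(rec["z"]),
                                 "score": float(lig["z"] + rec["z"])})
    out = pd.DataFrame(rows, columns=["pair", "ligand", "receptor", "source",
                                      "target", "ligand_z", "receptor_z", "score"])
    if not out.empty:
        out = out.sort_values(["score", "pair", "source", "target"],
                              ascending=[False, True, True, True],
                              key=lambda s: s if s.name == "score" else s.astype(str)
                              ).reset_index(drop=True)
    return out
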