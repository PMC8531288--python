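"""Per-cell signature scoring, median-split classification, stem-cluster
identification and stage-wise proportion dynamics.

Two scoring methods are provided:

* ``mean_diff`` — mean log-normalized expression of the signature's up-genes
  minus that of its down-genes (the cancer-signature score used for the
  normal/cancer median split);
* ``rank_es`` — a single-sample weighted Kolmogorov–Smirnov enrichment score
  on within-cell expression ranks (a GSVA/ssGSEA-style statistic): genes are
  ranked by decreasing expression (midranks for ties), in-set steps are
  proportional to ``(N + 1 - rank) ** weight_exponent`` normalized over the
  set, out-of-set steps are ``-1/(N - n)``, and the score is the maximum
  positive deviation plus the minimum negative deviation of the walk
  ("maxdiff" convention), which lies in [-1, 1] and depends on the cell's
  expression only through its ranks.

Cells scoring strictly above the sample median are called cancer, the rest
normal (ties at the median are conservatively normal). Stem-like (BCSC) cells
are operationally the cancer-labelled members of the top-scoring cluster.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import GeneSignature, NormalizedMatrix, ValidationError

logger = logging.getLogger("stemscore")


# ---------------------------------------------------------------------------
# core statistics (cells × genes arrays)


def _resolve_signature(sig: GeneSignature, gene_ids) -> tuple[np.ndarray, np.ndarray]:
    lookup = {g: i for i, g in enumerate(gene_ids)}
    up = [g for g in sig.up_genes if g in lookup]
    down = [g for g in sig.down_genes if g in lookup]
    missing = (len(sig.up_genes) - len(up)) + (len(sig.down_genes) - len(down))
    if missing:
        logger.warning("signature %s: %d genes absent from the matrix, dropped",
                       sig.name, missing)
    if not up and not down:
        raise ValidationError(f"no gene of signature {sig.name} present in the matrix")
    return (np.array([lookup[g] for g in up], dtype=int),
            np.array([lookup[g] for g in down], dtype=int))


def _mean_diff(X: np.ndarray, up_idx: np.ndarray, down_idx: np.ndarray) -> np.ndarray:
    up_term = X[:, up_idx].mean(axis=1) if up_idx.size else np.zeros(X.shape[0])
    down_term = X[:, down_idx].mean(axis=1) if down_idx.size else np.zeros(X.shape[0])
    return up_term - down_term


def _rank_es_one(x: np.ndarray, in_set: np.ndarray, tau: float) -> float:
    n_genes = x.size
    n_set = int(in_set.sum())
    ranks_desc = stats.rankdata(-x)  # midranks, 1 = highest expression
    weights = (n_genes + 1 - ranks_desc) ** tau
    order = np.lexsort((np.arange(n_genes), -x))  # descending, stable by index
    steps = np.where(in_set, weights / weights[in_set].sum(),
                     -1.0 / (n_genes - n_set))
    walk = np.cumsum(steps[order])
    return float(max(walk.max(), 0.0) + min(walk.min(), 0.0))


def _rank_es(X: np.ndarray, set_idx: np.ndarray, tau: float) -> np.ndarray:
    in_set = np.zeros(X.shape[1], dtype=bool)
    in_set[set_idx] = True
    if in_set.all():
        raise ValidationError("gene set equals the gene universe; walk undefined")
    return np.array([_rank_es_one(X[c], in_set, tau) for c in range(X.shape[0])])


# ---------------------------------------------------------------------------
# sklearn-style estimators


class SignatureScorer(TransformerMixin, BaseEstimator):
    """Score cells (rows) against a gene signature.

    ``method="mean_diff"`` subtracts the mean expression of the down-genes
    from that of the up-genes; ``method="rank_es"`` computes the weighted-KS
    rank enrichment score of the up-genes. Gene ids are bound at :meth:`fit`.
    """

    def __init__(self, signature: GeneSignature | None = None,
                 method: str = "mean_diff", weight_exponent: float = 1.0):
        self.signature = signature
        self.method = method
        self.weight_exponent = weight_exponent

    def fit(self, X, y=None, gene_ids=None):
        check_array(X)
        if self.signature is None:
            raise ValidationError("a signature is required")
        if self.method not in ("mean_diff", "rank_es"):
            raise ValidationError(f"unknown scoring method {self.method!r}")
        if gene_ids is None:
            raise ValidationError("gene_ids must be supplied at fit time")
        self.gene_ids_ = tuple(gene_ids)
        self.up_idx_, self.down_idx_ = _resolve_signature(self.signature, self.gene_ids_)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "gene_ids_")
        X = check_array(X, dtype=float)
        if self.method == "mean_diff":
            return _mean_diff(X, self.up_idx_, self.down_idx_)
        if self.up_idx_.size == 0:
            raise ValidationError("rank_es needs a non-empty up-gene set")
        return _rank_es(X, self.up_idx_, self.weight_exponent)


class MedianSplitClassifier(BaseEstimator):
    """Two-class split of scores at the sample median.

    ``fit`` stores ``threshold_`` (the median of the training scores);
    ``predict`` labels scores strictly above it ``"cancer"`` and everything
    else ``"normal"``. With all training scores identical every cell is
    normal (warned).
    """

    def __init__(self, positive_label: str = "cancer", negative_label: str = "normal"):
        self.positive_label = positive_label
        self.negative_label = negative_label

    def fit(self, X, y=None):
        scores = np.asarray(X, dtype=float).ravel()
        if scores.size < 2:
            raise ValidationError("need at least 2 scores for a median split")
        self.threshold_ = float(np.median(scores))
        if np.all(scores == scores[0]):
            logger.warning("all scores identical; every cell will be labelled %s",
                           self.negative_label)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        scores = np.asarray(X, dtype=float).ravel()
        return np.where(scores > self.threshold_, self.positive_label,
                        self.negative_label)


# ---------------------------------------------------------------------------
# container-level operations


def mean_difference_score(norm: NormalizedMatrix, sig: GeneSignature) -> pd.DataFrame:
    """Mean(up-genes) − mean(down-genes) per cell; empty down-set ⇒ 0 term."""
    scorer = SignatureScorer(sig, method="mean_diff")
    scores = scorer.fit(norm.values.T, gene_ids=norm.gene_ids).transform(norm.values.T)
    return pd.DataFrame({"cell_id": list(norm.cell_ids), "score": scores,
                         "signature": sig.name, "method": "mean_diff"})


def rank_enrichment_score(norm: NormalizedMatrix, gene_set,
                          weight_exponent: float = 1.0,
                          name: str = "gene_set") -> pd.DataFrame:
    """Single-sample weighted-KS enrichment score of *gene_set* per cell."""
    genes = list(gene_set)
    sig = GeneSignature(name, tuple(dict.fromkeys(genes)))
    scorer = SignatureScorer(sig, method="rank_es", weight_exponent=weight_exponent)
    scores = scorer.fit(norm.values.T, gene_ids=norm.gene_ids).transform(norm.values.T)
    return pd.DataFrame({"cell_id": list(norm.cell_ids), "score": scores,
                         "signature": name, "method": "rank_es"})


def classify_by_median(scores: pd.DataFrame, signature_name: str | None = None
                       ) -> pd.DataFrame:
    """Median-split cancer/normal labels from a score table.

    Scores strictly above the median are cancer; at or below, normal.
    """
    df = scores
    if signature_name is not None:
        df = df[df["signature"] == signature_name]
        if df.empty:
            raise ValidationError(f"no scores for signature {signature_name!r}")
    clf = MedianSplitClassifier().fit(df["score"].to_numpy())
    labels = clf.predict(df["score"].to_numpy())
    return pd.DataFrame({"cell_id": df["cell_id"].to_numpy(), "label": labels,
                         "threshold": clf.threshold_})


def identify_stem_cluster(scores: pd.DataFrame, clusters: pd.Series
                          ) -> tuple[pd.DataFrame, object, float]:
    """Rank clusters by mean signature score; return (ranking, top, margin).

    Ties between cluster means break by cluster label order (flagged). A
    single cluster is returned trivially with zero margin.
    """
    clusters = pd.Series(clusters)
    missing = set(scores["cell_id"]) - set(clusters.index)
    if missing:
        raise ValidationError(f"{len(missing)} scored cells have no cluster")
    df = scores.assign(cluster=scores["cell_id"].map(clusters).to_numpy())
    ranking = (df.groupby("cluster", sort=True)["score"].mean()
               .reset_index().rename(columns={"score": "mean_score"}))
    ranking = ranking.sort_values(["mean_score", "cluster"],
                                  ascending=[False, True],
                                  key=lambda s: s if s.name == "mean_score"
                                  else s.astype(str)).reset_index(drop=True)
    top = ranking.loc[0, "cluster"]
    if len(ranking) == 1:
        logger.warning("single cluster: stem-cluster identification is trivial")
        return ranking, top, 0.0
    margin = float(ranking.loc[0, "mean_score"] - ranking.loc[1, "mean_score"])
    if margin == 0.0:
        logger.warning("tied top clusters; tie broken by cluster label order")
    return ranking, top, margin


def proportion_dynamics(labels: pd.Series, stages: pd.Series,
                        denominator: pd.Index | list, stage_order=None
                        ) -> pd.DataFrame:
    """Per-stage fraction of denominator cells carrying each label.

    ``labels``/``stages`` are cell-id-indexed; *denominator* restricts the
    population (e.g. cancer cells, or all cells). A stage whose denominator
    is empty yields NaN, not 0.
    """
    labels = pd.Series(labels)
    stages = pd.Series(stages)
    denom = pd.Index(denominator)
    order = stage_order if stage_order is not None else sorted(stages.unique())
    label_values = sorted(labels.dropna().unique())
    rows = []
    for stage in order:
        stage_cells = stages.index[stages == stage]
        pool = stage_cells.intersection(denom)
        for lab in label_values:
            if len(pool) == 0:
                prop = np.nan
            else:
                prop = float((labels.loc[pool] == lab).sum()) / len(pool)
            rows.append({"stage": stage, "label": lab, "proportion": prop,
                         "n_denominator": len(pool)})
    return pd.DataFrame(rows)
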