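"""Normalization, variable-gene selection, scaling, PCA and graph clustering.

The pipeline's parameters follow the conventional single-cell workflow:
per-cell depth normalization to 10,000 counts followed by ``ln(1 + x)``, the
top 3,000 most variable genes, per-gene centering/scaling clipped at ±10,
50 principal components, and Leiden community detection on a shared-nearest-
neighbor graph at resolution 0.4.

The core implementations are sklearn-style estimators operating on
cells × genes arrays (so they compose with sklearn pipelines); the
module-level functions wrap them for the genes × cells containers used
elsewhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_array, check_is_fitted

from .io import CountMatrix, NormalizedMatrix, ValidationError

logger = logging.getLogger("stemscore")


@dataclass(frozen=True)
class Embedding:
    """PCA embedding: cells × components coordinates with their variances."""

    coordinates: np.ndarray
    component_variances: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        var = np.asarray(self.component_variances, dtype=float)
        if np.any(np.diff(var) > 1e-9 * max(var[0], 1.0)):
            raise ValidationError("component variances must be non-increasing")
        if self.coordinates.shape[1] != self.n_components:
            raise ValidationError("coordinate width must equal n_components")


class LogNormalizer(TransformerMixin, BaseEstimator):
    """Depth-normalize each cell to ``scale_factor`` counts, then ``ln(1+x)``.

    Stateless (fit is a no-op); rows are cells. Zero-total rows raise unless
    ``allow_zero_cells`` is set, in which case they stay all-zero.
    """

    def __init__(self, scale_factor: float = 1e4, allow_zero_cells: bool = False):
        self.scale_factor = scale_factor
        self.allow_zero_cells = allow_zero_cells

    def fit(self, X, y=None):
        check_array(X)
        self.n_features_in_ = np.shape(X)[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = check_array(X, dtype=float)
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be positive")
        totals = X.sum(axis=1)
        zero = totals == 0
        if zero.any() and not self.allow_zero_cells:
            raise ValidationError(
                f"{int(zero.sum())} cells have zero total counts (QC them out "
                "or pass allow_zero_cells=True)")
        safe = np.where(zero, 1.0, totals)
        return np.log1p(X * (self.scale_factor / safe)[:, None])


class HVGSelector(TransformerMixin, BaseEstimator):
    """Select the ``n_genes`` most variable genes.

    The default variability statistic is the plain variance of the
    log-normalized expression; ``method="standardized"`` uses variance of the
    per-gene z-scores of log expression against a mean-matched trend
    (variance/mean standardization). Ties break by gene id (lexicographic)
    when ids are supplied to :meth:`fit`, else by column index.
    """

    def __init__(self, n_genes: int = 3000, method: str = "variance"):
        self.n_genes = n_genes
        self.method = method

    def fit(self, X, y=None, gene_ids=None):
        X = check_array(X, dtype=float)
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if self.method not in ("variance", "standardized"):
            raise ValidationError(f"unknown HVG method {self.method!r}")
        var = X.var(axis=0)
        if self.method == "standardized":
            mean = X.mean(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                var = np.where(mean > 0, var / mean, 0.0)
        ids = [str(g) for g in gene_ids] if gene_ids is not None else [
            f"{i:09d}" for i in range(X.shape[1])]
        order = sorted(range(X.shape[1]), key=lambda i: (-var[i], ids[i]))
        k = min(self.n_genes, X.shape[1])
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[order[:k]] = True
        self.selected_ids_ = tuple(sorted((ids[i] for i in order[:k])))
        self.variances_ = var
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "support_")
        return check_array(X, dtype=float)[:, self.support_]


class GeneScaler(TransformerMixin, BaseEstimator):
    """Center each gene to mean 0 / variance 1 over cells, clip to ±clip.

    Constant genes map to all-zero columns.
    """

    def __init__(self, clip: float = 10.0):
        self.clip = clip

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "mean_")
        X = check_array(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        return np.clip(Z, -self.clip, self.clip)


class PCAEmbedder(TransformerMixin, BaseEstimator):
    """Deterministic PCA with a fixed sign convention.

    Thin wrapper over sklearn's full-SVD PCA; each component's sign is chosen
    so its largest-magnitude loading is positive, making the embedding
    reproducible across runs and LAPACK builds.
    """

    def __init__(self, n_components: int = 50, random_state: int | None = 0):
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        k = self.n_components
        if k > min(X.shape):
            raise ValidationError(
                f"n_components={k} exceeds min(cells, genes)={min(X.shape)}")
        pca = PCA(n_components=k, svd_solver="full", random_state=self.random_state)
        pca.fit(X)
        comps = pca.components_
        signs = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
        signs[signs == 0] = 1.0
        self.components_ = comps * signs[:, None]
        self.mean_ = pca.mean_
        self.explained_variance_ = pca.explained_variance_
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        return (X - self.mean_) @ self.components_.T


class SNNLeidenClusterer(ClusterMixin, BaseEstimator):
    """Leiden community detection on a shared-nearest-neighbor graph.

    A k-NN graph (Euclidean, on the embedding) is converted to SNN weights
    (Jaccard overlap of neighbor sets, edges below ``prune`` dropped) and
    partitioned with the seeded Leiden algorithm under the RB-configuration
    quality function, whose resolution parameter plays the role of the usual
    single-cell clustering "resolution". Singleton communities (usually cells
    isolated by SNN pruning) are absorbed into the cluster they are most
    connected to (nearest centroid when fully disconnected), as the common
    toolkits do. Labels are relabelled as contiguous integers in decreasing
    cluster-size order (ties by original label).
    """

    def __init__(self, resolution: float = 0.4, k_neighbors: int = 20,
                 prune: float = 1 / 15, random_state: int = 0,
                 group_singletons: bool = True):
        self.resolution = resolution
        self.k_neighbors = k_neighbors
        self.prune = prune
        self.random_state = random_state
        self.group_singletons = group_singletons

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n = X.shape[0]
        if n < self.k_neighbors + 1:
            raise ValidationError(
                f"need at least k_neighbors+1={self.k_neighbors + 1} cells, got {n}")
        nn = NearestNeighbors(n_neighbors=self.k_neighbors + 1).fit(X)
        _, knn = nn.kneighbors(X)
        knn = knn[:, 1:]  # drop self
        neighbor_sets = [set(row) | {i} for i, row in enumerate(knn)]
        edges, weights = [], []
        for i in range(n):
            for j in knn[i]:
                if i < j:
                    inter = len(neighbor_sets[i] & neighbor_sets[j])
                    union = len(neighbor_sets[i] | neighbor_sets[j])
                    w = inter / union
                    if w >= self.prune:
                        edges.append((i, int(j)))
                        weights.append(w)
        graph = ig.Graph(n=n, edges=edges)
        graph.es["weight"] = weights
        part = leidenalg.find_partition(
            graph, leidenalg.RBConfigurationVertexPartition,
            weights="weight", resolution_parameter=self.resolution,
            seed=int(self.random_state), n_iterations=3)
        raw = np.asarray(part.membership)
        if self.group_singletons:
            raw = self._absorb_singletons(raw, edges, weights, X)
        sizes = np.bincount(raw)
        order = sorted(range(len(sizes)), key=lambda c: (-sizes[c], c))
        remap = {old: new for new, old in enumerate(order)}
        self.labels_ = np.array([remap[c] for c in raw], dtype=int)
        self.n_clusters_ = len(sizes)
        logger.info("Leiden clustering: %d cells -> %d clusters (resolution %.3g)",
                    n, self.n_clusters_, self.resolution)
        return self

    @staticmethod
    def _absorb_singletons(labels: np.ndarray, edges, weights, X) -> np.ndarray:
        labels = labels.copy()
        while True:
            sizes = np.bincount(labels)
            singles = np.flatnonzero(sizes == 1)
            multis = np.flatnonzero(sizes > 1)
            if singles.size == 0 or multis.size == 0:
                return labels
            moved = False
            for c in singles:
                v = int(np.flatnonzero(labels == c)[0])
                conn: dict[int, float] = {}
                for (i, j), w in zip(edges, weights):
                    other = j if i == v else (i if j == v else None)
                    if other is not None and sizes[labels[other]] > 1:
                        conn[labels[other]] = conn.get(labels[other], 0.0) + w
                if conn:
                    target = max(conn, key=lambda k: (conn[k], -k))
                else:  # disconnected: nearest multi-member centroid
                    dists = [np.linalg.norm(X[labels == m].mean(axis=0) - X[v])
                             for m in multis]
                    target = int(multis[int(np.argmin(dists))])
                labels[v] = target
                moved = True
            if not moved:
                return labels

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# functional wrappers on the genes × cells containers


def lognormalize(counts: CountMatrix, scale_factor: float = 1e4,
                 allow_zero_cells: bool = False) -> NormalizedMatrix:
    """LogNormalize: per-cell scaling to *scale_factor* counts then ln(1+x)."""
    vals = LogNormalizer(scale_factor, allow_zero_cells).fit_transform(counts.values.T)
    return NormalizedMatrix(vals.T, counts.gene_ids, counts.cell_ids, scale_factor)


def select_hvgs(norm: NormalizedMatrix, n: int = 3000, method: str = "variance") -> list[str]:
    """Ids of the *n* most variable genes (ties by lexicographic gene id)."""
    if norm.shape[0] < 1:
        raise ValidationError("need at least one gene")
    sel = HVGSelector(n_genes=n, method=method).fit(norm.values.T, gene_ids=norm.gene_ids)
    keep = set(sel.selected_ids_)
    return [g for g in norm.gene_ids if g in keep]


def scale_genes(norm: NormalizedMatrix, hvgs: list[str] | None = None,
                clip: float = 10.0) -> tuple[np.ndarray, list[str]]:
    """Center/scale (genes × cells in, genes × cells out) with clipping."""
    genes = list(norm.gene_ids) if hvgs is None else list(hvgs)
    missing = set(genes) - set(norm.gene_ids)
    if missing:
        raise ValidationError(f"HVGs not in matrix: {sorted(missing)[:5]}")
    sub = norm.values[norm.gene_index(genes)]
    return GeneScaler(clip=clip).fit_transform(sub.T).T, genes


def run_pca(scaled: np.ndarray, n_components: int = 50, seed: int = 0) -> Embedding:
    """PCA of a genes × cells scaled matrix; returns a cells × components Embedding."""
    emb = PCAEmbedder(n_components=n_components, random_state=seed)
    coords = emb.fit_transform(scaled.T)
    return Embedding(coords, emb.explained_variance_, n_components)


def cluster_cells(embedding: Embedding, resolution: float = 0.4,
                  k_neighbors: int = 20, seed: int = 0) -> np.ndarray:
    """Leiden cluster labels (contiguous ints, decreasing size) for an embedding."""
    clus = SNNLeidenClusterer(resolution=resolution, k_neighbors=k_neighbors,
                              random_state=seed)
    return clus.fit_predict(embedding.coordinates)
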