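"""Differential expression, signature construction, ER-lineage calls.

Two DE routes feed the same signature gates:

* single-cell: per-gene two-sided Wilcoxon rank-sum between cell groups,
  with midrank tie handling — normal approximation (tie-corrected variance,
  continuity correction) for min(n_A, n_B) > 8, exact enumeration of the
  rank-sum null otherwise;
* bulk: Welch t-test on TMM-normalized log2-CPM (pseudocount 0.5).

Benjamini–Hochberg FDR across tested genes throughout (genes with zero total
count are excluded from the bulk background). A gene enters a signature's
up-set iff FDR < 0.05 and fold change > 1.5, the down-set iff FDR < 0.05 and
fold change < 0.67 — strict inequalities on both gates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, GeneSignature, NormalizedMatrix, ValidationError

logger = logging.getLogger("stemscore")

#: largest pooled size for which the exact rank-sum null is enumerated; above
#: it the tie-corrected normal approximation is accurate and far cheaper.
_EXACT_MAX_POOLED = 200


@dataclass(frozen=True)
class DEGates:
    """Selection gates for signature membership (strict inequalities)."""

    max_fdr: float = 0.05
    min_fc_up: float = 1.5
    max_fc_down: float = 0.67

    def __post_init__(self) -> None:
        if not 0 < self.max_fdr < 1:
            raise ValidationError("max_fdr must be in (0, 1)")
        if not self.max_fc_down < 1 < self.min_fc_up:
            raise ValidationError("need max_fc_down < 1 < min_fc_up")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def exact_ranksum_pvalue(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Exact two-sided rank-sum p, ties allowed.

    The null distribution of the group-A midrank sum over all
    C(nA+nB, nA) equally likely group assignments is built by a 0/1-knapsack
    count DP on doubled midranks (so they are integers); the two-sided p is
    ``min(1, 2 * min(P(W <= w), P(W >= w)))``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks2 = np.round(2 * stats.rankdata(pooled)).astype(np.int64)
    n_a = len(a)
    w_obs = int(ranks2[:n_a].sum())
    total = int(ranks2.sum())
    counts = np.zeros((n_a + 1, total + 1))
    counts[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(n_a, 0, -1):
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    dist = counts[n_a]
    n_total = dist.sum()
    p_low = dist[: w_obs + 1].sum() / n_total
    p_high = dist[w_obs:].sum() / n_total
    return float(min(1.0, 2 * min(p_low, p_high)))


def _normal_ranksum_pvalues(ranks: np.ndarray, tie_terms: np.ndarray,
                            n_a: int, n_b: int) -> np.ndarray:
    """Vectorized tie-corrected normal approximation with continuity correction."""
    n = n_a + n_b
    w = ranks[:, :n_a].sum(axis=1)
    mean_w = n_a * (n + 1) / 2.0
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_terms / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var_w, 0.0))
    diff = w - mean_w
    cc = np.clip(np.abs(diff) - 0.5, 0.0, None)  # continuity correction
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, cc / sd, 0.0)
    p = np.where(sd > 0, 2 * stats.norm.sf(z), 1.0)
    return np.minimum(p, 1.0)


def wilcoxon_de(norm: NormalizedMatrix, cells_a, cells_b,
                fc_pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum DE between two cell groups.

    Fold change is computed on ``expm1`` of the mean log-normalized values
    (i.e. back on the depth-normalized scale) with a pseudocount:
    ``fc = (mean_a + pc) / (mean_b + pc)``.

    Returns a DataFrame with columns gene, mean_a, mean_b, frac_a, frac_b,
    fold_change, log2_fc, stat, p_value, fdr.
    """
    cells_a, cells_b = list(cells_a), list(cells_b)
    if not cells_a or not cells_b:
        raise ValidationError("both groups must be non-empty")
    overlap = set(cells_a) & set(cells_b)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)[:5]}")
    lookup = {c: i for i, c in enumerate(norm.cell_ids)}
    ia = np.array([lookup[c] for c in cells_a])
    ib = np.array([lookup[c] for c in cells_b])
    A = norm.values[:, ia]
    B = norm.values[:, ib]
    n_a, n_b = len(cells_a), len(cells_b)
    pooled = np.concatenate([A, B], axis=1)
    ranks = stats.rankdata(pooled, axis=1)

    exact = min(n_a, n_b) <= 8 and (n_a + n_b) <= _EXACT_MAX_POOLED
    if exact:
        p = np.array([exact_ranksum_pvalue(A[g], B[g]) for g in range(A.shape[0])])
    else:
        if min(n_a, n_b) <= 8:
            logger.warning("groups too large for exact enumeration; "
                           "using the normal approximation despite min(n) <= 8")
        tie_terms = np.empty(pooled.shape[0])
        for g in range(pooled.shape[0]):
            _, t = np.unique(pooled[g], return_counts=True)
            tie_terms[g] = np.sum(t ** 3 - t)
        p = _normal_ranksum_pvalues(ranks, tie_terms, n_a, n_b)

    mean_a = np.expm1(A).mean(axis=1)
    mean_b = np.expm1(B).mean(axis=1)
    fc = (mean_a + fc_pseudocount) / (mean_b + fc_pseudocount)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": list(norm.gene_ids),
        "mean_a": mean_a, "mean_b": mean_b,
        "frac_a": (A > 0).mean(axis=1), "frac_b": (B > 0).mean(axis=1),
        "fold_change": fc, "log2_fc": np.log2(fc),
        "stat": ranks[:, :n_a].sum(axis=1),
        "p_value": p, "fdr": fdr,
    })


# ---------------------------------------------------------------------------
# TMM between-sample normalization


def _tmm_pair_factor(obs: np.ndarray, lib_obs: float, ref: np.ndarray,
                     lib_ref: float, m_trim: float = 0.3, a_trim: float = 0.05
                     ) -> float:
    both = (obs > 0) & (ref > 0)
    if both.sum() == 0:
        return 1.0
    o = obs[both] / lib_obs
    r = ref[both] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = (lib_obs - obs[both]) / (lib_obs * obs[both]) \
        + (lib_ref - ref[both]) / (lib_ref * ref[both])
    n = len(m)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    lo_m = np.floor(n * m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * a_trim) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if keep.sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(bulk: CountMatrix) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    The reference sample is the one whose 75th expression percentile (scaled
    by library size) is closest to the mean across samples. M-values are
    trimmed 30% two-sided, A-values 5% two-sided, and the weighted (inverse
    delta-method variance) mean M gives each factor; factors are rescaled to
    multiply to 1.
    """
    X = bulk.values.astype(float)
    if X.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    lib = X.sum(axis=0)
    if np.any(lib == 0):
        raise ValidationError("all-zero sample")
    f75 = np.array([np.quantile(X[:, j] / lib[j], 0.75) for j in range(X.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array([
        _tmm_pair_factor(X[:, j], lib[j], X[:, ref], lib[ref])
        for j in range(X.shape[1])])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=list(bulk.cell_ids), name="tmm_factor")


def log2_cpm(bulk: CountMatrix, factors: pd.Series | None = None,
             prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes."""
    if factors is None:
        factors = tmm_factors(bulk)
    X = bulk.values.astype(float)
    eff_lib = X.sum(axis=0) * factors.to_numpy()
    cpm = (X + prior_count) / (eff_lib + 2 * prior_count)[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm), index=list(bulk.gene_ids),
                        columns=list(bulk.cell_ids))


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone trigamma)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x = max(x - step, 1e-8)
        if abs(step) < 1e-10 * x:
            break
    return x


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to per-gene variances.

    Returns (prior df d0, prior variance s0^2); d0 = inf when the observed
    log-variance spread is no larger than expected from chi-square sampling
    alone (then every gene shares the common variance).
    """
    z = np.log(np.maximum(s2, 1e-12))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def bulk_de(bulk: CountMatrix, group_labels: pd.Series | dict,
            group_a: str = "tumor", group_b: str = "normal",
            moderated: bool = True) -> pd.DataFrame:
    """t-test DE on TMM-normalized log2-CPM, group A vs group B.

    By default the per-gene pooled variance is shrunk toward a common prior
    fitted across genes (empirical-Bayes moderated t, the standard remedy
    for 3-6-replicate bulk designs where the plain t has too few degrees of
    freedom); ``moderated=False`` gives the ordinary Welch t-test. Genes
    with zero counts everywhere are dropped from the tested background. A
    gene with identical normalized values in every sample gets p = 1 by
    convention. Fold change is the ratio of linear-CPM group means.
    """
    labels = pd.Series(group_labels)
    samples = list(bulk.cell_ids)
    ia = [i for i, s in enumerate(samples) if labels.get(s) == group_a]
    ib = [i for i, s in enumerate(samples) if labels.get(s) == group_b]
    if len(ia) < 2 or len(ib) < 2:
        raise ValidationError("need >= 2 replicates per group")
    expressed = bulk.values.sum(axis=1) > 0
    if (~expressed).any():
        logger.info("bulk_de: dropping %d all-zero genes from the background",
                    int((~expressed).sum()))
    lc = log2_cpm(bulk).to_numpy()[expressed]
    genes = [g for g, e in zip(bulk.gene_ids, expressed) if e]
    A, B = lc[:, ia], lc[:, ib]
    n_a, n_b = len(ia), len(ib)
    diff = A.mean(axis=1) - B.mean(axis=1)

    if moderated:
        df_resid = n_a + n_b - 2
        s2 = (A.var(axis=1, ddof=1) * (n_a - 1)
              + B.var(axis=1, ddof=1) * (n_b - 1)) / df_resid
        d0, s0_sq = _fit_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
        se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
        with np.errstate(invalid="ignore", divide="ignore"):
            t_stat = diff / se
        if np.isinf(df_total):
            p = 2 * stats.norm.sf(np.abs(t_stat))
        else:
            p = 2 * stats.t.sf(np.abs(t_stat), df_total)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            t_stat, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, np.asarray(p))
    t_stat = np.where(degenerate, 0.0, np.asarray(t_stat))
    cpm_a = (2.0 ** A).mean(axis=1)
    cpm_b = (2.0 ** B).mean(axis=1)
    fc = cpm_a / cpm_b
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": genes, "mean_a": cpm_a, "mean_b": cpm_b,
        "fold_change": fc, "log2_fc": np.log2(fc),
        "stat": t_stat, "p_value": p, "fdr": fdr,
    })


# ---------------------------------------------------------------------------
# signatures


def build_signature(de: pd.DataFrame, gates: DEGates = DEGates(),
                    name: str = "signature") -> GeneSignature:
    """Apply the FDR/fold-change gates to a DE table (strict inequalities)."""
    ok = de["fdr"] < gates.max_fdr
    up = de.loc[ok & (de["fold_change"] > gates.min_fc_up), "gene"].tolist()
    down = de.loc[ok & (de["fold_change"] < gates.max_fc_down), "gene"].tolist()
    if not up and not down:
        logger.warning("signature %s is empty at the configured gates", name)
    return GeneSignature(name, tuple(up), tuple(down))


def augment_signature(sig: GeneSignature, curated_genes,
                      universe=None) -> GeneSignature:
    """Union curated marker genes into the up-set.

    Curated genes not in *universe* (when given) are dropped with a warning;
    a curated gene currently in the down-set is moved to the up-set (curated
    membership wins), logged.
    """
    curated = list(dict.fromkeys(curated_genes))
    if universe is not None:
        known = set(universe)
        missing = [g for g in curated if g not in known]
        if missing:
            logger.warning("augment_signature: %d curated genes not in the gene "
                           "universe, dropped: %s", len(missing), missing[:5])
        curated = [g for g in curated if g in known]
    moved = [g for g in curated if g in sig.down_genes]
    if moved:
        logger.warning("augment_signature: moving %s from down to up set", moved)
    down = tuple(g for g in sig.down_genes if g not in moved)
    up = tuple(dict.fromkeys([*sig.up_genes, *curated]))
    return GeneSignature(sig.name, up, down)


def classify_er_lineage(norm: NormalizedMatrix, clusters: pd.Series,
                        er_gene: str = "Esr1", expr_threshold: float = 0.5
                        ) -> tuple[dict, pd.Series]:
    """Call each cluster ER-high or ER-low by its Esr1-positive fraction.

    A cluster is ER-high iff the fraction of its cells with a nonzero
    ``er_gene`` value exceeds *expr_threshold*; every cell inherits its
    cluster's label. Returns (per-cluster labels, per-cell labels).
    """
    if er_gene not in norm.gene_ids:
        raise ValidationError(f"{er_gene!r} not in gene universe")
    if expr_threshold <= 0:
        logger.warning("expr_threshold <= 0: any expressing cell makes a "
                       "cluster ER-high (degenerate)")
    clusters = pd.Series(clusters)
    expr = pd.Series(norm.values[norm.gene_index([er_gene])[0]] > 0,
                     index=list(norm.cell_ids))
    cluster_labels = {}
    for cl, members in clusters.groupby(clusters):
        frac = expr.loc[members.index].mean()
        cluster_labels[cl] = "ERhigh" if frac > expr_threshold else "ERlow"
    per_cell = clusters.map(cluster_labels)
    per_cell.name = "er_lineage"
    return cluster_labels, per_cell
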