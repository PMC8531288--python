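"""Per-cell QC metrics and compartment-specific cell filtration.

Epithelial and immune cells in staged mammary-tumor scRNA-seq differ markedly
in library size and detected-gene counts, so filtration is applied with
different criteria per compartment (compartment assignment — from marker-based
annotation or supplied metadata — precedes filtration). All bounds are strict
inequalities; a cell sitting exactly on a boundary is removed.

Shipped presets::

    MOUSE_EPITHELIAL  n_count > 5000, n_feature > 2000, pct_mito < 0.08
    MOUSE_IMMUNE      n_count > 1000, n_feature > 500,  pct_mito < 0.08
    HUMAN             n_feature > 400, n_feature < 7000, pct_mito < 0.20
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, ValidationError

logger = logging.getLogger("stemscore")


@dataclass(frozen=True)
class QCCriteria:
    """Strict per-cell bounds. ``None`` disables a bound.

    ``pct_mito`` is a fraction in [0, 1]; the conventional "<8%" maps to 0.08.
    """

    min_counts: int | None = None
    min_genes: int | None = None
    max_genes: int | None = None
    max_pct_mito: float | None = None

    def __post_init__(self) -> None:
        for b in (self.min_counts, self.min_genes, self.max_genes):
            if b is not None and b < 0:
                raise ValidationError("QC bounds must be non-negative")
        if (self.min_genes is not None and self.max_genes is not None
                and not self.min_genes < self.max_genes):
            raise ValidationError("min_genes must be < max_genes")
        if self.max_pct_mito is not None and not 0 < self.max_pct_mito <= 1:
            raise ValidationError("max_pct_mito must be in (0, 1]")


MOUSE_EPITHELIAL = QCCriteria(min_counts=5000, min_genes=2000, max_pct_mito=0.08)
MOUSE_IMMUNE = QCCriteria(min_counts=1000, min_genes=500, max_pct_mito=0.08)
HUMAN = QCCriteria(min_genes=400, max_genes=7000, max_pct_mito=0.20)

PRESETS = {"epithelial": MOUSE_EPITHELIAL, "immune": MOUSE_IMMUNE, "human": HUMAN}


def compute_qc_metrics(counts: CountMatrix, mito_prefix: str = "mt-") -> pd.DataFrame:
    """n_count, n_feature and pct_mito per cell.

    ``pct_mito`` is mito counts over total counts, 0 (with ``zero_total``
    flagged) for empty cells. Mitochondrial genes are recognized by id prefix.
    """
    vals = counts.values
    n_count = vals.sum(axis=0)
    n_feature = (vals > 0).sum(axis=0)
    mito_mask = np.array([g.startswith(mito_prefix) for g in counts.gene_ids])
    if not mito_mask.any():
        logger.warning("no gene id matches mito prefix %r; pct_mito will be 0", mito_prefix)
    mito_counts = vals[mito_mask].sum(axis=0) if mito_mask.any() else np.zeros_like(n_count)
    zero_total = n_count == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(zero_total, 0.0, mito_counts / np.maximum(n_count, 1))
    if zero_total.any():
        logger.warning("%d cells have zero total counts", int(zero_total.sum()))
    return pd.DataFrame({
        "cell_id": list(counts.cell_ids),
        "n_count": n_count.astype(int),
        "n_feature": n_feature.astype(int),
        "pct_mito": pct_mito,
        "zero_total": zero_total,
    })


def filter_cells(metrics: pd.DataFrame, criteria: QCCriteria
                 ) -> tuple[list[str], dict[str, int]]:
    """Apply strict QC bounds; a cell is kept iff it passes every bound.

    Returns the kept cell ids (input order) and per-criterion removal counts;
    a cell failing several criteria is counted once under each.
    """
    checks = {}
    if criteria.min_counts is not None:
        checks["min_counts"] = metrics["n_count"] > criteria.min_counts
    if criteria.min_genes is not None:
        checks["min_genes"] = metrics["n_feature"] > criteria.min_genes
    if criteria.max_genes is not None:
        checks["max_genes"] = metrics["n_feature"] < criteria.max_genes
    if criteria.max_pct_mito is not None:
        checks["max_pct_mito"] = metrics["pct_mito"] < criteria.max_pct_mito
    keep = np.ones(len(metrics), dtype=bool)
    removal_counts = {}
    for name, passed in checks.items():
        passed = passed.to_numpy()
        removal_counts[name] = int((~passed).sum())
        keep &= passed
    kept = metrics.loc[keep, "cell_id"].tolist()
    logger.info("QC filter: kept %d/%d cells; removals per criterion: %s",
                len(kept), len(metrics), removal_counts)
    return kept, removal_counts
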