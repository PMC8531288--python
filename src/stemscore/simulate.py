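"""Synthetic data with planted ground truth.

Emulates the statistical structure of a staged mouse mammary-tumor scRNA-seq
study without requiring any download: negative-binomial counts over four
progression stages (W07/W09/W11/W17), an epithelial and an immune compartment
with different sequencing depth and mitochondrial-content profiles, distinct
marker-driven cell types including a stem-like epithelial subpopulation,
planted cancer-signature up/down genes whose expression is shifted in
cancerous cells, matched tumor-vs-normal bulk replicates over the same gene
universe, and a survival cohort whose hazard depends on signature expression.

Counts are gamma–Poisson: for mean ``mu`` and dispersion ``d`` the variance is
``mu + d * mu**2`` (the standard overdispersed RNA-seq model). Each cell draws
a lognormal library size by compartment and a Beta-distributed mitochondrial
fraction; per-gene relative abundances come from a shared lognormal baseline,
with marker genes set to a low baseline weight and multiplied by their fold
change in their own cell type, and planted signature genes multiplied/divided
by ``signature_effect`` in cancer cells.

One global seed drives a per-stage ``SeedSequence`` spawn, so stages are
independently reproducible. Everything here is deterministic given the seed.

Not simulated: doublets, ambient RNA, batch effects, or realistic
transcriptome-wide correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSignature, ValidationError

STAGES = ("W07", "W09", "W11", "W17")

MITO_GENES = (
    "Nd1", "Nd2", "Co1", "Co2", "Atp8", "Atp6", "Co3",
    "Nd3", "Nd4l", "Nd4", "Nd5", "Nd6", "Cytb",
)


@dataclass(frozen=True)
class CellTypeSpec:
    """One simulated cell type.

    ``proportion`` is the fraction of the compartment occupied by this type
    (for epithelial non-stem types, relative to the non-stem remainder — see
    :class:`SimConfig`). ``named_markers`` are real gene symbols to include
    among the type's markers (e.g. Esr1 for the ER-high luminal type); the
    rest are auto-named ``<type>.mk<i>``.
    """

    name: str
    compartment: str  # "epithelial" | "immune"
    proportion: float
    n_markers: int = 25
    marker_fold: float = 40.0
    named_markers: tuple[str, ...] = ()


def _default_cell_types() -> tuple[CellTypeSpec, ...]:
    return (
        CellTypeSpec("LuminalER", "epithelial", 0.3125,
                     named_markers=("Esr1", "Foxa1", "Gata3", "Pgr")),
        CellTypeSpec("LuminalAV", "epithelial", 0.4375),
        CellTypeSpec("Basal", "epithelial", 0.25, named_markers=("Krt5", "Krt14")),
        CellTypeSpec("Stem", "epithelial", 0.0,  # proportion comes from stem_fraction
                     named_markers=("Cxcl1", "Cxcl16", "Cd24a", "Procr")),
        CellTypeSpec("Tcell", "immune", 0.5, named_markers=("Cd3e", "Cd3d", "Cxcr6")),
        CellTypeSpec("Macrophage", "immune", 0.5, named_markers=("Cd68", "Adgre1", "Cxcr2")),
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the single-cell simulator (shared with the bulk one)."""

    n_genes: int = 5000
    cells_per_stage: Mapping[str, int] = field(
        default_factory=lambda: {s: 500 for s in STAGES})
    epithelial_fraction: Mapping[str, float] = field(
        default_factory=lambda: {s: 0.6 for s in STAGES})
    cell_types: tuple[CellTypeSpec, ...] = field(default_factory=_default_cell_types)
    stem_type: str = "Stem"
    stem_fraction: float = 0.2
    cancer_fraction_by_stage: Mapping[str, float] = field(
        default_factory=lambda: {"W07": 0.2, "W09": 0.4, "W11": 0.6, "W17": 0.8})
    n_signature_up: int = 30
    n_signature_down: int = 30
    signature_effect: float = 8.0
    nb_dispersion: float = 0.1
    depth_mean: Mapping[str, float] = field(
        default_factory=lambda: {"epithelial": 12000.0, "immune": 3500.0})
    depth_sigma: Mapping[str, float] = field(
        default_factory=lambda: {"epithelial": 0.45, "immune": 0.45})
    mito_fraction_mean: Mapping[str, float] = field(
        default_factory=lambda: {"epithelial": 0.04, "immune": 0.05})
    mito_fraction_concentration: float = 60.0
    mito_prefix: str = "mt-"
    marker_baseline_weight: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if not 0 <= self.stem_fraction <= 1:
            raise ValidationError("stem_fraction must be in [0, 1]")
        for m, what in ((self.epithelial_fraction, "epithelial_fraction"),
                        (self.cancer_fraction_by_stage, "cancer_fraction_by_stage"),
                        (self.mito_fraction_mean, "mito_fraction_mean")):
            for k, v in m.items():
                if not 0 <= v <= 1:
                    raise ValidationError(f"{what}[{k}]={v} outside [0, 1]")
        for m in (self.depth_mean, self.depth_sigma):
            for k, v in m.items():
                if v <= 0:
                    raise ValidationError(f"depth parameter {k}={v} must be positive")
        if self.signature_effect <= 0:
            raise ValidationError("signature_effect must be positive")
        for ct in self.cell_types:
            if ct.compartment not in ("epithelial", "immune"):
                raise ValidationError(f"unknown compartment {ct.compartment!r}")
            if not 0 <= ct.proportion <= 1:
                raise ValidationError(f"cell type {ct.name}: proportion outside [0, 1]")
        names = [ct.name for ct in self.cell_types]
        if len(set(names)) != len(names):
            raise ValidationError("cell type names must be unique")
        if self.stem_type not in names:
            raise ValidationError(f"stem_type {self.stem_type!r} not among cell types")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for downstream tests.

    ``cells`` has one row per cell: cell_id, stage, compartment, cell_type,
    is_stem, is_cancer. ``up_genes``/``down_genes`` are the planted cancer
    signature. ``markers`` maps cell-type name to its marker gene tuple.
    ``subjects`` (cohorts only) has subject_id and true hazard group.
    """

    cells: pd.DataFrame | None = None
    up_genes: tuple[str, ...] = ()
    down_genes: tuple[str, ...] = ()
    markers: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    subjects: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# gene universe


def _build_universe(config: SimConfig):
    """Assign gene names, marker sets, mito genes, planted signature genes
    and the shared baseline abundance weights.

    Driven by its own seed stream derived from ``config.seed`` only, so the
    single-cell and bulk simulators plant the *same* signature genes and
    baseline abundances — bulk tumor-vs-normal DE must recover the genes
    that are shifted in the single-cell cancer cells.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    markers: dict[str, list[str]] = {}
    gene_ids: list[str] = []
    for ct in config.cell_types:
        mk = list(ct.named_markers)
        while len(mk) < ct.n_markers:
            mk.append(f"{ct.name}.mk{len(mk) + 1}")
        mk = mk[: ct.n_markers]
        markers[ct.name] = mk
        gene_ids.extend(mk)
    mito = [config.mito_prefix + g for g in MITO_GENES]
    gene_ids.extend(mito)
    n_filler = config.n_genes - len(gene_ids)
    if n_filler < config.n_signature_up + config.n_signature_down:
        raise ValidationError(
            "n_genes too small for the configured markers, mito genes and signature")
    filler = [f"gene{i:05d}" for i in range(1, n_filler + 1)]
    gene_ids.extend(filler)

    sig_pool = rng.permutation(n_filler)
    up = tuple(sorted(filler[i] for i in sig_pool[: config.n_signature_up]))
    down = tuple(sorted(
        filler[i] for i in
        sig_pool[config.n_signature_up: config.n_signature_up + config.n_signature_down]))

    weights = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    idx = {g: i for i, g in enumerate(gene_ids)}
    for mk in markers.values():  # markers rare outside their own type
        weights[[idx[g] for g in mk]] = config.marker_baseline_weight
    weights[[idx[g] for g in mito]] = 0.0  # handled via mito fraction
    return gene_ids, idx, {k: tuple(v) for k, v in markers.items()}, mito, up, down, weights


def _stage_layout(config: SimConfig, stage: str, rng: np.random.Generator):
    """Deterministic per-stage assignment of compartment, type, stem, cancer."""
    n = int(config.cells_per_stage[stage])
    n_epi = int(round(n * config.epithelial_fraction[stage]))
    n_imm = n - n_epi

    def allocate(specs: Sequence[CellTypeSpec], total: int) -> list[int]:
        props = np.array([s.proportion for s in specs], dtype=float)
        if props.sum() <= 0:
            raise ValidationError("cell-type proportions sum to zero")
        props = props / props.sum()
        counts = np.floor(props * total).astype(int)
        rema = props * total - counts
        for i in np.argsort(-rema)[: total - counts.sum()]:
            counts[i] += 1
        return counts.tolist()

    epi_specs = [ct for ct in config.cell_types
                 if ct.compartment == "epithelial" and ct.name != config.stem_type]
    stem_spec = next(ct for ct in config.cell_types if ct.name == config.stem_type)
    n_stem = int(round(n_epi * config.stem_fraction))
    epi_counts = allocate(epi_specs, n_epi - n_stem)
    imm_specs = [ct for ct in config.cell_types if ct.compartment == "immune"]
    imm_counts = allocate(imm_specs, n_imm) if n_imm else [0] * len(imm_specs)

    types: list[CellTypeSpec] = []
    for spec, cnt in zip(epi_specs, epi_counts):
        types.extend([spec] * cnt)
    types.extend([stem_spec] * n_stem)
    for spec, cnt in zip(imm_specs, imm_counts):
        types.extend([spec] * cnt)

    is_stem = np.array([t.name == config.stem_type for t in types])
    is_epi = np.array([t.compartment == "epithelial" for t in types])

    # cancer: stem cells first, then random non-stem epithelial cells
    n_cancer = int(round(n_epi * config.cancer_fraction_by_stage[stage]))
    is_cancer = np.zeros(n, dtype=bool)
    stem_idx = np.flatnonzero(is_stem)
    take = min(n_cancer, stem_idx.size)
    is_cancer[stem_idx[:take]] = True
    if n_cancer > take:
        rest = np.flatnonzero(is_epi & ~is_stem)
        extra = rng.choice(rest, size=min(n_cancer - take, rest.size), replace=False)
        is_cancer[extra] = True
    return types, is_stem, is_cancer


def simulate_single_cell(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Generate a staged single-cell count matrix with planted structure.

    Returns the counts, a cell table (cell_id, stage, compartment, cell_type)
    and the :class:`GroundTruth`.
    """
    root = np.random.SeedSequence(config.seed)
    gene_ids, idx, markers, mito, up, down, base_w = _build_universe(config)
    up_idx = np.array([idx[g] for g in up], dtype=int)
    down_idx = np.array([idx[g] for g in down], dtype=int)
    mito_idx = np.array([idx[g] for g in mito], dtype=int)

    stage_seeds = root.spawn(1 + len(STAGES))[1:]
    blocks, rows = [], []
    truth_rows = []
    for stage, seed in zip(STAGES, stage_seeds):
        rng = np.random.default_rng(seed)
        types, is_stem, is_cancer = _stage_layout(config, stage, rng)
        n = len(types)
        depth = np.array([
            rng.lognormal(np.log(config.depth_mean[t.compartment])
                          - config.depth_sigma[t.compartment] ** 2 / 2,
                          config.depth_sigma[t.compartment]) for t in types])
        conc = config.mito_fraction_concentration
        mfrac = np.array([
            rng.beta(config.mito_fraction_mean[t.compartment] * conc,
                     (1 - config.mito_fraction_mean[t.compartment]) * conc)
            for t in types])

        mu = np.empty((config.n_genes, n))
        for c, t in enumerate(types):
            w = base_w.copy()
            w[[idx[g] for g in markers[t.name]]] *= t.marker_fold
            if is_cancer[c]:
                w[up_idx] *= config.signature_effect
                w[down_idx] /= config.signature_effect
            w = w / w.sum() * (1 - mfrac[c])
            w[mito_idx] = mfrac[c] / len(mito_idx)
            mu[:, c] = depth[c] * w
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
        blocks.append(rng.poisson(lam).astype(np.int64))

        for c, t in enumerate(types):
            cid = f"{stage}_c{c + 1:05d}"
            rows.append({"cell_id": cid, "stage": stage,
                         "compartment": t.compartment, "cell_type": t.name})
            truth_rows.append({"cell_id": cid, "stage": stage,
                               "compartment": t.compartment, "cell_type": t.name,
                               "is_stem": bool(is_stem[c]), "is_cancer": bool(is_cancer[c])})

    counts = np.concatenate(blocks, axis=1)
    cells = pd.DataFrame(rows)
    truth = GroundTruth(cells=pd.DataFrame(truth_rows), up_genes=up, down_genes=down,
                        markers=markers)
    cm = CountMatrix(counts, tuple(gene_ids), tuple(cells["cell_id"]))
    return cm, cells, truth


# ---------------------------------------------------------------------------
# bulk replicates


def simulate_bulk(config: SimConfig, n_reps: int = 4, depth: float = 3e5,
                  fold: float | None = None, dispersion: float = 0.05
                  ) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Tumor-vs-normal bulk replicates over the same gene universe.

    The planted signature up-genes are multiplied by *fold* (default
    ``config.signature_effect``) and the down-genes divided by it in the
    tumor group. With ``fold == 1`` nothing is planted and the ground-truth
    gene lists are empty. Bulk replicates of genetically matched animals are
    far less dispersed than single cells, so the NB *dispersion* defaults to
    0.05 rather than the single-cell value.
    """
    if n_reps < 2:
        raise ValidationError("need >= 2 replicates per group")
    if dispersion <= 0:
        raise ValidationError("dispersion must be positive")
    fold = config.signature_effect if fold is None else float(fold)
    if fold <= 0:
        raise ValidationError("fold must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    gene_ids, idx, markers, mito, up, down, base_w = _build_universe(config)
    up_idx = np.array([idx[g] for g in up], dtype=int)
    down_idx = np.array([idx[g] for g in down], dtype=int)
    mito_idx = np.array([idx[g] for g in mito], dtype=int)

    base_w = base_w.copy()
    base_w[mito_idx] = config.marker_baseline_weight  # bulk has no mito bookkeeping
    w_tumor = base_w.copy()
    w_tumor[up_idx] *= fold
    w_tumor[down_idx] /= fold

    cols, labels = [], []
    shape = 1.0 / dispersion
    for group, w in (("normal", base_w), ("tumor", w_tumor)):
        p = w / w.sum()
        for r in range(1, n_reps + 1):
            lib = rng.lognormal(np.log(depth), 0.15)
            mu = lib * p
            cols.append(rng.poisson(rng.gamma(shape, mu / shape)))
            labels.append({"sample_id": f"{group}_{r}", "group": group})
    counts = np.stack(cols, axis=1).astype(np.int64)
    samples = pd.DataFrame(labels)
    planted_up = up if fold != 1.0 else ()
    planted_down = down if fold != 1.0 else ()
    truth = GroundTruth(up_genes=planted_up, down_genes=planted_down, markers=markers)
    cm = CountMatrix(counts, tuple(gene_ids), tuple(samples["sample_id"]))
    return cm, samples, truth


# ---------------------------------------------------------------------------
# survival cohort


def simulate_cohort(n_subjects: int = 200, hazard_ratio: float = 3.0,
                    censor_rate: float = 0.2, seed: int = 0, n_genes: int = 100,
                    n_signature_genes: int = 10, expression_effect: float = 3.0,
                    baseline_hazard: float = 0.05
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GeneSignature, GroundTruth]:
    """Survival cohort with a signature-dependent hazard.

    Half of the subjects (the planted "high" group) express the signature
    genes *expression_effect*-fold higher and have their exponential event
    hazard multiplied by *hazard_ratio*. Censoring times are independent
    exponentials with rate ``baseline_hazard * censor_rate / (1 - censor_rate)``
    (≈ *censor_rate* fraction censored at hazard_ratio 1); ``censor_rate = 0``
    disables censoring so every event indicator is 1.

    Returns (cohort table, genes × subjects expression, signature, truth).
    """
    if n_subjects < 4:
        raise ValidationError("need >= 4 subjects")
    if hazard_ratio <= 0 or baseline_hazard <= 0:
        raise ValidationError("hazard parameters must be positive")
    if not 0 <= censor_rate < 1:
        raise ValidationError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    gene_ids = [f"sg{i:03d}" for i in range(1, n_genes + 1)]
    sig_genes = tuple(gene_ids[:n_signature_genes])
    subjects = [f"subj{i:04d}" for i in range(1, n_subjects + 1)]
    high = np.zeros(n_subjects, dtype=bool)
    high[rng.choice(n_subjects, size=n_subjects // 2, replace=False)] = True

    base = rng.lognormal(1.0, 0.5, size=n_genes)
    expr = rng.lognormal(np.log(base)[:, None], 0.3, size=(n_genes, n_subjects))
    expr[:n_signature_genes, high] *= expression_effect

    hazard = baseline_hazard * np.where(high, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n_subjects)
    else:
        t_cens = np.full(n_subjects, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    cohort = pd.DataFrame({"subject_id": subjects, "time": time, "event": event})
    expr_df = pd.DataFrame(expr, index=gene_ids, columns=subjects)
    truth = GroundTruth(subjects=pd.DataFrame({"subject_id": subjects, "high_hazard": high}))
    sig = GeneSignature("planted_survival", sig_genes)
    return cohort, expr_df, sig, truth
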