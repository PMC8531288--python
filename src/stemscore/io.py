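"""Core data model and file I/O.

The pipeline's containers are deliberately small and explicit:

* :class:`CountMatrix` — integer gene × cell (or gene × sample) counts,
  read from / written to MatrixMarket coordinate files plus one-id-per-line
  gene and cell TSVs (the triplet layout used by droplet scRNA-seq tools).
* :class:`NormalizedMatrix` — log-normalized expression on the same axes.
* :class:`GeneSignature` — a named up-gene list with an optional down-gene
  list, serialized as GMT (down-sets via the ``_UP``/``_DN`` suffix
  convention, since GMT has no native down-set field).

MatrixMarket indices are 1-based on disk; everything in memory is 0-based.
Conversion happens only inside :func:`read_count_matrix` /
:func:`write_count_matrix` (scipy handles it).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger("stemscore")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """An in-memory object violates a type invariant or precondition."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dup = pd.Index(ids)
        dup = dup[dup.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dup}")


@dataclass(frozen=True)
class CountMatrix:
    """Dense non-negative integer expression matrix, genes × cells.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_cells)
        Raw counts; must be integral and >= 0.
    gene_ids, cell_ids : sequence of str
        Unique axis identifiers, in matrix order.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if scipy.sparse.issparse(self.values):  # keep the API forgiving
            vals = self.values.toarray()
        if vals.ndim != 2:
            raise ValidationError("count matrix must be 2-D")
        if np.any(vals < 0):
            raise ValidationError("negative counts are not allowed")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("counts must be integral")
        object.__setattr__(self, "values", vals.astype(np.int64))
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.cell_ids, "cell_ids")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match id lists "
                f"({len(self.gene_ids)} genes, {len(self.cell_ids)} cells)"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, cell_ids: Sequence[str]) -> "CountMatrix":
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        idx = np.array([lookup[c] for c in cell_ids], dtype=int)
        return CountMatrix(self.values[:, idx], self.gene_ids, tuple(cell_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.cell_ids))


@dataclass(frozen=True)
class NormalizedMatrix:
    """Log-normalized expression matrix (genes × cells).

    ``values[g, c] = ln(1 + count[g, c] * scale_factor / total[c])``; zeros in
    the source counts stay exactly zero.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValidationError("normalized matrix must be 2-D")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValidationError("normalized values must be finite and >= 0")
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be positive")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.cell_ids, "cell_ids")
        if vals.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("shape does not match id lists")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, cell_ids: Sequence[str]) -> "NormalizedMatrix":
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        idx = np.array([lookup[c] for c in cell_ids], dtype=int)
        return NormalizedMatrix(self.values[:, idx], self.gene_ids, tuple(cell_ids), self.scale_factor)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with up-regulated and (optionally) down-regulated members."""

    name: str
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        up = tuple(dict.fromkeys(str(g) for g in self.up_genes))
        dn = tuple(dict.fromkeys(str(g) for g in self.down_genes))
        if len(up) != len(self.up_genes) or len(dn) != len(self.down_genes):
            logger.warning("signature %s: duplicate genes removed", self.name)
        overlap = set(up) & set(dn)
        if overlap:
            raise ValidationError(
                f"signature {self.name}: up/down sets overlap: {sorted(overlap)[:5]}"
            )
        object.__setattr__(self, "up_genes", up)
        object.__setattr__(self, "down_genes", dn)


# ---------------------------------------------------------------------------
# MatrixMarket triplet I/O


def read_count_matrix(matrix_path, genes_path, cells_path) -> CountMatrix:
    """Read a MatrixMarket counts file with its gene/cell id TSVs.

    The first column of each id file is used; ids are taken in file order.
    Missing coordinate entries are zero.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    genes = _read_id_file(genes_path)
    cells = _read_id_file(cells_path)
    mat = mat.toarray() if scipy.sparse.issparse(mat) else np.asarray(mat)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix is {mat.shape[0]}×{mat.shape[1]} but id files list "
            f"{len(genes)} genes and {len(cells)} cells"
        )
    if np.any(mat < 0):
        raise ValidationError("negative entries in count matrix")
    if not np.allclose(mat, np.round(mat)):
        raise ValidationError("fractional entries in count matrix")
    logger.info("read counts %s: %d genes × %d cells", matrix_path, len(genes), len(cells))
    return CountMatrix(mat, tuple(genes), tuple(cells))


def _read_id_file(path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def write_count_matrix(cm: CountMatrix, matrix_path, genes_path, cells_path) -> None:
    """Write the triplet (MTX coordinate integer + id TSVs)."""
    sparse = scipy.sparse.coo_matrix(cm.values)
    scipy.io.mmwrite(str(matrix_path), sparse, field="integer")
    Path(genes_path).write_text("".join(g + "\n" for g in cm.gene_ids))
    Path(cells_path).write_text("".join(c + "\n" for c in cm.cell_ids))


# ---------------------------------------------------------------------------
# GMT gene-set I/O


def read_gmt(path, merge_up_down: bool = True) -> list[GeneSignature]:
    """Parse a GMT file into signatures.

    Each line is ``name<TAB>description<TAB>gene1<TAB>...``. When
    *merge_up_down* is true, line pairs named ``X_UP`` / ``X_DN`` are merged
    into one signature ``X`` with the ``_DN`` genes as the down-set.
    """
    raw: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: GMT line has {len(fields)} fields, need >= 3")
            name, genes = fields[0], fields[2:]
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning("GMT %s line %d (%s): duplicate genes dropped", path, ln, name)
            raw.append((name, deduped))

    if not merge_up_down:
        return [GeneSignature(name, tuple(genes)) for name, genes in raw]

    by_name = dict(raw)
    done: set[str] = set()
    out: list[GeneSignature] = []
    for name, genes in raw:
        if name in done:
            continue
        if name.endswith("_UP") and name[:-3] + "_DN" in by_name:
            base = name[:-3]
            out.append(GeneSignature(base, tuple(genes), tuple(by_name[base + "_DN"])))
            done.update({name, base + "_DN"})
        elif name.endswith("_DN") and name[:-3] + "_UP" in by_name:
            base = name[:-3]
            out.append(GeneSignature(base, tuple(by_name[base + "_UP"]), tuple(genes)))
            done.update({name, base + "_UP"})
        else:
            out.append(GeneSignature(name, tuple(genes)))
            done.add(name)
    return out


def write_gmt(signatures: Iterable[GeneSignature], path, description: str = "na") -> None:
    lines = []
    for sig in signatures:
        if sig.down_genes:
            lines.append("\t".join([sig.name + "_UP", description, *sig.up_genes]))
            lines.append("\t".join([sig.name + "_DN", description, *sig.down_genes]))
        else:
            lines.append("\t".join([sig.name, description, *sig.up_genes]))
    Path(path).write_text("".join(l + "\n" for l in lines))


# ---------------------------------------------------------------------------
# Tables and run configuration


def write_table(rows, path) -> None:
    """Write rectangular records as CSV with a header.

    Accepts a DataFrame or a sequence of dicts (all with identical key sets —
    ragged records are rejected). Numerics round-trip at 12 significant
    digits; the column order of the first record is preserved.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            keys = list(rows[0].keys())
            for i, r in enumerate(rows):
                if list(r.keys()) != keys:
                    raise ValidationError(f"ragged records: row {i} keys differ from row 0")
            df = pd.DataFrame(rows, columns=keys)
        else:
            df = pd.DataFrame()
    df.to_csv(path, index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def load_run_config(path) -> dict:
    """Load a JSON or YAML run-configuration mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise FormatError(f"{path}: run configuration must be a mapping")
    return dict(cfg)
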