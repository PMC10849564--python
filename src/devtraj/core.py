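"""Core data model, I/O, QC, normalization, scaling and PCA.

The universal container is :class:`CellTable`: a sparse genes × cells
integer count matrix plus per-cell annotations (sample, age, sex,
genotype, cell type, region) tied to an :class:`~devtraj.ladder.AgeLadder`.
On disk the schema is Matrix Market coordinate format plus row-aligned
TSV tables for genes and cells.

Normalization is log-CPX (counts per ``scale_factor``, log1p) followed by
per-gene standardization with clipping — a fully specified variance
stabilization whose downstream use is only to feed a PC embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA as _SkPCA

from .ladder import AgeLadder

logger = logging.getLogger(__name__)

#: Sentinel for cells without an assigned cell type / region.
UNASSIGNED = "unassigned"

CELL_META_COLUMNS = ("cell_id", "sample_id", "age", "sex", "genotype", "cell_type", "region")


class FormatError(ValueError):
    """Malformed or inconsistent on-disk input."""


class ValidationError(ValueError):
    """Inputs violate a documented precondition or invariant."""


@dataclass
class CellTable:
    """Sparse genes × cells counts with per-cell annotations.

    Invariants: unique gene ids, one metadata row per cell (in column
    order), nonnegative integer counts, and every age label a member of
    the attached ladder.
    """

    counts: sp.spmatrix
    gene_ids: list[str]
    cell_meta: pd.DataFrame
    ladder: AgeLadder

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and (self.counts.data < 0).any():
            raise ValidationError("counts must be nonnegative")
        if self.counts.nnz and not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise ValidationError("counts must be integers")
        self.counts.data = np.asarray(np.round(self.counts.data), dtype=np.int64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Series(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        if self.counts.shape[0] != len(self.gene_ids):
            raise FormatError(
                f"matrix has {self.counts.shape[0]} genes but {len(self.gene_ids)} gene ids"
            )
        meta = self.cell_meta.copy().reset_index(drop=True)
        for col in ("cell_id", "sample_id", "age"):
            if col not in meta.columns:
                raise FormatError(f"cell metadata missing required column {col!r}")
        for col, default in (("sex", "F"), ("genotype", "WT"),
                             ("cell_type", UNASSIGNED), ("region", UNASSIGNED)):
            if col not in meta.columns:
                meta[col] = default
        meta = meta.loc[:, list(CELL_META_COLUMNS)]
        if len(meta) != self.counts.shape[1]:
            raise FormatError(
                f"matrix has {self.counts.shape[1]} cells but metadata has {len(meta)} rows"
            )
        bad_ages = set(meta["age"]) - set(self.ladder.labels)
        if bad_ages:
            raise ValidationError(f"age labels not on ladder: {sorted(bad_ages)}")
        self.cell_meta = meta

    # -- basic properties -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def umi_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def gene_indices(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Indices of the given ids in this table's gene universe (missing ids dropped)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        found = [lookup[g] for g in gene_ids if g in lookup]
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            logger.warning("%d of %d gene ids not in table; ignored", len(missing), len(gene_ids))
        return np.asarray(found, dtype=int)

    def subset_cells(self, mask: np.ndarray) -> "CellTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellTable(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            cell_meta=self.cell_meta.iloc[idx].reset_index(drop=True),
            ladder=self.ladder,
        )

    def subset_genes(self, idx: np.ndarray) -> "CellTable":
        idx = np.asarray(idx)
        return CellTable(
            counts=self.counts[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_meta=self.cell_meta,
            ladder=self.ladder,
        )


@dataclass(frozen=True)
class QcParams:
    """Per-cell QC thresholds.

    Cells are kept when their UMI total lies in ``[min_umi, max_umi]``,
    they express at least ``min_genes`` genes, no single gene exceeds
    ``max_top_gene_frac`` of the cell's UMIs, mitochondrial and ribosomal
    fractions stay at or below their caps, and every flag list in
    ``flag_gene_lists`` other than mito/ribo (immediate-early, apoptotic,
    red-blood-cell markers) stays at or below ``max_flag_frac``.
    """

    min_umi: int = 400
    max_umi: int = 100_000
    min_genes: int = 250
    max_top_gene_frac: float = 0.20
    max_mito_frac: float = 0.10
    max_ribo_frac: float = 0.10
    max_flag_frac: float = 0.01
    flag_gene_lists: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.min_umi < self.max_umi):
            raise ValidationError("need 0 < min_umi < max_umi")
        for name in ("max_top_gene_frac", "max_mito_frac", "max_ribo_frac", "max_flag_frac"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must lie in (0, 1]")


# -- I/O -------------------------------------------------------------------

def read_cell_table(matrix_path: Path, gene_path: Path, cell_path: Path,
                    ladder: AgeLadder) -> CellTable:
    """Read a CellTable from Matrix Market + row-aligned gene/cell TSVs.

    The gene TSV's first column is the gene id; the cell TSV must carry
    ``cell_id, sample_id, age`` and may carry sex, genotype, cell_type and
    region.  Dimension mismatches and duplicate gene ids raise
    :class:`FormatError`; off-ladder ages raise :class:`ValidationError`.
    """
    counts = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    genes = pd.read_csv(gene_path, sep="\t", header=0, dtype=str)
    cells = pd.read_csv(cell_path, sep="\t", header=0, dtype=str)
    if len(genes) != counts.shape[0]:
        raise FormatError(
            f"gene table has {len(genes)} rows; matrix has {counts.shape[0]} genes"
        )
    if len(cells) != counts.shape[1]:
        raise FormatError(
            f"cell table has {len(cells)} rows; matrix has {counts.shape[1]} cells"
        )
    return CellTable(counts=counts, gene_ids=genes.iloc[:, 0].tolist(),
                     cell_meta=cells, ladder=ladder)


def write_cell_table(table: CellTable, matrix_path: Path, gene_path: Path,
                     cell_path: Path) -> None:
    """Write the on-disk schema (MTX + gene/cell TSVs) read by :func:`read_cell_table`."""
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(table.counts), field="integer")
    pd.DataFrame({"gene_id": table.gene_ids}).to_csv(gene_path, sep="\t", index=False)
    table.cell_meta.to_csv(cell_path, sep="\t", index=False)


# -- QC --------------------------------------------------------------------

def _flag_fraction(table: CellTable, gene_ids: Sequence[str],
                   totals: np.ndarray) -> np.ndarray:
    idx = table.gene_indices(gene_ids)
    if idx.size == 0:
        return np.zeros(table.n_cells)
    flagged = np.asarray(table.counts[idx, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, flagged / np.maximum(totals, 1), 0.0)
    return frac


def qc_filter(table: CellTable, params: QcParams) -> CellTable:
    """Drop cells failing any QC rule; genes are untouched.

    Rules (all strict on the "over"/"under" side): UMI total in
    ``[min_umi, max_umi]``; at least ``min_genes`` expressed genes; top
    gene ≤ ``max_top_gene_frac`` of UMIs; mito/ribo fractions ≤ their
    caps; each remaining flag list ≤ ``max_flag_frac``.  Per-rule removal
    counts are logged at INFO level.
    """
    totals = table.umi_per_cell()
    n_genes = table.genes_per_cell()
    top = np.asarray(table.counts.max(axis=0).todense()).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        top_frac = np.where(totals > 0, top / np.maximum(totals, 1), 0.0)

    fails: dict[str, np.ndarray] = {
        "low_umi": totals < params.min_umi,
        "high_umi": totals > params.max_umi,
        "few_genes": n_genes < params.min_genes,
        "top_gene": top_frac > params.max_top_gene_frac,
    }
    lists = dict(params.flag_gene_lists)
    for name, cap in (("mito", params.max_mito_frac), ("ribo", params.max_ribo_frac)):
        if name in lists:
            fails[name] = _flag_fraction(table, lists.pop(name), totals) > cap
    for name, ids in lists.items():
        fails[name] = _flag_fraction(table, ids, totals) > params.max_flag_frac

    keep = np.ones(table.n_cells, dtype=bool)
    for rule, bad in fails.items():
        logger.info("qc rule %-10s removes %d cells", rule, int(bad.sum()))
        keep &= ~bad
    logger.info("qc keeps %d of %d cells", int(keep.sum()), table.n_cells)
    if keep.sum() == 0:
        logger.warning("qc_filter removed every cell")
    return table.subset_cells(keep)


# -- normalization / scaling ----------------------------------------------

def lognormalize(table: CellTable | sp.spmatrix, scale_factor: float = 1e4) -> sp.csr_matrix:
    """log1p of library-size-normalized counts, genes × cells.

    Each entry becomes ``log(1 + count / library_size * scale_factor)``;
    all-zero cells stay all-zero.  Sparsity (the zero pattern) is
    preserved exactly.
    """
    counts = table.counts if isinstance(table, CellTable) else sp.csr_matrix(table)
    mat = sp.csc_matrix(counts, copy=True).astype(np.float64)
    libsize = np.asarray(mat.sum(axis=0)).ravel()
    scale = np.where(libsize > 0, scale_factor / np.maximum(libsize, 1), 0.0)
    mat = mat @ sp.diags(scale)
    mat.data = np.log1p(mat.data)
    return sp.csr_matrix(mat)


def scale_genes(matrix: np.ndarray | sp.spmatrix, clip: float = 10.0) -> np.ndarray:
    """Center each gene row and divide by its n−1 standard deviation, then clip.

    Zero-variance genes map to all-zero rows; values are clipped to
    ``[-clip, clip]``.  Returns a dense array.
    """
    dense = np.asarray(matrix.todense()) if sp.issparse(matrix) else np.array(matrix, dtype=float)
    mean = dense.mean(axis=1, keepdims=True)
    sd = dense.std(axis=1, ddof=1, keepdims=True) if dense.shape[1] > 1 else np.zeros_like(mean)
    out = np.where(sd > 0, (dense - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return np.clip(out, -clip, clip)


def highly_variable_genes(lognorm: sp.spmatrix | np.ndarray, n_top: int = 2000) -> np.ndarray:
    """Indices of the ``n_top`` genes with highest variance of log-normalized values."""
    if sp.issparse(lognorm):
        mat = sp.csr_matrix(lognorm)
        mean = np.asarray(mat.mean(axis=1)).ravel()
        sq = np.asarray(mat.multiply(mat).mean(axis=1)).ravel()
        var = sq - mean**2
    else:
        var = np.var(np.asarray(lognorm), axis=1)
    n_top = min(n_top, var.size)
    # stable order so equal-variance ties resolve by gene index
    order = np.argsort(-var, kind="stable")[:n_top]
    return np.sort(order)


# -- PCA -------------------------------------------------------------------

@dataclass
class Embedding:
    """Cells × components PC scores with per-component variance fractions.

    ``components`` (components × genes) and ``mean`` (per-gene centering
    vector) are retained so new cells can be projected into the same
    space.
    """

    scores: np.ndarray
    variance_fractions: np.ndarray
    cell_index: list[str]
    components: np.ndarray | None = None
    mean: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def subset_components(self, k: int) -> "Embedding":
        return Embedding(self.scores[:, :k], self.variance_fractions[:k],
                         self.cell_index,
                         None if self.components is None else self.components[:k],
                         self.mean)

    def project(self, matrix: np.ndarray) -> np.ndarray:
        """Project new genes × cells data (same gene order) into this space."""
        if self.components is None or self.mean is None:
            raise ValidationError("embedding was built without projection parameters")
        x = np.asarray(matrix, dtype=float).T - self.mean
        return x @ self.components.T


def pca(matrix: np.ndarray | sp.spmatrix, n_components: int,
        cell_index: Sequence[str] | None = None) -> Embedding:
    """PCA of a genes × cells matrix; scores are cells × components.

    Genes are mean-centered; each component's sign is fixed so its
    largest-magnitude gene loading is positive.  ``variance_fractions``
    are relative to the total variance of the centered matrix.
    """
    dense = np.asarray(matrix.todense()) if sp.issparse(matrix) else np.asarray(matrix, float)
    x = dense.T  # cells × genes
    n_cells, n_genes = x.shape
    if n_components > min(n_cells, n_genes):
        raise ValidationError(
            f"n_components={n_components} exceeds min(genes, cells)={min(n_cells, n_genes)}"
        )
    solver = "full" if min(n_cells, n_genes) <= 600 or n_components > min(n_cells, n_genes) // 2 \
        else "randomized"
    fit = _SkPCA(n_components=n_components, svd_solver=solver, random_state=0).fit(x)
    scores = fit.transform(x)
    comps = fit.components_.copy()
    # deterministic sign: largest-|loading| gene positive per component
    for k in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] *= -1
            scores[:, k] *= -1
    if cell_index is None:
        cell_index = [str(i) for i in range(n_cells)]
    return Embedding(scores=scores,
                     variance_fractions=np.asarray(fit.explained_variance_ratio_),
                     cell_index=list(cell_index), components=comps,
                     mean=np.asarray(fit.mean_))
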