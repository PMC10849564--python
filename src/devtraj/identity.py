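"""Soft cell-type classification and identity-ratio quantification.

A correlation-softmax classifier stands in for anchor-based label
transfer: each query cell receives a score per reference cell type
(Pearson correlation to the type's mean profile, negatives clipped to
zero, renormalized to sum 1).  The module's contracts are over the
score matrix itself, so externally computed prediction scores can be
pushed through the same assignment rules:

* reference mapping — assign the top type when its score exceeds 0.6;
* across-age mapping — assign when the top score exceeds 0.8, or when it
  exceeds 0.5 and is at least twice the second-best score;
* identity ratio — (diagonal − best off-diagonal) / diagonal of the
  type-averaged score matrix: 1 means one-to-one mapping, 0 equal
  mapping to two types, negative a mismatch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CellTable, ValidationError, lognormalize, scale_genes


def classify_against_reference(table: CellTable, reference_age: str | None = None,
                               *, clip: float = 10.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end soft classification of all non-reference cells.

    Genes are log-normalized and standardized jointly (standardization
    removes the baseline expression structure shared by all cell types,
    which would otherwise dominate the correlations); reference profiles
    are the per-type means at the reference age (default adult).
    Returns ``(scores, profiles)``.
    """
    ref_age = reference_age or table.ladder.adult
    scaled = scale_genes(lognormalize(table), clip=clip)
    ref_mask = (table.cell_meta["age"] == ref_age).to_numpy()
    if not ref_mask.any():
        raise ValidationError(f"no cells at reference age {ref_age!r}")
    profiles = reference_profiles(scaled[:, np.flatnonzero(ref_mask)],
                                  table.cell_meta.loc[ref_mask, "cell_type"],
                                  table.gene_ids)
    query_idx = np.flatnonzero(~ref_mask)
    query = pd.DataFrame(scaled[:, query_idx], index=table.gene_ids,
                         columns=table.cell_meta.loc[~ref_mask, "cell_id"])
    return soft_classify(query, profiles), profiles


def reference_profiles(norm_matrix, cell_types, gene_ids) -> pd.DataFrame:
    """Mean log-normalized profile per reference cell type (genes × types)."""
    dense = np.asarray(norm_matrix.todense()) if sp.issparse(norm_matrix) \
        else np.asarray(norm_matrix, float)
    cell_types = np.asarray(cell_types)
    cols = {ct: dense[:, cell_types == ct].mean(axis=1)
            for ct in sorted(pd.unique(cell_types))}
    return pd.DataFrame(cols, index=list(gene_ids))


def soft_classify(query: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-cell prediction scores over reference types (rows sum to 1).

    ``query`` is genes × cells (log-normalized), ``profiles`` genes ×
    reference types; both indexed by gene id.  Scores are max(Pearson r,
    0) renormalized; cells with no positive correlation fall back to a
    uniform row.  Requires ≥ 10 shared genes.
    """
    shared = query.index.intersection(profiles.index)
    if len(shared) < 10:
        raise ValidationError(f"only {len(shared)} shared genes (< 10)")
    q = query.loc[shared].to_numpy(dtype=float)
    r = profiles.loc[shared].to_numpy(dtype=float)
    qc = q - q.mean(axis=0)
    rc = r - r.mean(axis=0)
    qn = np.linalg.norm(qc, axis=0)
    rn = np.linalg.norm(rc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (qc.T @ rc) / np.outer(qn, rn)
    corr = np.nan_to_num(corr, nan=0.0)
    pos = np.maximum(corr, 0.0)
    totals = pos.sum(axis=1, keepdims=True)
    uniform = np.full(pos.shape[1], 1.0 / pos.shape[1])
    scores = np.where(totals > 0, pos / np.where(totals > 0, totals, 1.0), uniform)
    return pd.DataFrame(scores, index=query.columns, columns=profiles.columns)


def _top_two(scores: pd.DataFrame) -> tuple[pd.Series, np.ndarray, np.ndarray]:
    mat = scores.to_numpy(dtype=float)
    order = np.argsort(-mat, axis=1, kind="stable")
    top = mat[np.arange(len(mat)), order[:, 0]]
    second = mat[np.arange(len(mat)), order[:, 1]] if mat.shape[1] > 1 \
        else np.zeros(len(mat))
    labels = scores.columns.to_numpy()[order[:, 0]]
    return pd.Series(labels, index=scores.index), top, second


def assign_labels_reference(scores: pd.DataFrame,
                            threshold: float = 0.6) -> pd.Series:
    """Assign the top type when its score strictly exceeds ``threshold``."""
    labels, top, _ = _top_two(scores)
    return labels.where(top > threshold, other="unassigned").rename("cell_type")


def assign_labels_acrossage(scores: pd.DataFrame, hi: float = 0.8,
                            lo: float = 0.5, ratio: float = 2.0) -> pd.Series:
    """Across-age assignment rule.

    Assign the top type when top > ``hi``, or when top > ``lo`` and top
    is at least ``ratio`` × the second-best score; otherwise unassigned.
    """
    labels, top, second = _top_two(scores)
    ok = (top > hi) | ((top > lo) & (top >= ratio * second))
    return labels.where(ok, other="unassigned").rename("cell_type")


def prediction_matrix(scores: pd.DataFrame,
                      query_types: pd.Series | np.ndarray) -> pd.DataFrame:
    """Mean score vector per query cell type (rows = nonempty query types)."""
    query_types = np.asarray(query_types)
    rows = {}
    for qt in sorted(pd.unique(query_types)):
        mask = query_types == qt
        rows[qt] = scores.to_numpy()[mask].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=scores.columns)


def identity_ratio(matrix: pd.DataFrame, row: str,
                   reference_type: str | None = None) -> float:
    """(diagonal − best off-diagonal) / diagonal for one query type.

    ``reference_type`` defaults to the query type's own name.  Returns 1
    when every off-diagonal is 0, ≤ 0 when some off-diagonal matches or
    exceeds the diagonal, NaN when the diagonal is 0.
    """
    ref = reference_type if reference_type is not None else row
    if ref not in matrix.columns:
        raise ValidationError(f"reference type {ref!r} not among columns")
    diag = float(matrix.loc[row, ref])
    if diag == 0:
        return float("nan")
    off = matrix.loc[row].drop(labels=[ref])
    top_off = float(off.max()) if len(off) else 0.0
    return (diag - top_off) / diag


def identity_ratio_table(matrix: pd.DataFrame) -> pd.Series:
    """Identity ratio for every query type whose name matches a reference column."""
    out = {}
    for row in matrix.index:
        if row in matrix.columns:
            out[row] = identity_ratio(matrix, row)
    return pd.Series(out, name="identity_ratio")
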