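"""Developmental gene programs: devDEGs, sharing, trends, module scores.

A *devDEG* is a gene whose sample-pseudobulk expression changes across
ages within one cell type (one-way F-test on log-CPM, BH-adjusted p <
0.05).  Genes are then classified by how widely they are shared across
cell types, their age trends are fit with a fixed-df cubic regression
spline and clustered hierarchically, and gene-set activity is summarized
by binned-control module scores.  The *refinement score* of a gene set
is the fraction of expressed (gene, cell type) combinations that change
significantly between a late juvenile age (P10) and adulthood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.cluster import AgglomerativeClustering

from .contrast import DEResult, de_test, pseudobulk
from .core import CellTable, ValidationError
from .ladder import AgeLadder

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCatalog:
    """Named gene-id lists (signaling classes etc.)."""

    sets: Mapping[str, list[str]]

    def __post_init__(self) -> None:
        self.sets = {str(k): [str(g) for g in v] for k, v in dict(self.sets).items()}

    def resolve(self, name: str, universe: Sequence[str]) -> list[str]:
        """Members of one set present in a gene universe (missing logged)."""
        members = self.sets[name]
        present = set(universe)
        found = [g for g in members if g in present]
        if len(found) < len(members):
            logger.warning("gene set %s: %d of %d ids not in universe",
                           name, len(members) - len(found), len(members))
        return found

    @classmethod
    def from_tsv(cls, path) -> "GeneSetCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str)
        sets: dict[str, list[str]] = {}
        for name, sub in df.groupby(df.columns[0]):
            sets[name] = sub.iloc[:, 1].tolist()
        return cls(sets)


# -- devDEG ---------------------------------------------------------------

def dev_de(table: CellTable, cell_type: str, *, alpha: float = 0.05,
           exclude: list[str] | None = None) -> DEResult:
    """Across-age pseudobulk F-test within one cell type (devDEG call)."""
    sub = table.subset_cells((table.cell_meta["cell_type"] == cell_type).to_numpy())
    pb = pseudobulk(sub)
    ages = sub.cell_meta.groupby("sample_id")["age"].first()
    n_ages_with_2 = (ages.value_counts() >= 2).sum()
    if n_ages_with_2 < 2:
        raise ValidationError("dev_de needs ≥ 2 samples at ≥ 2 ages")
    keep = ages.value_counts()[ages.value_counts() >= 2].index
    pb = pb.loc[:, [s for s in pb.columns if ages[s] in set(keep)]]
    return de_test(pb, ages.loc[list(pb.columns)], exclude=exclude, alpha=alpha)


def pairwise_age_de(table: CellTable, cell_type: str, age_a: str, age_b: str, *,
                    alpha: float = 0.05) -> DEResult:
    """Dedicated two-age contrast (e.g. P10 vs adult) within one cell type."""
    meta = table.cell_meta
    mask = ((meta["cell_type"] == cell_type)
            & meta["age"].isin([age_a, age_b])).to_numpy()
    sub = table.subset_cells(mask)
    pb = pseudobulk(sub)
    ages = sub.cell_meta.groupby("sample_id")["age"].first()
    return de_test(pb, ages, alpha=alpha)


def classify_sharing(devdeg_sets: Mapping[str, Sequence[str]],
                     n_celltypes: int | None = None) -> pd.Series:
    """Shared / intermediate / cell-type-specific label per devDEG.

    f = fraction of cell types calling the gene; f > 0.7 → "shared",
    f < 0.2 → "specific", otherwise "intermediate" (strict boundaries).
    """
    if n_celltypes is None:
        n_celltypes = len(devdeg_sets)
    if n_celltypes <= 0:
        raise ValidationError("n_celltypes must be positive")
    counts: dict[str, int] = {}
    for genes in devdeg_sets.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    labels = {}
    for g, c in counts.items():
        f = c / n_celltypes
        labels[g] = "shared" if f > 0.7 else ("specific" if f < 0.2 else "intermediate")
    return pd.Series(labels, name="sharing").sort_index()


# -- trends ---------------------------------------------------------------

def _spline_basis(x: np.ndarray, df: int, degree: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """B-spline design matrix with ``df`` basis functions on the span of x."""
    lo, hi = float(x.min()), float(x.max())
    n_internal = df - (degree + 1)
    if n_internal < 0:
        raise ValidationError(f"df={df} too small for degree {degree}")
    internal = np.quantile(np.unique(x), np.linspace(0, 1, n_internal + 2)[1:-1]) \
        if n_internal else np.array([])
    knots = np.r_[[lo] * (degree + 1), internal, [hi] * (degree + 1)]
    basis = BSpline.design_matrix(np.clip(x, lo, hi), knots, degree).toarray()
    return basis, knots


def fit_trend(values: np.ndarray, ages: Sequence[str], ladder: AgeLadder,
              df: int = 4) -> pd.Series:
    """Cubic regression-spline trend over the age grid (least squares).

    ``values`` are per-sample measurements, ``ages`` their age labels.
    With df = 4 the basis is a cubic polynomial in the age index; larger
    df adds interior knots.  Constant and linear inputs are reproduced
    exactly.  Needs ≥ df + 1 distinct ages.
    """
    values = np.asarray(values, dtype=float)
    x = np.array([ladder.index(a) for a in ages], dtype=float)
    distinct = np.unique(x)
    if distinct.size < df + 1:
        raise ValidationError(f"fit_trend needs ≥ {df + 1} distinct ages, got {distinct.size}")
    basis, knots = _spline_basis(x, df)
    coef, *_ = np.linalg.lstsq(basis, values, rcond=None)
    grid = np.array([ladder.index(a) for a in ladder.labels], dtype=float)
    grid_basis = BSpline.design_matrix(
        np.clip(grid, x.min(), x.max()), knots, 3).toarray()
    return pd.Series(grid_basis @ coef, index=list(ladder.labels), name="trend")


def zscore_trends(trends: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score (population sd); constant rows map to all-zero."""
    mat = trends.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (mat - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=trends.index, columns=trends.columns)


def cluster_trends(trends: pd.DataFrame, n_clusters: int) -> pd.Series:
    """Ward hierarchical clustering of z-scored trends, cut at ``n_clusters``.

    Labels are renumbered by first appearance in the row order of
    ``trends`` sorted by index, so permuting input rows yields the same
    partition.
    """
    if len(trends) < n_clusters:
        raise ValidationError("need at least n_clusters trends")
    ordered = trends.sort_index()
    z = zscore_trends(ordered).to_numpy()
    labels = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward").fit_predict(z)
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap)
    return pd.Series([remap[l] for l in labels], index=ordered.index, name="cluster")


# -- module scores ---------------------------------------------------------

def module_score(norm_matrix: pd.DataFrame, gene_set: Sequence[str], *,
                 n_bins: int = 24, n_ctrl: int = 100, seed: int = 0) -> np.ndarray:
    """Binned-control gene-set score per cell.

    ``norm_matrix`` is genes × cells (log-normalized), indexed by gene
    id.  Genes are binned into ``n_bins`` by average expression; each
    set gene contributes ``n_ctrl`` control genes sampled from its bin.
    Score = mean(set genes) − mean(control pool), per cell.
    """
    genes = [g for g in gene_set if g in norm_matrix.index]
    if not genes:
        raise ValidationError("gene set resolves to no genes in the matrix")
    avg = norm_matrix.mean(axis=1)
    ranks = avg.rank(method="first")
    bins = pd.cut(ranks, bins=min(n_bins, len(ranks)), labels=False)
    rng = np.random.default_rng(seed)
    mat = norm_matrix.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(norm_matrix.index)}
    ctrl_rows: list[np.ndarray] = []
    for g in genes:
        pool = bins.index[bins == bins[g]]
        pool = [p for p in pool if p != g]
        if not pool:
            continue
        take = rng.choice(len(pool), size=min(n_ctrl, len(pool)), replace=False)
        ctrl_rows.extend(pos[pool[t]] for t in take)
    set_mean = mat[[pos[g] for g in genes]].mean(axis=0)
    ctrl_mean = mat[ctrl_rows].mean(axis=0) if ctrl_rows else np.zeros(mat.shape[1])
    return set_mean - ctrl_mean


def aggregate_score_by_age(scores: np.ndarray, ages: Sequence[str],
                           ladder: AgeLadder) -> pd.Series:
    """Per-age mean score, z-scored across ages (zero vector if constant)."""
    ages = np.asarray(ages)
    present = [a for a in ladder.labels if (ages == a).any()]
    if len(present) < 2:
        raise ValidationError("aggregate_score_by_age needs ≥ 2 ages")
    means = np.array([float(np.mean(scores[ages == a])) for a in present])
    sd = means.std()
    z = (means - means.mean()) / sd if sd > 0 else np.zeros_like(means)
    return pd.Series(z, index=present, name="module_score_z")


# -- refinement ------------------------------------------------------------

def refinement_score(de_results: Mapping[str, DEResult],
                     expressed: Mapping[str, set[str]],
                     gene_set: Sequence[str],
                     cell_types: Sequence[str]) -> float:
    """Fraction of expressed (gene, cell type) combos significant P10 vs adult.

    ``de_results[ct]`` is the dedicated two-age DE result for cell type
    ``ct``; ``expressed[ct]`` is the set of genes with nonzero
    pseudobulk at ≥ 1 age for that cell type.  Returns NaN when no
    combination is expressed.
    """
    numerator = denominator = 0
    for ct in cell_types:
        sig = set(de_results[ct].significant_genes()) if ct in de_results else set()
        expr = expressed.get(ct, set())
        for g in gene_set:
            if g in expr:
                denominator += 1
                if g in sig:
                    numerator += 1
    if denominator == 0:
        return float("nan")
    return numerator / denominator


def refinement_pipeline(table: CellTable, catalog: GeneSetCatalog,
                        young: str = "P10", *, alpha: float = 0.05) -> pd.Series:
    """Compute the refinement score of every catalog set from a CellTable."""
    ladder = table.ladder
    adult = ladder.adult
    cell_types = sorted(ct for ct in table.cell_meta["cell_type"].unique()
                        if ct != "unassigned")
    de_results: dict[str, DEResult] = {}
    expressed: dict[str, set[str]] = {}
    for ct in cell_types:
        de_results[ct] = pairwise_age_de(table, ct, young, adult, alpha=alpha)
        sub = table.subset_cells((table.cell_meta["cell_type"] == ct).to_numpy())
        pb = pseudobulk(sub)
        expressed[ct] = set(np.asarray(pb.index)[pb.to_numpy().sum(axis=1) > 0])
    out = {}
    for name in catalog.sets:
        members = catalog.resolve(name, table.gene_ids)
        out[name] = refinement_score(de_results, expressed, members, cell_types)
    return pd.Series(out, name="refinement_score")
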