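"""Maturation pseudotime along a principal path, and the delay test.

For one cell type, a reference genotype's cells define a 20-PC space
(2000 variable genes, scaled, PCA).  The *principal path* is the
piecewise-linear curve through the age centroids in ladder order;
pseudotime of any cell (reference or projected mutant/control) is the
arc-length position of its nearest point on the path.  Genotype delays
are tested by averaging pseudotime within samples and comparing the
per-sample (or per-cell-type) means between genotypes with a two-sided
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (CellTable, Embedding, ValidationError, highly_variable_genes,
                   lognormalize, pca, scale_genes)
from .ladder import AgeLadder

#: The reference space uses the top 20 PCs of 2000 variable genes.
N_PCS_PSEUDOTIME = 20


@dataclass
class ReferenceSpace:
    """Frozen normalization + PC basis fitted on reference cells only."""

    gene_index: np.ndarray  # HVG indices into the full gene universe
    gene_mean: np.ndarray  # per-gene scaling center (log-normalized units)
    gene_sd: np.ndarray  # per-gene n−1 sd; 0 marks zero-variance genes
    clip: float
    embedding: Embedding  # reference scores + components + PCA mean

    def transform(self, table: CellTable) -> np.ndarray:
        """Project any cells with the same gene universe into this space."""
        lognorm = lognormalize(table)
        dense = np.asarray(lognorm[self.gene_index, :].todense())
        sd = np.where(self.gene_sd > 0, self.gene_sd, 1.0)
        scaled = (dense - self.gene_mean[:, None]) / sd[:, None]
        scaled[self.gene_sd == 0, :] = 0.0
        scaled = np.clip(scaled, -self.clip, self.clip)
        return self.embedding.project(scaled)


@dataclass
class PrincipalPath:
    """Piecewise-linear path through age centroids in ladder order."""

    ages: list[str]
    centroids: np.ndarray  # n_ages × n_dims
    cumulative_length: np.ndarray  # starts at 0, nondecreasing

    @property
    def total_length(self) -> float:
        return float(self.cumulative_length[-1])


@dataclass
class PseudotimeResult:
    """Per-cell pseudotime with sample/genotype aggregation and delay test."""

    pseudotime: pd.Series  # indexed by cell id
    sample_means: pd.Series
    genotype_means: pd.Series
    p_value: float
    degenerate: bool


def build_reference_space(table: CellTable, cell_type: str,
                          reference_genotype: str = "WT", *,
                          n_hvg: int = 2000,
                          n_pcs: int = N_PCS_PSEUDOTIME,
                          clip: float = 10.0) -> ReferenceSpace:
    """Fit HVGs, scaling and a PC basis on the reference genotype's cells."""
    meta = table.cell_meta
    mask = ((meta["cell_type"] == cell_type)
            & (meta["genotype"] == reference_genotype)).to_numpy()
    if mask.sum() < n_pcs + 1:
        raise ValidationError(
            f"only {int(mask.sum())} reference cells for {cell_type!r}")
    ref = table.subset_cells(mask)
    if ref.cell_meta["age"].nunique() < 2:
        raise ValidationError("reference cells must span ≥ 2 ages")
    lognorm = lognormalize(ref)
    hvg = highly_variable_genes(lognorm, n_hvg)
    dense = np.asarray(lognorm[hvg, :].todense())
    mean = dense.mean(axis=1)
    sd = dense.std(axis=1, ddof=1)
    scaled = np.where(sd[:, None] > 0,
                      (dense - mean[:, None]) / np.where(sd[:, None] > 0, sd[:, None], 1.0),
                      0.0)
    scaled = np.clip(scaled, -clip, clip)
    emb = pca(scaled, min(n_pcs, scaled.shape[0], ref.n_cells - 1),
              cell_index=ref.cell_meta["cell_id"].tolist())
    return ReferenceSpace(gene_index=hvg, gene_mean=mean, gene_sd=sd,
                          clip=clip, embedding=emb)


def principal_path(embedding: Embedding, ages, ladder: AgeLadder) -> PrincipalPath:
    """Age centroids joined in ladder order; Euclidean arc length."""
    ages = np.asarray(ages)
    present = [a for a in ladder.labels if (ages == a).any()]
    if len(present) < 2:
        raise ValidationError("principal path needs centroids at ≥ 2 ages")
    centroids = np.vstack([embedding.scores[ages == a].mean(axis=0) for a in present])
    seg = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    cumulative = np.r_[0.0, np.cumsum(seg)]
    return PrincipalPath(ages=present, centroids=centroids,
                         cumulative_length=cumulative)


def project_cells(path: PrincipalPath, coords: np.ndarray) -> np.ndarray:
    """Arc-length pseudotime of each cell's nearest point on the path.

    Orthogonal projection per segment, clamped to the segment; the
    globally nearest projection wins, ties going to the earlier segment.
    Values lie in [0, total_length].
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n_seg = len(path.centroids) - 1
    best_d2 = np.full(len(coords), np.inf)
    best_t = np.zeros(len(coords))
    for s in range(n_seg):
        a, b = path.centroids[s], path.centroids[s + 1]
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            t = np.zeros(len(coords))
        else:
            t = np.clip((coords - a) @ ab / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = ((coords - proj) ** 2).sum(axis=1)
        better = d2 < best_d2 - 1e-12  # strict: ties keep the earlier segment
        best_d2[better] = d2[better]
        seg_len = path.cumulative_length[s + 1] - path.cumulative_length[s]
        best_t[better] = path.cumulative_length[s] + t[better] * seg_len
    return best_t


def delay_test(pseudotime: pd.Series, samples: pd.Series,
               genotypes: pd.Series, *, by: str = "sample") -> PseudotimeResult:
    """Two-sided t-test for a genotype shift in mean pseudotime.

    Cells are averaged within samples; with ``by="sample"`` the t-test
    compares per-sample means between the two genotypes (requires ≥ 2
    samples each).  Degenerate (zero-variance) inputs report p = 1.
    """
    df = pd.DataFrame({"pt": pseudotime, "sample": samples.values,
                       "genotype": genotypes.values})
    sample_means = df.groupby("sample")["pt"].mean()
    sample_geno = df.groupby("sample")["genotype"].first()
    genotype_means = sample_means.groupby(sample_geno).mean()
    levels = sorted(sample_geno.unique())
    if len(levels) != 2:
        raise ValidationError("delay_test needs exactly two genotypes")
    a = sample_means[sample_geno == levels[0]].to_numpy()
    b = sample_means[sample_geno == levels[1]].to_numpy()
    if min(len(a), len(b)) < 2:
        raise ValidationError("delay_test needs ≥ 2 samples per genotype")
    pooled = np.r_[a, b]
    if np.allclose(pooled, pooled[0]):
        return PseudotimeResult(pseudotime, sample_means, genotype_means, 1.0, True)
    p = float(stats.ttest_ind(a, b).pvalue)
    return PseudotimeResult(pseudotime, sample_means, genotype_means, p, False)


def celltype_delay_test(table: CellTable, cell_type: str,
                        reference_genotype: str = "WT", *,
                        ages: list[str] | None = None,
                        n_hvg: int = 2000) -> PseudotimeResult:
    """End-to-end delay test for one cell type.

    Builds the reference space and principal path on the reference
    genotype, projects every genotype's cells, optionally restricts the
    test to specified ages, and runs :func:`delay_test` on per-sample
    means.
    """
    space = build_reference_space(table, cell_type, reference_genotype,
                                  n_hvg=n_hvg)
    meta = table.cell_meta
    ref_mask = ((meta["cell_type"] == cell_type)
                & (meta["genotype"] == reference_genotype)).to_numpy()
    ref = table.subset_cells(ref_mask)
    path = principal_path(space.embedding, ref.cell_meta["age"].to_numpy(),
                          table.ladder)
    mask = (meta["cell_type"] == cell_type).to_numpy()
    if ages is not None:
        mask &= meta["age"].isin(ages).to_numpy()
    sub = table.subset_cells(mask)
    coords = space.transform(sub)
    pt = pd.Series(project_cells(path, coords),
                   index=sub.cell_meta["cell_id"].values, name="pseudotime")
    return delay_test(pt, sub.cell_meta["sample_id"],
                      sub.cell_meta["genotype"])
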