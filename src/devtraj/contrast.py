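"""Group contrasts: centroid-distance statistics, pseudobulk DE, proportions.

The centroid-distance contrast asks, per cell type, whether samples of
two groups (sexes or genotypes) occupy distinct regions of PC space.
Each sample is reduced to its centroid; the effect size is the mean
Manhattan distance between groups divided by the pooled mean distance
within groups, and the p-value is a two-sided t-test between the
inter-group and intra-group distance lists.  The t-test treats pairwise
distances as independent although they share samples — this mirrors the
procedure being replicated; a permutation p-value is available as a
conservative alternative.

Pseudobulk DE aggregates raw counts per sample and runs a per-gene
one-way F-test on log-CPM values (equivalent to a two-sided t-test for
two groups), with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import (CellTable, Embedding, ValidationError, highly_variable_genes,
                   lognormalize, pca, scale_genes)
from .maturation import MAX_PCS, N_HVG, VARIANCE_TARGET, select_pc_count

logger = logging.getLogger(__name__)


@dataclass
class GroupContrast:
    """Inter/intra centroid-distance ratio and test result for one cell type."""

    cell_type: str
    ratio: float
    p_raw: float
    p_adj: float
    n_per_group: dict[str, int]
    n_pcs_used: int
    degenerate: bool = False


@dataclass
class DEResult:
    """Per-gene differential-expression table.

    ``table`` columns: gene_id, per-group means (``mean_<group>``),
    statistic, p_raw, p_adj, sign (sign of second-group minus
    first-group mean for two groups, else 0), flag (True where the test
    was degenerate and p was set to 1).
    """

    table: pd.DataFrame
    groups: list[str]
    alpha: float = 0.05

    def significant(self, adjusted: bool = True) -> pd.DataFrame:
        col = "p_adj" if adjusted else "p_raw"
        return self.table[self.table[col] < self.alpha]

    def significant_genes(self, adjusted: bool = True) -> list[str]:
        return self.significant(adjusted)["gene_id"].tolist()


def sample_centroids(embedding: Embedding, sample_ids: pd.Series | np.ndarray) -> pd.DataFrame:
    """Coordinate-wise mean of PC scores per sample (rows = sample ids)."""
    sample_ids = np.asarray(sample_ids)
    rows = {}
    for sid in pd.unique(sample_ids):
        rows[sid] = embedding.scores[sample_ids == sid].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def _pair_distances(centroids: pd.DataFrame, groups: pd.Series) -> tuple[list, list]:
    """Manhattan distances split into between-group and pooled within-group lists."""
    samples = list(centroids.index)
    coords = centroids.to_numpy()
    between, within = [], []
    for i, j in combinations(range(len(samples)), 2):
        d = float(np.abs(coords[i] - coords[j]).sum())
        if groups[samples[i]] == groups[samples[j]]:
            within.append(d)
        else:
            between.append(d)
    return between, within


def group_distance_statistic(centroids: pd.DataFrame,
                             groups: pd.Series | dict) -> tuple[float, float, bool]:
    """Inter/intra Manhattan-distance ratio and two-sided t-test p-value.

    Returns ``(ratio, p_raw, degenerate)``.  All zero distances give
    ratio 1, p 1; zero within-distance with nonzero between gives an
    infinite ratio.
    """
    groups = pd.Series(groups)
    labels = groups.loc[list(centroids.index)]
    counts = labels.value_counts()
    if len(counts) != 2 or (counts < 2).any():
        raise ValidationError("need exactly two groups with ≥ 2 samples each")
    between, within = _pair_distances(centroids, labels)
    mean_b, mean_w = float(np.mean(between)), float(np.mean(within))
    if mean_w == 0 and mean_b == 0:
        return 1.0, 1.0, True
    if mean_w == 0:
        return float("inf"), 0.0, True
    ratio = mean_b / mean_w
    if np.allclose(between + within, (between + within)[0]):
        return ratio, 1.0, True
    p = float(stats.ttest_ind(between, within).pvalue)
    return ratio, p, False


def group_distance_permutation_p(centroids: pd.DataFrame, groups: pd.Series | dict,
                                 n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation p-value for the inter/intra ratio (label shuffling)."""
    groups = pd.Series(groups)
    labels = groups.loc[list(centroids.index)]
    observed, _, _ = group_distance_statistic(centroids, labels)
    rng = np.random.default_rng(seed)
    values = labels.to_numpy().copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(values)
        perm = pd.Series(values, index=labels.index)
        try:
            r, _, _ = group_distance_statistic(centroids, perm)
        except ValidationError:
            continue
        if r >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def contrast_all_celltypes(table: CellTable, group_field: str = "sex", *,
                           n_hvg: int = N_HVG, max_pcs: int = MAX_PCS,
                           variance_target: float = VARIANCE_TARGET) -> pd.DataFrame:
    """Centroid-distance contrast for every cell type, BH across cell types.

    Per cell type: subset → log-normalize → HVGs → scale → PCA → PC
    selection (20% variance, ≤ 100 PCs) → sample centroids → inter/intra
    statistic.  Cell types lacking ≥ 2 samples per group are skipped
    with a warning.
    """
    if group_field not in ("sex", "genotype"):
        raise ValidationError("group_field must be 'sex' or 'genotype'")
    results = []
    for ct in sorted(table.cell_meta["cell_type"].unique()):
        if ct == "unassigned":
            continue
        mask = (table.cell_meta["cell_type"] == ct).to_numpy()
        sub = table.subset_cells(mask)
        sample_groups = sub.cell_meta.groupby("sample_id")[group_field].first()
        counts = sample_groups.value_counts()
        if len(counts) != 2 or (counts < 2).any():
            logger.warning("cell type %s skipped: needs 2 groups with ≥2 samples", ct)
            continue
        lognorm = lognormalize(sub)
        hvg = highly_variable_genes(lognorm, n_hvg)
        scaled = scale_genes(lognorm[hvg, :])
        n_comp = min(max_pcs, scaled.shape[0], sub.n_cells)
        emb = pca(scaled, n_comp, cell_index=sub.cell_meta["cell_id"].tolist())
        k = select_pc_count(emb.variance_fractions, variance_target, max_pcs)
        emb = emb.subset_components(k)
        centroids = sample_centroids(emb, sub.cell_meta["sample_id"])
        ratio, p_raw, degen = group_distance_statistic(centroids, sample_groups)
        n_per_group = sample_groups.value_counts().to_dict()
        results.append({"cell_type": ct, "ratio": ratio, "p_raw": p_raw,
                        "n_pcs_used": k, "degenerate": degen,
                        **{f"n_{g}": n for g, n in sorted(n_per_group.items())}})
    out = pd.DataFrame(results)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out


# -- pseudobulk DE ---------------------------------------------------------

def pseudobulk(table: CellTable) -> pd.DataFrame:
    """Sum raw counts per sample: genes × samples DataFrame (total conserved)."""
    sample_ids = table.cell_meta["sample_id"].to_numpy()
    cols = {}
    for sid in pd.unique(sample_ids):
        mask = sample_ids == sid
        cols[sid] = np.asarray(table.counts[:, np.flatnonzero(mask)].sum(axis=1)).ravel()
    return pd.DataFrame(cols, index=table.gene_ids).sort_index(axis=1)


def log_cpm(pb: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    """log(1 + counts-per-million) of a pseudobulk matrix."""
    totals = pb.sum(axis=0)
    totals = totals.replace(0, 1)
    return np.log1p(pb / totals * scale)


def de_test(pb: pd.DataFrame, groups: pd.Series | dict,
            exclude: list[str] | None = None, alpha: float = 0.05) -> DEResult:
    """Per-gene one-way F-test across groups on log-CPM pseudobulk.

    Excluded gene ids are removed before testing (and absent from the
    output).  Genes with zero residual variance get p = 1 and a flag.
    """
    groups = pd.Series(groups)
    groups = groups.loc[list(pb.columns)]
    level_names = sorted(groups.unique())
    if len(level_names) < 2 or groups.value_counts().min() < 2:
        raise ValidationError("need ≥ 2 groups with ≥ 2 samples each")
    if exclude:
        drop = set(exclude)
        pb = pb.loc[[g for g in pb.index if g not in drop]]
    lc = log_cpm(pb)
    arrays = [lc.loc[:, groups[groups == g].index].to_numpy() for g in level_names]

    grand = np.hstack(arrays)
    n_total = grand.shape[1]
    group_means = [a.mean(axis=1) for a in arrays]
    grand_mean = grand.mean(axis=1)
    ss_between = sum(a.shape[1] * (gm - grand_mean) ** 2
                     for a, gm in zip(arrays, group_means))
    ss_within = sum(((a - gm[:, None]) ** 2).sum(axis=1)
                    for a, gm in zip(arrays, group_means))
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat = (ss_between / df_between) / (ss_within / df_within)
    # no residual variance → no within-group noise estimate → untestable
    flagged = ss_within < 1e-12
    p_raw = stats.f.sf(np.where(flagged, 0.0, f_stat), df_between, df_within)
    p_raw = np.where(flagged, 1.0, p_raw)
    p_adj = bh_adjust(p_raw)

    out = pd.DataFrame({"gene_id": lc.index})
    for name, gm in zip(level_names, group_means):
        out[f"mean_{name}"] = gm
    if len(level_names) == 2:
        out["sign"] = np.sign(group_means[1] - group_means[0]).astype(int)
    else:
        out["sign"] = 0
    out["statistic"] = f_stat
    out["p_raw"] = p_raw
    out["p_adj"] = p_adj
    out["flag"] = flagged
    return DEResult(table=out.reset_index(drop=True), groups=level_names, alpha=alpha)


def celltype_proportions(table: CellTable) -> pd.DataFrame:
    """Per-sample cell-type composition; rows (samples) sum to 1."""
    tab = pd.crosstab(table.cell_meta["sample_id"], table.cell_meta["cell_type"])
    return tab.div(tab.sum(axis=1), axis=0)
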