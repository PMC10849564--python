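"""Regionalization: how sub-regional transcriptomic identity sharpens with age.

Cell-type expression profiles (mean scaled expression per type) are
correlated pairwise; the mean off-diagonal correlation among cell types
of one region, normalized to its adult value, tracks the emergence of
regional identity.  Region markers are called one-vs-rest with a
Wilcoxon rank-sum test on log-normalized values, BH-adjusted within
region.  This module is fully deterministic (no RNG).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contrast import bh_adjust
from .core import CellTable, ValidationError, lognormalize, scale_genes
from .ladder import AgeLadder

logger = logging.getLogger(__name__)


def scorable_regions(region_map: Mapping[str, str]) -> list[str]:
    """Regions with ≥ 2 member cell types (the only ones with a within-region score)."""
    counts = pd.Series(region_map).value_counts()
    return sorted(counts[counts >= 2].index)


def celltype_profiles(scaled_matrix: np.ndarray,
                      cell_types: Sequence[str]) -> pd.DataFrame:
    """Mean scaled expression per cell type: genes × cell types."""
    cell_types = np.asarray(cell_types)
    cols = {}
    for ct in sorted(pd.unique(cell_types)):
        cols[ct] = np.asarray(scaled_matrix)[:, cell_types == ct].mean(axis=1)
    return pd.DataFrame(cols)


def profile_correlation(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between cell-type profiles (unit diagonal).

    Zero-variance profiles yield NaN rows/columns (flagged by a warning).
    """
    if profiles.shape[0] < 2:
        raise ValidationError("profile correlation needs ≥ 2 genes")
    mat = profiles.to_numpy(dtype=float)
    sd = mat.std(axis=0)
    if (sd == 0).any():
        logger.warning("%d zero-variance profiles; correlations set to NaN",
                       int((sd == 0).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat.T)
    corr = pd.DataFrame(corr, index=profiles.columns, columns=profiles.columns)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def per_age_profile_correlations(table: CellTable, *, clip: float = 10.0
                                 ) -> dict[str, pd.DataFrame]:
    """Cell-type correlation matrix at each age (within-age gene scaling).

    Scaling within each age keeps the age signal out of the region
    correlations; cell types with cells at that age are included.
    """
    out = {}
    lognorm = lognormalize(table)
    ages = table.cell_meta["age"].to_numpy()
    cts = table.cell_meta["cell_type"].to_numpy()
    for age in table.ladder.labels:
        mask = ages == age
        if not mask.any():
            continue
        scaled = scale_genes(lognorm[:, np.flatnonzero(mask)], clip=clip)
        profiles = celltype_profiles(scaled, cts[mask])
        if profiles.shape[1] >= 2:
            out[age] = profile_correlation(profiles)
    return out


def within_region_correlation(per_age: Mapping[str, pd.DataFrame],
                              region_map: Mapping[str, str],
                              adult: str) -> pd.DataFrame:
    """Mean within-region off-diagonal correlation per age, adult-normalized.

    Rows = ages (in input order), columns = scorable regions; each value
    is mean(age) / mean(adult), so the adult row is 1 by construction.
    Single-member regions are excluded with a warning.
    """
    if adult not in per_age:
        raise ValidationError(f"adult age {adult!r} missing from per-age matrices")
    regions = scorable_regions(region_map)
    if not regions:
        raise ValidationError("no region has ≥ 2 member cell types")
    raw = pd.DataFrame(index=list(per_age), columns=regions, dtype=float)
    for age, corr in per_age.items():
        for region in regions:
            members = [ct for ct, r in region_map.items()
                       if r == region and ct in corr.index]
            if len(members) < 2:
                logger.warning("region %s has <2 members at age %s", region, age)
                continue
            block = corr.loc[members, members].to_numpy()
            off = block[~np.eye(len(members), dtype=bool)]
            raw.loc[age, region] = float(np.nanmean(off))
    normalized = raw / raw.loc[adult]
    return normalized


def find_region_markers(table: CellTable, alpha: float = 0.05,
                        *, min_cells: int = 3) -> dict[str, list[str]]:
    """One-vs-rest Wilcoxon region markers on log-normalized expression.

    A gene is region R's marker when BH-adjusted p < alpha and its mean
    log-normalized expression is higher inside R than outside.
    """
    regions = [r for r in sorted(table.cell_meta["region"].unique())
               if r != "unassigned"]
    if len(regions) < 2:
        raise ValidationError("find_region_markers needs ≥ 2 regions")
    lognorm = np.asarray(lognormalize(table).todense())
    labels = table.cell_meta["region"].to_numpy()
    out: dict[str, list[str]] = {}
    for region in regions:
        mask = labels == region
        if mask.sum() < min_cells or (~mask).sum() < min_cells:
            out[region] = []
            continue
        x = lognorm[:, mask]
        y = lognorm[:, ~mask]
        res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided")
        p_adj = bh_adjust(res.pvalue)
        higher = x.mean(axis=1) > y.mean(axis=1)
        hits = np.flatnonzero((p_adj < alpha) & higher)
        out[region] = [table.gene_ids[i] for i in hits]
    return out


def region_marker_profiles(table: CellTable, markers: Sequence[str]
                           ) -> dict[str, pd.DataFrame]:
    """Per age: region × marker mean log-normalized expression matrix."""
    idx = table.gene_indices(markers)
    if idx.size == 0:
        raise ValidationError("no marker genes found in table")
    lognorm = np.asarray(lognormalize(table).todense())[idx, :]
    ages = table.cell_meta["age"].to_numpy()
    regions = table.cell_meta["region"].to_numpy()
    region_names = [r for r in sorted(pd.unique(regions)) if r != "unassigned"]
    out = {}
    for age in table.ladder.labels:
        amask = ages == age
        if not amask.any():
            continue
        rows = {}
        for region in region_names:
            m = amask & (regions == region)
            if m.any():
                rows[region] = lognorm[:, m].mean(axis=1)
        out[age] = pd.DataFrame.from_dict(rows, orient="index",
                                          columns=[markers[i] for i in range(idx.size)])
    return out


def marker_correlation_to_adult(profiles_by_age: Mapping[str, pd.DataFrame],
                                adult: str) -> pd.Series:
    """Pearson correlation of each age's flattened region×marker matrix to adult's."""
    if adult not in profiles_by_age:
        raise ValidationError(f"adult age {adult!r} missing")
    ref = profiles_by_age[adult]
    out = {}
    for age, mat in profiles_by_age.items():
        aligned = mat.reindex(index=ref.index, columns=ref.columns)
        a, b = aligned.to_numpy().ravel(), ref.to_numpy().ravel()
        keep = ~(np.isnan(a) | np.isnan(b))
        a, b = a[keep], b[keep]
        if a.size < 2 or a.std() == 0 or b.std() == 0:
            out[age] = float("nan")
        else:
            out[age] = float(np.corrcoef(a, b)[0, 1])
    return pd.Series(out, name="marker_correlation_to_adult")
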