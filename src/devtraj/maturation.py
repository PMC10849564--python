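"""Per-cell-type maturation trajectories in PC space.

For each cell type, maturity at an age is the Manhattan distance between
that age's centroid and the adult centroid in a PC embedding built from
that cell type's cells alone.  Distances are clamped to be nonincreasing
with age (transient excursions away from the adult state are flattened),
decomposed into per-stage deltas, and classified as gradual /
intermediate / stepwise by how many stages carry 90% of the total
change.  A k-NN adult-neighbor fraction provides an independent maturity
readout, and trajectories can be compared between groups (e.g. male vs
female) with a paired t-test across cell types and ages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .core import (CellTable, Embedding, ValidationError, highly_variable_genes,
                   lognormalize, pca, scale_genes)
from .ladder import AgeLadder

#: Pipeline defaults: HVG count, max PCs, and the variance target for PC selection.
N_HVG = 2000
MAX_PCS = 100
VARIANCE_TARGET = 0.20


@dataclass
class Trajectory:
    """One cell type's distance-to-adult trajectory and its classification."""

    cell_type: str
    ladder: AgeLadder
    raw_distance: pd.Series  # indexed by age label; NaN where an age had no cells
    clamped_distance: pd.Series
    stage_deltas: pd.Series  # indexed by "young-old" stage labels
    total_change: float
    class_label: int | None
    n_pcs_used: int


def select_pc_count(variance_fractions: np.ndarray, target: float = VARIANCE_TARGET,
                    cap: int = MAX_PCS) -> int:
    """Smallest k whose cumulative variance fraction reaches ``target``.

    Falls back to ``cap`` (bounded by the vector length) when the target
    is unreachable within the cap.
    """
    fractions = np.asarray(variance_fractions, dtype=float)
    if fractions.size == 0:
        raise ValidationError("variance_fractions is empty")
    cumulative = np.cumsum(fractions)
    reached = np.flatnonzero(cumulative >= target)
    limit = min(cap, fractions.size)
    if reached.size == 0 or reached[0] + 1 > limit:
        return limit
    return int(reached[0] + 1)


def age_centroids(embedding: Embedding, ages: pd.Series | np.ndarray,
                  ladder: AgeLadder) -> pd.DataFrame:
    """Coordinate-wise mean per age (rows = ladder ages present among cells)."""
    ages = np.asarray(ages)
    rows = {}
    for age in ladder.labels:
        mask = ages == age
        if mask.any():
            rows[age] = embedding.scores[mask].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index")


def distance_trajectory(embedding: Embedding, ages: pd.Series | np.ndarray,
                        ladder: AgeLadder) -> pd.Series:
    """Manhattan distance from each age's centroid to the adult centroid.

    Ages with no cells get NaN (excluded from staging downstream); the
    adult entry is exactly 0.
    """
    centroids = age_centroids(embedding, ages, ladder)
    if ladder.adult not in centroids.index:
        raise ValidationError(f"no cells at adult age {ladder.adult!r}")
    adult = centroids.loc[ladder.adult].to_numpy()
    out = pd.Series(np.nan, index=list(ladder.labels), name="raw_distance")
    for age in centroids.index:
        out[age] = float(np.abs(centroids.loc[age].to_numpy() - adult).sum())
    return out


def clamp_monotone(raw: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Left-to-right clamp: any rise above the previous clamped value is flattened.

    NaN entries (missing ages) are carried through untouched and do not
    act as clamping references.
    """
    values = np.asarray(raw, dtype=float).copy()
    prev = np.nan
    for i, v in enumerate(values):
        if np.isnan(v):
            continue
        if not np.isnan(prev) and v > prev:
            values[i] = prev
        prev = values[i]
    if isinstance(raw, pd.Series):
        return pd.Series(values, index=raw.index, name="clamped_distance")
    return values


def stage_deltas(clamped: pd.Series | np.ndarray, ladder: AgeLadder) -> pd.Series:
    """Per-stage drop of the clamped distance, over the ladder's stage set.

    Stages whose endpoint ages are missing contribute NaN; deltas are
    nonnegative because the clamped curve is nonincreasing.
    """
    if isinstance(clamped, pd.Series):
        series = clamped
    else:
        series = pd.Series(np.asarray(clamped, float), index=list(ladder.labels))
    out = {}
    for young, old in ladder.stage_set:
        out[f"{young}-{old}"] = series[young] - series[old]
    return pd.Series(out, name="stage_delta")


def classify_trajectory(deltas: pd.Series | np.ndarray, threshold: float = 0.9) -> int:
    """Gradual (1) / intermediate (2) / stepwise (3) from stage concentration.

    k* = fewest stages, largest first, holding ≥ ``threshold`` of the
    total change.  With S stages: k*/S ≤ 0.4 → class 3, ≤ 0.6 → class 2,
    else class 1 (the 2 / 3 / 4–5 split when S = 5).
    """
    values = np.asarray(deltas, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0 or (values < 0).any():
        raise ValidationError("stage deltas must be nonnegative and nonempty")
    total = values.sum()
    if total <= 0:
        raise ValidationError("total change is zero; trajectory class undefined")
    ordered = np.sort(values)[::-1]
    k_star = int(np.searchsorted(np.cumsum(ordered), threshold * total - 1e-12) + 1)
    frac = k_star / values.size
    if frac <= 0.4:
        return 3
    if frac <= 0.6:
        return 2
    return 1


def celltype_trajectory(table: CellTable, cell_type: str, *,
                        n_hvg: int = N_HVG, max_pcs: int = MAX_PCS,
                        variance_target: float = VARIANCE_TARGET) -> Trajectory:
    """Full per-cell-type pipeline: subset → normalize → HVG → scale → PCA →
    PC selection → centroid distances → clamp → stage deltas → class."""
    mask = (table.cell_meta["cell_type"] == cell_type).to_numpy()
    if mask.sum() < 3:
        raise ValidationError(f"cell type {cell_type!r} has fewer than 3 cells")
    sub = table.subset_cells(mask)
    lognorm = lognormalize(sub)
    hvg = highly_variable_genes(lognorm, n_hvg)
    scaled = scale_genes(lognorm[hvg, :])
    n_comp = min(max_pcs, scaled.shape[0], sub.n_cells)
    embedding = pca(scaled, n_comp, cell_index=sub.cell_meta["cell_id"].tolist())
    k = select_pc_count(embedding.variance_fractions, variance_target, max_pcs)
    embedding = embedding.subset_components(k)

    ages = sub.cell_meta["age"].to_numpy()
    raw = distance_trajectory(embedding, ages, table.ladder)
    clamped = clamp_monotone(raw)
    deltas = stage_deltas(clamped, table.ladder)
    finite = deltas.dropna()
    total = float(finite.sum())
    try:
        label = classify_trajectory(finite)
    except ValidationError:
        label = None
    return Trajectory(cell_type=cell_type, ladder=table.ladder, raw_distance=raw,
                      clamped_distance=clamped, stage_deltas=deltas,
                      total_change=total, class_label=label, n_pcs_used=k)


def all_trajectories(table: CellTable, *, min_cells_per_age: int = 1,
                     **kwargs) -> dict[str, Trajectory]:
    """Run :func:`celltype_trajectory` for every assigned cell type."""
    out = {}
    for ct in sorted(table.cell_meta["cell_type"].unique()):
        if ct == "unassigned":
            continue
        out[ct] = celltype_trajectory(table, ct, **kwargs)
    return out


# -- k-NN maturity ---------------------------------------------------------

def adult_neighbor_fraction(embedding: Embedding, ages: pd.Series | np.ndarray,
                            ladder: AgeLadder, k: int = 50) -> pd.Series:
    """Per-age fraction of k nearest neighbors (Euclidean, self excluded)
    that come from adult cells."""
    ages = np.asarray(ages)
    n = embedding.scores.shape[0]
    if k >= n - 1 or k < 1:
        raise ValidationError(f"k={k} must satisfy 1 ≤ k < n_cells−1={n - 1}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding.scores)
    _, idx = nn.kneighbors(embedding.scores)
    # drop self; with duplicate points self may not come first, so mask by index
    neighbor_idx = np.empty((n, k), dtype=int)
    for i in range(n):
        row = idx[i][idx[i] != i]
        neighbor_idx[i] = row[:k] if row.size >= k else idx[i][:k]
    is_adult = ages == ladder.adult
    adult_hits = is_adult[neighbor_idx].sum(axis=1)
    out = {}
    for age in ladder.labels:
        mask = ages == age
        if mask.any():
            out[age] = float(adult_hits[mask].sum() / (k * mask.sum()))
    return pd.Series(out, name="adult_neighbor_fraction")


def scaled_cumulative_fraction(fractions: pd.Series) -> pd.Series:
    """Cumulative sum over ages rescaled to [0, 1] (a maturity index display)."""
    cum = fractions.cumsum()
    span = cum.iloc[-1] - cum.iloc[0]
    if span == 0:
        return pd.Series(0.0, index=fractions.index)
    return (cum - cum.iloc[0]) / span


# -- group comparison ------------------------------------------------------

def compare_trajectories(traj_a: Trajectory, traj_b: Trajectory) -> pd.DataFrame:
    """Per-age clamped-distance difference, b − a."""
    if traj_a.ladder.labels != traj_b.ladder.labels:
        raise ValidationError("trajectories use different ladders")
    return pd.DataFrame({
        "age": list(traj_a.ladder.labels),
        "distance_a": traj_a.clamped_distance.to_numpy(),
        "distance_b": traj_b.clamped_distance.to_numpy(),
        "difference_b_minus_a": (traj_b.clamped_distance - traj_a.clamped_distance).to_numpy(),
    })


def compare_trajectory_sets(group_a: dict[str, Trajectory],
                            group_b: dict[str, Trajectory]) -> tuple[pd.DataFrame, float]:
    """Pooled b − a comparison across cell types shared by both groups.

    Returns the per (cell type, age) difference table and a two-sided
    paired t-test p-value over all matched (cell type, age) distance
    pairs.  Degenerate (zero-variance) differences report p = 1.
    """
    shared = sorted(set(group_a) & set(group_b))
    if not shared:
        raise ValidationError("no cell types shared between the two groups")
    frames = []
    for ct in shared:
        diff = compare_trajectories(group_a[ct], group_b[ct])
        diff.insert(0, "cell_type", ct)
        frames.append(diff)
    combined = pd.concat(frames, ignore_index=True)
    paired = combined.dropna(subset=["distance_a", "distance_b"])
    d = paired["difference_b_minus_a"].to_numpy()
    if d.size < 2 or np.allclose(d, d[0]):
        return combined, 1.0
    p = float(stats.ttest_rel(paired["distance_b"], paired["distance_a"]).pvalue)
    return combined, p
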