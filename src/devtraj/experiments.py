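"""Canned validation experiments on synthetic data.

Each function simulates a dataset under fixed study conditions, runs the
corresponding pipeline, and returns summary statistics of recovery,
calibration, or power.  These are the workflows behind the package's
reported operating characteristics; they are deliberately small enough
to run on a laptop in minutes.

Problem sizes: trajectory-class recovery uses 30 cell types (10 gradual,
10 intermediate, 10 stepwise), 6 ages, 200 cells per type per age, and
log(4) maturation effects on 200 of 400 genes.  Contrast calibration and
power use 20 cell types with 4 samples per sex; sex effects (log 4, 50
genes) are planted in 5 types for the power arm.  Delay recovery uses a
one-stage genotype shift read out at a single intermediate age.  devDEG
calibration uses 10,000 unplanted genes; power uses 200 step genes at n
= 4 samples per age.
"""

from __future__ import annotations

import numpy as np

from .contrast import contrast_all_celltypes
from .ladder import AgeLadder
from .maturation import celltype_trajectory
from .programs import dev_de
from .pseudotime import celltype_delay_test
from .regional import per_age_profile_correlations, within_region_correlation
from .simulate import CellTypeSpec, SimConfig, simulate_dataset

SIX_AGES = ("P0", "P4", "P10", "P18", "P28", "P65")


def _sub_seed(seed: int, offset: int) -> int:
    return (seed * 1009 + offset) % (2**31 - 1)


def trajectory_class_recovery(seed: int, *, n_types: int = 30,
                              cells_per_type_per_age: int = 200) -> tuple[int, int]:
    """Fraction of cell types whose trajectory class is recovered.

    10 types per class; the stepwise third splits its step between two
    postnatal stages.  Returns (n_correct, n_types).
    """
    ladder = AgeLadder(SIX_AGES)
    per_class = n_types // 3
    specs = (["gradual"] * per_class + ["intermediate"] * per_class
             + ["stepwise:3", "stepwise:4"] * ((n_types - 2 * per_class + 1) // 2))
    specs = specs[:n_types]
    cts = tuple(CellTypeSpec(f"ct{i:02d}", "rA", specs[i]) for i in range(n_types))
    samples_per_sex = 2
    cfg = SimConfig(
        n_genes=400, ladder=ladder, cell_types=cts,
        samples_per_age_per_sex=samples_per_sex,
        cells_per_sample_per_type=cells_per_type_per_age // (2 * samples_per_sex),
        n_maturation_genes=200, n_marker_genes=0, n_region_genes=0,
        n_sex_genes=0, seed=seed)
    table, truth = simulate_dataset(cfg)
    n_correct = sum(
        celltype_trajectory(table, ct.name).class_label == truth.true_class[ct.name]
        for ct in cts)
    return n_correct, n_types


def _contrast_config(seed: int, affected: tuple[str, ...]) -> SimConfig:
    ladder = AgeLadder(("P0", "P10", "P65"))
    names = tuple(f"ct{i:02d}" for i in range(20))
    cts = tuple(CellTypeSpec(n, "rA", "gradual") for n in names)
    return SimConfig(
        n_genes=300, ladder=ladder, cell_types=cts,
        samples_per_age_per_sex=4, cells_per_sample_per_type=25,
        n_maturation_genes=100, n_marker_genes=0, n_region_genes=0,
        n_sex_genes=50 if affected else 0, sex_effect_windows=("P10",),
        sex_affected_celltypes=affected, seed=seed)


def contrast_null_flags(seed: int, n_seeds: int = 10) -> list[int]:
    """Per-seed count of cell types (of 20) significant at BH 0.05, no sex effect."""
    flags = []
    for i in range(n_seeds):
        cfg = _contrast_config(_sub_seed(seed, i), ())
        table, _ = simulate_dataset(cfg)
        sub = table.subset_cells((table.cell_meta["age"] == "P10").to_numpy())
        res = contrast_all_celltypes(sub, "sex")
        flags.append(int((res["p_adj"] < 0.05).sum()))
    return flags


def contrast_power_hits(seed: int, n_seeds: int = 10) -> list[bool]:
    """Per-seed success: the 5 affected types rank top-5 by ratio and all
    reach BH-adjusted p < 0.05."""
    hits = []
    for i in range(n_seeds):
        cfg = _contrast_config(_sub_seed(seed, 100 + i),
                               tuple(f"ct{j:02d}" for j in range(5)))
        table, _ = simulate_dataset(cfg)
        sub = table.subset_cells((table.cell_meta["age"] == "P10").to_numpy())
        res = contrast_all_celltypes(sub, "sex")
        affected = {f"ct{j:02d}" for j in range(5)}
        top5 = set(res.nlargest(5, "ratio")["cell_type"])
        sig = res[res["cell_type"].isin(affected)]
        hits.append(top5 == affected and bool((sig["p_adj"] < 0.05).all()))
    return hits


def _delay_config(seed: int, delay: int) -> SimConfig:
    ladder = AgeLadder(SIX_AGES)
    cts = (CellTypeSpec("ct00", "rA", "gradual"),)
    return SimConfig(
        n_genes=300, ladder=ladder, cell_types=cts,
        samples_per_age_per_sex=2, cells_per_sample_per_type=25,
        n_maturation_genes=150, n_marker_genes=0, n_region_genes=0,
        n_sex_genes=0, genotypes={"WT": 0, "MUT": delay}, seed=seed)


def delay_detections(seed: int, delay: int, n_seeds: int = 10) -> list[bool]:
    """Per-seed: mutant mean pseudotime significantly below control at P10."""
    out = []
    for i in range(n_seeds):
        cfg = _delay_config(_sub_seed(seed, 200 + 10 * delay + i), delay)
        table, _ = simulate_dataset(cfg)
        res = celltype_delay_test(table, "ct00", "WT", ages=["P10"])
        lower = res.genotype_means["MUT"] < res.genotype_means["WT"]
        out.append(bool(res.p_value < 0.05 and lower))
    return out


def devdeg_null_rate(seed: int, n_genes: int = 10_000) -> float:
    """Raw p < 0.05 rate across unplanted genes in the across-age F-test."""
    ladder = AgeLadder(SIX_AGES)
    cfg = SimConfig(
        n_genes=n_genes, ladder=ladder,
        cell_types=(CellTypeSpec("ct00", "rA", "gradual"),),
        samples_per_age_per_sex=2, cells_per_sample_per_type=15,
        n_maturation_genes=0, n_marker_genes=0, n_region_genes=0,
        n_sex_genes=0, seed=seed)
    table, _ = simulate_dataset(cfg)
    res = dev_de(table, "ct00")
    return float((res.table["p_raw"] < 0.05).mean())


def devdeg_power(seed: int) -> float:
    """Detection rate (BH < 0.05) of 200 planted 4-fold step genes, n=4/age."""
    ladder = AgeLadder(SIX_AGES)
    cfg = SimConfig(
        n_genes=2000, ladder=ladder,
        cell_types=(CellTypeSpec("ct00", "rA", "stepwise:3"),),
        samples_per_age_per_sex=2, cells_per_sample_per_type=15,
        n_maturation_genes=200, n_marker_genes=0, n_region_genes=0,
        n_sex_genes=0, seed=seed)
    table, truth = simulate_dataset(cfg)
    res = dev_de(table, "ct00")
    sig = set(res.significant_genes())
    planted = truth.genes_with_role("maturation")
    return float(np.mean([g in sig for g in planted]))


def regionalization_monotone_fraction(seed: int) -> float:
    """Fraction of scorable regions whose adult-normalized within-region
    correlation is nondecreasing across all six ages."""
    ladder = AgeLadder(SIX_AGES)
    cts = (CellTypeSpec("c1", "rA", "gradual"), CellTypeSpec("c2", "rA", "gradual"),
           CellTypeSpec("c3", "rB", "gradual"), CellTypeSpec("c4", "rB", "gradual"))
    cfg = SimConfig(
        n_genes=400, ladder=ladder, cell_types=cts,
        samples_per_age_per_sex=2, cells_per_sample_per_type=40,
        n_maturation_genes=100, n_marker_genes=20, n_region_genes=80,
        n_sex_genes=0, seed=seed)
    table, _ = simulate_dataset(cfg)
    per_age = per_age_profile_correlations(table)
    region_map = {c.name: c.region for c in cts}
    trend = within_region_correlation(per_age, region_map, ladder.adult)
    trend = trend.loc[list(ladder.labels)]
    monotone = (trend.diff().dropna() >= -1e-9).all(axis=0)
    return float(monotone.mean())
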