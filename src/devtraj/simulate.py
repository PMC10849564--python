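"""Seeded generator for multi-age single-nucleus count data with known truth.

The generator emulates the design of a developmental single-nucleus
atlas: an ordered age ladder, two sexes with a fixed number of samples
per sex per age, one or more genotypes, and a panel of cell types each
assigned a *maturation schedule* m(a) ∈ [0, 1] (0 at the youngest age, 1
at the adult age).  Gene classes:

* maturation genes — signed log-effects scaled by the cell type's m(a);
* marker genes — up in their own cell type at all ages;
* region genes — up in all cell types of one region, with the effect
  sharpening linearly from 25% to 100% of full size across ages;
* sex genes — signed male-vs-female log-effects active only at ages in a
  configurable window.

Genotypes may carry a developmental delay measured in stages: a delayed
genotype at age index *i* expresses the schedule value of age *i − d*
(clamped at the youngest age).  Counts are negative binomial with a
shared dispersion and a log-normal per-cell library factor.  The
returned :class:`SimTruth` records every schedule, effect and delay so
that downstream statistics can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CellTable, ValidationError
from .ladder import AgeLadder
from .maturation import classify_trajectory, clamp_monotone, stage_deltas


@dataclass(frozen=True)
class CellTypeSpec:
    """A simulated cell type: name, home region, and trajectory shape.

    ``class_spec`` is ``"gradual"``, ``"intermediate"`` or
    ``"stepwise:k"`` (all maturation in stage *k*, 1-based on the
    ladder's consecutive pairs).
    """

    name: str
    region: str
    class_spec: str = "gradual"


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults mirror the emulated study design.

    Two samples per sex per age, negative-binomial dispersion 10 (strong
    overdispersion at high means, near-Poisson at low), log-normal
    library factors with σ=0.3, and a log(4) effect size for every
    planted gene class.
    """

    n_genes: int = 600
    ladder: AgeLadder = field(default_factory=AgeLadder.default)
    cell_types: tuple[CellTypeSpec, ...] = (
        CellTypeSpec("ct01", "regionA", "gradual"),
        CellTypeSpec("ct02", "regionA", "intermediate"),
        CellTypeSpec("ct03", "regionB", "stepwise:4"),
        CellTypeSpec("ct04", "regionB", "gradual"),
    )
    samples_per_age_per_sex: int = 2
    cells_per_sample_per_type: int = 25
    n_maturation_genes: int = 100
    n_marker_genes: int = 40
    n_region_genes: int = 60
    n_sex_genes: int = 50
    effect_size_log: float = float(np.log(4.0))
    sex_effect_windows: tuple[str, ...] = ()
    sex_affected_celltypes: tuple[str, ...] = ()
    genotypes: Mapping[str, int] = field(default_factory=lambda: {"WT": 0})
    nb_dispersion: float = 10.0
    libsize_logmean: float = 0.0
    libsize_logsd: float = 0.3
    baseline_logmean: float = 1.0
    baseline_logsd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = (self.n_maturation_genes + self.n_marker_genes
                 + self.n_region_genes + self.n_sex_genes)
        if total > self.n_genes:
            raise ValidationError(
                f"gene-class counts sum to {total} > n_genes={self.n_genes}"
            )
        for g, d in self.genotypes.items():
            if not (0 <= d < len(self.ladder)):
                raise ValidationError(f"delay for genotype {g!r} must be in [0, n_ages)")
        if self.effect_size_log <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("effect_size_log and nb_dispersion must be positive")
        object.__setattr__(self, "cell_types", tuple(self.cell_types))
        object.__setattr__(self, "sex_effect_windows", tuple(self.sex_effect_windows))
        object.__setattr__(self, "sex_affected_celltypes",
                           tuple(self.sex_affected_celltypes))
        object.__setattr__(self, "genotypes", dict(self.genotypes))


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``schedule`` maps cell type → m(a) over ladder ages; ``true_class``
    is the trajectory class the noiseless schedule implies under the
    90% staging rule; ``gene_effects`` lists every planted gene with its
    role, signed log effect and target; ``delay`` maps genotype →
    stages; ``baseline_log`` is the per-gene baseline log-mean.
    """

    schedule: dict[str, np.ndarray]
    true_class: dict[str, int | None]
    gene_effects: pd.DataFrame
    delay: dict[str, int]
    baseline_log: np.ndarray
    gene_ids: list[str]

    def genes_with_role(self, role: str) -> list[str]:
        sub = self.gene_effects[self.gene_effects["role"] == role]
        return sub["gene_id"].tolist()


# -- schedules -------------------------------------------------------------

#: Logistic steepness giving an "intermediate" schedule whose 90% mass
#: spans three stages with balanced slack to both class boundaries on
#: ladders of 6–8 ages.
_LOGISTIC_STEEPNESS = 3.0


def maturation_schedule(shape: str, ladder: AgeLadder) -> np.ndarray:
    """Nondecreasing m(a) over ladder ages with m(first)=0, m(adult)=1.

    ``gradual`` is linear in age index; ``stepwise:k`` jumps from 0 to 1
    at stage *k* (1-based consecutive pair); ``intermediate`` is a
    logistic centered mid-ladder, rescaled to [0, 1].
    """
    n = len(ladder)
    if n < 3:
        raise ValidationError("maturation schedules need a ladder of ≥ 3 ages")
    idx = np.arange(n, dtype=float)
    if shape == "gradual":
        return idx / (n - 1)
    if shape == "intermediate":
        z = 1.0 / (1.0 + np.exp(-_LOGISTIC_STEEPNESS * (idx - (n - 1) / 2)))
        return (z - z[0]) / (z[-1] - z[0])
    if shape.startswith("stepwise"):
        try:
            k = int(shape.split(":", 1)[1])
        except (IndexError, ValueError):
            raise ValidationError(f"stepwise spec must be 'stepwise:k', got {shape!r}") from None
        if not (1 <= k <= n - 1):
            raise ValidationError(f"stepwise stage {k} outside 1..{n - 1}")
        return (idx >= k).astype(float)
    raise ValidationError(f"unknown schedule shape {shape!r}")


def _noiseless_class(schedule: np.ndarray, ladder: AgeLadder) -> int | None:
    """Trajectory class implied by a noiseless schedule under the staging rule."""
    distance = 1.0 - schedule  # any positive scale gives identical deltas
    clamped = clamp_monotone(distance)
    deltas = stage_deltas(clamped, ladder)
    if deltas.sum() <= 0:
        return None
    return classify_trajectory(deltas)


def region_sharpening(ladder: AgeLadder) -> np.ndarray:
    """Fraction of full region effect expressed at each age: linear 0.25 → 1."""
    n = len(ladder)
    return 0.25 + 0.75 * np.arange(n) / (n - 1)


# -- expected means --------------------------------------------------------

def _build_truth(config: SimConfig, rng: np.random.Generator) -> SimTruth:
    ladder = config.ladder
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    baseline_log = rng.normal(config.baseline_logmean, config.baseline_logsd,
                              size=config.n_genes)

    schedule = {ct.name: maturation_schedule(ct.class_spec, ladder)
                for ct in config.cell_types}
    true_class = {ct.name: _noiseless_class(schedule[ct.name], ladder)
                  for ct in config.cell_types}

    rows = []
    cursor = 0
    e = config.effect_size_log
    for i in range(config.n_maturation_genes):
        sign = 1.0 if i % 2 == 0 else -1.0
        rows.append((gene_ids[cursor], "maturation", sign * e, "all"))
        cursor += 1
    type_names = [ct.name for ct in config.cell_types]
    for i in range(config.n_marker_genes):
        rows.append((gene_ids[cursor], "marker", e, type_names[i % len(type_names)]))
        cursor += 1
    regions = sorted({ct.region for ct in config.cell_types})
    for i in range(config.n_region_genes):
        rows.append((gene_ids[cursor], "region", e, regions[i % len(regions)]))
        cursor += 1
    for i in range(config.n_sex_genes):
        sign = 1.0 if i % 2 == 0 else -1.0
        rows.append((gene_ids[cursor], "sex", sign * e, "M"))
        cursor += 1
    gene_effects = pd.DataFrame(rows, columns=["gene_id", "role", "effect", "target"])
    return SimTruth(schedule=schedule, true_class=true_class,
                    gene_effects=gene_effects, delay=dict(config.genotypes),
                    baseline_log=baseline_log, gene_ids=gene_ids)


def _log_mean_vector(truth: SimTruth, config: SimConfig, cell_type: CellTypeSpec,
                     age: str, sex: str, genotype: str) -> np.ndarray:
    """Per-gene log expected mean for one (cell type, age, sex, genotype) condition."""
    ladder = config.ladder
    age_idx = ladder.index(age)
    delay = truth.delay.get(genotype, 0)
    shifted_idx = max(age_idx - delay, 0)
    m = truth.schedule[cell_type.name][shifted_idx]
    r = region_sharpening(ladder)[age_idx]
    in_window = (not config.sex_effect_windows) or (age in config.sex_effect_windows)
    affected = (not config.sex_affected_celltypes) or \
        (cell_type.name in config.sex_affected_celltypes)
    in_window = in_window and affected

    log_mu = truth.baseline_log.copy()
    eff = truth.gene_effects
    gidx = {g: i for i, g in enumerate(truth.gene_ids)}
    for _, row in eff.iterrows():
        i = gidx[row["gene_id"]]
        if row["role"] == "maturation":
            log_mu[i] += row["effect"] * m
        elif row["role"] == "marker" and row["target"] == cell_type.name:
            log_mu[i] += row["effect"]
        elif row["role"] == "region" and row["target"] == cell_type.region:
            log_mu[i] += row["effect"] * r
        elif row["role"] == "sex" and sex == row["target"] and in_window:
            log_mu[i] += row["effect"]
    return log_mu


def expected_mean(gene: str, cell_type: str, age: str, sex: str, genotype: str,
                  truth: SimTruth, config: SimConfig) -> float:
    """Expected count (before library-size scaling) for one gene in one condition."""
    spec = next((ct for ct in config.cell_types if ct.name == cell_type), None)
    if spec is None:
        raise ValidationError(f"unknown cell type {cell_type!r}")
    if gene not in truth.gene_ids:
        raise ValidationError(f"unknown gene {gene!r}")
    log_mu = _log_mean_vector(truth, config, spec, age, sex, genotype)
    return float(np.exp(log_mu[truth.gene_ids.index(gene)]))


# -- sampling --------------------------------------------------------------

def _precompute_effect_arrays(truth: SimTruth, config: SimConfig):
    """Vectorized effect lookup: arrays indexed by gene."""
    n = config.n_genes
    gidx = {g: i for i, g in enumerate(truth.gene_ids)}
    mat_eff = np.zeros(n)
    marker_eff: dict[str, np.ndarray] = {ct.name: np.zeros(n) for ct in config.cell_types}
    region_eff: dict[str, np.ndarray] = {}
    sex_eff = np.zeros(n)
    for _, row in truth.gene_effects.iterrows():
        i = gidx[row["gene_id"]]
        if row["role"] == "maturation":
            mat_eff[i] = row["effect"]
        elif row["role"] == "marker":
            marker_eff[row["target"]][i] = row["effect"]
        elif row["role"] == "region":
            region_eff.setdefault(row["target"], np.zeros(n))[i] = row["effect"]
        elif row["role"] == "sex":
            sex_eff[i] = row["effect"]
    return mat_eff, marker_eff, region_eff, sex_eff


def simulate_dataset(config: SimConfig) -> tuple[CellTable, SimTruth]:
    """Draw a full dataset; identical config (incl. seed) gives identical output.

    Counts are NB(mean = expected mean × library factor, dispersion
    ``nb_dispersion``); metadata covers sample, age, sex, genotype, cell
    type and region.  One generator seeded from ``config.seed`` drives
    every draw in a fixed iteration order.
    """
    rng = np.random.default_rng(config.seed)
    truth = _build_truth(config, rng)
    ladder = config.ladder
    mat_eff, marker_eff, region_eff, sex_eff = _precompute_effect_arrays(truth, config)
    sharpen = region_sharpening(ladder)
    theta = config.nb_dispersion

    blocks: list[sp.csr_matrix] = []
    meta_rows: list[dict] = []
    cell_counter = 0
    for ct in config.cell_types:
        sched = truth.schedule[ct.name]
        reg = region_eff.get(ct.region, np.zeros(config.n_genes))
        for age_idx, age in enumerate(ladder.labels):
            for genotype, delay in config.genotypes.items():
                m = sched[max(age_idx - delay, 0)]
                for sex in ("F", "M"):
                    in_window = ((not config.sex_effect_windows)
                                 or (age in config.sex_effect_windows)) and \
                        ((not config.sex_affected_celltypes)
                         or (ct.name in config.sex_affected_celltypes))
                    log_mu = (truth.baseline_log + mat_eff * m
                              + marker_eff[ct.name] + reg * sharpen[age_idx])
                    if sex == "M" and in_window:
                        log_mu = log_mu + sex_eff
                    mu_base = np.exp(log_mu)
                    for rep in range(config.samples_per_age_per_sex):
                        sample_id = f"{genotype}_{age}_{sex}{rep + 1}"
                        n_cells = config.cells_per_sample_per_type
                        factors = rng.lognormal(config.libsize_logmean,
                                                config.libsize_logsd, size=n_cells)
                        mu = mu_base[:, None] * factors[None, :]
                        p = theta / (theta + mu)
                        counts = rng.negative_binomial(theta, p)
                        blocks.append(sp.csr_matrix(counts))
                        for _ in range(n_cells):
                            meta_rows.append({
                                "cell_id": f"c{cell_counter:06d}",
                                "sample_id": sample_id, "age": age, "sex": sex,
                                "genotype": genotype, "cell_type": ct.name,
                                "region": ct.region,
                            })
                            cell_counter += 1
    counts = sp.hstack(blocks, format="csr")
    table = CellTable(counts=counts, gene_ids=truth.gene_ids,
                      cell_meta=pd.DataFrame(meta_rows), ladder=ladder)
    return table, truth


def write_truth_tables(truth: SimTruth, config: SimConfig, out_dir) -> None:
    """Write truth_*.tsv tables alongside the simulated dataset."""
    from pathlib import Path

    out = Path(out_dir)
    sched = pd.DataFrame(truth.schedule, index=list(config.ladder.labels))
    sched.rename_axis("age").to_csv(out / "truth_schedule.tsv", sep="\t")
    truth.gene_effects.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    pd.DataFrame({
        "cell_type": list(truth.true_class),
        "true_class": [("NA" if c is None else c) for c in truth.true_class.values()],
    }).to_csv(out / "truth_class.tsv", sep="\t", index=False)
    pd.DataFrame({
        "genotype": list(truth.delay), "delay_stages": list(truth.delay.values()),
    }).to_csv(out / "truth_delay.tsv", sep="\t", index=False)
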