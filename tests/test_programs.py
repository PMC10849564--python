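import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from devtraj.core import ValidationError
from devtraj.ladder import AgeLadder
from devtraj.programs import (GeneSetCatalog, aggregate_score_by_age,
                              classify_sharing, cluster_trends, dev_de,
                              fit_trend, module_score, pairwise_age_de,
                              refinement_pipeline, refinement_score,
                              zscore_trends)
from devtraj.simulate import CellTypeSpec, SimConfig, simulate_dataset


class TestClassifySharing:
    def test_shared_above_70_percent(self):
        sets = {f"ct{i}": ["gShared"] for i in range(8)}
        sets.update({f"ct{i}": [] for i in range(8, 10)})
        assert classify_sharing(sets, 10)["gShared"] == "shared"

    def test_specific_below_20_percent(self):
        sets = {"ct0": ["gOnce"], **{f"ct{i}": [] for i in range(1, 10)}}
        assert classify_sharing(sets, 10)["gOnce"] == "specific"

    def test_exact_boundary_is_intermediate(self):
        sets = {f"ct{i}": ["gEdge"] for i in range(7)}
        sets.update({f"ct{i}": [] for i in range(7, 10)})
        assert classify_sharing(sets, 10)["gEdge"] == "intermediate"

    def test_partition_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(1)
        sets = {f"ct{i}": [f"g{j}" for j in rng.choice(50, size=20, replace=False)]
                for i in range(10)}
        labels = classify_sharing(sets, 10)
        assert set(labels.unique()) <= {"shared", "intermediate", "specific"}
        all_genes = {g for genes in sets.values() for g in genes}
        assert set(labels.index) == all_genes


class TestFitTrend:
    def test_constant_input_gives_constant(self, six_age_ladder):
        ages = [a for a in six_age_ladder.labels for _ in range(3)]
        trend = fit_trend(np.full(len(ages), 4.2), ages, six_age_ladder)
        assert np.allclose(trend, 4.2)

    def test_linear_input_reproduced(self, six_age_ladder):
        ages = [a for a in six_age_ladder.labels for _ in range(2)]
        x = np.array([six_age_ladder.index(a) for a in ages], float)
        trend = fit_trend(2.0 * x + 1.0, ages, six_age_ladder)
        grid = np.arange(6.0)
        assert np.abs(trend.to_numpy() - (2 * grid + 1)).max() < 1e-6

    def test_noisy_step_endpoints_recovered(self, six_age_ladder):
        rng = np.random.default_rng(0)
        ages = [a for a in six_age_ladder.labels for _ in range(8)]
        x = np.array([six_age_ladder.index(a) for a in ages])
        y = np.where(x >= 3, 10.0, 2.0) + rng.normal(0, 0.3, size=len(x))
        trend = fit_trend(y, ages, six_age_ladder, df=5)
        assert abs(trend.iloc[0] - 2.0) < 1.0
        assert abs(trend.iloc[-1] - 10.0) < 1.0

    def test_too_few_ages_rejected(self):
        ladder = AgeLadder(("P0", "P4", "P65"))
        with pytest.raises(ValidationError):
            fit_trend(np.ones(3), list(ladder.labels), ladder, df=4)


class TestClusterTrends:
    def _planted(self, n_per=50, noise=0.3, seed=0):
        rng = np.random.default_rng(seed)
        grid = np.linspace(0, 1, 8)
        shapes = [grid, 1 - grid, np.sin(np.pi * grid), -np.sin(np.pi * grid)]
        rows, truth = [], []
        for s, shape in enumerate(shapes):
            for i in range(n_per):
                rows.append(shape + rng.normal(0, noise, size=8))
                truth.append(s)
        idx = [f"t{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=idx), np.array(truth)

    def test_two_well_separated_shapes_fully_recovered(self):
        trends, truth = self._planted(n_per=30, noise=0.05)
        two = trends.iloc[:60]
        labels = cluster_trends(two, 2)
        assert adjusted_rand_score(truth[:60], labels.loc[two.index]) == 1.0

    def test_four_planted_shapes_ari(self):
        trends, truth = self._planted(n_per=50, noise=0.3)
        labels = cluster_trends(trends, 4)
        assert adjusted_rand_score(truth, labels.loc[trends.index]) >= 0.9

    def test_permutation_invariant_partition(self):
        trends, _ = self._planted(n_per=10, noise=0.2, seed=3)
        labels1 = cluster_trends(trends, 3)
        shuffled = trends.sample(frac=1, random_state=7)
        labels2 = cluster_trends(shuffled, 3)
        assert adjusted_rand_score(labels1.sort_index(), labels2.sort_index()) == 1.0

    def test_zscore_rows_standardized(self):
        trends = pd.DataFrame([[1, 2, 3.0], [5, 5, 5]])
        z = zscore_trends(trends)
        assert z.iloc[0].mean() == pytest.approx(0)
        assert z.iloc[0].std(ddof=0) == pytest.approx(1)
        assert (z.iloc[1] == 0).all()


class TestModuleScore:
    def _matrix(self, rng, n_genes=200, n_cells=50):
        mat = rng.lognormal(0, 0.2, size=(n_genes, n_cells))
        return pd.DataFrame(mat, index=[f"g{i}" for i in range(n_genes)])

    def test_null_set_scores_near_zero(self, rng):
        mat = self._matrix(rng)
        scores = module_score(mat, [f"g{i}" for i in range(0, 40)], seed=0)
        assert abs(scores.mean()) < 0.05

    def test_uplifted_set_scores_positive(self, rng):
        mat = self._matrix(rng)
        boosted = [f"g{i}" for i in range(10)]
        mat.loc[boosted] *= 2
        scores = module_score(mat, boosted, seed=0)
        assert (scores > 0).mean() >= 0.99

    def test_same_seed_identical(self, rng):
        mat = self._matrix(rng)
        genes = [f"g{i}" for i in range(15)]
        assert np.array_equal(module_score(mat, genes, seed=3),
                              module_score(mat, genes, seed=3))

    def test_empty_resolved_set_rejected(self, rng):
        with pytest.raises(ValidationError):
            module_score(self._matrix(rng), ["nope"], seed=0)


class TestAggregateScoreByAge:
    def test_zscore_properties(self, six_age_ladder):
        ages = np.repeat(list(six_age_ladder.labels), 4)
        scores = np.arange(24.0)
        z = aggregate_score_by_age(scores, ages, six_age_ladder)
        assert z.mean() == pytest.approx(0)
        assert z.std(ddof=0) == pytest.approx(1)
        assert (np.diff(z) > 0).all()  # monotone means → monotone z

    def test_constant_means_all_zero(self, six_age_ladder):
        ages = np.repeat(list(six_age_ladder.labels), 2)
        z = aggregate_score_by_age(np.ones(12), ages, six_age_ladder)
        assert (z == 0).all()

    def test_single_age_rejected(self, six_age_ladder):
        with pytest.raises(ValidationError):
            aggregate_score_by_age(np.ones(5), ["P0"] * 5, six_age_ladder)


class FakeDE:
    def __init__(self, genes):
        self._genes = genes

    def significant_genes(self, adjusted=True):
        return self._genes


class TestRefinementScore:
    def test_arithmetic_from_definition(self):
        genes = [f"g{i}" for i in range(10)]
        cell_types = [f"ct{i}" for i in range(5)]
        expressed = {ct: set(genes) for ct in cell_types}
        # two never-expressed combos
        expressed["ct0"] -= {"g9"}
        expressed["ct1"] -= {"g9"}
        de = {ct: FakeDE([]) for ct in cell_types}
        de["ct0"] = FakeDE(["g0", "g1"])
        de["ct1"] = FakeDE(["g0"])
        score = refinement_score(de, expressed, genes, cell_types)
        assert score == pytest.approx(3 / 48)

    def test_bounds(self):
        genes = ["g0"]
        cts = ["ct0"]
        assert refinement_score({"ct0": FakeDE([])}, {"ct0": {"g0"}}, genes, cts) == 0
        assert refinement_score({"ct0": FakeDE(["g0"])}, {"ct0": {"g0"}}, genes, cts) == 1

    def test_never_expressed_gene_leaves_score_unchanged(self):
        cts = ["ct0", "ct1"]
        expressed = {ct: {"g0", "g1"} for ct in cts}
        de = {ct: FakeDE(["g0"]) for ct in cts}
        base = refinement_score(de, expressed, ["g0", "g1"], cts)
        extended = refinement_score(de, expressed, ["g0", "g1", "gGhost"], cts)
        assert base == extended

    def test_no_expressed_combo_is_nan(self):
        score = refinement_score({"ct0": FakeDE([])}, {"ct0": set()}, ["g0"], ["ct0"])
        assert np.isnan(score)


class TestDevDe:
    @pytest.fixture(scope="class")
    @staticmethod
    def sim():
        ladder = AgeLadder(("P0", "P4", "P10", "P18", "P28", "P65"))
        cfg = SimConfig(n_genes=500, ladder=ladder,
                        cell_types=(CellTypeSpec("a", "rA", "stepwise:3"),),
                        samples_per_age_per_sex=2, cells_per_sample_per_type=10,
                        n_maturation_genes=100, n_marker_genes=0,
                        n_region_genes=0, n_sex_genes=0, seed=9)
        return simulate_dataset(cfg)

    def test_planted_step_genes_detected(self, sim):
        table, truth = sim
        res = dev_de(table, "a")
        sig = set(res.significant_genes())
        planted = truth.genes_with_role("maturation")
        assert np.mean([g in sig for g in planted]) >= 0.9

    def test_null_genes_near_nominal_raw_rate(self, sim):
        table, truth = sim
        res = dev_de(table, "a")
        null_genes = set(truth.gene_ids) - set(truth.genes_with_role("maturation"))
        null_rows = res.table[res.table["gene_id"].isin(null_genes)]
        rate = (null_rows["p_raw"] < 0.05).mean()
        assert 0.01 < rate < 0.10

    def test_shuffled_ages_kill_signal(self, sim):
        table, truth = sim
        rng = np.random.default_rng(4)
        meta = table.cell_meta.copy()
        # permute sample→age assignment, preserving samples
        sample_age = meta.groupby("sample_id")["age"].first()
        permuted = pd.Series(rng.permutation(sample_age.values), index=sample_age.index)
        meta["age"] = meta["sample_id"].map(permuted)
        shuffled = table.subset_cells(np.arange(table.n_cells))
        shuffled.cell_meta = meta
        res = dev_de(shuffled, "a")
        assert (res.table["p_adj"] < 0.05).mean() < 0.25

    def test_refinement_pipeline_runs_on_simulation(self, sim):
        table, truth = sim
        catalog = GeneSetCatalog({
            "planted": truth.genes_with_role("maturation")[:20],
            "null": list(truth.gene_ids[-20:]),
        })
        scores = refinement_pipeline(table, catalog, young="P10")
        assert 0 <= scores["planted"] <= 1
        assert 0 <= scores["null"] <= 1
        # stepwise:3 matures before P10 → few P10-vs-P65 changes expected in
        # planted genes; null set should be near zero regardless
        assert scores["null"] <= 0.3


class TestGeneSetCatalog:
    def test_tsv_round_trip(self, tmp_path):
        df = pd.DataFrame({"set_name": ["s1", "s1", "s2"],
                           "gene_id": ["g1", "g2", "g3"]})
        df.to_csv(tmp_path / "sets.tsv", sep="\t", index=False)
        cat = GeneSetCatalog.from_tsv(tmp_path / "sets.tsv")
        assert cat.sets == {"s1": ["g1", "g2"], "s2": ["g3"]}
        assert cat.resolve("s1", ["g1", "gX"]) == ["g1"]
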