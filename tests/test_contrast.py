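import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from devtraj.contrast import (bh_adjust, celltype_proportions,
                              contrast_all_celltypes, de_test,
                              group_distance_permutation_p,
                              group_distance_statistic, log_cpm, pseudobulk,
                              sample_centroids)
from devtraj.core import Embedding, ValidationError
from devtraj.ladder import AgeLadder
from devtraj.simulate import CellTypeSpec, SimConfig, simulate_dataset

from conftest import make_table


def embedding_from(scores):
    scores = np.asarray(scores, dtype=float)
    return Embedding(scores=scores, variance_fractions=np.full(scores.shape[1], 0.01),
                     cell_index=[f"c{i}" for i in range(len(scores))])


class TestSampleCentroids:
    def test_mean_and_order_invariance(self):
        emb = embedding_from([[0, 0], [2, 2], [5, 5]])
        cents = sample_centroids(emb, ["s1", "s1", "s2"])
        assert cents.loc["s1"].tolist() == [1.0, 1.0]
        assert cents.loc["s2"].tolist() == [5.0, 5.0]
        emb2 = embedding_from([[5, 5], [2, 2], [0, 0]])
        cents2 = sample_centroids(emb2, ["s2", "s1", "s1"])
        pd.testing.assert_frame_equal(cents, cents2)


class TestGroupDistanceStatistic:
    def test_hand_enumerated_ratio(self):
        cents = pd.DataFrame([[0, 0], [0, 2], [10, 0], [10, 2]],
                             index=["a1", "a2", "b1", "b2"], dtype=float)
        groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        ratio, p, degen = group_distance_statistic(cents, groups)
        # within {2, 2}, between {10, 12, 12, 10} → 11 / 2
        assert ratio == pytest.approx(5.5)
        assert not degen

    def test_all_identical_degenerate(self):
        cents = pd.DataFrame([[1, 1]] * 4, index=list("abcd"), dtype=float)
        groups = pd.Series({"a": "A", "b": "A", "c": "B", "d": "B"})
        ratio, p, degen = group_distance_statistic(cents, groups)
        assert (ratio, p, degen) == (1.0, 1.0, True)

    def test_zero_within_nonzero_between_is_infinite(self):
        cents = pd.DataFrame([[0, 0], [0, 0], [5, 0], [5, 0]],
                             index=list("abcd"), dtype=float)
        groups = pd.Series({"a": "A", "b": "A", "c": "B", "d": "B"})
        ratio, p, degen = group_distance_statistic(cents, groups)
        assert np.isinf(ratio) and degen

    def test_label_symmetry_and_translation_invariance(self, rng):
        cents = pd.DataFrame(rng.normal(size=(6, 3)),
                             index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["A", "B"] * 3, index=cents.index)
        r1, p1, _ = group_distance_statistic(cents, groups)
        flipped = groups.map({"A": "B", "B": "A"})
        r2, p2, _ = group_distance_statistic(cents, flipped)
        assert r1 == pytest.approx(r2) and p1 == pytest.approx(p2)
        r3, p3, _ = group_distance_statistic(cents + 7.3, groups)
        assert r1 == pytest.approx(r3) and p1 == pytest.approx(p3)

    def test_exchangeable_labels_mean_ratio_near_one(self, rng):
        ratios = []
        for _ in range(300):
            cents = pd.DataFrame(rng.normal(size=(8, 2)),
                                 index=[f"s{i}" for i in range(8)])
            labels = np.array(["A"] * 4 + ["B"] * 4)
            rng.shuffle(labels)
            r, _, _ = group_distance_statistic(cents, pd.Series(labels, index=cents.index))
            ratios.append(r)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_permutation_p_not_small_under_null(self, rng):
        cents = pd.DataFrame(rng.normal(size=(8, 2)),
                             index=[f"s{i}" for i in range(8)])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=cents.index)
        p = group_distance_permutation_p(cents, groups, n_perm=200, seed=1)
        assert p > 0.01


class TestBhAdjust:
    def test_step_up_by_hand(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03] * 3)

    def test_single_value_unchanged(self):
        assert bh_adjust(np.array([0.4]))[0] == 0.4

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_definition(self, ps):
        p = np.array(ps)
        adj = bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        for rank_pos, i in enumerate(order):
            candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
            assert adj[i] == pytest.approx(min(1.0, min(candidates)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust(np.array([0.5, 1.5]))


class TestPseudobulk:
    def test_addition_and_conservation(self):
        table = make_table([[1, 3], [2, 4]], ["P65", "P65"],
                           sample_ids=["s1", "s1"])
        pb = pseudobulk(table)
        assert pb["s1"].tolist() == [4, 6]
        table2 = make_table([[1, 3, 7], [2, 4, 9]], ["P65"] * 3,
                            sample_ids=["s1", "s1", "s2"])
        pb2 = pseudobulk(table2)
        assert pb2.to_numpy().sum() == table2.counts.sum()

    def test_one_cell_per_sample_is_identity(self):
        table = make_table([[1, 3], [2, 4]], ["P65", "P65"],
                           sample_ids=["s1", "s2"])
        pb = pseudobulk(table)
        assert pb["s1"].tolist() == [1, 2]
        assert pb["s2"].tolist() == [3, 4]


class TestDeTest:
    def test_constant_gene_not_significant(self):
        pb = pd.DataFrame({"s1": [5, 1], "s2": [5, 9], "s3": [5, 2], "s4": [5, 8]},
                          index=["const", "var"])
        # equal library sizes keep the constant gene constant in log-CPM
        pb.loc["filler"] = [10, 2, 9, 3]
        res = de_test(pb, {"s1": "F", "s2": "M", "s3": "F", "s4": "M"})
        row = res.table.set_index("gene_id").loc["const"]
        assert row["p_raw"] == 1.0 and bool(row["flag"])

    def test_excluded_genes_absent(self):
        pb = pd.DataFrame(np.arange(12).reshape(3, 4) + 1,
                          index=["gA", "gB", "gC"],
                          columns=["s1", "s2", "s3", "s4"])
        res = de_test(pb, {"s1": "F", "s2": "M", "s3": "F", "s4": "M"},
                      exclude=["gB"])
        assert "gB" not in set(res.table["gene_id"])

    def test_f_equals_textbook_t_squared_for_two_groups(self, rng):
        pb = pd.DataFrame(rng.integers(1, 400, size=(30, 8)),
                          index=[f"g{i}" for i in range(30)],
                          columns=[f"s{i}" for i in range(8)])
        groups = {f"s{i}": ("F" if i < 4 else "M") for i in range(8)}
        res = de_test(pb, groups)
        lc = log_cpm(pb)
        for gene in ["g0", "g7", "g19"]:
            x = lc.loc[gene, ["s0", "s1", "s2", "s3"]]
            y = lc.loc[gene, ["s4", "s5", "s6", "s7"]]
            t = stats.ttest_ind(x, y)
            row = res.table.set_index("gene_id").loc[gene]
            assert row["statistic"] == pytest.approx(t.statistic**2, rel=1e-9)
            assert row["p_raw"] == pytest.approx(t.pvalue, rel=1e-9)

    def test_null_rate_near_alpha(self):
        rng = np.random.default_rng(0)
        pb = pd.DataFrame(rng.poisson(100, size=(4000, 8)),
                          index=[f"g{i}" for i in range(4000)],
                          columns=[f"s{i}" for i in range(8)])
        groups = {f"s{i}": ("F" if i % 2 else "M") for i in range(8)}
        res = de_test(pb, groups)
        rate = (res.table["p_raw"] < 0.05).mean()
        assert 0.03 < rate < 0.07


class TestCelltypeProportions:
    def test_fractions_and_rows_sum_to_one(self):
        table = make_table(np.ones((2, 12), dtype=int), ["P65"] * 12,
                           sample_ids=["s1"] * 12,
                           cell_types=["X"] * 3 + ["Y"] * 9)
        props = celltype_proportions(table)
        assert props.loc["s1", "X"] == 0.25
        assert props.sum(axis=1).tolist() == [1.0]


class TestContrastPipeline:
    def test_duplicating_cells_leaves_ratio_unchanged(self, six_age_ladder):
        cfg = SimConfig(n_genes=80, ladder=six_age_ladder,
                        cell_types=(CellTypeSpec("a", "rA", "gradual"),),
                        cells_per_sample_per_type=8, n_maturation_genes=20,
                        n_marker_genes=0, n_region_genes=0, n_sex_genes=20,
                        sex_effect_windows=("P65",), seed=2)
        table, _ = simulate_dataset(cfg)
        sub = table.subset_cells((table.cell_meta["age"] == "P65").to_numpy())
        res1 = contrast_all_celltypes(sub, "sex")
        doubled = sub.subset_cells(np.r_[np.arange(sub.n_cells), np.arange(sub.n_cells)])
        res2 = contrast_all_celltypes(doubled, "sex")
        assert res1.loc[0, "ratio"] == pytest.approx(res2.loc[0, "ratio"], rel=1e-6)

    def test_p_adj_at_least_p_raw(self, six_age_ladder):
        cfg = SimConfig(n_genes=60, ladder=six_age_ladder,
                        cell_types=(CellTypeSpec("a", "rA", "gradual"),
                                    CellTypeSpec("b", "rA", "gradual")),
                        cells_per_sample_per_type=6, n_maturation_genes=20,
                        n_marker_genes=0, n_region_genes=0, n_sex_genes=0, seed=3)
        table, _ = simulate_dataset(cfg)
        sub = table.subset_cells((table.cell_meta["age"] == "P10").to_numpy())
        res = contrast_all_celltypes(sub, "sex")
        assert (res["p_adj"] >= res["p_raw"] - 1e-12).all()
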