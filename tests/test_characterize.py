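"""Group characterisation: rank tests, contingency tests, mapping matrix."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from jiatraj import (compare_categorical, compare_continuous, cross_tabulate,
                     generate_cohort, group_summaries)

from conftest import oracle_fisher_2x2, oracle_kruskal, two_group_config


class TestKruskalWallis:
    def test_no_tie_hand_computation(self):
        h, p = compare_continuous([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert h == pytest.approx(27 / 7)       # 3.857...
        assert 0 < p < 1

    def test_identical_group_multisets_give_zero(self):
        h, p = compare_continuous([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_values_degenerate(self):
        h, p = compare_continuous([5, 5, 5, 5], [0, 0, 1, 1])
        assert (h, p) == (0.0, 1.0)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        g = rng.integers(0, 3, 30)
        h1, _ = compare_continuous(v, g)
        perm = rng.permutation(30)
        h2, _ = compare_continuous(v[perm], g[perm])
        assert h1 == pytest.approx(h2)

    def test_matches_rank_formula_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            v = rng.integers(0, 6, 24).astype(float)   # heavy ties
            g = rng.integers(0, 3, 24)
            if len(np.unique(g)) < 2 or np.ptp(v) == 0:
                continue
            h, _ = compare_continuous(v, g)
            assert h == pytest.approx(oracle_kruskal(v, g), abs=1e-10)


class TestCategorical:
    def test_perfect_association_fisher(self):
        stat, p, used = compare_categorical([[10, 0], [0, 10]])
        assert used == "fisher"
        assert p == pytest.approx(2 / math.comb(20, 10))

    def test_identical_rows_give_null_chi2(self):
        stat, p, used = compare_categorical([[20, 30], [20, 30]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert used == "chi2"

    def test_doubling_counts_doubles_chi2(self):
        t = np.array([[20, 10], [10, 25]])
        s1, _, _ = compare_categorical(t)
        s2, _, _ = compare_categorical(2 * t)
        assert s2 == pytest.approx(2 * s1)

    def test_fisher_matches_enumeration_on_exhaustive_small_tables(self):
        """Every 2x2 table with all cells <= 3 and low expected counts."""
        checked = 0
        for a, b, c, d in itertools.product(range(4), repeat=4):
            t = [[a, b], [c, d]]
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            stat, p, used = compare_categorical(t)
            if used != "fisher":
                continue
            assert p == pytest.approx(oracle_fisher_2x2(t), abs=1e-12)
            checked += 1
        assert checked > 50

    def test_larger_sparse_table_flagged(self):
        stat, p, used = compare_categorical([[1, 2, 1], [2, 1, 2]])
        assert used == "chi2_low_expected"

    def test_zero_margins_dropped(self):
        stat, p, used = compare_categorical([[5, 0, 5], [5, 0, 5], [0, 0, 0]])
        assert used == "chi2"
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            compare_categorical([[0, 0], [0, 0]])


class TestCrossTabulate:
    def test_identical_assignments_are_diagonal(self):
        a = pd.Series([0, 0, 1, 1], index=list("abcd"))
        m = cross_tabulate(a, a)
        np.testing.assert_array_equal(m.counts.to_numpy(), [[2, 0], [0, 2]])
        assert m.total == 4

    def test_hand_counted_cells(self):
        base = pd.Series([0, 0, 1], index=["a", "b", "c"])
        traj = pd.Series([1, 0, 1], index=["a", "b", "c"])
        m = cross_tabulate(base, traj)
        np.testing.assert_array_equal(m.counts.to_numpy(), [[1, 1], [0, 1]])
        assert m.row_percent.iloc[0, 0] == pytest.approx(50.0)

    def test_total_equals_intersection_size(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            ids_a = [f"i{j}" for j in rng.choice(50, size=30, replace=False)]
            ids_b = [f"i{j}" for j in rng.choice(50, size=30, replace=False)]
            a = pd.Series(rng.integers(0, 3, 30), index=ids_a)
            b = pd.Series(rng.integers(0, 4, 30), index=ids_b)
            common = set(ids_a) & set(ids_b)
            if not common:
                continue
            assert cross_tabulate(a, b).total == len(common)

    def test_disjoint_assignments_rejected(self):
        a = pd.Series([0], index=["a"])
        b = pd.Series([0], index=["b"])
        with pytest.raises(ValueError):
            cross_tabulate(a, b)

    def test_independent_assignments_have_marginal_row_profiles(self):
        rng = np.random.default_rng(3)
        n = 20_000
        ids = [f"i{j}" for j in range(n)]
        a = pd.Series(rng.integers(0, 2, n), index=ids)
        b = pd.Series(rng.choice(3, size=n, p=[0.5, 0.3, 0.2]), index=ids)
        m = cross_tabulate(a, b)
        for _, row in m.row_percent.iterrows():
            np.testing.assert_allclose(row.to_numpy() / 100,
                                       [0.5, 0.3, 0.2], atol=0.02)


@pytest.fixture(scope="module")
def cohort_and_assignment():
    cohort, truth = generate_cohort(two_group_config(200, 4))
    ids = cohort.covariates.index
    assignment = pd.Series(truth.labels, index=[f"id{i:05d}" for i in range(200)])
    return cohort, assignment.loc[ids]


class TestGroupSummaries:

    def test_median_iqr_linear_interpolation(self, cohort_and_assignment):
        cohort, assignment = cohort_and_assignment
        cohort.covariates["toy"] = np.nan
        cohort.covariates.loc[assignment.index[assignment == 0][:3], "toy"] = [1.0, 2.0, 3.0]
        res = group_summaries(cohort, assignment, ["toy"])
        cell = res.table.loc[res.table["variable"] == "toy", "group0"].item()
        assert cell == "2.0 (1.5-2.5)"

    def test_all_missing_variable_row_without_test(self, cohort_and_assignment):
        cohort, assignment = cohort_and_assignment
        cohort.covariates["void"] = np.nan
        res = group_summaries(cohort, assignment, ["void"])
        row = res.table[res.table["variable"] == "void"].iloc[0]
        assert row["n_available"] == 0
        assert "void" not in set(res.tests["variable"])

    def test_categorical_percentages_over_available_data(self, cohort_and_assignment):
        cohort, assignment = cohort_and_assignment
        res = group_summaries(cohort, assignment, ["gender"])
        tests = res.tests.set_index("variable")
        assert tests.loc["gender", "test_used"] in ("chi2", "fisher")
        # percentages in each group column sum to ~100
        for col in ("group0", "group1"):
            pcts = [float(v.split("(")[1].rstrip("%)"))
                    for v in res.table[res.table["variable"] == "gender"][col]]
            assert sum(pcts) == pytest.approx(100, abs=1.0)

    def test_identical_groups_give_identical_summaries(self):
        cov = pd.DataFrame({"x": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                           index=[f"i{j}" for j in range(6)])

        class Dummy:
            covariates = cov

        assignment = pd.Series([0, 0, 0, 1, 1, 1], index=cov.index)
        res = group_summaries(Dummy(), assignment, ["x"])
        row = res.table.iloc[0]
        assert row["group0"] == row["group1"]

    def test_unknown_variable_raises(self, cohort_and_assignment):
        cohort, assignment = cohort_and_assignment
        with pytest.raises(KeyError):
            group_summaries(cohort, assignment, ["no_such_column"])
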