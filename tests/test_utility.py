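"""Marginal and refitted-model comparisons between observed and
synthetic tables."""

import numpy as np
import pandas as pd
import pytest

from cohortsynth import (
    DataTable,
    ci_overlap,
    compare_marginals,
    fit_glm_both,
)
from cohortsynth.core import ContractError


class TestCiOverlap:
    @pytest.mark.parametrize("a, b, expect", [
        ((0.0, 1.0), (0.0, 1.0), 1.0),      # identical
        ((0.0, 1.0), (2.0, 3.0), 0.0),      # disjoint
        ((0.0, 2.0), (1.0, 3.0), 0.5),      # mean(1/2, 1/2)
        ((0.0, 4.0), (1.0, 2.0), 0.625),    # mean(1/4, 1)
        ((1.0, 1.0), (1.0, 1.0), 1.0),      # equal points
        ((1.0, 1.0), (2.0, 2.0), 0.0),      # distinct points
    ])
    def test_direct_arithmetic(self, a, b, expect):
        assert ci_overlap(a, b) == pytest.approx(expect)
        assert ci_overlap(b, a) == pytest.approx(expect)  # symmetric

    def test_rejects_inverted_bounds(self):
        with pytest.raises(ContractError):
            ci_overlap((1.0, 0.0), (0.0, 1.0))

    def test_bounded_symmetric_and_maximal_on_identity(self):
        from hypothesis import given, settings, strategies as st
        bounds = st.tuples(
            st.floats(-1e6, 1e6), st.floats(0, 1e6)).map(
                lambda t: (t[0], t[0] + t[1]))

        @settings(max_examples=200, derandomize=True, deadline=None)
        @given(a=bounds, b=bounds)
        def check(a, b):
            f = ci_overlap(a, b)
            assert 0.0 <= f <= 1.0
            assert f == pytest.approx(ci_overlap(b, a))
            assert ci_overlap(a, a) == 1.0

        check()


class TestCompareMarginals:
    def test_identity_gives_zero_differences(self, cohort_small):
        table, _ = cohort_small
        comp = compare_marginals(table, table)
        assert comp.max_pct_point_diff() == 0.0
        for t in comp.tables.values():
            assert (t["abs_diff"] == 0).all()

    def test_counts_match_hand_tally(self):
        obs = DataTable.from_dataframe(pd.DataFrame({
            "g": ["a", "a", "b", "b", "b", None]}))
        syn = DataTable.from_dataframe(pd.DataFrame({
            "g": ["a", "b", "b", None, None, None]}))
        t = compare_marginals(obs, syn).tables["g"].set_index("category")
        assert t.loc["a", "observed"] == 2 and t.loc["a", "synthetic"] == 1
        assert t.loc["b", "observed"] == 3 and t.loc["b", "synthetic"] == 2
        assert t.loc["NA", "observed"] == 1 and t.loc["NA", "synthetic"] == 3
        assert t.loc["NA", "abs_diff"] == 2

    def test_counts_sum_to_table_sizes(self, cohort_small):
        from cohortsynth import synthesize
        table, _ = cohort_small
        rel = synthesize(table, seed=9)
        comp = compare_marginals(table, rel.table)
        for t in comp.tables.values():
            assert t["observed"].sum() == table.n
            assert t["synthetic"].sum() == rel.table.n

    def test_unseen_synthetic_category_reported_with_zero_observed(self):
        from cohortsynth import VariableSchema
        obs = DataTable(pd.DataFrame({"g": ["a", "b", "a"]}),
                        (VariableSchema("g", "binary", ("a", "b")),))
        syn = DataTable(pd.DataFrame({"g": ["a", "c", "c"]}),
                        (VariableSchema("g", "nominal", ("a", "b", "c")),))
        comp = compare_marginals(obs, syn)
        t = comp.tables["g"].set_index("category")
        assert t.loc["c", "observed"] == 0
        assert t.loc["c", "synthetic"] == 2

    def test_symmetry_up_to_count_swap(self, cohort_small):
        table, _ = cohort_small
        from cohortsynth import synthesize
        syn = synthesize(table, seed=10).table
        # swapping the roles swaps the count columns for shared categories
        fwd = compare_marginals(table, syn).tables["housing"].set_index("category")
        rev = compare_marginals(syn, table).tables["housing"].set_index("category")
        common = fwd.index.intersection(rev.index)
        assert (fwd.loc[common, "observed"].to_numpy()
                == rev.loc[common, "synthetic"].to_numpy()).all()


class TestFitGlmBoth:
    def test_same_data_identical_fits_and_full_overlap(self, cohort_small):
        table, _ = cohort_small
        comp = fit_glm_both("depression_17 ~ mat_dep + matage", "binomial",
                            table, table)
        t = comp.table
        np.testing.assert_allclose(t["est_obs"], t["est_syn"])
        np.testing.assert_allclose(t["ci_overlap"], 1.0)

    def test_z_times_se_equals_estimate(self, cohort_small):
        table, _ = cohort_small
        comp = fit_glm_both("bwt ~ gest + matage", "gaussian", table, table)
        t = comp.table
        np.testing.assert_allclose(t["z_obs"] * t["se_obs"], t["est_obs"],
                                   rtol=1e-12)

    def test_row_order_invariance(self, cohort_small):
        table, _ = cohort_small
        shuffled = table.with_data(
            table.data.sample(frac=1.0, random_state=0).reset_index(drop=True))
        a = fit_glm_both("depression_17 ~ mat_dep", "binomial", table, table)
        b = fit_glm_both("depression_17 ~ mat_dep", "binomial",
                         shuffled, shuffled)
        np.testing.assert_allclose(a.table["est_obs"], b.table["est_obs"],
                                   rtol=1e-8)

    def test_known_truth_recovered_on_both_tables(self):
        """Observed and synthetic-style tables simulated from the same
        logistic truth (b1 = 0.4) both recover it within 3 SE."""
        rng = np.random.default_rng(21)
        n = 20000
        frames = []
        for _ in range(2):
            x = rng.normal(size=n)
            p = 1 / (1 + np.exp(-(-1.0 + 0.4 * x)))
            y = np.where(rng.random(n) < p, "yes", "no")
            frames.append(DataTable.from_dataframe(
                pd.DataFrame({"x": x, "y": y})))
        comp = fit_glm_both("y ~ x", "binomial", *frames)
        row = comp.table.set_index("term").loc["x"]
        assert abs(row["est_obs"] - 0.4) < 3 * row["se_obs"]
        assert abs(row["est_syn"] - 0.4) < 3 * row["se_syn"]
        assert abs(row["est_obs"] - row["est_syn"]) < \
            3 * np.hypot(row["se_obs"], row["se_syn"])

    def test_multivariable_exposure_z_same_sign(self, cohort_5000):
        """Binary outcome on continuous exposure plus covariates: the
        synthetic and observed exposure z-values share a sign."""
        from cohortsynth import synthesize
        table, _ = cohort_5000
        rel = synthesize(table, seed=22)
        comp = fit_glm_both(
            "depression_17 ~ mat_dep + matage + ethnic + gender + mated + housing",
            "binomial", table, rel.table)
        row = comp.table.set_index("term").loc["mat_dep"]
        assert np.sign(row["z_obs"]) == np.sign(row["z_syn"])
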