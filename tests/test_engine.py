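"""Synthesis engine: marginal resampling, CART donor-sampling,
parametric draws, smoothing, rules and the sequential pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cohortsynth import (
    CartControls,
    Condition,
    DataTable,
    Rule,
    SequentialSynthesizer,
    VariableSchema,
    apply_rules,
    apply_smoothing,
    cart_synthesize_column,
    default_plan,
    parametric_synthesize_column,
    sample_marginal,
    synthesize,
)
from cohortsynth.core import ContractError
from cohortsynth.engine import _PredictorEncoder, CartColumnSynthesizer


class TestSampleMarginal:
    def test_constant_column(self):
        assert list(sample_marginal(pd.Series([5.0, 5.0, 5.0]), 4, seed=1)) \
            == [5.0, 5.0, 5.0, 5.0]

    def test_missing_proportion_preserved(self):
        col = pd.Series([np.nan] * 30 + [1.0] * 70)
        out = pd.Series(sample_marginal(col, 10000, seed=2))
        p = out.isna().mean()
        se = np.sqrt(0.3 * 0.7 / 10000)
        assert abs(p - 0.3) < 3 * se

    def test_uniform_over_rows(self):
        col = pd.Series(["A"] * 50 + ["B"] * 50)
        out = pd.Series(sample_marginal(col, 10000, seed=3))
        counts = out.value_counts()
        chi2, p = stats.chisquare([counts["A"], counts["B"]])
        assert p > 0.001

    def test_rejects_nonpositive_size(self):
        with pytest.raises(ContractError):
            sample_marginal(pd.Series([1.0]), 0)


def _schemas(**kinds):
    out = {}
    for name, kind in kinds.items():
        if isinstance(kind, tuple):
            out[name] = VariableSchema(name, kind[0], kind[1])
        else:
            out[name] = VariableSchema(name, kind)
    return out


class TestCartColumn:
    def test_pure_leaves_reproduce_deterministic_map(self):
        x = pd.DataFrame({"x": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]})
        y = pd.Series([10.0, 10.0, 10.0, 20.0, 20.0, 20.0])
        xs = pd.DataFrame({"x": [1.0, 0.0, 1.0, 0.0]})
        out = cart_synthesize_column(
            y, x, xs, _schemas(x="continuous"), kind="continuous",
            controls=CartControls(min_leaf=1), seed=4)
        assert list(out) == [20.0, 10.0, 20.0, 10.0]

    def test_out_of_range_predictor_routed_not_raised(self):
        x = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]})
        y = pd.Series([0.0, 0.0, 0.0, 9.0, 9.0, 9.0])
        xs = pd.DataFrame({"x": [-100.0, 100.0]})
        out = cart_synthesize_column(
            y, x, xs, _schemas(x="continuous"), kind="continuous",
            controls=CartControls(min_leaf=1), seed=0)
        assert list(out) == [0.0, 9.0]

    def test_depth1_split_matches_exhaustive_enumeration(self):
        """Leaf membership and donor sets of a depth-1 regression tree
        equal the best single split found by brute force over all
        (feature, midpoint) partitions (SSE criterion)."""
        rng = np.random.default_rng(12)
        for trial in range(8):
            n = int(rng.integers(6, 11))
            X = pd.DataFrame({
                "a": np.round(rng.normal(size=n), 3),
                "b": np.round(rng.normal(size=n), 3),
            })
            y = pd.Series(np.round(rng.normal(size=n) + 2 * X["a"], 3))

            def sse(v):
                return float(((v - v.mean()) ** 2).sum()) if len(v) else 0.0

            best, best_part = np.inf, None
            for feat in X.columns:
                vals = np.sort(X[feat].unique())
                for lo, hi in zip(vals[:-1], vals[1:]):
                    thr = (lo + hi) / 2
                    left = X.index[X[feat] <= thr]
                    right = X.index[X[feat] > thr]
                    total = sse(y[left]) + sse(y[right])
                    if total < best - 1e-12:
                        best = total
                        best_part = {frozenset(left), frozenset(right)}

            enc = _PredictorEncoder().fit(X, _schemas(a="continuous",
                                                      b="continuous"))
            model = CartColumnSynthesizer(
                kind="continuous",
                controls=CartControls(min_leaf=1, max_depth=1),
                random_state=0).fit(enc.transform(X), y)
            leaves = model.leaf_assignments(enc.transform(X))
            got = {frozenset(np.flatnonzero(leaves == l)) for l in set(leaves)}
            assert got == best_part, f"trial {trial}"
            # donor sets per leaf are exactly the observed values there
            for leaf in set(leaves):
                donors = sorted(model.donors_[int(leaf)])
                expect = sorted(y[np.flatnonzero(leaves == leaf)])
                assert donors == expect

    def test_conditional_means_preserved_at_scale(self):
        rng = np.random.default_rng(5)
        n = 5000
        x = rng.integers(0, 4, n).astype(float)
        y = 3.0 * x + rng.normal(0, 1, n)
        obs = pd.DataFrame({"x": x})
        target = pd.Series(y)
        out = cart_synthesize_column(
            target, obs, obs, _schemas(x="continuous"),
            kind="continuous", seed=6)
        out = pd.Series(np.asarray(out, float))
        for bin_ in range(4):
            sel = x == bin_
            mu_obs = target[sel].mean()
            mu_syn = out[sel].mean()
            sd = target[sel].std()
            se = sd * np.sqrt(2.0 / sel.sum())
            assert abs(mu_obs - mu_syn) < 3 * se, bin_


class TestParametric:
    def test_noiseless_line_reproduced_exactly(self):
        x = pd.DataFrame({"x": np.arange(10.0)})
        y = pd.Series(2.0 * x["x"])
        xs = pd.DataFrame({"x": np.array([1.5, 3.5, 7.0])})
        out = parametric_synthesize_column(
            y, x, xs, _schemas(x="continuous"), family="norm", seed=7)
        np.testing.assert_allclose(np.asarray(out, float),
                                   [3.0, 7.0, 14.0], atol=1e-8)

    def test_null_logit_preserves_marginal_rate(self):
        rng = np.random.default_rng(8)
        n = 4000
        x = pd.DataFrame({"x": rng.normal(size=n)})
        y = pd.Series(np.where(rng.random(n) < 0.5, "yes", "no"))
        out = parametric_synthesize_column(
            y, x, x, _schemas(x="continuous"), family="logit", seed=9)
        rate_obs = (y == "yes").mean()
        rate_syn = (pd.Series(out) == "yes").mean()
        se = np.sqrt(rate_obs * (1 - rate_obs) * 2 / n)
        assert abs(rate_obs - rate_syn) < 3 * se

    def test_known_logistic_model_recovered(self):
        """Synthetic draws from a logit fit of y ~ x with truth
        (b0, b1) = (-1, 0.5) refit to the generating coefficients."""
        import statsmodels.api as sm
        rng = np.random.default_rng(10)
        n = 20000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-1.0 + 0.5 * x)))
        y = pd.Series(np.where(rng.random(n) < p, "1", "0"))
        obs = pd.DataFrame({"x": x})
        out = parametric_synthesize_column(
            y, obs, obs, _schemas(x="continuous"), family="logit", seed=11)
        y_syn = (pd.Series(out) == "1").astype(float)
        fit = sm.GLM(y_syn, sm.add_constant(x),
                     family=sm.families.Binomial()).fit()
        for truth, est, se in zip((-1.0, 0.5), fit.params, fit.bse):
            assert abs(est - truth) < 3 * se


class TestSmoothing:
    def test_zero_bandwidth_is_identity(self):
        col = np.array([1.0, 2.0, np.nan, 3.0])
        out = apply_smoothing(col, bandwidth=0.0, seed=1)
        np.testing.assert_array_equal(np.asarray(out, float)[[0, 1, 3]],
                                      [1.0, 2.0, 3.0])
        assert np.isnan(np.asarray(out, float)[2])

    def test_reduces_exact_match_share(self):
        rng = np.random.default_rng(2)
        observed = np.round(rng.normal(size=500), 1)
        synthetic = rng.choice(observed, 500)
        before = np.isin(synthetic, observed).mean()
        out = np.asarray(apply_smoothing(synthetic, seed=3), float)
        after = np.isin(out, observed).mean()
        assert after < before

    def test_convolution_identity_for_mean_and_variance(self):
        rng = np.random.default_rng(4)
        col = rng.normal(10, 2, 20000)
        bw = 0.5
        out = np.asarray(apply_smoothing(col, bandwidth=bw, seed=5,
                                         clip_range=(-1e9, 1e9)), float)
        n = len(col)
        assert abs(out.mean() - col.mean()) < 3 * bw / np.sqrt(n)
        target_var = col.var() + bw ** 2
        se_var = target_var * np.sqrt(2.0 / n) * 2
        assert abs(out.var() - target_var) < 3 * se_var

    def test_constant_column_unchanged_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = apply_smoothing(np.array([2.0, 2.0, 2.0]), seed=6)
        np.testing.assert_array_equal(np.asarray(out, float), [2.0] * 3)


@pytest.fixture
def smoking_table():
    df = pd.DataFrame({
        "ever_smoked": ["never", "past", "current", "never", np.nan],
        "per_day": [3.0, 10.0, 15.0, 7.0, 2.0],
    })
    return DataTable(df, (
        VariableSchema("ever_smoked", "nominal", ("never", "past", "current")),
        VariableSchema("per_day", "continuous"),
    ))


class TestRules:
    def test_never_smokers_forced_to_zero(self, smoking_table):
        rule = Rule("per_day", 0.0, (Condition("ever_smoked", "==", "never"),))
        out = apply_rules(smoking_table, (rule,))
        expect = [0.0, 10.0, 15.0, 0.0, 2.0]  # missing row untouched
        np.testing.assert_array_equal(out.data["per_day"].to_numpy(float),
                                      expect)

    def test_empty_rule_list_is_identity(self, smoking_table):
        out = apply_rules(smoking_table, ())
        pd.testing.assert_frame_equal(out.data, smoking_table.data)

    def test_non_overlapping_rules_commute(self, smoking_table):
        r1 = Rule("per_day", 0.0, (Condition("ever_smoked", "==", "never"),))
        r2 = Rule("per_day", 99.0, (Condition("ever_smoked", "==", "current"),))
        ab = apply_rules(apply_rules(smoking_table, (r1,)), (r2,))
        ba = apply_rules(apply_rules(smoking_table, (r2,)), (r1,))
        pd.testing.assert_frame_equal(ab.data, ba.data)


class TestSequentialSynthesizer:
    def test_determinism_bit_identical(self, cohort_small):
        table, _ = cohort_small
        a = synthesize(table, seed=42)
        b = synthesize(table, seed=42)
        pd.testing.assert_frame_equal(a.table.data, b.table.data)
        assert a.provenance == b.provenance

    def test_support_containment_without_smoothing(self, cohort_small):
        table, _ = cohort_small
        rel = synthesize(table, seed=1)
        for s in table.schema:
            obs = set(table.data[s.name].dropna())
            syn = set(rel.table.data[s.name].dropna())
            assert syn <= obs, s.name

    def test_sequentiality_trace(self, cohort_small):
        table, _ = cohort_small
        synth = SequentialSynthesizer(seed=2).fit(table)
        synth.sample()
        seen = set()
        for target, preds in synth.trace_:
            assert set(preds) <= seen, target
            seen.add(target)

    def test_sample_only_plan_destroys_association(self):
        rng = np.random.default_rng(13)
        g = rng.choice(["a", "b"], 2000)
        df = pd.DataFrame({"u": g, "v": g})  # perfectly associated
        table = DataTable.from_dataframe(df)
        plan = default_plan(table, method="sample", seed=3)
        rel = synthesize(table, plan)
        syn = rel.table.data
        tab = pd.crosstab(syn["u"], syn["v"]).to_numpy()
        chi2 = stats.chi2_contingency(tab)[0]
        v = np.sqrt(chi2 / tab.sum())
        assert v < 0.1
        # marginals preserved within 3 binomial SE
        for col in ("u", "v"):
            p_obs = (df[col] == "a").mean()
            p_syn = (syn[col] == "a").mean()
            assert abs(p_obs - p_syn) < 3 * np.sqrt(p_obs * (1 - p_obs) * 2 / 2000)

    def test_smoothing_exempts_rule_forced_values(self):
        rng = np.random.default_rng(14)
        n = 400
        smoked = rng.choice(["never", "current"], n)
        amount = np.where(smoked == "never", 0.0,
                          np.round(rng.gamma(5, 2, n), 1))
        table = DataTable.from_dataframe(
            pd.DataFrame({"smoked": smoked, "amount": amount}))
        rule = Rule("amount", 0.0, (Condition("smoked", "==", "never"),))
        plan = default_plan(table, seed=4, smoothing=("amount",), rules=(rule,))
        rel = synthesize(table, plan)
        syn = rel.table.data
        forced = syn.loc[syn["smoked"] == "never", "amount"].to_numpy(float)
        np.testing.assert_array_equal(forced, np.zeros(len(forced)))

    def test_invalid_plan_aborts_with_column_named(self, toy_table):
        plan = default_plan(toy_table)
        plan.predictors["sex"] = ("height",)
        with pytest.raises(ContractError, match="sex"):
            synthesize(toy_table, plan)

    def test_refitted_exposure_coefficient_inside_observed_ci(self, cohort_5000):
        """A default CART synthesis preserves the exposure-outcome
        association: the synthetic logistic coefficient falls inside
        the observed fit's 95% CI."""
        from cohortsynth import fit_glm_both
        table, _ = cohort_5000
        rel = synthesize(table, seed=20)
        comp = fit_glm_both("depression_17 ~ mat_dep", "binomial",
                            table, rel.table)
        row = comp.table.set_index("term").loc["mat_dep"]
        assert row["ci_lo_obs"] <= row["est_syn"] <= row["ci_hi_obs"]
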