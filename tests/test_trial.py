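"""Mixed trial models: REML components, BLUPs, LRT, Tukey HSD, regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermoqtl import simulate as sim
from thermoqtl.errors import DomainError, InvalidParameterError, LookupError_
from thermoqtl.trial import (
    TrialModel,
    average_blups,
    fit_fixed_tukey,
    lrt_drop_term,
    trait_regression,
    variance_partition,
)


def balanced_oneway(n_groups=25, reps=4, sg=1.3, se=0.7, seed=3):
    rng = np.random.default_rng(seed)
    eff = rng.normal(0, sg, n_groups)
    rows = [
        {"line_id": f"g{i:02d}", "row": j + 1, "column": 1,
         "y": 10 + eff[i] + rng.normal(0, se)}
        for i in range(n_groups) for j in range(reps)
    ]
    return pd.DataFrame(rows), n_groups, reps


class TestRandomTrialModel:
    def test_constant_response_gives_zero_components(self):
        df, *_ = balanced_oneway()
        df["y"] = 4.2
        res = TrialModel(df, "y", random_terms=("genotype",)).fit()
        assert res.variance_components["genotype"] == 0.0
        assert res.resid_variance == 0.0
        assert (res.blups == 0).all()
        assert res.intercept == 4.2

    def test_matches_balanced_anova_closed_form(self):
        # REML in a balanced one-way layout equals the ANOVA estimators
        # sigma2_e = MSE, sigma2_g = (MSG - MSE) / r
        df, g, r = balanced_oneway()
        y = df["y"].to_numpy().reshape(g, r)
        gm = y.mean(axis=1)
        msg = r * np.sum((gm - y.mean()) ** 2) / (g - 1)
        mse = np.sum((y - gm[:, None]) ** 2) / (g * (r - 1))
        res = TrialModel(df, "y", random_terms=("genotype",)).fit(tol=1e-12, maxiter=20000)
        assert res.variance_components["genotype"] == pytest.approx((msg - mse) / r, abs=1e-6)
        assert res.resid_variance == pytest.approx(mse, abs=1e-6)

    def test_blup_shrinkage_bound(self):
        # |BLUP| never exceeds |raw genotype mean - grand mean|
        df, g, r = balanced_oneway(seed=8)
        res = TrialModel(df, "y", random_terms=("genotype",)).fit()
        raw = df.groupby("line_id")["y"].mean() - df["y"].mean()
        assert (res.blups.abs() <= raw.loc[res.blups.index].abs() + 1e-8).all()
        assert abs(res.blups.sum()) < 1e-6

    def test_recovers_augmented_design_components(self, study_map, bc2s3):
        # truth sigma2_g=1, row=col=0.25, e=1; median recovery over seeds
        vs = sim.VarianceSpec(1.0, 0.25, 0.25, 1.0)
        est = []
        for s in range(9):
            lay = sim.make_augmented_layout(
                160, n_rows=16, n_columns=15, seed=300 + s, entry_ids=bc2s3.line_ids
            )
            ph = sim.simulate_phenotypes(
                bc2s3, study_map, [], lay, vs, seed=400 + s, traits=["y"]
            )
            res = TrialModel(ph, "y").fit()
            est.append(
                [res.variance_components["genotype"],
                 res.variance_components["row"],
                 res.variance_components["column"],
                 res.resid_variance]
            )
        med = np.median(np.array(est), axis=0)
        truth = np.array([1.0, 0.25, 0.25, 1.0])
        assert np.all(np.abs(med - truth) / truth < 0.25)

    def test_partition_permutation_invariant_to_relabeling(self, study_map, bc2s3):
        vs = sim.VarianceSpec(1.0, 0.25, 0.25, 1.0)
        lay = sim.make_augmented_layout(
            160, n_rows=16, n_columns=15, seed=1, entry_ids=bc2s3.line_ids
        )
        ph = sim.simulate_phenotypes(bc2s3, study_map, [], lay, vs, seed=2, traits=["y"])
        res1 = TrialModel(ph, "y").fit()
        relab = ph.copy()
        rmap = {r: 100 - r for r in relab["row"].unique()}
        cmap = {c: 200 - c for c in relab["column"].unique()}
        relab["row"] = relab["row"].map(rmap)
        relab["column"] = relab["column"].map(cmap)
        res2 = TrialModel(relab, "y").fit()
        pd.testing.assert_series_equal(
            res1.variance_partition(), res2.variance_partition(), atol=1e-6
        )


class TestVariancePartition:
    def test_half_half(self):
        p = variance_partition({"genotype": 1.0, "row": 0.0, "column": 0.0, "residual": 1.0})
        assert p["genotype"] == 50.0 and p["residual"] == 50.0

    def test_percentages_reproduce_themselves(self):
        # a published-style turgor partition given as percentages of their sum
        p = variance_partition(
            {"genotype": 45.55, "row": 11.40, "column": 5.64, "residual": 37.41}
        )
        assert p["genotype"] == pytest.approx(45.55, abs=0.01)
        assert p["row"] == pytest.approx(11.40, abs=0.01)
        assert p["column"] == pytest.approx(5.64, abs=0.01)
        assert p["residual"] == pytest.approx(37.41, abs=0.01)

    def test_sums_to_100(self, rng):
        comps = dict(zip("abcd", rng.uniform(0.1, 5, 4)))
        assert variance_partition(comps).sum() == pytest.approx(100.0, abs=0.01)

    def test_zero_total_rejected(self):
        with pytest.raises(DomainError):
            variance_partition({"a": 0.0, "b": 0.0})


class TestAverageBlups:
    def test_identical_environments(self):
        b = pd.Series({"a": 0.3, "b": -0.1})
        out = average_blups({"summer": b, "fall": b})
        pd.testing.assert_series_equal(out, b, check_names=False)

    def test_opposite_values_cancel(self):
        out = average_blups(
            {"e1": pd.Series({"a": 0.2}), "e2": pd.Series({"a": -0.2})}
        )
        assert out["a"] == 0.0

    def test_partial_coverage_averages_available(self):
        out = average_blups(
            {"e1": pd.Series({"a": 0.2, "b": 1.0}), "e2": pd.Series({"a": 0.4})}
        )
        assert out["a"] == pytest.approx(0.3)
        assert out["b"] == pytest.approx(1.0)

    def test_absent_everywhere_raises(self):
        with pytest.raises(LookupError_):
            average_blups(
                {"e1": pd.Series({"a": np.nan}), "e2": pd.Series({"a": np.nan})}
            )


class TestLrt:
    def _sim(self, sg, seed):
        rng = np.random.default_rng(seed)
        rows = []
        eff = rng.normal(0, np.sqrt(sg), 40) if sg > 0 else np.zeros(40)
        roweff = rng.normal(0, 0.5, 8)
        for i in range(40):
            for j in range(4):
                r = rng.integers(0, 8)
                rows.append(
                    {"line_id": f"g{i}", "row": r + 1, "column": 1,
                     "y": eff[i] + roweff[r] + rng.normal(0, 1)}
                )
        return pd.DataFrame(rows)

    def test_null_term_yields_large_p(self):
        ps = [
            lrt_drop_term(self._sim(0.0, s), "y", "genotype",
                          random_terms=("genotype", "row")).p_value
            for s in range(12)
        ]
        assert np.median(ps) >= 0.3  # conservative-or-uniform under the null

    def test_strong_term_detected(self):
        ps = [
            lrt_drop_term(self._sim(2.0, s), "y", "genotype",
                          random_terms=("genotype", "row")).p_value
            for s in range(8)
        ]
        assert np.mean(np.array(ps) < 0.01) >= 0.95

    def test_bic_favors_true_model(self):
        cmp_ = lrt_drop_term(self._sim(2.0, 1), "y", "genotype",
                             random_terms=("genotype", "row"))
        assert cmp_.bic_full < cmp_.bic_reduced
        assert cmp_.statistic >= 0

    def test_unknown_term_rejected(self):
        with pytest.raises(InvalidParameterError):
            lrt_drop_term(self._sim(0.0, 0), "y", "block",
                          random_terms=("genotype", "row"))


class TestTukey:
    def _groups(self, means, reps=6, se=0.5, seed=0):
        rng = np.random.default_rng(seed)
        rows = [
            {"grp": f"G{i}", "block": j % 2, "y": m + rng.normal(0, se)}
            for i, m in enumerate(means) for j in range(reps)
        ]
        return pd.DataFrame(rows)

    def test_identical_groups_share_letter(self):
        df = self._groups([5.0, 5.0], se=0.3)
        res = fit_fixed_tukey(df, "y", "grp", "block")
        assert res.letters["G0"] == res.letters["G1"] == "a"

    def test_separated_groups_distinct_letters(self):
        df = self._groups([0.0, 1e6], se=0.5)
        res = fit_fixed_tukey(df, "y", "grp", "block")
        assert not set(res.letters["G0"]) & set(res.letters["G1"])

    def test_studentized_range_quantile_oracle(self):
        # q(0.05, k=3, df=10) = 3.877 from tabulated quadrature of the
        # studentized-range distribution
        q = stats.studentized_range.ppf(0.95, 3, 10)
        assert q == pytest.approx(3.877, abs=1e-3)

    def test_three_groups_middle_shares_both(self):
        df = self._groups([0.0, 1.2, 2.4], reps=8, se=0.6, seed=5)
        res = fit_fixed_tukey(df, "y", "grp", "block")
        # monotone means: letters respect ordering; extremes differ
        if not set(res.letters["G0"]) & set(res.letters["G2"]):
            assert res.group_means["G0"] < res.group_means["G2"]

    def test_single_observation_groups_rejected(self):
        df = pd.DataFrame({"grp": ["a", "b"], "y": [1.0, 2.0]})
        with pytest.raises(InvalidParameterError):
            fit_fixed_tukey(df, "y", "grp")


class TestTraitRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = trait_regression(x, 2 * x)
        assert res.slope == pytest.approx(2.0) and res.r_squared == pytest.approx(1.0)

    def test_independent_noise_r2_near_zero(self):
        r2 = [
            trait_regression(
                np.random.default_rng(s).normal(size=1000),
                np.random.default_rng(s + 1000).normal(size=1000),
            ).r_squared
            for s in range(9)
        ]
        assert np.median(r2) < 0.01

    def test_degenerate_x_rejected(self):
        with pytest.raises(DomainError):
            trait_regression(np.ones(5), np.arange(5.0))

    def test_too_few_points(self):
        with pytest.raises(InvalidParameterError):
            trait_regression([1.0, 2.0], [1.0, 2.0])
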