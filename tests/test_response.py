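import numpy as np
import pandas as pd
import pytest

from soyphen.response import (
    PCAResult,
    correlation_suite,
    cv_of_yr,
    drought_index,
    pca_biplot,
    reduce_variables,
    yr_table,
)


class TestDroughtIndex:
    @pytest.mark.parametrize(
        "control, drought, expected",
        # treatment means of maximum canopy height and growth rate: the
        # index rounds to 0.11 / 0.22 / 0.22
        [(87.57, 78.00, 0.11), (12.51, 9.70, 0.22), (12.07, 9.42, 0.22)],
    )
    def test_worked_examples_round_to_published_precision(self, control, drought, expected):
        assert round(drought_index(control, drought), 2) == expected

    def test_equal_performance_is_zero(self):
        assert drought_index(5.0, 5.0) == 0.0

    def test_sign_convention_higher_under_drought_is_negative(self):
        assert drought_index(5.0, 6.0) == pytest.approx(-0.2)

    def test_control_at_floor_is_missing_with_warning(self):
        with pytest.warns(UserWarning):
            out = drought_index(np.array([0.0, 10.0]), np.array([1.0, 5.0]), floor=1e-6)
        assert np.isnan(out[0]) and out[1] == pytest.approx(0.5)


class TestYrTable:
    def _blups(self, ids, **cols):
        return pd.DataFrame(cols, index=pd.Index(ids, name="genotype_id"))

    def test_disjoint_genotype_sets_raise(self):
        with pytest.raises(ValueError, match="both treatments"):
            yr_table(self._blups(["a"], CH=[1.0]), self._blups(["b"], CH=[1.0]))

    def test_identical_tables_give_zero_index_and_full_overlap(self):
        t = self._blups(list("abc"), CH=[80.0, 85.0, 90.0])
        out = yr_table(t, t.copy())
        assert (out["yr"] == 0.0).all()
        assert (out["n_common"] == 3).all()

    def test_pre_drought_and_habit_traits_are_skipped(self):
        c = self._blups(list("ab"), CH=[80.0, 85.0], PLV=[10.0, 11.0], CC75=[450.0, 460.0], DET=[400.0, 420.0])
        out = yr_table(c, c.copy())
        assert set(out["trait"]) == {"CH"}

    def test_uniform_multiplicative_reduction_recovered(self):
        rng = np.random.default_rng(0)
        base = 80 + rng.normal(0, 6, 200)
        c = self._blups([f"g{i}" for i in range(200)], CH=base)
        d = self._blups([f"g{i}" for i in range(200)], CH=0.71 * base)
        out = yr_table(c, d)
        np.testing.assert_allclose(out["yr"], 0.29, rtol=1e-12)


class TestCV:
    def test_constant_values_have_zero_cv(self):
        assert cv_of_yr([0.1, 0.1, 0.1]) == pytest.approx(0.0, abs=1e-12)

    def test_ratio_definition(self):
        x = np.array([0.15, 0.25])  # mean 0.2, sd 0.0707
        assert cv_of_yr(x) == pytest.approx(100 * np.std(x, ddof=1) / 0.2)

    def test_two_pass_oracle(self, rng):
        x = rng.normal(0.3, 0.1, 500)
        mean = sum(x) / len(x)
        sd = (sum((v - mean) ** 2 for v in x) / (len(x) - 1)) ** 0.5
        assert cv_of_yr(x) == pytest.approx(100 * sd / abs(mean), rel=1e-12)


class TestCorrelations:
    def test_self_and_negated_correlations(self, rng):
        y = rng.normal(0, 1, 40)
        tab = pd.DataFrame({"a": y, "b": -y}, index=[f"g{i}" for i in range(40)])
        out = correlation_suite({"t": tab})
        r = out.loc[(out["x"] == "a") & (out["y"] == "b"), "r"].iloc[0]
        assert r == pytest.approx(-1.0)

    def test_matches_definition_oracle(self, rng):
        a, b = rng.normal(0, 1, 60), rng.normal(0, 1, 60)
        tab = pd.DataFrame({"a": a, "b": b})
        out = correlation_suite({"t": tab})
        got = out["r"].iloc[0]
        want = np.cov(a, b, ddof=1)[0, 1] / (np.std(a, ddof=1) * np.std(b, ddof=1))
        assert got == pytest.approx(want, abs=1e-12)

    def test_cross_table_same_trait_family(self, rng):
        y = rng.normal(0, 1, 30)
        t1 = pd.DataFrame({"CH": y}, index=range(30))
        t2 = pd.DataFrame({"CH": y * 0.7 + rng.normal(0, 0.1, 30)}, index=range(30))
        out = correlation_suite({"c2018": t1, "c2019": t2})
        fam = out[out["family"] == "c2018~c2019"]
        assert len(fam) == 1 and fam["r"].iloc[0] > 0.9

    def test_too_few_pairs_is_missing(self):
        t = pd.DataFrame({"a": [1.0, 2.0, np.nan], "b": [1.0, np.nan, 3.0]})
        out = correlation_suite({"t": t})
        assert np.isnan(out["r"].iloc[0]) and out["n"].iloc[0] == 1


class TestReduceVariables:
    def test_duplicate_column_dropped(self, rng):
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(0, 1, 50)})
        kept, dropped = reduce_variables(df)
        assert kept == ["a", "c"]
        assert dropped[0][:2] == ("b", "a")

    def test_uncorrelated_variables_all_retained(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (60, 4)), columns=list("abcd"))
        kept, dropped = reduce_variables(df)
        assert kept == list("abcd") and not dropped

    def test_composite_duration_is_redundant(self):
        # R2R8 = R2R5 + R5R8 with strongly correlated parts is dropped
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            r2r5 = rng.normal(300, 60, 150)
            r5r8 = 0.8 * r2r5 + rng.normal(500, 20, 150)
            df = pd.DataFrame({"R2R5": r2r5, "R5R8": r5r8, "R2R8": r2r5 + r5r8})
            kept, _ = reduce_variables(df, {"dev": ["R2R5", "R5R8", "R2R8"]})
            hits += "R2R8" not in kept
        assert hits >= 18

    def test_subsets_limit_comparisons(self, rng):
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({"a": x, "b": x.copy()})
        kept, _ = reduce_variables(df, {"s1": ["a"], "s2": ["b"]})
        assert kept == ["a", "b"]  # duplicates in different subsets both stay


class TestPCA:
    def test_two_perfectly_correlated_variables(self, rng):
        x = rng.normal(0, 1, 40)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1}, index=range(40))
        res = pca_biplot(df)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (80, 5)), columns=list("abcde"))
        res = pca_biplot(df)
        gram = res.loadings.to_numpy().T @ res.loadings.to_numpy()
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-10)

    def test_scores_reconstruct_standardized_data(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (50, 4)), columns=list("abcd"))
        res = pca_biplot(df)
        z = (df - df.mean()) / df.std(ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, z.to_numpy(), atol=1e-8)

    def test_constant_column_error_names_column(self, rng):
        df = pd.DataFrame({"a": rng.normal(0, 1, 30), "flat": 1.0})
        with pytest.raises(ValueError, match="flat"):
            pca_biplot(df)

    def test_variance_explained_invariant_to_order_and_scale(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (60, 3)), columns=list("abc"))
        base = pca_biplot(df).explained_variance_ratio
        shuffled = pca_biplot(df[["c", "a", "b"]]).explained_variance_ratio
        rescaled = pca_biplot(df.assign(a=df["a"] * 37.0 + 5.0)).explained_variance_ratio
        np.testing.assert_allclose(base, shuffled, atol=1e-12)
        np.testing.assert_allclose(base, rescaled, atol=1e-12)

    def test_too_few_complete_rows(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (4, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="complete-case"):
            pca_biplot(df)

    def test_summary_mentions_dropped_variables(self, rng):
        x = rng.normal(0, 1, 40)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(0, 1, 40)})
        res = pca_biplot(df, r_threshold=0.8)
        assert isinstance(res, PCAResult)
        assert "dropped b" in res.summary()
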