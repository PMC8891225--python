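import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soyphen.design import build_design
from soyphen.mixedmodel import (
    AugmentedTrialModel,
    ModelSpec,
    TrialFitResults,
    candidate_models,
    filter_emergence,
    h2_class,
    heritability,
    maybe_transform,
    select_model,
    summarize_blups,
    tukey_clean,
)
from soyphen.simulate import EffectConfig, simulate_effects

GENO_ONLY = ModelSpec(("genotype",))


def balanced_oneway(seed, g=12, r=5, sg=1.2, se=1.0):
    """Balanced g x r one-way layout plus its closed-form ANOVA/BLUP oracle."""
    rng = np.random.default_rng(seed)
    names = [f"G{i:03d}" for i in range(g)]
    y = np.repeat(rng.normal(0, sg, g), r) + rng.normal(0, se, g * r) + rng.normal(0, 3)
    df = pd.DataFrame({"genotype_id": np.repeat(names, r), "block": 1, "row": 1, "column": 1})
    ym = y.reshape(g, r)
    gm, grand = ym.mean(axis=1), y.mean()
    msb = r * np.sum((gm - grand) ** 2) / (g - 1)
    mse = np.sum((ym - gm[:, None]) ** 2) / (g * (r - 1))
    s2g = max((msb - mse) / r, 0.0)
    shrink = s2g / (s2g + mse / r) if s2g + mse / r > 0 else 0.0
    blup_dev = pd.Series(shrink * (gm - grand), index=names)
    return y, df, {"genotype": s2g, "residual": mse, "blup_dev": blup_dev, "grand": grand}


class TestCandidateModels:
    def test_exactly_six_specs_all_with_genotype(self):
        specs = candidate_models()
        assert len(specs) == 6
        assert all("genotype" in s.random_terms for s in specs)

    def test_specs_are_distinct_term_sets(self):
        sets = {frozenset(s.random_terms) for s in candidate_models()}
        assert len(sets) == 6

    def test_no_spec_mixes_crossed_and_nested_versions(self):
        for s in candidate_models():
            assert not ({"column", "column_in_block"} <= set(s.random_terms))
            assert not ({"row", "row_in_block"} <= set(s.random_terms))

    def test_spec_invariants_enforced(self):
        with pytest.raises(ValueError, match="genotype"):
            ModelSpec(("block",))
        with pytest.raises(ValueError, match="duplicated"):
            ModelSpec(("genotype", "block", "block"))
        with pytest.raises(ValueError, match="co-occur"):
            ModelSpec(("genotype", "column", "column_in_block"))


class TestREMLOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_balanced_oneway_matches_anova_and_shrinkage(self, seed):
        y, df, oracle = balanced_oneway(seed)
        fit = AugmentedTrialModel(y, df).fit(GENO_ONLY)
        assert fit.varcomps["genotype"] == pytest.approx(oracle["genotype"], abs=1e-6)
        assert fit.varcomps["residual"] == pytest.approx(oracle["residual"], abs=1e-6)
        dev = (fit.genotype_blups - fit.intercept).loc[oracle["blup_dev"].index]
        np.testing.assert_allclose(dev.to_numpy(), oracle["blup_dev"].to_numpy(), atol=1e-8)

    def test_null_genotype_variance_estimated_near_zero(self):
        h2s = []
        for seed in range(15):
            y, df, _ = balanced_oneway(seed, g=20, r=4, sg=0.0)
            h2s.append(AugmentedTrialModel(y, df).fit(GENO_ONLY).h2)
        assert np.median(h2s) < 0.05

    def test_refitting_identical_data_is_deterministic(self):
        y, df, _ = balanced_oneway(7)
        a = AugmentedTrialModel(y, df).fit(GENO_ONLY)
        b = AugmentedTrialModel(y, df).fit(GENO_ONLY)
        assert a.varcomps == b.varcomps
        pd.testing.assert_series_equal(a.genotype_blups, b.genotype_blups)

    def test_aic_counting_rule(self):
        y, df, _ = balanced_oneway(3)
        fit = AugmentedTrialModel(y, df).fit(GENO_ONLY)
        # genotype + residual variance + intercept = 3 parameters
        assert fit.n_params == 3
        assert fit.aic == pytest.approx(-2 * fit.loglik_reml + 6)

    def test_shrinkage_never_exceeds_raw_mean_spread(self):
        for seed in range(5):
            y, df, _ = balanced_oneway(seed, g=15, r=3)
            fit = AugmentedTrialModel(y, df).fit(GENO_ONLY)
            raw_sd = pd.Series(y).groupby(df["genotype_id"].to_numpy()).mean().std()
            assert fit.blup_deviations.std() <= raw_sd + 1e-12


class TestAugmentedRecovery:
    def test_variance_components_recovered_on_augmented_design(self):
        """Generative/analytic duality at trial scale (mean over 50 seeds).

        An 8x7 block grid gives the row/column factors enough levels for
        their variances to be identifiable at this precision.
        """
        truth = {"genotype": 4.0, "block": 1.0, "row": 0.5, "column": 0.5, "residual": 4.0}
        design = build_design(grid=(8, 7), seed=0)
        spec = ModelSpec(("genotype", "block", "row", "column"))
        acc = {k: [] for k in truth}
        for seed in range(50):
            cfg = {
                "Y": EffectConfig(
                    mu=50.0, sigma2_g=4.0, sigma2_block=1.0,
                    sigma2_row=0.5, sigma2_col=0.5, sigma2_e=4.0,
                )
            }
            values, _ = simulate_effects(design, cfg, seed=seed)
            df = design.frame.merge(values, left_on="plot_id", right_index=True)
            fit = AugmentedTrialModel(df["Y"], df).fit(spec)
            for k in truth:
                acc[k].append(fit.varcomps[k])
        for k, want in truth.items():
            assert np.mean(acc[k]) == pytest.approx(want, rel=0.15)

    def test_model_selection_prefers_block_when_block_variance_exists(self):
        design = build_design(
            n_unreplicated=60, check_classes=((4, 6), (6, 3)), grid=(6, 6), n_blocks=3, seed=1
        )
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = {
                "Y": EffectConfig(
                    mu=20.0, sigma2_g=2.0, sigma2_block=2.0,
                    sigma2_row=1.0, sigma2_col=0.0, sigma2_e=1.0,
                )
            }
            values, _ = simulate_effects(design, cfg, seed=seed)
            df = design.frame.merge(values, left_on="plot_id", right_index=True)
            best = AugmentedTrialModel(df["Y"], df).fit_best()
            wins += "block" in best.spec.random_terms
        assert wins >= 0.9 * n_seeds


class TestSelection:
    def _fit(self, aic, n_params, converged=True):
        return TrialFitResults(
            spec=GENO_ONLY, varcomps={"genotype": 1.0, "residual": 1.0},
            loglik_reml=-(aic - 2 * n_params) / 2, aic=aic, n_params=n_params,
            intercept=0.0, genotype_blups=pd.Series(dtype=float), converged=converged, n_obs=10,
        )

    def test_lowest_aic_wins(self):
        fits = [self._fit(206, 4), self._fit(210, 4), self._fit(204, 4)]
        assert select_model(fits).aic == 204

    def test_tie_breaks_to_fewest_parameters(self):
        fits = [self._fit(204, 4), self._fit(204, 3)]
        assert select_model(fits).n_params == 3

    def test_nonconverged_fits_excluded(self):
        fits = [self._fit(100, 3, converged=False), self._fit(204, 4)]
        assert select_model(fits).aic == 204
        with pytest.raises(ValueError, match="no candidate"):
            select_model([self._fit(100, 3, converged=False)])


class TestHeritability:
    @pytest.mark.parametrize(
        "vg, ve, h2, cls",
        [(3.0, 1.0, 0.75, "high"), (0.0, 1.0, 0.0, "low"), (1.0, 1.0, 0.5, "medium")],
    )
    def test_ratio_and_classification(self, vg, ve, h2, cls):
        got = heritability({"genotype": vg, "residual": ve})
        assert got == pytest.approx(h2)
        assert h2_class(got) == cls

    def test_zero_total_variance_is_missing(self):
        assert np.isnan(heritability({"genotype": 0.0, "residual": 0.0}))

    @given(shift=st.floats(-1000.0, 1000.0))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_invariant_to_adding_a_constant(self, shift):
        y, df, _ = balanced_oneway(4)
        a = AugmentedTrialModel(y, df).fit(GENO_ONLY).h2
        b = AugmentedTrialModel(y + shift, df).fit(GENO_ONLY).h2
        assert b == pytest.approx(a, abs=1e-6)


class TestSummaries:
    def _fit_with_blups(self, blups):
        return TrialFitResults(
            spec=GENO_ONLY, varcomps={"genotype": 1.0, "residual": 1.0},
            loglik_reml=0.0, aic=0.0, n_params=3, intercept=0.0,
            genotype_blups=pd.Series(blups), converged=True, n_obs=len(blups),
        )

    def test_constant_blups_have_zero_cv(self):
        meta = pd.DataFrame({"genotype_id": ["a", "b", "c"], "growth_group": [1, 1, 2]})
        out = summarize_blups(self._fit_with_blups({"a": 10.0, "b": 10.0, "c": 10.0}), meta)
        assert out.loc[out["group"] == "all", "cv_pct"].iloc[0] == pytest.approx(0.0)

    def test_singleton_group_has_zero_sd(self):
        meta = pd.DataFrame({"genotype_id": ["a", "b"], "growth_group": [1, 2]})
        out = summarize_blups(self._fit_with_blups({"a": 5.0, "b": 9.0}), meta)
        assert (out.loc[out["group"] != "all", "sd"] == 0.0).all()
        assert (out["min"] <= out["mean"]).all() and (out["mean"] <= out["max"]).all()


class TestCleaning:
    def test_emergence_threshold_boundary(self):
        plots = pd.DataFrame({"plot_id": list("abc"), "emergence_pct": [29.9, 30.0, 45.0]})
        kept, report = filter_emergence(plots)
        assert list(kept["emergence_pct"]) == [30.0, 45.0]
        assert report["n_removed"].sum() == 1

    def test_all_passing_is_identity(self):
        plots = pd.DataFrame({"plot_id": list("ab"), "emergence_pct": [80.0, 90.0]})
        kept, report = filter_emergence(plots)
        pd.testing.assert_frame_equal(kept, plots)
        assert report["n_removed"].sum() == 0

    def test_tukey_flags_single_outlier(self):
        mask = tukey_clean(list(range(1, 10)) + [100])
        assert mask.sum() == 1 and mask[-1]

    def test_tukey_constant_and_symmetric_flag_nothing(self, rng):
        assert not tukey_clean([5.0] * 10).any()
        assert not tukey_clean(np.linspace(-1, 1, 50)).any()

    def test_tukey_small_sample_untouched(self):
        assert not tukey_clean([1.0, 2.0, np.nan]).any()

    def test_transform_skips_symmetric_data(self, rng):
        _, flag = maybe_transform(rng.normal(0, 1, 500))
        assert flag == "none"

    def test_transform_catches_lognormal_skew(self):
        chosen = 0
        for seed in range(20):
            x = np.random.default_rng(seed).lognormal(0, 1.2, 400)
            _, flag = maybe_transform(x)
            chosen += flag == "log1p"
        assert chosen >= 19

    def test_transform_falls_back_below_minus_one(self):
        x = np.concatenate([np.random.default_rng(0).lognormal(0, 1.5, 200), [-2.0]])
        with pytest.warns(UserWarning):
            out, flag = maybe_transform(x)
        assert flag == "none"
        np.testing.assert_array_equal(out, x)
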