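"""Generator contracts: PD repair, moment convergence, reliability structure,
and path-model recovery."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.correlation_tools import corr_clipped

import medmod as mm
from medmod.synthetic import repair_correlation_matrix


class TestRepairCorrelationMatrix:
    def test_identity_is_untouched(self):
        res = repair_correlation_matrix(np.eye(4))
        assert res.max_abs_change == 0.0
        assert not res.modified
        np.testing.assert_array_equal(res.corr, np.eye(4))

    def test_published_2x2_block_already_pd(self):
        # the strongest published pairwise correlation (0.80) is fine as-is
        corr = np.array([[1.0, 0.80], [0.80, 1.0]])
        res = repair_correlation_matrix(corr)
        assert res.max_abs_change == 0.0
        np.testing.assert_array_equal(res.corr, corr)

    def test_indefinite_3x3_repaired(self):
        corr = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        assert np.linalg.eigvalsh(corr).min() < 0
        res = repair_correlation_matrix(corr, floor=1e-6)
        assert res.modified and res.max_abs_change > 0
        assert np.linalg.eigvalsh(res.corr).min() >= 1e-6 * (1 - 1e-9)
        np.testing.assert_allclose(np.diag(res.corr), 1.0, atol=1e-12)
        np.testing.assert_allclose(res.corr, res.corr.T, atol=1e-12)
        # independent eigenvalue-clipping implementation (statsmodels)
        ref = corr_clipped(corr, threshold=1e-6)
        np.testing.assert_allclose(res.corr, ref, atol=0.05)
        # reported change bounds the actual elementwise perturbation
        assert res.max_abs_change == pytest.approx(np.abs(res.corr - corr).max())

    def test_repair_is_idempotent(self):
        corr = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        once = repair_correlation_matrix(corr).corr
        twice = repair_correlation_matrix(once)
        assert twice.max_abs_change < 1e-12

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[1.0, 0.5], [0.2, 1.0]]),  # asymmetric
            np.array([[2.0, 0.5], [0.5, 1.0]]),  # diagonal not 1
            np.array([[1.0, 1.5], [1.5, 1.0]]),  # off-diagonal out of range
        ],
    )
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValueError):
            repair_correlation_matrix(bad)


class TestScaleLevelGenerator:
    def test_same_seed_identical(self, study_spec):
        a = mm.generate_scale_level(study_spec, 500, seed=3, demographics=mm.study_demographics())
        b = mm.generate_scale_level(study_spec, 500, seed=3, demographics=mm.study_demographics())
        pd.testing.assert_frame_equal(a, b)
        c = mm.generate_scale_level(study_spec, 500, seed=4, demographics=mm.study_demographics())
        assert not a["ct"].equals(c["ct"])

    def test_target_correlation_recovered(self, sampled_study_df):
        # Monte-Carlo error on r at n=6057 via the Fisher-z standard error
        tol = 4.0 / np.sqrt(mm.STUDY_N - 3)
        assert sampled_study_df["ct"].corr(sampled_study_df["se"]) == pytest.approx(-0.41, abs=tol)

    def test_zero_correlation_spec_independent(self):
        spec = mm.MomentSpec(("u", "v", "w"), np.zeros(3), np.ones(3), np.eye(3))
        df = mm.generate_scale_level(spec, 20_000, seed=11)
        r = df[["u", "v", "w"]].corr().to_numpy()
        off = r[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 4.0 / np.sqrt(20_000)

    def test_fisher_z_bound_large_n(self, study_spec):
        n = 200_000
        df = mm.generate_scale_level(study_spec, n, seed=8)
        r = df[list(study_spec.variables)].corr().to_numpy()
        assert np.abs(r - study_spec.corr).max() < 4.0 / np.sqrt(n)

    def test_exact_moments(self, exact_study_df, study_spec):
        sub = exact_study_df[list(study_spec.variables)]
        np.testing.assert_allclose(sub.mean(), study_spec.means, atol=1e-8)
        np.testing.assert_allclose(sub.std(ddof=1), study_spec.sds, atol=1e-8)
        np.testing.assert_allclose(sub.corr(), study_spec.corr, atol=1e-8)

    def test_demographics_quota_and_age(self, sampled_study_df):
        df = sampled_study_df
        assert int(df["sex"].sum()) == 2422  # published female count, by quota
        assert df["age"].min() >= 18.0
        assert df["age"].median() == pytest.approx(34.0, abs=0.5)
        assert df["age"].quantile(0.25) == pytest.approx(30.0, abs=0.5)
        assert df["age"].quantile(0.75) == pytest.approx(40.0, abs=0.5)
        # the published age-outcome correlations survive the monotone transform
        assert df["age"].corr(df["phq9"]) == pytest.approx(-0.13, abs=0.04)
        assert df["age"].corr(df["gad7"]) == pytest.approx(-0.10, abs=0.04)

    def test_small_n_rejected(self, study_spec):
        with pytest.raises(ValueError):
            mm.generate_scale_level(study_spec, 1, seed=0)


class TestItemLevelGenerator:
    def test_latent_alpha_matches_closed_form(self):
        spec = mm.ItemBatterySpec(n_items=10, inter_item_corr=0.40)
        implied = 10 * 0.40 / (1 + 9 * 0.40)
        assert spec.implied_alpha == pytest.approx(implied)
        items = mm.generate_item_level(spec, 50_000, seed=21, discretize=False)
        assert mm.cronbach_alpha(items).alpha == pytest.approx(implied, abs=0.01)

    def test_uncorrelated_items_alpha_near_zero(self):
        spec = mm.ItemBatterySpec(n_items=8, inter_item_corr=0.0)
        items = mm.generate_item_level(spec, 4000, seed=2, discretize=False)
        assert abs(mm.cronbach_alpha(items).alpha) < 0.05

    def test_discrete_responses_in_range(self):
        spec = mm.ItemBatterySpec(n_items=28, inter_item_corr=0.222)
        items = mm.generate_item_level(spec, 800, seed=5)
        assert items.to_numpy().min() >= 1 and items.to_numpy().max() <= 5
        assert items.dtypes.eq(int).all()
        # discretization attenuates alpha; inflation compensates
        att = mm.cronbach_alpha(items).alpha
        assert att < spec.implied_alpha
        inflated = mm.ItemBatterySpec(n_items=28, inter_item_corr=0.222, rho_inflation=0.03)
        boosted = mm.cronbach_alpha(mm.generate_item_level(inflated, 800, seed=5)).alpha
        assert boosted > att

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_items=1, inter_item_corr=0.3),
            dict(n_items=5, inter_item_corr=1.0),
            dict(n_items=5, inter_item_corr=0.3, thresholds=(0.5,)),  # wrong count
            dict(n_items=5, inter_item_corr=0.3, thresholds=(0.5, 0.4, 0.6, 0.7)),
            dict(n_items=5, inter_item_corr=0.3, thresholds=(0.1, 0.2, np.inf, 0.4)),
        ],
    )
    def test_invalid_battery_spec(self, kwargs):
        with pytest.raises(ValueError):
            mm.ItemBatterySpec(**kwargs)


class TestStructuralGenerator:
    def test_mediation_parameter_recovery(self):
        spec = mm.StructuralSpec(a=-0.4, b=-0.25, c_prime=0.2)
        df = mm.generate_structural(spec, 50_000, seed=13)
        res = mm.fit_mediation(df, "x", "m", "y")
        assert abs(res.a - spec.a) < 3 * res.a_se
        assert abs(res.b - spec.b) < 3 * res.b_se
        assert abs(res.c_prime - spec.c_prime) < 3 * res.c_prime_se

    def test_zero_first_stage_kills_indirect(self):
        spec = mm.StructuralSpec(a=0.0, b=-0.3, c_prime=0.2)
        df = mm.generate_structural(spec, 30_000, seed=14)
        res = mm.fit_mediation(df, "x", "m", "y")
        assert abs(res.indirect) < 3 * abs(res.b) * res.a_se

    def test_second_stage_interaction_recovery(self):
        # a published-magnitude second-stage interaction is recoverable
        spec = mm.StructuralSpec(a=-0.4, b=-0.25, c_prime=0.2, b_w=-0.05)
        df = mm.generate_structural(spec, 50_000, seed=15)
        fit = mm.ols_fit(df, "y", ["x", "w", "m", "m:w"], standardized=False)
        assert abs(fit.params["m:w"] - spec.b_w) < 3 * fit.bse["m:w"]

    def test_reduces_to_moment_generator_when_linear(self):
        spec = mm.StructuralSpec(
            a=-0.4, b=-0.25, c_prime=0.2, w_to_m=0.3, w_to_y=-0.2, sd_m=0.8, sd_y=1.2
        )
        implied = spec.implied_moment_spec()
        n = 200_000
        tol = 4.0 / np.sqrt(n)
        struct = mm.generate_structural(spec, n, seed=16)
        r_struct = struct[["x", "w", "m", "y"]].corr().to_numpy()
        np.testing.assert_allclose(r_struct, implied.corr, atol=tol)
        np.testing.assert_allclose(
            struct[["x", "w", "m", "y"]].std(ddof=1), implied.sds, rtol=0.02
        )
        moment = mm.generate_scale_level(implied, n, seed=17)
        r_moment = moment[["x", "w", "m", "y"]].corr().to_numpy()
        np.testing.assert_allclose(r_struct, r_moment, atol=2 * tol)

    def test_interactions_block_implied_moments(self):
        with pytest.raises(ValueError):
            mm.StructuralSpec(a=0.1, b=0.1, c_prime=0.0, b_w=0.05).implied_moment_spec()
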