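"""Stage models, simple-effect algebra and conditional bootstrap tests."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import medmod as mm
from medmod.moderated import simple_effects, subgroup_simple_effects
from medmod.stats_core import zscore

from _oracles import ols_via_elimination, reference_bc_bounds


def moderated_frame(seed=0, n=2000, a=-0.4, b=-0.25, cp=0.2, a_w=0.0, b_w=0.0):
    spec = mm.StructuralSpec(a=a, b=b, c_prime=cp, a_w=a_w, b_w=b_w)
    return mm.generate_structural(spec, n, seed=seed, include_covariates=True)


class TestStageModels:
    def test_hierarchical_step_structure(self):
        df = moderated_frame(seed=1, n=400, a_w=0.1, b_w=-0.1)
        fits = mm.fit_stage_models(df, "x", "m", "y", "w", covariates=("age", "sex"))
        # step blocks: covariates | main effects | interaction
        assert [b.block_terms for b in fits.first.blocks] == [
            ("age", "sex"),
            ("x", "w"),
            ("x:w",),
        ]
        assert [b.block_terms for b in fits.second.blocks] == [
            ("age", "sex"),
            ("x", "w", "m"),
            ("m:w",),
        ]
        # step-3 model contains exactly the step-2 terms plus the interaction
        step2 = set(fits.second.blocks[1].fit.terms)
        step3 = set(fits.second.blocks[2].fit.terms)
        assert step3 - step2 == {"m:w"}

    def test_toy_coefficients_match_elimination_oracle(self):
        df = moderated_frame(seed=2, n=12, a_w=0.2)
        fits = mm.fit_stage_models(
            df, "x", "m", "y", "w", moderated_stages="both", standardized=False
        )
        design = df.assign(xw=df["x"] * df["w"])[["x", "w", "xw"]]
        ref = ols_via_elimination(design.to_numpy(), df["m"].to_numpy())
        final = fits.first.final.params
        np.testing.assert_allclose(
            final[["const", "x", "w", "x:w"]].to_numpy(), ref, atol=1e-10
        )

    def test_first_stage_interaction_recovery(self):
        # a published-magnitude first-stage interaction is recoverable at scale
        spec = mm.StructuralSpec(a=-0.4, b=-0.25, c_prime=0.2, a_w=-0.05)
        df = mm.generate_structural(spec, 50_000, seed=3)
        fits = mm.fit_stage_models(df, "x", "m", "y", "w", standardized=False)
        est = fits.a_interaction
        se = fits.first.final.bse["x:w"]
        assert abs(est - spec.a_w) < 3 * se

    def test_null_moderator_interaction_near_zero(self):
        df = moderated_frame(seed=4, n=6000)
        fits = mm.fit_stage_models(df, "x", "m", "y", "w")
        se = fits.first.final.bse["x:w"]
        assert abs(fits.a_interaction) < 4 * se
        assert fits.first.blocks[-1].incremental_f < 6.7  # ~ null 99th percentile

    def test_single_stage_moderation_constant_other_stage(self):
        df = moderated_frame(seed=5, n=800, b_w=-0.2)
        fits = mm.fit_stage_models(df, "x", "m", "y", "w", moderated_stages="second")
        assert fits.a_interaction == 0.0
        table = simple_effects(fits)
        assert np.ptp(table.first) == 0.0  # unmoderated stage constant across w
        assert np.ptp(table.second) > 0.0


class TestSimpleEffects:
    def test_published_coefficient_combination(self):
        # second-stage main effect -0.25 with interaction -0.05:
        # effect is -0.30 one SD above the mean, -0.20 one SD below
        fits = SimpleNamespace(a=-0.40, a_interaction=0.0, b=-0.25, b_interaction=-0.05)
        table = simple_effects(fits, levels=(-1.0, 0.0, 1.0))
        np.testing.assert_allclose(table.second, [-0.20, -0.25, -0.30], atol=1e-12)
        assert table.diff_second == pytest.approx(-0.10, abs=1e-12)
        np.testing.assert_allclose(table.indirect, table.first * table.second, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_high_low_difference_is_twice_interaction(self, seed):
        g = np.random.default_rng(seed)
        fits = SimpleNamespace(
            a=g.normal(),
            a_interaction=g.normal(),
            b=g.normal(),
            b_interaction=g.normal(),
        )
        table = simple_effects(fits, levels=(-1.0, 0.0, 1.0))
        assert table.diff_first == pytest.approx(2 * fits.a_interaction, abs=1e-12)
        assert table.diff_second == pytest.approx(2 * fits.b_interaction, abs=1e-12)

    def test_zero_interaction_constant_table(self):
        fits = SimpleNamespace(a=0.3, a_interaction=0.0, b=-0.5, b_interaction=0.0)
        table = simple_effects(fits)
        assert np.ptp(table.first) == 0.0 and np.ptp(table.indirect) == 0.0

    def test_cross_module_consistency_without_moderator(self):
        df = moderated_frame(seed=6, n=500)
        fits = mm.fit_stage_models(
            df, "x", "m", "y", w=None, covariates=("age", "sex"), standardized=True
        )
        table = simple_effects(fits)
        zd = pd.DataFrame({c: zscore(df[c]) for c in ["x", "m", "y", "age", "sex"]})
        med = mm.fit_mediation(zd, "x", "m", "y", covariates=("age", "sex"))
        np.testing.assert_allclose(table.indirect, med.indirect, atol=1e-10)


class TestBootstrapConditional:
    def test_index_stream_oracle(self):
        df = moderated_frame(seed=7, n=30, a_w=0.3, b_w=-0.3)
        n_boot, seed = 200, 55
        table = mm.bootstrap_conditional(
            df, "x", "m", "y", "w", n_boot=n_boot, seed=seed
        )
        zd = pd.DataFrame({c: zscore(df[c]) for c in ["x", "m", "y", "w"]})
        n = len(df)
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        X1 = np.column_stack([np.ones(n), zd["x"], zd["w"], zd["x"] * zd["w"]])
        X2 = np.column_stack(
            [np.ones(n), zd["x"], zd["w"], zd["m"], zd["m"] * zd["w"]]
        )
        draws = {k: [] for k in ("indirect@-1", "indirect@1", "diff_second")}
        for rows in idx:
            c1 = np.linalg.lstsq(X1[rows], zd["m"].to_numpy()[rows], rcond=None)[0]
            c2 = np.linalg.lstsq(X2[rows], zd["y"].to_numpy()[rows], rcond=None)[0]
            first = c1[1] + np.array([-1.0, 1.0]) * c1[3]
            second = c2[3] + np.array([-1.0, 1.0]) * c2[4]
            draws["indirect@-1"].append(first[0] * second[0])
            draws["indirect@1"].append(first[1] * second[1])
            draws["diff_second"].append(second[1] - second[0])
        points = {
            "indirect@-1": table.indirect[0],
            "indirect@1": table.indirect[-1],
            "diff_second": table.diff_second,
        }
        for key, boots in draws.items():
            lo, hi = reference_bc_bounds(boots, points[key])
            assert table.intervals[key].lower == pytest.approx(lo, abs=1e-10)
            assert table.intervals[key].upper == pytest.approx(hi, abs=1e-10)

    def test_second_stage_moderation_pattern(self):
        # moderation of the M->Y path only: the second-stage and indirect
        # high-low differences are detected, the first-stage one is not
        df = moderated_frame(seed=8, n=6057, b_w=-0.15)
        table = mm.bootstrap_conditional(
            df, "x", "m", "y", "w", covariates=("age", "sex"), n_boot=600, seed=9
        )
        assert not table.intervals["diff_first"].excludes_zero
        assert table.intervals["diff_second"].excludes_zero
        assert table.intervals["diff_indirect"].excludes_zero

    def test_same_seed_reproducible(self):
        df = moderated_frame(seed=10, n=120, b_w=-0.2)
        t1 = mm.bootstrap_conditional(df, "x", "m", "y", "w", n_boot=100, seed=4)
        t2 = mm.bootstrap_conditional(df, "x", "m", "y", "w", n_boot=100, seed=4)
        assert t1.intervals["diff_indirect"] == t2.intervals["diff_indirect"]

    def test_power_monotone_in_interaction_strength(self):
        # rejection rate of the second-stage difference test grows with |b_w|
        reps, n, n_boot = 60, 400, 300
        rates = []
        for k, b_w in enumerate((0.0, 0.05, 0.1, 0.2)):
            hits = 0
            for rep in range(reps):
                df = moderated_frame(seed=3000 + 100 * k + rep, n=n, b_w=-b_w)
                table = mm.bootstrap_conditional(
                    df, "x", "m", "y", "w", moderated_stages="second",
                    n_boot=n_boot, seed=rep,
                )
                hits += table.intervals["diff_second"].excludes_zero
            rates.append(hits / reps)
        assert rates[-1] > 0.9
        for lo, hi in zip(rates, rates[1:]):
            assert hi >= lo - 0.08  # non-decreasing up to Monte-Carlo error


class TestSubgroupProtocol:
    def test_strong_moderation_recovered_by_subgroups(self):
        df = moderated_frame(seed=11, n=8000, b_w=-0.3)
        out = subgroup_simple_effects(df, "x", "m", "y", "w")
        assert set(out.index) == {"low", "high", "high-low"}
        # b is more negative when w is high
        assert out.loc["high", "b"] < out.loc["low", "b"]
        assert out.loc["high-low", "b"] < -0.1

    def test_split_validation(self):
        df = moderated_frame(seed=12, n=100)
        with pytest.raises(ValueError):
            subgroup_simple_effects(df, "x", "m", "y", "w", split="tertile")
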