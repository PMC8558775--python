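import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pupvox.stats import (
    ModelSpec,
    StatResult,
    bonferroni_alpha,
    coefficient_of_variation,
    fit_random_intercept_model,
    mann_whitney,
    pairwise_condition_tests,
    per_seal_intensity_tests,
    permutation_p,
)
from pupvox.synth import simulate_feature_table


def exact_mw_p(x, y):
    """Exhaustive enumeration oracle: two-sided p as the fraction of
    group assignments with U at least as extreme (min-U based)."""
    x, y = list(x), list(y)
    pooled = x + y
    nx = len(x)
    obs = _u_min(x, y)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if _u_min(xs, ys) <= obs:
            count += 1
    return count / total


def _u_min(x, y):
    u = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b
    )
    return min(u, len(x) * len(y) - u)


class TestBonferroni:
    def test_three_way_constant(self):
        assert round(bonferroni_alpha(3), 4) == 0.0167

    def test_twentyfour_way_constant(self):
        assert round(bonferroni_alpha(24), 5) == 0.00208

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0)


class TestRandomInterceptModel:
    def test_ols_limit_with_zero_random_variance(self):
        # no group effects: at the zero-variance boundary the GLS estimates
        # collapse exactly to OLS, and the free fit lands near it
        from pupvox.stats import _fixed_design, _indicator, _profiled_loglik

        df = simulate_feature_table(
            8, seed=3, sd_session=0.0, sd_seal=0.0, sd_resid=1.0,
            condition_effect={"no_playback": 0.0, "low": 1.0, "high": 2.0},
            n_pairs=2,
        )
        y = df["y"].to_numpy()
        X, _ = _fixed_design(df, ("condition", "trial_index"))
        Zs = [_indicator(df, c) for c in ("session_id", "seal_id")]
        _, beta_boundary, _ = _profiled_loglik(
            np.array([-30.0, -30.0]), y, X, Zs, reml=True
        )
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(beta_boundary, beta_ols, atol=1e-6)

        fit = fit_random_intercept_model(df, ModelSpec(response="y"))
        np.testing.assert_allclose(fit.beta.to_numpy(), beta_ols, atol=0.05)
        assert fit.var_components["session_id"] < 0.05
        assert fit.var_components["seal_id"] < 0.05

    def test_matches_statsmodels_crossed_vc(self):
        import statsmodels.formula.api as smf

        df = simulate_feature_table(
            14, seed=1, sd_session=1.0, sd_seal=2.0, sd_resid=1.0, n_pairs=4
        )
        fit = fit_random_intercept_model(df, ModelSpec(response="y"))
        md = smf.mixedlm(
            "y ~ condition + trial_index",
            df,
            groups=np.ones(len(df)),
            vc_formula={
                "session": "0 + C(session_id)",
                "seal": "0 + C(seal_id)",
            },
        ).fit(reml=True)
        sm_vc = dict(zip(["seal", "session"], md.vcomp))
        assert fit.var_components["session_id"] == pytest.approx(
            sm_vc["session"], rel=1e-3, abs=1e-4
        )
        assert fit.var_components["seal_id"] == pytest.approx(
            sm_vc["seal"], rel=1e-3, abs=1e-4
        )
        assert fit.var_components["residual"] == pytest.approx(md.scale, rel=1e-3)
        assert fit.beta["trial_index"] == pytest.approx(
            md.fe_params["trial_index"], abs=1e-4
        )

    def test_variance_component_recovery(self):
        sess, seal, resid = [], [], []
        for seed in range(5):
            df = simulate_feature_table(
                28, seed=seed, sd_session=1.0, sd_seal=2.0, sd_resid=1.0,
                n_pairs=4, calls_per_block=1.7,
            )
            fit = fit_random_intercept_model(df, ModelSpec(response="y"))
            sess.append(fit.var_components["session_id"])
            seal.append(fit.var_components["seal_id"])
            resid.append(fit.var_components["residual"])
        assert np.mean(sess) == pytest.approx(1.0, rel=0.30)
        assert np.mean(seal) == pytest.approx(4.0, rel=0.45)  # few seal levels
        assert np.mean(resid) == pytest.approx(1.0, rel=0.30)

    def test_noise_predictor_barely_moves_pseudo_r2(self):
        df = simulate_feature_table(
            14, seed=5, sd_session=0.5, sd_seal=0.5, sd_resid=1.0, n_pairs=2,
            calls_per_block=3.5,
        )
        base = fit_random_intercept_model(df, ModelSpec(response="y"))
        df2 = df.copy()
        df2["junk"] = np.random.default_rng(0).standard_normal(len(df))
        noisy = fit_random_intercept_model(
            df2, ModelSpec(response="y", fixed=("condition", "trial_index", "junk"))
        )
        assert abs(noisy.pseudo_r2 - base.pseudo_r2) < 0.01


class TestPermutation:
    def test_two_atom_support_with_single_permutation(self):
        df = simulate_feature_table(4, seed=8, n_pairs=1)
        p, _ = permutation_p(df, ModelSpec(response="y", n_perm=1, seed=0))
        assert p in (0.5, 1.0)

    def test_strong_planted_effect_reaches_minimum_p(self):
        hits = 0
        for seed in range(10):
            df = simulate_feature_table(
                10, seed=100 + seed, sd_session=0.2, sd_seal=0.3, sd_resid=1.0,
                condition_effect={"no_playback": 0.0, "low": -2.0, "high": -4.0},
                n_pairs=2, calls_per_block=2.5,
            )
            p, _ = permutation_p(df, ModelSpec(response="y", n_perm=99, seed=seed))
            hits += p == pytest.approx(1 / 100)
        assert hits >= 9

    def test_affine_invariance(self):
        df = simulate_feature_table(8, seed=11, sd_seal=0.5, n_pairs=2)
        spec = ModelSpec(response="y", n_perm=99, seed=21)
        p1, s1 = permutation_p(df, spec)
        df2 = df.copy()
        df2["y"] = 3.0 * df2["y"] + 7.0
        p2, s2 = permutation_p(df2, spec)
        assert p1 == p2
        assert s1 == pytest.approx(s2, rel=1e-8)

    def test_pairwise_alpha_and_directional_consistency(self):
        df = simulate_feature_table(
            14, seed=42, sd_session=0.3, sd_seal=0.5, sd_resid=1.0,
            condition_effect={"no_playback": 0.0, "low": -1.0, "high": -2.0},
            n_pairs=2, calls_per_block=3.0,
        )
        spec = ModelSpec(response="y", n_perm=199, seed=2)
        results = pairwise_condition_tests(df, spec)
        assert len(results) == 3
        for r in results:
            assert r.alpha_adjusted == pytest.approx(0.05 / 3)
            assert r.significant
        # every call appears in exactly two of the three pairs
        assert sum(r.n for r in results) == 2 * len(df)
        # monotone medians in the planted direction
        med = df.groupby("condition")["y"].median()
        assert med["no_playback"] > med["low"] > med["high"]


class TestMannWhitney:
    def test_small_sample_exact_example(self):
        res = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res["U"] == 0.0
        assert res["p"] == pytest.approx(1 / 3)
        assert res["method"] == "exact"

    def test_identical_samples(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["p"] >= 0.99

    def test_large_shifted_normals(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100) + 1.0
        assert mann_whitney(x, y)["p"] < 0.001

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize(
        "nx, ny", [(1, 1), (1, 3), (2, 2), (2, 4), (3, 3), (3, 5), (4, 4), (2, 6)]
    )
    def test_matches_enumeration_oracle(self, nx, ny):
        r = np.random.default_rng(nx * 10 + ny)
        for _ in range(5):
            x = r.standard_normal(nx)
            y = r.standard_normal(ny)
            res = mann_whitney(x, y)
            assert res["p"] == pytest.approx(exact_mw_p(x, y), abs=1e-12)


class TestPerSeal:
    def _features(self, lombard_seal=None, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for seal in [f"seal_{c}" for c in "ABCDEFGH"]:
            for cond in ("no_playback", "low", "high"):
                base = 1.0
                if seal == lombard_seal and cond == "high":
                    base = 4.0  # ~ +6 dB in power
                for i in range(30):
                    rows.append(
                        {
                            "session_id": f"S{i % 7}",
                            "seal_id": seal,
                            "condition": cond,
                            "intensity_linear": base * math.exp(0.4 * rng.standard_normal()),
                            "octave_slope_db_per_oct": rng.standard_normal(),
                            "r14_db": rng.standard_normal(),
                        }
                    )
        return pd.DataFrame(rows)

    def test_alpha_for_eight_seals(self):
        res = per_seal_intensity_tests(self._features())
        assert res[0].alpha_adjusted == pytest.approx(0.05 / 24)

    def test_planted_lombard_seal_detected_and_nulls_quiet(self):
        res = per_seal_intensity_tests(self._features(lombard_seal="seal_G"))
        intensity = [r for r in res if r.response == "intensity_linear"]
        target = [
            r for r in intensity
            if r.comparison == "seal_G:no_playback_vs_high"
        ]
        assert target and target[0].significant
        null_hits = [
            r for r in intensity
            if r.significant and not r.comparison.startswith("seal_G")
        ]
        assert len(null_hits) == 0

    def test_family_wise_error_under_global_null(self):
        # Bonferroni guarantee: any significant comparison is rare
        fw_errors = 0
        n_rep = 60
        for rep in range(n_rep):
            res = per_seal_intensity_tests(
                self._features(seed=500 + rep), measures=("intensity_linear",)
            )
            fw_errors += any(r.significant for r in res)
        # binomial(60, 0.05) upper bound: observing > 8 would be p < 1e-3
        assert fw_errors <= 8

    def test_empty_cell_skipped(self):
        df = self._features()
        df = df[~((df.seal_id == "seal_A") & (df.condition == "high"))]
        res = per_seal_intensity_tests(df)
        assert not any(
            r.comparison in ("seal_A:no_playback_vs_high", "seal_A:low_vs_high")
            for r in res
        )


class TestCoefficientOfVariation:
    def _table(self, values_by_group):
        rows = []
        for (sess, seal, cond), vals in values_by_group.items():
            for v in vals:
                rows.append(
                    {
                        "session_id": sess, "seal_id": seal,
                        "condition": cond, "resp": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_constant_group_cv_zero(self):
        t = self._table({("s", "a", "high"): [100.0, 100.0, 100.0]})
        cv, _ = coefficient_of_variation(t, "resp")
        assert cv["cv"].iloc[0] == 0.0

    def test_sample_sd_convention(self):
        t = self._table({("s", "a", "high"): [90.0, 100.0, 110.0]})
        cv, _ = coefficient_of_variation(t, "resp")
        # sample sd (n-1) of {90,100,110} is 10 -> CV = 10/100
        assert cv["cv"].iloc[0] == pytest.approx(0.1)

    def test_small_groups_dropped(self):
        t = self._table(
            {
                ("s", "a", "high"): [90.0, 100.0, 110.0],
                ("s", "a", "low"): [100.0, 101.0],
            }
        )
        cv, _ = coefficient_of_variation(t, "resp")
        assert list(cv["condition"]) == ["high"]

    def test_recovers_lower_dispersion_under_high_noise(self):
        # generator: same median, lower CV in high noise
        rng = np.random.default_rng(7)
        rows = []
        cv_true = {"no_playback": 0.10, "low": 0.10, "high": 0.05}
        for s in range(14):
            for seal in ("a", "b"):
                for b, cond in enumerate(
                    ["no_playback", "low", "high"] * 3
                ):
                    for _ in range(4):
                        sigma = math.sqrt(math.log(1 + cv_true[cond] ** 2))
                        rows.append(
                            {
                                "session_id": f"S{s}", "seal_id": seal,
                                "condition": cond, "block_index": b,
                                "resp": 400.0 * math.exp(sigma * rng.standard_normal()),
                            }
                        )
        t = pd.DataFrame(rows)
        cv_table, result = coefficient_of_variation(
            t, "resp", ModelSpec(response="cv", fixed=("condition",), n_perm=199, seed=1)
        )
        assert result is not None and result.significant
        fit = fit_random_intercept_model(
            cv_table, ModelSpec(response="cv", fixed=("condition",))
        )
        assert fit.beta["condition[high]"] < 0


class TestStatResult:
    def test_significance_threshold(self):
        r = StatResult("c", "y", 1.0, p_perm=0.01, pseudo_r2=0.1, n=10,
                       alpha_adjusted=0.0167)
        assert r.significant
        r2 = StatResult("c", "y", 1.0, p_perm=0.02, pseudo_r2=0.1, n=10,
                        alpha_adjusted=0.0167)
        assert not r2.significant

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            StatResult("c", "y", 1.0, p_perm=0.0, pseudo_r2=0.1, n=10,
                       alpha_adjusted=0.05)
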