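import numpy as np
import pandas as pd
import pytest

from heterothermy.drivers import (
    CandidateSpec,
    FitResult,
    aicc,
    build_candidates,
    coefficient_table,
    fit_mixed,
    make_model_frame,
    rank_models,
    simulate_model_frame,
    vif,
)


@pytest.fixture(scope="module")
def model6_frame():
    return simulate_model_frame(n=5000, seed=1)


class TestBuildCandidates:
    def test_exactly_nine_candidates(self):
        assert len(build_candidates()) == 9

    def test_model_six_is_the_food_photoperiod_interaction(self):
        m6 = next(s for s in build_candidates() if s.name == "model_6")
        assert set(m6.terms) == {"food", "photoperiod", "food:photoperiod"}
        assert set(m6.random) == {"week", "id", "date"}

    def test_model_one_has_reduced_random_structure(self):
        m1 = next(s for s in build_candidates() if s.name == "model_1")
        assert m1.terms == ("food",)
        assert set(m1.random) == {"id", "date"}

    def test_formulas_render_in_mixed_model_notation(self):
        m1 = next(s for s in build_candidates() if s.name == "model_1")
        assert m1.formula == "t_diff ~ food + (1 | id) + (1 | date)"


class TestAicc:
    def test_zero_parameters_zero_likelihood(self):
        assert aicc(0.0, 0, 10) == 0.0

    def test_worked_example(self):
        # -2(-100) + 2*5 + 2*5*6/(100-5-1) = 210.63829787...
        assert aicc(-100.0, 5, 100) == pytest.approx(210.63829787234042)

    def test_converges_to_aic_for_large_n(self):
        aic = -2 * (-100.0) + 2 * 5
        assert abs(aicc(-100.0, 5, 10**7) - aic) < 1e-3

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            aicc(-10.0, 5, 6)


class TestFitMixed:
    def test_degenerate_random_effects_reduce_to_ols(self):
        rng = np.random.default_rng(0)
        n = 600
        x = rng.normal(size=n)
        resid = rng.normal(0, 1, n)
        ids = np.arange(n) % 5
        # remove every trace of between-group variation from the residuals
        for g in range(5):
            resid[ids == g] -= resid[ids == g].mean()
        y = 1.5 + 2.0 * x + resid
        frame = pd.DataFrame(
            {
                "t_diff": y,
                "food": "ad_libitum",
                "t_a": x,
                "photoperiod": 0.0,
                "delta_m_b": 0.0,
                "id": [f"i{g}" for g in ids],
                "week": 0,
                "date": "d",
            }
        )
        spec = CandidateSpec("ols_check", ("t_a",), ("id",))
        fit = fit_mixed(spec, frame)
        ols = np.polyfit(x, y, 1)
        coef = fit.coefficients.set_index("term")["coef"]
        assert coef["t_a"] == pytest.approx(ols[0], abs=1e-4)
        assert coef["Intercept"] == pytest.approx(ols[1], abs=1e-4)

    def test_generate_and_refit_recovers_coefficients(self, model6_frame):
        spec = next(s for s in build_candidates() if s.name == "model_6")
        fit = fit_mixed(spec, model6_frame)
        assert fit.converged
        coefs = fit.coefficients.set_index("term")
        for term, truth in {
            "photoperiod": 10.0,
            "food[restricted]:photoperiod": -3.0,
        }.items():
            est, se = coefs.loc[term, "coef"], coefs.loc[term, "se"]
            assert abs(est - truth) < 3 * se

    def test_loglik_matches_external_mixed_model_solver(self):
        """Independent oracle: statsmodels MixedLM with crossed variance
        components must agree on the ML and REML log-likelihoods."""
        import statsmodels.formula.api as smf

        frame = simulate_model_frame(n=600, seed=3, n_week=8)
        spec = next(s for s in build_candidates() if s.name == "model_6")
        df = frame.assign(
            g=1, food01=(frame["food"] == "restricted").astype(float)
        )
        mod = smf.mixedlm(
            "t_diff ~ food01 * photoperiod",
            df,
            groups="g",
            re_formula="0",
            vc_formula={
                "id": "0 + C(id)",
                "week": "0 + C(week)",
                "date": "0 + C(date)",
            },
        )
        for reml in (False, True):
            mine = fit_mixed(spec, frame, reml=reml)
            ref = mod.fit(reml=reml)
            assert mine.loglik == pytest.approx(ref.llf, abs=1e-3)
            np.testing.assert_allclose(
                mine.coefficients["coef"].to_numpy(),
                ref.fe_params.to_numpy(),
                atol=1e-4,
            )

    def test_single_level_random_term_degrades_with_warning(self, model6_frame):
        frame = model6_frame.assign(week=0)
        spec = next(s for s in build_candidates() if s.name == "model_6")
        with pytest.warns(UserWarning, match="single level"):
            fit = fit_mixed(spec, frame)
        assert set(fit.variance_components) == {"id", "date"}
        assert fit.converged

    def test_adding_noise_covariate_never_lowers_ml_loglik(self, model6_frame):
        m3 = next(s for s in build_candidates() if s.name == "model_3")
        m4 = next(s for s in build_candidates() if s.name == "model_4")
        f3 = fit_mixed(m3, model6_frame)
        f4 = fit_mixed(m4, model6_frame)  # m4 = m3 + delta_m_b (pure noise here)
        assert f4.loglik >= f3.loglik - 1e-4

    def test_parameter_count_convention(self, model6_frame):
        spec = next(s for s in build_candidates() if s.name == "model_6")
        fit = fit_mixed(spec, model6_frame)
        # 4 fixed (incl. intercept) + 3 variance components + residual
        assert fit.k == 8


class TestVif:
    def test_orthogonal_covariates_have_unit_vif(self):
        n = 400
        frame = pd.DataFrame(
            {
                "t_a": np.tile([1.0, -1.0], n // 2),
                "photoperiod": np.repeat([1.0, -1.0], n // 2),
                "food": "ad_libitum",
                "delta_m_b": 0.0,
                "t_diff": 0.0,
                "id": "a",
                "week": 0,
                "date": "d",
            }
        )
        spec = CandidateSpec("v", ("t_a", "photoperiod"), ("id",))
        per_term, mx = vif(frame, spec)
        assert per_term["t_a"] == pytest.approx(1.0, abs=1e-9)
        assert mx == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_covariate_is_infinite(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        frame = pd.DataFrame(
            {"t_a": x, "photoperiod": x, "t_diff": 0.0, "food": "ad_libitum",
             "delta_m_b": 0.0, "id": "a", "week": 0, "date": "d"}
        )
        spec = CandidateSpec("v", ("t_a", "photoperiod"), ("id",))
        _, mx = vif(frame, spec)
        assert np.isinf(mx)

    def test_correlation_point_nine_gives_known_vif(self):
        n = 1000
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=n)
        x1 = (x1 - x1.mean()) / x1.std()
        z = rng.normal(size=n)
        z -= z.mean() + x1 * (z @ x1) / n  # orthogonalize against x1
        z /= z.std()
        x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * z
        frame = pd.DataFrame(
            {"t_a": x1, "photoperiod": x2, "t_diff": 0.0, "food": "ad_libitum",
             "delta_m_b": 0.0, "id": "a", "week": 0, "date": "d"}
        )
        spec = CandidateSpec("v", ("t_a", "photoperiod"), ("id",))
        per_term, mx = vif(frame, spec)
        assert mx == pytest.approx(1.0 / (1.0 - 0.81), rel=1e-6)

    def test_single_column_design_is_unity_by_convention(self, model6_frame):
        m1 = next(s for s in build_candidates() if s.name == "model_1")
        per_term, mx = vif(model6_frame, m1)
        assert mx == 1.0


def _dummy_fit(name, aicc_value, k=5, n=1000):
    spec = CandidateSpec(name, ("food",), ("id",))
    return FitResult(
        spec=spec, loglik=0.0, k=k, n=n, aicc=aicc_value, converged=True,
        singular=False, coefficients=pd.DataFrame(), variance_components={},
        sigma2=1.0, reml=False,
    )


class TestRankModels:
    def test_single_model_gets_full_weight(self):
        tab = rank_models([_dummy_fit("m", 100.0)])
        assert tab["weight"].iloc[0] == pytest.approx(1.0)
        assert tab["delta_aicc"].iloc[0] == 0.0

    def test_two_models_delta_two(self):
        tab = rank_models([_dummy_fit("a", 100.0), _dummy_fit("b", 102.0)])
        assert tab["weight"].iloc[0] == pytest.approx(0.7310585786, abs=1e-6)
        assert tab["weight"].iloc[1] == pytest.approx(0.2689414214, abs=1e-6)

    def test_equal_aicc_split_evenly(self):
        tab = rank_models([_dummy_fit(s, 50.0) for s in "abc"])
        np.testing.assert_allclose(tab["weight"], 1 / 3)

    def test_weights_sum_to_one_and_are_permutation_invariant(self):
        rng = np.random.default_rng(7)
        vals = list(rng.uniform(100, 130, 6))
        fits = [_dummy_fit(f"m{i}", v) for i, v in enumerate(vals)]
        tab1 = rank_models(fits)
        tab2 = rank_models(fits[::-1])
        assert tab1["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        merged = tab1.set_index("model")["weight"] - tab2.set_index("model")["weight"]
        assert np.allclose(merged, 0.0)

    def test_nonconverged_fits_excluded_with_warning(self):
        bad = _dummy_fit("bad", 90.0)
        object.__setattr__(bad, "converged", False)
        with pytest.warns(UserWarning, match="non-converged"):
            tab = rank_models([bad, _dummy_fit("ok", 100.0)])
        assert list(tab["model"]) == ["ok"]


class TestCoefficientTable:
    def test_model_six_reports_the_four_expected_rows(self, model6_frame):
        spec = next(s for s in build_candidates() if s.name == "model_6")
        fit = fit_mixed(spec, model6_frame)
        tab = coefficient_table(fit)
        assert list(tab["term"]) == [
            "Intercept",
            "food[restricted]",
            "photoperiod",
            "food[restricted]:photoperiod",
        ]
        coefs = tab.set_index("term")["coef"]
        assert coefs["photoperiod"] > 0
        assert coefs["food[restricted]:photoperiod"] < 0
        assert (tab.loc[tab["term"].str.contains("food"), "reference_level"]
                == "ad_libitum").all()

    def test_intercept_only_on_centred_response(self):
        rng = np.random.default_rng(1)
        n = 500
        y = rng.normal(0, 1, n)
        y -= y.mean()
        frame = pd.DataFrame(
            {"t_diff": y, "food": "ad_libitum", "t_a": 0.0, "photoperiod": 0.0,
             "delta_m_b": 0.0, "id": [f"i{k % 4}" for k in range(n)],
             "week": np.arange(n) % 8, "date": [f"d{k % 20}" for k in range(n)]}
        )
        spec = CandidateSpec("null", (), ("id", "week", "date"))
        fit = fit_mixed(spec, frame)
        assert fit.coefficients["coef"].iloc[0] == pytest.approx(0.0, abs=0.05)


class TestMakeModelFrame:
    def test_complete_case_and_columns(self):
        aligned = pd.DataFrame(
            {
                "individual_id": ["a", "a", "b"],
                "timestamp": pd.date_range("2019-06-01", periods=3, freq="h"),
                "t_b": [35.0, np.nan, 20.0],
                "t_a": [10.0, 10.0, 10.0],
                "t_diff": [25.0, np.nan, 10.0],
                "food": ["restricted", "restricted", "ad_libitum"],
                "daylength_h": [9.5, 9.5, 9.5],
                "m_b": [40.0, 40.0, 30.0],
                "delta_m_b": [0.0, 0.0, -1.0],
                "week": [0, 0, 0],
                "date": pd.to_datetime(["2019-06-01"] * 3),
            }
        )
        frame = make_model_frame(aligned)
        assert len(frame) == 2  # NaN row dropped
        assert set(frame.columns) == {
            "t_diff", "food", "t_a", "photoperiod", "delta_m_b", "id", "week", "date"
        }
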