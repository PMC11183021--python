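"""Group tests, logistic fitting, C_DCE, nomogram and risk stratification."""

import numpy as np
import pandas as pd
import pytest

from helpers import newton_logistic
from hepadce import modeling as mdl
from hepadce import perfusion as pf
from hepadce import synthetic as syn


class TestGroupComparisons:
    def test_exact_mann_whitney_small_groups(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "mvi": [0, 0, 1, 1]})
        res = mdl.compare_groups(df, "x", continuous=True)
        assert res.test == "mann-whitney"
        assert res.p_value == pytest.approx(1 / 3, abs=1e-9)

    def test_identical_distributions_give_p_one(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 5.0, 1.5, 2.5, 5.5], "mvi": [0, 0, 0, 1, 1, 1]})
        res = mdl.compare_groups(df, "x", continuous=True)
        assert res.p_value > 0.5

    def test_fisher_exact_diagonal_table(self):
        df = pd.DataFrame({"x": [1] * 5 + [0] * 5, "mvi": [1] * 5 + [0] * 5})
        res = mdl.compare_groups(df, "x", continuous=False)
        assert res.test == "fisher"
        assert res.p_value == pytest.approx(2 / 252, abs=1e-9)

    def test_constant_variable_skipped(self):
        df = pd.DataFrame({"x": [3.0] * 10, "mvi": [0, 1] * 5})
        res = mdl.compare_groups(df, "x")
        assert res.test == "skipped" and res.reason == "constant variable"


class TestLogistic:
    def test_single_binary_predictor_equals_log_odds_ratio(self):
        # 2x2 counts: exposed 30/50 events, unexposed 10/50
        x = np.repeat([1, 1, 0, 0], [30, 20, 10, 40]).astype(float)
        y = np.repeat([1, 0, 1, 0], [30, 20, 10, 40]).astype(float)
        model = mdl.fit_logistic(pd.DataFrame({"x": x}), y)
        log_or = np.log((30 * 40) / (20 * 10))
        assert model.coefficients["x"] == pytest.approx(log_or, abs=1e-8)

    def test_symmetric_design_gives_zero_intercept(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 4000)
        y = (rng.random(4000) < 1 / (1 + np.exp(-1.2 * x))).astype(float)
        model = mdl.fit_logistic(pd.DataFrame({"x": x}), y)
        assert abs(model.intercept) < 0.1

    def test_matches_newton_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (40, 2))
        y = (rng.random(40) < 1 / (1 + np.exp(-(0.5 + X @ [1.0, -0.7])))).astype(float)
        model = mdl.fit_logistic(pd.DataFrame(X, columns=["a", "b"]), y)
        ref = newton_logistic(X, y)
        assert model.intercept == pytest.approx(ref[0], abs=1e-6)
        assert model.coefficients["a"] == pytest.approx(ref[1], abs=1e-6)
        assert model.coefficients["b"] == pytest.approx(ref[2], abs=1e-6)

    def test_perfect_separation_flagged(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = (x > 0).astype(float)
        model = mdl.fit_logistic(pd.DataFrame({"x": x}), y)
        assert model.separation and not model.converged


class TestCdce:
    def test_intercept_only(self):
        assert mdl.compute_cdce(0.0, 0.0) == pytest.approx(-10.052)

    def test_at_the_univariate_cutoffs(self):
        assert mdl.compute_cdce(180.71, 28.19) == pytest.approx(-0.5612, abs=1e-4)

    def test_linearity_of_the_non_intercept_part(self):
        base = mdl.compute_cdce(100.0, 20.0) - mdl.CDCE_INTERCEPT
        doubled = mdl.compute_cdce(200.0, 40.0) - mdl.CDCE_INTERCEPT
        assert doubled == pytest.approx(2 * base)

    def test_missing_propagates(self):
        assert np.isnan(mdl.compute_cdce(np.nan, 20.0))


class TestNomogram:
    def setup_method(self):
        self.nomo = mdl.preset_nomogram()

    def test_baseline_patient(self):
        assert mdl.nomogram_points(self.nomo, 0, False, False, 0.0) == 208.0

    def test_high_risk_worked_example(self):
        rs = mdl.nomogram_points(self.nomo, mdl.afp_band(12.0), True, True, 1.268)
        assert rs == pytest.approx(258.948)
        assert round(rs) == 259
        assert mdl.stratify_risk(rs) == "HMVI"

    def test_low_risk_worked_example(self):
        rs = mdl.nomogram_points(self.nomo, mdl.afp_band(95.0), False, False, -1.252)
        assert rs == pytest.approx(208.228)
        assert round(rs) == 208
        assert mdl.stratify_risk(rs) == "LMVI"

    def test_cutoff_is_strict(self):
        assert mdl.stratify_risk(232.3) == "LMVI"
        assert mdl.stratify_risk(232.3 + 1e-9) == "HMVI"

    def test_probability_mapping_reproduces_calibration_pairs(self):
        assert mdl.points_to_probability(self.nomo, 258.948) == pytest.approx(0.989, abs=1e-9)
        assert mdl.points_to_probability(self.nomo, 208.228) == pytest.approx(0.009, abs=1e-9)

    def test_probability_slope_from_two_point_solve(self):
        logit = lambda p: np.log(p / (1 - p))
        expected = (logit(0.989) - logit(0.009)) / (258.948 - 208.228)
        assert self.nomo.prob_slope == pytest.approx(expected, rel=1e-12)
        assert self.nomo.prob_slope == pytest.approx(0.1814, abs=2e-4)

    def test_score_increases_11_points_per_cdce_unit(self):
        r0 = mdl.nomogram_points(self.nomo, 0, False, False, 0.0)
        r1 = mdl.nomogram_points(self.nomo, 0, False, False, 1.0)
        assert r1 - r0 == pytest.approx(11.0)

    def test_uncalibrated_mapping_errors(self):
        with pytest.raises(pf.InvalidInputError):
            mdl.points_to_probability(mdl.Nomogram(), 250.0)

    def test_unknown_afp_band_rejected(self):
        with pytest.raises(pf.InvalidInputError):
            mdl.nomogram_points(self.nomo, 5, False, False, 0.0)


class TestAfpBanding:
    @pytest.mark.parametrize(
        "afp,band", [(0.0, 0), (20.0, 0), (20.01, 1), (400.0, 1), (400.01, 2), (9e4, 2)]
    )
    def test_band_boundaries(self, afp, band):
        assert mdl.afp_band(afp) == band


class TestSplitAndSuite:
    def test_stratified_split_preserves_prevalence(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_patients=400, seed=2))
        split = mdl.stratified_split(cohort, ratio=0.7, seed=1)
        train = cohort[split == "training"]
        valid = cohort[split == "validation"]
        assert len(train) == pytest.approx(280, abs=1)
        assert train["mvi"].mean() == pytest.approx(valid["mvi"].mean(), abs=0.05)

    def test_suite_recovers_generator_effect_signs(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_patients=600, seed=5))
        suite = mdl.build_model_suite(cohort[cohort["split"] == "training"])
        combined = suite.models["combined"]
        assert combined is not None
        for name in ("afp_band_2", "corona", "ttpvi", "c_dce"):
            assert combined.coefficients[name] > 0

    def test_preset_nomogram_attached_to_suite(self):
        cohort = syn.generate_cohort(syn.CohortSpec(n_patients=300, seed=9))
        suite = mdl.build_model_suite(cohort[cohort["split"] == "training"])
        rs = mdl.nomogram_points(suite.nomogram, 0, True, True, 1.268)
        assert round(rs) == 259

    def test_null_afp_effect_rarely_selected(self):
        # AFP distributions identical across groups: the univariate screen
        # should admit AFP only at roughly the nominal false-positive rate
        probs = {"MP": (0.4, 0.4, 0.2), "MN": (0.4, 0.4, 0.2)}
        hits = 0
        for seed in range(30):
            cohort = syn.generate_cohort(
                syn.CohortSpec(n_patients=200, seed=seed, afp_probs=probs)
            )
            res = mdl.compare_groups(cohort, "afp_band", continuous=False)
            hits += res.p_value < 0.05
        assert hits <= 5

    def test_refit_nomogram_probability_consistency(self):
        cohort = syn.generate_cohort(
            syn.CohortSpec(n_patients=3000, seed=13, label_mode="logistic")
        )
        suite = mdl.build_model_suite(
            cohort[cohort["split"] == "training"], nomogram_mode="refit"
        )
        nomo = suite.nomogram
        assert nomo.calibration == "refit"
        # points -> probability must agree with the fitted model itself
        combined = suite.models["combined"]
        row = cohort.iloc[[0]]
        rs = mdl.nomogram_points(
            nomo, int(row["afp_band"].iloc[0]), bool(row["corona"].iloc[0]),
            bool(row["ttpvi"].iloc[0]), float(row["c_dce"].iloc[0]),
        )
        p_nomo = mdl.points_to_probability(nomo, rs)
        p_model = combined.predict_proba(mdl.combined_design(row))[0]
        assert p_nomo == pytest.approx(p_model, abs=1e-10)
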