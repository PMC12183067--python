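"""Tests for the scaled logistic-regression live-birth models."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ovafit import (
    CohortConfig,
    LogitModel,
    WeightedAgeSeries,
    aor_from_coefficient,
    cumulative_live_birth,
    evaluate_model,
    filter_opu_cohort,
    fit_logit,
    fit_svbt_pipeline,
    fit_wnlsr,
    map_grade,
    predict_live_birth,
    scale_covariate,
)
from ovafit.birth import ScaledDesign, inverse_scale
from ovafit.errors import DataError, DomainError, RankDeficiencyError

SVBT_BETA = np.array([4.552, -0.129, -0.328, -0.502])


def make_model(names, coef):
    coef = np.asarray(coef, dtype=float)
    z = np.zeros_like(coef)
    return LogitModel(
        names=names, coef=coef, se=z + 0.1,
        ci95=np.column_stack([coef - 0.2, coef + 0.2]), pvalues=z, n=100,
    )


class TestMapGrade:
    @pytest.mark.parametrize(
        "grade,expected",
        [("AA", 0), ("AB", 1), ("BA", 1), ("BB", 2), ("AC", 2), ("BC", 3), ("CB", 3)],
    )
    def test_groups(self, grade, expected):
        assert map_grade(grade) == expected

    @pytest.mark.parametrize("grade", ["CA", "CC"])
    def test_excluded(self, grade):
        assert map_grade(grade) is None

    def test_unknown_raises(self):
        with pytest.raises(DataError):
            map_grade("XY")


class TestScaleCovariate:
    def _constant_curve(self, rate):
        # linear fit to constant data predicts that constant everywhere
        s = WeightedAgeSeries(
            np.arange(27.0, 33.0), np.full(6, rate), np.full(6, 10)
        )
        return fit_wnlsr(s, "linear", seed=0)

    def test_fifty_percent_maps_to_zero(self):
        assert scale_covariate(30.0, self._constant_curve(50.0)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_logit_arithmetic(self):
        assert scale_covariate(30.0, self._constant_curve(26.89)) == pytest.approx(
            -1.000, abs=1e-3
        )

    def test_unfitted_curve_raises(self):
        with pytest.raises(DataError):
            scale_covariate(30.0, None)

    def test_scaling_metadata_roundtrip(self, small_series):
        curve = fit_wnlsr(small_series, "logistic", seed=0)
        raw = np.array([30.0, 35.0, 41.0])
        scaled = scale_covariate(raw, curve)
        back = np.array([inverse_scale(s, curve, bracket=(20.0, 60.0)) for s in scaled])
        assert np.allclose(back, raw, atol=1e-7)


class TestFitLogit:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 25 + [0] * 75)
        model = fit_logit(pd.DataFrame(index=range(100)), y)
        assert model.coef[0] == pytest.approx(logit(0.25), abs=1e-6)

    def test_printed_svbt_equation_recovery(self):
        """Coefficients simulated from the published per-transfer logit are
        recovered within 2 SE at n = 50,000."""
        rng = np.random.default_rng(123)
        n = 50_000
        X = np.column_stack([
            rng.uniform(10, 45, n), rng.uniform(0, 3, n),
            rng.integers(0, 2, n).astype(float),
        ])
        p = expit(SVBT_BETA[0] + X @ SVBT_BETA[1:])
        y = (rng.random(n) < p).astype(int)
        model = fit_logit(X, y)
        for est, se, truth in zip(model.coef, model.se, SVBT_BETA):
            assert abs(est - truth) < 2 * se

    def test_duplicated_data_shrinks_se(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(2000, 2))
        y = (rng.random(2000) < expit(0.3 + X @ [0.5, -0.7])).astype(int)
        m1 = fit_logit(X, y)
        m2 = fit_logit(np.vstack([X, X]), np.concatenate([y, y]))
        assert np.allclose(m1.coef, m2.coef, atol=1e-6)
        assert np.allclose(m2.se, m1.se / np.sqrt(2), rtol=1e-3)

    def test_aor_coefficient_identity(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(500, 2))
        y = (rng.random(500) < expit(X @ [0.5, -0.7])).astype(int)
        model = fit_logit(X, y)
        assert np.allclose(model.aor, np.exp(model.coef), rtol=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(DataError):
            fit_logit(np.random.default_rng(0).normal(size=(10, 1)), np.ones(10))

    def test_collinear_design_raises(self):
        x = np.linspace(0, 1, 50)
        X = np.column_stack([x, 2 * x])
        y = (x > 0.5).astype(int)
        with pytest.raises(RankDeficiencyError):
            fit_logit(X, y)


class TestPrediction:
    def test_printed_intercept_probability(self):
        model = make_model(["const", "age", "grade", "day"], SVBT_BETA)
        p = predict_live_birth(model, [[0.0, 0.0, 0.0]])
        assert p == pytest.approx(1 / (1 + np.exp(-4.552)), abs=1e-6)
        assert p == pytest.approx(0.9896, abs=1e-4)

    def test_zero_linear_predictor(self):
        model = make_model(["const", "x"], [0.0, 1.0])
        assert predict_live_birth(model, [[0.0]]) == pytest.approx(0.5)

    def test_monotone_in_negative_coefficient(self):
        model = make_model(["const", "age"], [1.0, -0.5])
        p = [predict_live_birth(model, [[v]]) for v in (0.0, 1.0, 2.0)]
        assert p[0] > p[1] > p[2]

    def test_arity_mismatch(self):
        model = make_model(["const", "a", "b"], [0.0, 1.0, 1.0])
        with pytest.raises(DataError):
            predict_live_birth(model, [[1.0]])


class TestCumulativeLiveBirth:
    def test_single_cycle_equals_p1(self):
        model = make_model(["const", "cycle"], [0.5, -0.2])
        tab = cumulative_live_birth(model, {}, 1)
        assert tab["clbr"][0] == pytest.approx(tab["p_cycle"][0])

    def test_two_cycle_complement_product(self):
        # engineered per-cycle probabilities (0.3, 0.25)
        b1 = logit(0.3)
        b_cyc = logit(0.25) - logit(0.3)
        model = make_model(["const", "cycle"], [b1 - b_cyc, b_cyc])
        tab = cumulative_live_birth(model, {}, 2)
        assert tab["p_cycle"].tolist() == pytest.approx([0.3, 0.25], abs=1e-9)
        assert tab["clbr"][1] == pytest.approx(0.475, abs=1e-9)

    def test_monotone_bounded_and_limit(self):
        model = make_model(["const", "cycle"], [0.0, 0.0])  # constant p = 0.5
        tab = cumulative_live_birth(model, {}, 25)
        assert np.all(np.diff(tab["clbr"]) >= 0)
        assert np.all(tab["clbr"] <= 1.0)
        assert tab["clbr"].iloc[-1] == pytest.approx(1.0, abs=1e-6)

    def test_decreasing_per_cycle_under_negative_coefficient(self):
        model = make_model(["const", "cycle"], [1.0, -0.3])
        tab = cumulative_live_birth(model, {}, 6)
        assert np.all(np.diff(tab["p_cycle"]) < 0)

    def test_domain_error(self):
        model = make_model(["const", "cycle"], [0.0, -0.1])
        with pytest.raises(DomainError):
            cumulative_live_birth(model, {}, 0)


class TestEvaluateModel:
    def _scored_model(self):
        return make_model(["const", "x"], [0.0, 5.0])

    def test_perfect_scores(self):
        model = self._scored_model()
        X = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        y = np.array([1, 1, 0, 0])
        evaluate_model(model, X, y)
        assert model.auc == 1.0
        assert model.accuracy == 1.0

    def test_constant_scores_auc_half(self):
        model = make_model(["const", "x"], [0.3, 0.0])
        X = np.zeros((40, 1))
        y = np.array([0, 1] * 20)
        evaluate_model(model, X, y)
        assert model.auc == pytest.approx(0.5)

    def test_four_point_worked_auc(self):
        """Scores (.9,.8,.3,.2) with labels (1,0,1,0): 3 of 4 concordant
        pairs -> AUC 0.75 by exhaustive pair counting."""
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        model = make_model(["const", "x"], [0.0, 1.0])
        X = logit(scores).reshape(-1, 1)
        y = np.array([1, 0, 1, 0])
        evaluate_model(model, X, y)
        assert model.auc == pytest.approx(0.75)

    def test_single_class_error(self):
        model = self._scored_model()
        with pytest.raises(DataError):
            evaluate_model(model, np.zeros((5, 1)), np.ones(5))


class TestAorFromCoefficient:
    @pytest.mark.parametrize(
        "coef,expected", [(-0.502, 0.605), (1.361, 3.900), (0.0, 1.0)]
    )
    def test_published_aors(self, coef, expected):
        aor, _ = aor_from_coefficient(coef, 0.1)
        assert aor == pytest.approx(expected, abs=5e-4)

    def test_ci(self):
        aor, (lo, hi) = aor_from_coefficient(-0.502, 0.119)
        assert lo == pytest.approx(np.exp(-0.502 - 1.96 * 0.119), rel=1e-12)
        assert hi == pytest.approx(np.exp(-0.502 + 1.96 * 0.119), rel=1e-12)
        assert lo < aor < hi


class TestFilterOpuCohort:
    def test_censored_removed_and_tallied(self):
        df = pd.DataFrame(
            {
                "age": [30, 31, 32, 33],
                "cycle_index": [1, 1, 2, 1],
                "factor_value": [2.0, 0.0, 1.0, 3.0],
                "live_birth": [1, 0, np.nan, np.nan],
                "censored_reason": ["none", "none", "spontaneous_pregnancy",
                                    "patient_reasons"],
            }
        )
        kept, report = filter_opu_cohort(df)
        assert len(kept) == 2
        assert report == {"spontaneous_pregnancy": 1, "patient_reasons": 1}

    def test_zero_factor_cycle_retained(self):
        df = pd.DataFrame(
            {"age": [40], "cycle_index": [1], "factor_value": [0.0],
             "live_birth": [0], "censored_reason": ["none"]}
        )
        kept, report = filter_opu_cohort(df)
        assert len(kept) == 1 and report == {}

    def test_empty_input(self):
        kept, report = filter_opu_cohort(pd.DataFrame())
        assert len(kept) == 0 and report == {}


class TestSvbtPipeline:
    def test_grade_and_day_monotonicity(self, svbt_raw):
        """Predicted live birth: excellent > good > average > fair at fixed
        age and day, and day 5 > day 6 at fixed grade."""
        model, design, y, scalers = fit_svbt_pipeline(svbt_raw, seed=0)
        age_s = scale_covariate(35.0, scalers["age"])
        for day in (0.0, 1.0):
            preds = [
                predict_live_birth(
                    model, [[age_s, scale_covariate(float(g), scalers["grade"]), day]]
                )
                for g in range(4)
            ]
            assert all(np.diff(preds) < 0)
        g_s = scale_covariate(1.0, scalers["grade"])
        assert predict_live_birth(model, [[age_s, g_s, 0.0]]) > predict_live_birth(
            model, [[age_s, g_s, 1.0]]
        )

    def test_auc_above_half_and_metrics_attached(self, svbt_raw):
        model, *_ = fit_svbt_pipeline(svbt_raw, seed=0)
        assert 0.5 < model.auc <= 1.0
        assert 0.0 <= model.accuracy <= 1.0
        assert 0.0 <= model.threshold <= 1.0


class TestScaledDesignRoundtrip:
    def test_from_raw_passthrough_and_scaling(self, small_series):
        curve = fit_wnlsr(small_series, "logistic", seed=0)
        raw = pd.DataFrame({"age": [30.0, 40.0], "flag": [0.0, 1.0]})
        design = ScaledDesign.from_raw(raw, {"age": curve, "flag": None})
        assert design.data["flag"].tolist() == [0.0, 1.0]
        assert np.allclose(
            design.data["age"], scale_covariate(raw["age"].to_numpy(), curve)
        )
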