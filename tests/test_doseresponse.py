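"""Logistic dose-response fitting, IC50, Wald bands, probability combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from ocuscreen import (
    FitError,
    LogisticFit,
    SeparationError,
    SimDoseConfig,
    ValidationError,
    combine_probabilities,
    confidence_band,
    fit_logistic,
    ic50,
    irritation_profile,
    predict,
    simulate_binary_dose_response,
)

SLS_MODEL = LogisticFit.from_coefficients(-1.1057, 1e-6)
EMA_MODEL = LogisticFit.from_coefficients(-0.9490, 0.0)

SLS_CONCENTRATIONS = [100.0, 1e3, 1e4, 1e5, 1e6, 1e7]
EMA_CONCENTRATIONS = [500.0, 5e3, 5e4, 5e5, 5e6]


def loglik(b0, b1, c, y):
    eta = b0 + b1 * c
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


class TestFit:
    def test_two_point_saturated_fit_matches_closed_form(self):
        c = np.array([0.0] * 100 + [2e6] * 100)
        y = np.array([1] * 30 + [0] * 70 + [1] * 70 + [0] * 30, dtype=float)
        fit = fit_logistic(c, y)
        b0_exact = logit(0.3)
        b1_exact = (logit(0.7) - logit(0.3)) / 2e6
        assert fit.converged
        assert fit.beta0 == pytest.approx(b0_exact, abs=1e-6)
        assert fit.beta1 == pytest.approx(b1_exact, rel=1e-6)

    @pytest.mark.parametrize("beta0", [-2.0, -1.0, 0.0])
    @pytest.mark.parametrize("beta1", [0.0, 1e-6, 1e-5])
    def test_parameter_recovery_within_three_se(self, beta0, beta1):
        cfg = SimDoseConfig(
            beta0=beta0, beta1=beta1, concentrations=SLS_CONCENTRATIONS,
            n_patterns_per_conc=500, seed=hash((beta0, beta1)) % 2**31,
        )
        df = simulate_binary_dose_response(cfg)
        fit = fit_logistic(df)
        se0, se1 = fit.standard_errors()
        assert fit.converged
        assert abs(fit.beta0 - beta0) < 3 * se0
        assert abs(fit.beta1 - beta1) < 3 * se1

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        cfg = SimDoseConfig(
            beta0=-1.0, beta1=1e-6, concentrations=SLS_CONCENTRATIONS,
            n_patterns_per_conc=100, seed=5,
        )
        df = simulate_binary_dose_response(cfg)
        fit = fit_logistic(df)
        X = sm.add_constant(df["concentration_nM"].to_numpy())
        ref = sm.GLM(
            df["outcome"].to_numpy(), X, family=sm.families.Binomial()
        ).fit()
        assert fit.beta0 == pytest.approx(ref.params[0], rel=1e-6)
        assert fit.beta1 == pytest.approx(ref.params[1], rel=1e-6)
        se0, se1 = fit.standard_errors()
        assert se0 == pytest.approx(ref.bse[0], rel=1e-4)
        assert se1 == pytest.approx(ref.bse[1], rel=1e-4)

    def test_irls_optimum_matches_dense_loglik_grid_search(self):
        cfg = SimDoseConfig(
            beta0=-1.0, beta1=1e-6, concentrations=[0.0, 5e5, 2e6],
            n_patterns_per_conc=60, seed=17,
        )
        df = simulate_binary_dose_response(cfg)
        c = df["concentration_nM"].to_numpy()
        y = df["outcome"].to_numpy(dtype=float)
        fit = fit_logistic(c, y)
        # independent oracle: dense grid around the generator truth
        b0_grid = np.linspace(-2.5, 0.5, 121)
        b1_grid = np.linspace(-1e-6, 3e-6, 121)
        ll = np.array([[loglik(b0, b1, c, y) for b1 in b1_grid] for b0 in b0_grid])
        i, j = np.unravel_index(ll.argmax(), ll.shape)
        db0 = b0_grid[1] - b0_grid[0]
        db1 = b1_grid[1] - b1_grid[0]
        assert abs(fit.beta0 - b0_grid[i]) <= db0
        assert abs(fit.beta1 - b1_grid[j]) <= db1

    def test_all_identical_outcomes_raise_separation_error(self):
        c = np.array([0.0, 1e3, 1e6] * 10)
        with pytest.raises(SeparationError, match="separat"):
            fit_logistic(c, np.zeros(30))
        with pytest.raises(SeparationError):
            fit_logistic(c, np.ones(30))

    def test_single_concentration_rejected(self):
        with pytest.raises(ValidationError, match="distinct"):
            fit_logistic(np.full(20, 100.0), np.r_[np.ones(10), np.zeros(10)])

    def test_perfectly_separated_data_flagged(self):
        c = np.r_[np.zeros(20), np.full(20, 1e6)]
        y = np.r_[np.zeros(20), np.ones(20)]
        fit = fit_logistic(c, y)
        assert fit.separation_flag


class TestPredictAndIC50:
    def test_null_model_predicts_half_everywhere(self):
        null = LogisticFit.from_coefficients(0.0, 0.0)
        assert predict(null, 0.0) == 0.5
        assert predict(null, 1e9) == 0.5

    def test_printed_surfactant_model_probabilities(self):
        # at the 0.05% w/w exposure concentration the probability exceeds 0.99
        assert predict(SLS_MODEL, 1.73e7) > 0.99
        # direct evaluation of the logistic expression at C = 0
        assert predict(SLS_MODEL, 0.0) == pytest.approx(0.2487, abs=5e-5)

    def test_predict_monotonicity_matches_slope_sign(self):
        grid = np.linspace(0, 1e7, 50)
        rising = predict(SLS_MODEL, grid)
        assert np.all(np.diff(rising) > 0)
        flat = predict(EMA_MODEL, grid)
        assert np.all(flat == flat[0])

    def test_ic50_of_printed_model_is_about_one_millimolar(self):
        value = ic50(SLS_MODEL)
        assert value == pytest.approx(1.1057e6, rel=1e-12)
        # ~1e6 nM to one significant figure
        assert round(value / 10 ** np.floor(np.log10(value))) == 1
        assert predict(SLS_MODEL, value) == pytest.approx(0.5, abs=1e-15)

    def test_ic50_degenerate_cases(self):
        assert ic50(LogisticFit.from_coefficients(0.0, 1e-6)) == 0.0
        with pytest.raises(FitError, match="IC50"):
            ic50(EMA_MODEL)  # printed slope-zero model has no IC50


class TestConfidenceBand:
    def _fit(self, n, seed=3):
        cfg = SimDoseConfig(
            beta0=-1.1057, beta1=1e-6,
            concentrations=[0.0, 2.5e5, 5e5, 1e6, 2e6],
            n_patterns_per_conc=n, seed=seed,
        )
        return fit_logistic(simulate_binary_dose_response(cfg))

    def test_band_brackets_point_estimate_everywhere(self):
        fit = self._fit(200)
        grid = np.linspace(0, 2e6, 41)
        lo, hi = confidence_band(fit, grid)
        p = predict(fit, grid)
        assert np.all(lo <= p) and np.all(p <= hi)

    def test_band_width_shrinks_with_sample_size(self):
        widths = []
        for n in [100, 1000, 10000]:
            lo, hi = confidence_band(self._fit(n), np.array([1e6]))
            widths.append(float(hi[0] - lo[0]))
        assert widths[0] > widths[1] > widths[2]

    def test_band_coverage_is_nominal_at_mid_range(self):
        true_p = float(expit(-1.1057 + 1e-6 * 1e6))
        covered = 0
        n_sims = 500
        for s in range(n_sims):
            fit = self._fit(100, seed=10_000 + s)
            lo, hi = confidence_band(fit, np.array([1e6]))
            covered += bool(lo[0] <= true_p <= hi[0])
        assert 0.91 <= covered / n_sims <= 0.99

    def test_band_requires_covariance(self):
        with pytest.raises(FitError):
            confidence_band(SLS_MODEL, np.array([1e5]))


class TestCombination:
    def test_printed_worked_example_for_mild_irritant(self):
        # P_apoptosis = expit(-0.9490) = 0.2791, P_TRPV1 = 0.8 -> union 0.8558
        pa = predict(EMA_MODEL, 5e5)
        combined = combine_probabilities(pa, 0.8)
        assert combined == pytest.approx(0.8558, abs=5e-5)
        assert combined >= 0.85

    def test_union_with_null_and_certain_events(self):
        assert combine_probabilities(0.3, 0.0) == pytest.approx(0.3)
        assert combine_probabilities(1.0, 1.0) == 1.0

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValidationError):
            combine_probabilities(1.2, 0.5)
        with pytest.raises(ValidationError):
            combine_probabilities(0.5, -0.1)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None)
    def test_union_symmetry_and_frechet_bounds(self, pa, pb):
        u = combine_probabilities(pa, pb)
        assert u == pytest.approx(combine_probabilities(pb, pa), abs=1e-12)
        assert max(pa, pb) - 1e-12 <= u <= min(1.0, pa + pb) + 1e-12

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None)
    def test_union_monotone_in_each_argument(self, pa, pb, pa2):
        lo, hi = sorted([pa, pa2])
        assert combine_probabilities(lo, pb) <= combine_probabilities(hi, pb) + 1e-12

    def test_custom_intersection_rules(self):
        # comonotone upper Fréchet intersection: union = max(pa, pb)
        u = combine_probabilities(0.3, 0.6, intersection=lambda a, b: np.minimum(a, b))
        assert u == pytest.approx(0.6)
        with pytest.raises(ValidationError, match="Fréchet"):
            combine_probabilities(0.3, 0.6, intersection=lambda a, b: a * 0 + 0.9)


class TestIrritationProfile:
    def test_potent_surfactant_below_cytotoxic_range(self):
        # apoptosis from the printed model, TRPV1 activation ~0.5:
        # combined likelihood below 1e6 nM is ~0.6
        profile = irritation_profile(SLS_MODEL, 0.5, [1e5])
        assert profile.p_combined[0] == pytest.approx(0.63, abs=0.005)
        assert round(profile.p_combined[0], 1) == 0.6

    def test_zero_probability_assays_combine_to_zero(self):
        profile = irritation_profile(0.0, 0.0, np.linspace(0, 1e6, 5))
        assert np.all(profile.p_combined == 0.0)

    def test_combined_dominates_each_component(self):
        grid = np.logspace(2, 7, 30)
        profile = irritation_profile(SLS_MODEL, 0.5, grid)
        assert np.all(profile.p_combined >= profile.p_apoptosis - 1e-12)
        assert np.all(profile.p_combined >= profile.p_trpv1 - 1e-12)

    def test_constant_probability_must_be_valid(self):
        with pytest.raises(ValidationError):
            irritation_profile(SLS_MODEL, 1.3, [1e5])
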