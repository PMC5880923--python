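"""Maximum-likelihood engine: likelihood values, indices, LRT."""

import numpy as np
import pytest

from lgmsearch.fit import (
    FitOptions,
    FitResult,
    baseline_fit,
    fit_indices,
    fit_ml,
    fit_ml_moments,
    lrt,
    sample_moments,
    saturated_loglik,
)
from lgmsearch.model import ModelSpec
from lgmsearch.population import PopulationCondition, generate_dataset


@pytest.fixture(scope="module")
def linear_data():
    cond = PopulationCondition("linear4", "UN1", 0.3, 210)
    return generate_dataset(cond, 314)


def _fake_fit(**kw):
    base = dict(
        spec=None, estimates=None, loglik=0.0, k=1, df=1, n=100,
        converged=True, chi_square=0.0, aic=0.0, bic=0.0,
        mu_hat=np.zeros(2), sigma_hat=np.eye(2),
        sample_mean=np.zeros(2), sample_cov=np.eye(2),
    )
    base.update(kw)
    return FitResult(**base)


class TestSaturatedModel:
    def test_reproduces_closed_form_maximum(self, linear_data):
        ybar, S, n = sample_moments(linear_data.y)
        result = fit_ml(linear_data, ModelSpec(4, 3, "UN", "none"))
        assert result.converged
        assert result.loglik == pytest.approx(saturated_loglik(S, n), abs=1e-6)
        assert result.chi_square == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(result.mu_hat, ybar, atol=1e-6)
        np.testing.assert_allclose(result.sigma_hat, S, atol=1e-6)


class TestOracleEquivalence:
    def test_un_residual_matches_iterative_gls(self, gls_oracle, rng):
        # ten random small instances; the acceptance suite runs fifty
        for _ in range(10):
            t = int(rng.integers(4, 7))
            order = int(rng.integers(0, t - 2))
            n = int(rng.integers(50, 200))
            A = rng.standard_normal((t, t)) / np.sqrt(t)
            sigma = A @ A.T + np.eye(t)
            y = rng.multivariate_normal(rng.normal(0, 1, t), sigma, size=n)
            ybar, S, n = sample_moments(y)
            fit = fit_ml_moments(
                ybar, S, n, ModelSpec(t, order, "UN", "none"),
                FitOptions(gtol=1e-7),
            )
            alpha_o, sigma_o = gls_oracle(ybar, S, order, t)
            assert fit.converged
            np.testing.assert_allclose(fit.estimates.alpha, alpha_o, atol=1e-6)
            np.testing.assert_allclose(fit.sigma_hat, sigma_o, atol=1e-6)


class TestParameterRecovery:
    def test_true_spec_estimates_near_truth_at_large_n(self):
        cond = PopulationCondition("linear4", "UN1", 0.0, 50_000)
        data = generate_dataset(cond, 2024)
        fit = fit_ml(data, ModelSpec(4, 1, "UN1", "full_identified"))
        assert fit.converged
        # ~3 Monte Carlo standard errors at this n
        np.testing.assert_allclose(fit.estimates.alpha, [1.0, 0.5], atol=0.02)
        np.testing.assert_allclose(
            fit.estimates.psi, [[0.20, 0.05], [0.05, 0.10]], atol=0.03
        )
        np.testing.assert_allclose(
            fit.estimates.theta, [1.0, 0.80, 0.64, 0.512], atol=0.05
        )


class TestBaseline:
    def test_baseline_is_most_restrictive_covariance(self, linear_data):
        base = baseline_fit(linear_data)
        assert base.k == 2 * 4
        for order in (0, 1, 2):
            fit = fit_ml(linear_data, ModelSpec(4, order, "UN", "none"))
            assert base.chi_square >= fit.chi_square - 1e-8

    def test_zero_correlation_data_fits_perfectly(self, rng):
        y = rng.standard_normal((2000, 4)) * np.array([1.0, 2.0, 0.5, 1.5])
        ybar, _, n = sample_moments(y)
        # orthogonalize columns so empirical correlations are exactly zero
        q, _ = np.linalg.qr(y - ybar)
        y0 = q * np.sqrt(n) + 1.0
        base = baseline_fit(y0)
        assert base.chi_square == pytest.approx(0.0, abs=1e-8)


class TestFitIndices:
    def test_saturated_model_gets_perfect_indices(self, linear_data):
        fit = fit_ml(linear_data, ModelSpec(4, 3, "UN", "none"))
        fit_indices(fit, baseline_fit(linear_data))
        assert fit.cfi == pytest.approx(1.0, abs=1e-9)
        assert fit.rmsea == 0.0  # df = 0 convention
        assert fit.srmr == pytest.approx(0.0, abs=1e-5)

    def test_chi_square_equal_df_gives_zero_rmsea(self):
        fit = _fake_fit(chi_square=5.0, df=5, sigma_hat=np.eye(2))
        base = _fake_fit(chi_square=100.0, df=1)
        fit_indices(fit, base)
        assert fit.rmsea == 0.0
        assert fit.cfi == 1.0

    def test_information_criteria_recomputable_from_loglik(self, linear_data):
        for order in (0, 1, 2):
            fit = fit_ml(linear_data, ModelSpec(4, order, "UN", "none"))
            assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k)
            assert fit.bic == pytest.approx(
                -2 * fit.loglik + fit.k * np.log(fit.n)
            )


class TestLrt:
    def test_identical_loglik_gives_zero_statistic_p_one(self):
        simple = _fake_fit(loglik=-500.0, df=5)
        complex_ = _fake_fit(loglik=-500.0, df=3)
        delta, ddf, p = lrt(simple, complex_)
        assert (delta, ddf, p) == (0.0, 2, 1.0)

    def test_against_saturated_equals_model_chi_square(self, linear_data):
        simple = fit_ml(linear_data, ModelSpec(4, 1, "UN", "none"))
        saturated = fit_ml(linear_data, ModelSpec(4, 3, "UN", "none"))
        delta, ddf, _ = lrt(simple, saturated)
        assert delta == pytest.approx(simple.chi_square, abs=1e-6)
        assert ddf == simple.df

    def test_non_nested_order_rejected(self, linear_data):
        fit = fit_ml(linear_data, ModelSpec(4, 1, "UN", "none"))
        with pytest.raises(ValueError, match="nested"):
            lrt(fit, fit)


class TestLikelihoodProperties:
    def test_monotone_in_mean_order(self, linear_data):
        logliks = [
            fit_ml(linear_data, ModelSpec(4, q, "UN", "none")).loglik
            for q in range(0, 4)
        ]
        assert np.all(np.diff(logliks) >= -1e-6)

    def test_scale_equivariance(self, linear_data):
        c = 3.7
        scaled = linear_data.y * c
        base_o = baseline_fit(linear_data)
        base_s = baseline_fit(scaled)
        for order, resid, pol in [(1, "UN", "none"), (1, "ID", "full_identified")]:
            fo = fit_ml(linear_data.y, ModelSpec(4, order, resid, pol))
            fs = fit_ml(scaled, ModelSpec(4, order, resid, pol))
            fit_indices(fo, base_o)
            fit_indices(fs, base_s)
            n, t = linear_data.y.shape
            assert fs.chi_square == pytest.approx(fo.chi_square, abs=1e-4)
            assert fs.loglik == pytest.approx(
                fo.loglik - n * t * np.log(c), rel=1e-9
            )
            for attr in ("cfi", "rmsea", "srmr"):
                assert getattr(fs, attr) == pytest.approx(
                    getattr(fo, attr), abs=1e-5
                )

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            fit_ml(np.ones((5, 4)) + np.eye(5, 4), ModelSpec(4, 0, "UN", "none"))

    def test_singular_sample_covariance_rejected(self):
        y = np.outer(np.arange(50.0), np.ones(4))  # rank-1 data
        with pytest.raises(ValueError, match="singular"):
            fit_ml(y, ModelSpec(4, 1, "ID", "full_identified"))
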