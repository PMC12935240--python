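"""Circular regression: likelihood, sampler invariances, prediction."""

import math

import numpy as np
import pytest

from phenoshift.circular_glm import (
    CircularGLMConfig,
    circular_mean,
    fit,
    loglik,
    predict_mean_direction,
    wrap_angle,
)
from phenoshift.records_io import CircularObservation

I0_OF_1 = 1.2660658777520082  # modified Bessel I0(1), tabulated


def make_series(theta, years):
    return [CircularObservation(int(y), 0.0, float(t)) for y, t in zip(years, theta)]


def simulate_series(rng, n, years_range, beta0, beta1, kappa):
    years = rng.integers(years_range[0], years_range[1] + 1, n)
    z = years - years.mean()
    theta = rng.vonmises(beta0 + 2 * np.arctan(beta1 * z), kappa)
    return make_series(theta, years)


class TestLoglik:
    def test_single_obs_at_mean(self):
        # kappa*cos(0) - log(2 pi I0(1)) with kappa = 1
        expected = 1.0 - math.log(2 * math.pi * I0_OF_1)
        got = loglik([0.3], [2000.0], beta0=0.3, beta1=0.5, kappa=1.0, x_center=2000.0)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_uniform_limit_small_kappa(self):
        theta = np.linspace(-3, 3, 7)
        got = loglik(theta, np.arange(7), 0.0, 0.0, 1e-10)
        assert got == pytest.approx(-7 * math.log(2 * math.pi), abs=1e-6)

    def test_zero_slope_is_constant_mean(self):
        theta = np.array([0.5, 0.5, 0.5])
        years = np.array([1900.0, 1950.0, 2000.0])
        got = loglik(theta, years, beta0=0.5, beta1=0.0, kappa=3.0)
        expected = 3 * (3.0 - math.log(2 * math.pi) - np.log(np.i0(3.0)))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_large_kappa_stable(self):
        got = loglik([0.0], [2000.0], 0.0, 0.0, 5000.0, x_center=2000.0)
        assert np.isfinite(got)

    def test_invalid_kappa(self):
        with pytest.raises(ValueError):
            loglik([0.0], [2000.0], 0.0, 0.0, 0.0)


class TestFit:
    def test_requires_temporal_contrast(self):
        series = make_series([0.1, 0.2, 0.3], [2000, 2000, 2000])
        with pytest.raises(ValueError, match="temporal contrast"):
            fit(series, CircularGLMConfig(seed=0))

    def test_requires_three_obs(self):
        with pytest.raises(ValueError):
            fit(make_series([0.1, 0.2], [2000, 2001]), CircularGLMConfig(seed=0))

    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        series = simulate_series(rng, 50, (1950, 2000), 0.3, 0.01, 10)
        cfg = CircularGLMConfig(iterations=500, seed=5)
        a, b = fit(series, cfg), fit(series, cfg)
        assert np.array_equal(a.beta1_samples, b.beta1_samples)
        assert np.array_equal(a.beta0_samples, b.beta0_samples)

    def test_sample_count_and_kappa_positive(self):
        rng = np.random.default_rng(1)
        series = simulate_series(rng, 40, (1950, 2000), 0.0, 0.0, 8)
        cfg = CircularGLMConfig(n_chains=3, iterations=400, seed=2)
        f = fit(series, cfg)
        assert f.beta1_samples.size == 3 * 400
        assert (f.kappa_samples > 0).all()

    def test_parameter_recovery_moderate_n(self):
        rng = np.random.default_rng(7)
        beta0, beta1, kappa = 0.0, 0.02, 15.0
        series = simulate_series(rng, 300, (1950, 2010), beta0, beta1, kappa)
        f = fit(series, CircularGLMConfig(seed=3))
        assert abs(f.beta1_mean - beta1) < 3 * f.beta1_sd
        assert abs(wrap_angle(f.beta0_mean - beta0)) < 3 * 0.1
        assert f.kappa_mean == pytest.approx(kappa, rel=0.3)
        assert all(r < 1.05 for r in f.rhat.values())

    def test_rotation_invariance(self):
        """Rotating every angle by delta shifts beta0 and nothing else."""
        rng = np.random.default_rng(9)
        series = simulate_series(rng, 50, (1950, 2000), 0.2, 0.01, 12)
        delta = 1.1
        rotated = [
            CircularObservation(o.year, o.doy, float(wrap_angle(o.theta + delta)))
            for o in series
        ]
        cfg = CircularGLMConfig(iterations=1500, seed=4)
        fa, fb = fit(series, cfg), fit(rotated, cfg)
        assert wrap_angle(fb.beta0_mean - fa.beta0_mean) == pytest.approx(delta, abs=0.1)
        assert fb.beta1_mean == pytest.approx(fa.beta1_mean, abs=3 * fa.beta1_sd / 10)
        assert fb.kappa_mean == pytest.approx(fa.kappa_mean, rel=0.1)

    def test_predictor_rescaling(self):
        """Stretching the year axis by c shrinks beta1 by 1/c."""
        rng = np.random.default_rng(13)
        years = rng.integers(1950, 2001, 60)
        theta = rng.vonmises(0.3 + 2 * np.arctan(0.01 * (years - years.mean())), 10)
        series = make_series(theta, years)
        stretched = make_series(theta, years.mean() + 5 * (years - years.mean()))
        cfg = CircularGLMConfig(iterations=1500, seed=6)
        fa, fb = fit(series, cfg), fit(stretched, cfg)
        assert fb.beta1_mean == pytest.approx(fa.beta1_mean / 5, rel=0.15)

    def test_small_angle_limit_matches_ols(self):
        """Concentrated dates far from the wrap: posterior-mean shift per
        decade tracks the ordinary least-squares slope on doy."""
        rng = np.random.default_rng(17)
        years = rng.integers(1950, 2011, 400).astype(float)
        doy = 150 + 0.3 * (years - years.mean()) + rng.normal(0, 6, years.size)
        from phenoshift.records_io import day_to_radians
        from phenoshift.shift_metrics import shift_from_fit

        series = make_series(day_to_radians(doy), years)
        f = fit(series, CircularGLMConfig(seed=8))
        est = shift_from_fit(f, "x")
        ols_slope = np.polyfit(years, doy, 1)[0] * 10  # days/decade
        assert est.days_per_decade == pytest.approx(ols_slope, rel=0.05)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(21)
    series = simulate_series(rng, 120, (1950, 2010), 0.5, 0.015, 15)
    return fit(series, CircularGLMConfig(iterations=1000, seed=10))


class TestPredictMeanDirection:

    def test_center_year_returns_intercept_mean(self, fitted):
        mu = predict_mean_direction(fitted, fitted.x_center)
        assert mu == pytest.approx(circular_mean(fitted.beta0_samples), abs=1e-12)

    def test_monotone_in_year_for_positive_slope(self, fitted):
        years = np.arange(1950, 2011, 5)
        mus = np.unwrap([predict_mean_direction(fitted, y) for y in years])
        assert np.all(np.diff(mus) > 0)

    def test_mu_never_wraps_past_one_turn(self, fitted):
        for year in (1700.0, 2300.0):
            mu_draws = fitted.beta0_samples + 2 * np.arctan(
                fitted.beta1_samples * (year - fitted.x_center)
            )
            assert np.all(np.abs(mu_draws - fitted.beta0_samples) < np.pi)
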