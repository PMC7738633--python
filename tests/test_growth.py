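"""Gompertz model, rate estimation, and initiation-time backward projection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from pdacgrowth import (
    GompertzParams,
    LesionObservation,
    characteristic_time,
    cohort_fit_quality,
    cumulative_initiation_probability,
    fit_gompertz,
    fit_lognormal,
    generate_cohort,
    gompertz_volume,
    initiation_time,
    run_pipeline,
)
from pdacgrowth.growth import CarryingCapacityError

K = 180_000.0


def observations_from_curve(alpha, x0, times, k=K):
    """Noiseless biaxial observations lying exactly on a Gompertz curve."""
    params = GompertzParams(alpha=alpha, x0=x0, k=k)
    vols = gompertz_volume(np.asarray(times), params)
    diams = (6 * vols / math.pi) ** (1 / 3)
    return [LesionObservation(float(t), float(d), float(d)) for t, d in zip(times, diams)]


def crossing_time_oracle(alpha, x0, x_target, k=K):
    """Independent root-find for the time at which X(t) = x_target."""
    params = GompertzParams(alpha=alpha, x0=x0, k=k)
    return brentq(
        lambda t: gompertz_volume(t, params) - x_target, -50 / alpha, 50 / alpha,
        xtol=1e-10,
    )


class TestGompertzVolume:
    def test_anchored_at_x0(self):
        p = GompertzParams(alpha=0.05, x0=500.0)
        assert gompertz_volume(0.0, p) == pytest.approx(500.0, rel=1e-12)

    def test_asymptote_is_carrying_capacity(self):
        p = GompertzParams(alpha=0.05, x0=500.0)
        assert gompertz_volume(1e6, p) == pytest.approx(K, rel=1e-6)

    def test_closed_form_value(self):
        # frozen from high-precision evaluation of K exp(ln(X0/K) exp(-alpha t))
        p = GompertzParams(alpha=0.088, x0=1000.0, k=K)
        assert gompertz_volume(12.0, p) == pytest.approx(29565.728, abs=1.0)

    def test_strictly_increasing_and_bounded(self):
        p = GompertzParams(alpha=0.1, x0=100.0)
        t = np.linspace(0, 100, 500)
        v = gompertz_volume(t, p)
        assert np.all(np.diff(v) > 0)
        assert np.all((v >= 100.0 * (1 - 1e-12)) & (v < K))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GompertzParams(alpha=-0.1, x0=100.0)
        with pytest.raises(ValueError):
            GompertzParams(alpha=0.1, x0=2 * K)


class TestFitGompertz:
    @pytest.mark.parametrize("alpha_true", [0.01, 0.05, 0.088, 0.3])
    @pytest.mark.parametrize("times", [(0, 8), (0, 8, 16), (0, 3, 9, 14, 22, 30)])
    def test_noiseless_recovery(self, alpha_true, times):
        obs = observations_from_curve(alpha_true, 800.0, times)
        fit = fit_gompertz(obs)
        assert fit.converged
        assert fit.alpha == pytest.approx(alpha_true, rel=1e-6)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_two_points_exact(self):
        obs = observations_from_curve(0.07, 400.0, (0, 10))
        fit = fit_gompertz(obs)
        assert fit.alpha == pytest.approx(0.07, rel=1e-9)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_x0_anchored_to_first_observation(self):
        obs = observations_from_curve(0.05, 1234.0, (0, 6, 12))
        fit = fit_gompertz(obs)
        assert fit.params.x0 == pytest.approx(obs[0].volume_mm3)

    def test_noisy_median_recovery(self, rng):
        # multiplicative 10% diameter noise, 6 scans, 500 replicates
        alpha_true = 0.088
        times = np.array([0, 6, 12, 18, 24, 30], dtype=float)
        estimates = []
        params = GompertzParams(alpha=alpha_true, x0=800.0, k=K)
        clean_d = (6 * gompertz_volume(times, params) / math.pi) ** (1 / 3)
        d_cap = (6 * 0.99 * K / math.pi) ** (1 / 3)  # keep noisy volumes < K
        for _ in range(500):
            noisy = np.minimum(clean_d * rng.lognormal(-0.005, 0.1, size=len(times)), d_cap)
            obs = [LesionObservation(float(t), float(d), float(d)) for t, d in zip(times, noisy)]
            estimates.append(fit_gompertz(obs).alpha)
        assert np.median(estimates) == pytest.approx(alpha_true, rel=0.15)

    def test_decreasing_data_flagged(self):
        obs = [
            LesionObservation(0.0, 30.0, 30.0),
            LesionObservation(8.0, 20.0, 20.0),
            LesionObservation(16.0, 15.0, 15.0),
        ]
        fit = fit_gompertz(obs)
        assert not fit.converged
        assert fit.alpha == pytest.approx(1e-4)

    def test_volume_at_capacity_rejected(self):
        d_k = (6 * K / math.pi) ** (1 / 3)
        obs = [
            LesionObservation(0.0, 10.0, 10.0),
            LesionObservation(8.0, d_k + 1, d_k + 1),
        ]
        with pytest.raises(CarryingCapacityError):
            fit_gompertz(obs)


class TestCohortFitQuality:
    def test_exact_fits_give_unit_correlation(self):
        cohort = generate_cohort(n_low=3, n_high=3, diameter_noise_cv=0.0, seed=5)
        report = run_pipeline(cohort)
        for r in report.summary["fit_quality_pooled_r"].values():
            assert r == pytest.approx(1.0, abs=1e-6)

    def test_anticorrelated_residuals(self, default_cohort):
        # contrived fits whose 'fitted' values are -observed + c
        from pdacgrowth.growth import GompertzFit

        fits = {}
        c = 1e6
        for p in default_cohort:
            obs = p.volumes_mm3
            fitted = -obs + c
            fits[p.patient_id] = GompertzFit(
                params=GompertzParams(alpha=0.05, x0=obs[0]),
                pearson_r=-1.0,
                residuals=fitted - obs,
                n_obs=len(obs),
                converged=True,
            )
        quality = cohort_fit_quality(fits, default_cohort)
        for r in quality.values():
            assert r == pytest.approx(-1.0, abs=1e-9)


class TestCharacteristicTime:
    @pytest.mark.parametrize(
        "alpha, expected", [(0.024, 41.6667), (0.088, 11.3636), (1.0, 1.0)]
    )
    def test_reciprocal(self, alpha, expected):
        assert characteristic_time(alpha) == pytest.approx(expected, abs=1e-4)

    def test_domain(self):
        with pytest.raises(ValueError):
            characteristic_time(0.0)


class TestInitiationTime:
    @pytest.mark.parametrize("alpha, expected", [(0.024, 40.528), (0.088, 11.053)])
    def test_reference_values(self, alpha, expected):
        # frozen from the bisection crossing-time oracle
        assert initiation_time(alpha, x0=800.0) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("alpha", [0.005, 0.024, 0.088, 0.2, 0.5])
    @pytest.mark.parametrize("k_cm3", [90.0, 180.0, 360.0])
    def test_matches_crossing_oracle(self, alpha, k_cm3):
        k = k_cm3 * 1000.0
        x0 = 800.0
        t_oracle = crossing_time_oracle(alpha, x0, 10.0, k) - crossing_time_oracle(
            alpha, x0, 1e-6, k
        )
        assert initiation_time(alpha, x0=x0, k=k) == pytest.approx(t_oracle, abs=1e-3)

    @given(
        alpha=st.floats(0.005, 0.5),
        x0a=st.floats(20.0, 50_000.0),
        x0b=st.floats(20.0, 50_000.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_independent_of_x0(self, alpha, x0a, x0b):
        t_a = initiation_time(alpha, x0=x0a)
        t_b = initiation_time(alpha, x0=x0b)
        assert t_a == pytest.approx(t_b, rel=1e-9)

    @given(alpha=st.floats(0.005, 0.5), c=st.floats(0.1, 10.0))
    @settings(derandomize=True, max_examples=50)
    def test_inverse_proportional_to_alpha(self, alpha, c):
        assert initiation_time(c * alpha, x0=500.0) == pytest.approx(
            initiation_time(alpha, x0=500.0) / c, rel=1e-9
        )

    def test_unit_invariance(self):
        # converting every volume mm^3 -> cm^3 leaves T unchanged
        t_mm = initiation_time(0.05, x0=800.0, k=K, x_start=1e-6, x_end=10.0)
        t_cm = initiation_time(0.05, x0=0.8, k=180.0, x_start=1e-9, x_end=0.01)
        assert t_mm == pytest.approx(t_cm, rel=1e-12)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            initiation_time(0.05, x0=800.0, x_start=10.0, x_end=1e-6)


class TestLognormal:
    def test_identical_samples_degenerate(self):
        dist = fit_lognormal([3.0, 3.0, 3.0])
        assert dist.degenerate
        assert dist.mu == pytest.approx(math.log(3.0))
        assert dist.sigma == 0.0

    def test_mode_closed_form(self, rng):
        samples = rng.lognormal(1.5, 0.4, size=200)
        dist = fit_lognormal(samples)
        logs = np.log(samples)
        m, s = logs.mean(), logs.std()
        assert dist.mode == pytest.approx(math.exp(m - s**2), rel=1e-12)

    def test_mle_recovery_large_n(self, rng):
        samples = rng.lognormal(2.0, 0.5, size=100_000)
        dist = fit_lognormal(samples)
        assert dist.mu == pytest.approx(2.0, abs=0.01)
        assert dist.sigma == pytest.approx(0.5, abs=0.01)

    def test_ddof_variants(self, rng):
        samples = rng.lognormal(1.0, 0.3, size=50)
        ml = fit_lognormal(samples, ddof=0)
        unbiased = fit_lognormal(samples, ddof=1)
        assert unbiased.sigma > ml.sigma
        assert unbiased.sigma**2 == pytest.approx(ml.sigma**2 * 50 / 49, rel=1e-9)

    def test_positive_samples_required(self):
        with pytest.raises(ValueError):
            fit_lognormal([1.0, -2.0])

    def test_cdf_median_and_limits(self, rng):
        dist = fit_lognormal(rng.lognormal(1.0, 0.5, size=500))
        assert cumulative_initiation_probability(dist, dist.median) == pytest.approx(0.5)
        assert cumulative_initiation_probability(dist, 1e9) == pytest.approx(1.0)
        assert cumulative_initiation_probability(dist, -5.0) == 0.0
        ts = np.linspace(0.1, 100, 200)
        cdf = dist.cdf(ts)
        assert np.all(np.diff(cdf) >= 0)

    def test_quantile_inverts_cdf(self, rng):
        dist = fit_lognormal(rng.lognormal(2.0, 0.7, size=500))
        q90 = dist.quantile(0.9)
        assert dist.cdf(q90) == pytest.approx(0.9, rel=1e-9)
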