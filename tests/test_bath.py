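import numpy as np
import pytest

from excitonbath import (
    BathParameters,
    CorrelationFunction,
    SiteEnergyTrajectory,
    aggregate_bath,
    autocorrelation,
    drude_spectral_density,
    fit_biexponential_wnr,
    fit_trajectory,
    fluctuations,
    numerical_spectral_density,
    transport_parameter,
)
from excitonbath.fmo import reference_bath_parameters
from excitonbath.units import matsubara_timescale, thermal_energy, timescale_to_wavenumber

KBT_300 = thermal_energy(300.0)


def exponential_correlation(lam, tau, t_max=400.0, dt=0.5, temperature=300.0):
    t = np.arange(0.0, t_max, dt)
    amp = 2.0 * lam * thermal_energy(temperature)
    return CorrelationFunction(lags=t, values=amp * np.exp(-t / tau))


class TestFluctuations:
    def test_constant_series_maps_to_zeros(self):
        traj = SiteEnergyTrajectory("1", "A", 0.5, np.full(10, 11450.0))
        assert np.allclose(fluctuations(traj), 0.0)

    def test_output_mean_is_zero(self, rng):
        traj = SiteEnergyTrajectory("1", "A", 0.5, 11450 + rng.normal(0, 100, 500))
        df = fluctuations(traj)
        assert abs(df.mean()) < 1e-9 * 11450


class TestAutocorrelation:
    def test_zero_series_gives_zero_correlation(self):
        corr = autocorrelation([np.zeros(100)], 0.5, max_lag=10.0)
        assert np.allclose(corr.values, 0.0)

    def test_alternating_series_matches_double_loop(self):
        a = 3.0
        x = a * np.array([1.0, -1.0] * 50)
        n = x.size
        corr = autocorrelation([x], 1.0, max_lag=5.0)
        # independent brute-force biased estimator
        for j, lag in enumerate(corr.lags.astype(int)):
            expected = sum(x[i] * x[i + lag] for i in range(n - lag)) / n
            assert corr.values[j] == pytest.approx(expected, rel=1e-12)
        assert corr.values[0] == pytest.approx(a**2)
        assert corr.values[1] == pytest.approx(-(a**2) * (n - 1) / n)

    def test_lag_zero_equals_pooled_biased_variance(self, rng):
        series = [rng.normal(0, 5, 400) - 0 for _ in range(3)]
        series = [s - s.mean() for s in series]
        corr = autocorrelation(series, 0.5, max_lag=20.0)
        pooled = np.mean([np.mean(s**2) for s in series])
        assert corr.values[0] == pytest.approx(pooled, rel=1e-12)

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            autocorrelation([np.zeros(10), np.zeros(11)], 0.5, max_lag=2.0)

    def test_lag_grid_validation(self):
        with pytest.raises(ValueError, match="start at 0"):
            CorrelationFunction(lags=np.array([1.0, 2.0]), values=np.zeros(2))


class TestBiexponentialFit:
    def test_pure_exponential_recovery(self):
        corr = exponential_correlation(lam=100.0, tau=15.0)
        params = fit_biexponential_wnr(corr, 300.0)
        assert params.lambda_reorg == pytest.approx(100.0, abs=0.1)
        assert params.tau_slow == pytest.approx(15.0, abs=0.01)

    def test_exact_biexponential_recovery_unconstrained(self):
        t = np.arange(0.0, 400.0, 0.5)
        a, b = 30000.0, 12000.0
        corr = CorrelationFunction(
            lags=t, values=a * np.exp(-t / 15.0) + b * np.exp(-t / 4.0)
        )
        p = fit_biexponential_wnr(corr, 300.0, mode="unconstrained")
        assert p.amplitude_slow == pytest.approx(a, rel=0.01)
        assert p.amplitude_fast == pytest.approx(b, rel=0.01)
        assert p.tau_slow == pytest.approx(15.0, rel=0.01)
        assert p.tau_fast == pytest.approx(4.0, rel=0.01)

    def test_constrained_mode_pins_fast_timescale_by_temperature(self):
        corr = exponential_correlation(lam=80.0, tau=12.0)
        p = fit_biexponential_wnr(corr, 300.0, mode="pade")
        assert p.tau_fast == pytest.approx(matsubara_timescale(300.0), rel=1e-12)
        assert 3.0 < p.tau_fast < 6.0

    def test_ou_recovery_at_production_scale(self, ou_paper_scale):
        config, trajs = ou_paper_scale
        p = fit_trajectory(trajs, config.temperature)
        assert p.lambda_reorg == pytest.approx(config.lambda_reorg, rel=0.10)
        assert p.tau_slow == pytest.approx(config.tau_corr, rel=0.10)

    def test_too_few_lags_rejected(self):
        corr = CorrelationFunction(
            lags=np.arange(10.0), values=np.exp(-np.arange(10.0))
        )
        with pytest.raises(ValueError, match="20 lags"):
            fit_biexponential_wnr(corr, 300.0)

    def test_unknown_mode_rejected(self):
        corr = exponential_correlation(100.0, 15.0)
        with pytest.raises(ValueError, match="mode"):
            fit_biexponential_wnr(corr, 300.0, mode="bogus")

    def test_parameter_ordering_invariant(self):
        with pytest.raises(ValueError, match="tau_slow > tau_fast"):
            BathParameters(
                lambda_reorg=10.0, tau_slow=2.0, tau_fast=5.0,
                amplitude_slow=1.0, amplitude_fast=1.0, temperature=300.0,
            )


class TestDrudeSpectralDensity:
    def test_peak_identity_j_of_gamma_is_lambda(self):
        for lam, gamma in [(100.0, 330.0), (35.0, 106.0), (1.0, 5.0)]:
            sd = drude_spectral_density(lam, gamma, np.array([gamma]))
            assert sd.j_values[0] == pytest.approx(lam, rel=1e-12)

    def test_zero_lambda_gives_zero_everywhere(self):
        sd = drude_spectral_density(0.0, 100.0, np.linspace(0, 1000, 50))
        assert np.allclose(sd.j_values, 0.0)

    def test_high_frequency_tail(self):
        lam, gamma = 100.0, 330.0
        omega = np.array([1e7])
        sd = drude_spectral_density(lam, gamma, omega)
        assert sd.j_values[0] * omega[0] == pytest.approx(2 * lam * gamma, rel=1e-6)

    def test_zero_at_zero_frequency_and_nonnegative(self):
        sd = drude_spectral_density(100.0, 330.0, np.linspace(0, 2000, 100))
        assert sd.j_values[0] == 0.0
        assert np.all(sd.j_values >= 0)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            drude_spectral_density(100.0, 0.0, np.array([1.0]))


class TestNumericalSpectralDensity:
    def test_exponential_correlation_matches_drude_form(self):
        lam, tau = 100.0, 15.0
        gamma = timescale_to_wavenumber(tau)
        corr = exponential_correlation(lam, tau, t_max=2000.0, dt=0.1)
        omega = np.linspace(gamma / 5, 5 * gamma, 40)
        numeric = numerical_spectral_density(corr, 300.0, omega)
        analytic = drude_spectral_density(lam, gamma, omega)
        assert np.allclose(numeric.j_values, analytic.j_values, rtol=0.01)

    def test_zero_correlation_gives_zero_density(self):
        corr = CorrelationFunction(lags=np.arange(0.0, 50.0), values=np.zeros(50))
        sd = numerical_spectral_density(corr, 300.0, np.linspace(0, 500, 20))
        assert np.allclose(sd.j_values, 0.0)

    def test_linearity_in_correlation_amplitude(self):
        corr = exponential_correlation(50.0, 10.0, t_max=1000.0, dt=0.2)
        doubled = CorrelationFunction(lags=corr.lags, values=2 * corr.values)
        omega = np.linspace(10, 1500, 30)
        j1 = numerical_spectral_density(corr, 300.0, omega).j_values
        j2 = numerical_spectral_density(doubled, 300.0, omega).j_values
        assert np.allclose(j2, 2 * j1, rtol=1e-12)

    def test_undecayed_correlation_warns(self):
        corr = exponential_correlation(100.0, 15.0, t_max=20.0, dt=0.5)
        with pytest.warns(UserWarning, match="decayed"):
            numerical_spectral_density(corr, 300.0, np.array([100.0]))


class TestAggregates:
    def test_reference_table_aggregates(self):
        summary = aggregate_bath(reference_bath_parameters())
        assert summary.mean_lambda == pytest.approx(101.61, abs=0.01)
        assert summary.mean_tau_slow == pytest.approx(16.065, abs=0.01)
        assert summary.cutoff_wavenumber == pytest.approx(330.0, abs=1.0)
        assert summary.mean_tau_fast == pytest.approx(4.20, abs=0.01)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_bath([])


class TestTransportParameter:
    def test_zero_reorganization_gives_zero(self):
        assert transport_parameter(0.0, 300.0, 45.0, 300.0) == 0.0

    def test_default_formula_arithmetic(self):
        value = transport_parameter(100.0, 300.0, 45.0, 300.0)
        assert value == pytest.approx(100 * 300 / (45 * KBT_300), rel=1e-9)
        assert value == pytest.approx(3.197, abs=0.005)

    def test_formula_plug_in_contract(self):
        assert transport_parameter(
            100.0, 300.0, 45.0, 300.0, formula=lambda *args: 1.0
        ) == 1.0

    def test_nonpositive_scales_rejected(self):
        with pytest.raises(ValueError):
            transport_parameter(100.0, -1.0, 45.0, 300.0)


class TestConsistencyTriangle:
    def test_fitted_drude_matches_numerical_transform_near_peak(self, ou_paper_scale):
        """Fit -> Drude and direct cosine transform agree on OU data."""
        config, trajs = ou_paper_scale
        from excitonbath.bath import fluctuations as fl

        series = [fl(t) for t in trajs]
        corr = autocorrelation(series, config.time_step, max_lag=150.0)
        params = fit_biexponential_wnr(corr, config.temperature)
        gamma = params.gamma_wavenumber
        peak = numerical_spectral_density(
            corr, config.temperature, np.array([gamma])
        ).j_values[0]
        assert peak == pytest.approx(params.lambda_reorg, rel=0.10)
        omega = np.linspace(0.5 * gamma, 2.0 * gamma, 25)
        fitted = drude_spectral_density(params.lambda_reorg, gamma, omega)
        numeric = numerical_spectral_density(corr, config.temperature, omega)
        median_dev = np.median(np.abs(numeric.j_values / fitted.j_values - 1.0))
        assert median_dev < 0.10
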