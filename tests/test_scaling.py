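"""Master-curve fitting, collapse metrics, sensitivity, temperature suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msbsim import (
    SimulationConfig,
    collapse_test,
    fit_langevin_master,
    langevin_function,
    sensitivity_curve,
    simulate_dimensionless,
    sweep_dimensionless,
    temperature_invariance_suite,
)
from msbsim.scaling import SweepResult

from msbsim.spectroscopy import harmonic_spectrum
from msbsim.parameters import DriveField, Environment, ParticleSpec


def _exact_sweep(b: float, grid: np.ndarray, harmonic: int = 3) -> SweepResult:
    vals = langevin_function(b * grid)
    return SweepResult(
        a=grid,
        xi0_mean=grid,
        omega_mean=np.ones_like(grid),
        harmonics={harmonic: vals},
        se={harmonic: np.full(len(grid), 1e-3)},
    )


class TestLangevinFunction:
    @settings(max_examples=100, derandomize=True)
    @given(x=st.floats(min_value=1e-8, max_value=50.0))
    def test_bounded_odd_and_monotone(self, x):
        l = langevin_function(x)
        assert 0.0 < l < 1.0
        assert langevin_function(-x) == pytest.approx(-l, rel=1e-12)
        assert langevin_function(1.001 * x) > l

    def test_series_matches_direct_form_at_crossover(self):
        below, above = langevin_function(0.99e-4), langevin_function(1.01e-4)
        assert above - below == pytest.approx(0.02e-4 / 3, rel=1e-4)

    def test_known_value(self):
        assert langevin_function(1.0) == pytest.approx(0.3130, abs=5e-5)


class TestLangevinFit:
    @pytest.mark.parametrize("b", [0.5, 1.0, 2.0, 5.0])
    def test_parameter_recovery_on_exact_data(self, b):
        grid = np.logspace(-1, 2, 12)
        fit = fit_langevin_master(grid, langevin_function(b * grid))
        assert fit.b == pytest.approx(b, rel=1e-3)
        assert fit.r_squared > 1 - 1e-10

    def test_agrees_with_brute_force_grid_search(self):
        """Refined log-grid scan of the loss lands on the same optimum."""
        rng = np.random.default_rng(0)
        grid = np.logspace(-1, 2, 15)
        y = langevin_function(1.7 * grid) + 0.01 * rng.standard_normal(15)
        y = np.clip(y, 0, 1)
        fit = fit_langevin_master(grid, y)

        bs = np.logspace(-3, 3, 200)
        for _ in range(3):
            losses = [np.sum((y - langevin_function(b * grid)) ** 2) for b in bs]
            best = bs[int(np.argmin(losses))]
            bs = np.logspace(np.log10(best / 3), np.log10(best * 3), 200)
        assert fit.b == pytest.approx(best, rel=0.01)

    def test_r_squared_definition_on_worked_example(self):
        a = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        y = np.array([0.10, 0.35, 0.55, 0.80, 0.93])
        fit = fit_langevin_master(a, y)
        ss_res = np.sum((y - langevin_function(fit.b * a)) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot, abs=1e-14)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_langevin_master(np.array([1.0, 2.0]), np.array([0.1, 0.2]))
        with pytest.raises(ValueError, match="flat"):
            fit_langevin_master(np.ones(6), np.full(6, 0.5))

    def test_summary_mentions_estimate(self):
        grid = np.logspace(-1, 2, 8)
        fit = fit_langevin_master(grid, langevin_function(grid), harmonic=3)
        assert "R^2" in fit.summary() and "l=3" in fit.summary()


class TestSensitivity:
    def test_steepest_log_slope_matches_numerical_oracle(self):
        """On exact L(bA) data the optimum is x*/b, with x* located
        independently as the zero of the numerically differentiated
        log-slope (the maximum itself is too flat to compare argmaxes)."""
        from scipy.optimize import brentq

        h = 1e-4

        def log_slope(x):
            return (langevin_function(x * np.exp(h)) -
                    langevin_function(x * np.exp(-h))) / (2 * h)

        def slope_diff(x):  # d/dx of the log-slope, central difference
            return (log_slope(x + 1e-2) - log_slope(x - 1e-2)) / 2e-2

        x_star = brentq(slope_diff, 0.5, 10.0, xtol=1e-9)
        # grid deep into saturation so normalizing by the maximum is a no-op
        grid = np.logspace(-2, 9, 400)
        for b in (0.5, 2.0):
            s = sensitivity_curve(_exact_sweep(b, grid))
            assert s.a_star_log == pytest.approx(x_star / b, rel=1e-3)

    def test_doubling_b_halves_a_star(self):
        grid = np.logspace(-2, 9, 100)
        s1 = sensitivity_curve(_exact_sweep(1.0, grid))
        s2 = sensitivity_curve(_exact_sweep(2.0, grid))
        assert s2.a_star_log == pytest.approx(s1.a_star_log / 2, rel=1e-6)

    def test_linear_axis_slope_peaks_at_low_a(self):
        grid = np.logspace(-1, 2, 50)
        s = sensitivity_curve(_exact_sweep(1.0, grid))
        assert s.a_star_linear == grid[0]

    def test_undersampled_grid_rejected(self):
        with pytest.raises(ValueError, match="coarse"):
            sensitivity_curve(_exact_sweep(1.0, np.logspace(-1, 2, 8)))

    def test_simulated_third_harmonic_optimum_is_tens(self, fig_sweep):
        """Best a3 sensitivity sits at A of order tens for typical particles."""
        s = sensitivity_curve(fig_sweep, harmonic=3)
        assert 5.0 < s.a_star_log < 250.0


class TestCollapse:
    def test_sweep_compared_with_itself_is_exact(self):
        sweep = _exact_sweep(1.0, np.logspace(-1, 2, 20))
        c = collapse_test(sweep, sweep)
        assert c.max_abs_deviation == 0.0
        assert c.rms_deviation == 0.0

    def test_disjoint_ranges_rejected(self):
        s1 = _exact_sweep(1.0, np.logspace(-1, 0, 6))
        s2 = _exact_sweep(1.0, np.logspace(1, 2, 6))
        with pytest.raises(ValueError, match="disjoint"):
            collapse_test(s1, s2)

    def test_noise_free_sweeps_collapse_to_machine_precision(self):
        """Without noise the dynamics are A-only: xi0-swept and Omega-swept
        spectra coincide on the same grid."""
        grid = np.logspace(0, 1.5, 6)
        cfg = lambda: SimulationConfig(  # noqa: E731
            n_particles=32, seed=9, noise_enabled=False,
            n_periods_transient=6, n_periods_analysis=1,
        )
        s1 = sweep_dimensionless(grid, 1.0, cfg(), harmonics=(3,))
        s2 = sweep_dimensionless(grid, 2.0, cfg(), harmonics=(3,))
        c = collapse_test(s1, s2)
        assert c.max_abs_deviation < 1e-6

    def test_collapse_error_shrinks_with_unitless_frequency(self):
        """At fixed xi0/Omega, the (xi0,Omega) vs (2xi0,2Omega) trace deviation
        decreases as Omega grows — the collapse-validity trend."""
        def rms_dev(omega):
            a = simulate_dimensionless(
                6 * omega, omega, SimulationConfig(n_particles=10_000, seed=41)
            )
            b = simulate_dimensionless(
                12 * omega, 2 * omega, SimulationConfig(n_particles=10_000, seed=42)
            )
            return np.sqrt(np.mean((a.mz_mean - b.mz_mean) ** 2))

        devs = [rms_dev(om) for om in (0.5, 1.0, 2.0)]
        assert devs[0] > devs[1] > devs[2]


class TestSweep:
    def test_single_point_sweep_is_composition(self):
        """One grid point reduces to simulate + harmonic_spectrum."""
        grid = np.array([5.0])
        cfg = SimulationConfig(n_particles=300, seed=8, n_periods_transient=3)
        sw = sweep_dimensionless(grid, 1.0, cfg)

        master = np.random.default_rng(8)
        point_seed = int(master.integers(2**31, size=1)[0])
        cfg_pt = SimulationConfig(n_particles=300, seed=point_seed,
                                  n_periods_transient=3)
        tr = simulate_dimensionless(5.0, 1.0, cfg_pt)
        sp = harmonic_spectrum(tr, l_max=11)
        assert sw.harmonics[3][0] == pytest.approx(sp[3], rel=1e-12)

    def test_normalized_third_harmonic_is_sigmoidal(self, fig_sweep):
        """a3 rises monotonically (within MC noise) from ~0 toward saturation."""
        norm = fig_sweep.normalized(3)
        se = fig_sweep.normalized_se(3)
        tol = 4 * np.sqrt(se[1:] ** 2 + se[:-1] ** 2)
        assert np.all(np.diff(norm) > -tol)
        assert norm[0] < 0.02  # linear response: harmonics vanish at low A
        assert norm[-1] == pytest.approx(1.0, abs=1e-12) or norm.max() == 1.0

    def test_infeasible_step_rule_names_the_point(self):
        grid = np.logspace(0, 1, 3)
        cfg = SimulationConfig(n_particles=16, seed=1, dt_star=0.5)
        with pytest.raises(ValueError, match="A="):
            sweep_dimensionless(grid, 1.0, cfg)

    def test_physical_sweep_records_provenance_and_exact_a(self):
        grid = np.logspace(0, 1, 3)
        spec, env = ParticleSpec(), Environment()
        cfg = SimulationConfig(n_particles=200, seed=2, n_periods_transient=2,
                               n_periods_analysis=1)
        from msbsim import sweep_master_variable

        sw = sweep_master_variable(grid, vary="f", spec=spec, env=env,
                                   field=DriveField(amplitude=5e-3, frequency=1000.0),
                                   config=cfg, harmonics=(3,))
        assert sw.provenance == "f"
        assert np.allclose(sw.a, grid, rtol=1e-9)
        df = sw.to_frame()
        assert list(df.columns[:3]) == ["A", "xi0_mean", "Omega_mean"]
        assert "a3" in df.columns and "a3_se" in df.columns


class TestTemperatureSuite:
    def test_single_temperature_has_zero_deviation(self):
        rep = temperature_invariance_suite(
            a_values=(2.0,), t_grid=np.array([300.0]),
            n_particles=100, seed=0,
        )
        assert rep["max_pairwise_deviation"].iloc[0] == 0.0

    def test_different_master_variables_are_distinct(self):
        """A and 4A produce clearly different mean dynamics (>> MC error)."""
        cfg1 = SimulationConfig(n_particles=2000, seed=14)
        cfg2 = SimulationConfig(n_particles=2000, seed=15)
        a = simulate_dimensionless(2 * 3.0, 3.0, cfg1)
        b = simulate_dimensionless(8 * 3.0, 3.0, cfg2)
        d = np.abs(a.mz_mean - b.mz_mean)
        pooled = np.sqrt(a.mz_sem**2 + b.mz_sem**2)
        assert (d / pooled).max() > 10
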