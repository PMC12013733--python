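import numpy as np
import pytest

from vo2fit import (
    BreathSeries,
    InsufficientDataError,
    UnitError,
    alactic_energy,
    fit_model,
    integral_report,
    model_volume,
    trapezoid_volume,
)
from vo2fit.fitting import FitBounds, FitResult
from vo2fit.models import BiParams, MonoParams, curve_integral, eval_bi


def _fake_fit(params, unit_mode="absolute", body_mass=None):
    model = "mono" if isinstance(params, MonoParams) else "bi"
    return FitResult(
        params=params, model=model, baseline_fixed=True, rss=1.0, n=100,
        k=3 if model == "mono" else 5, converged=True, n_iterations=10,
        bounds=FitBounds({"td": (0, 30)}), unit_mode=unit_mode,
        body_mass_kg=body_mass,
    )


class TestTrapezoidVolume:
    def test_constant_rectangle(self):
        t = np.linspace(0, 300, 31)
        s = BreathSeries(t=t, vo2=np.full(31, 384.4))
        assert trapezoid_volume(s, 0, 300) == pytest.approx(1.922, abs=1e-3)

    def test_linear_ramp_triangle(self):
        t = np.linspace(0, 600, 61)
        s = BreathSeries(t=t, vo2=2.0 * t)  # 0 -> 1200 mL/min
        assert trapezoid_volume(s, 0, 600) == pytest.approx(6.0)

    def test_dense_bi_exponential_matches_closed_form(self, truth):
        t = np.arange(0.0, 900.0001, 0.25)
        s = BreathSeries(t=t, vo2=eval_bi(truth, t))
        assert trapezoid_volume(s, 0, 900) == pytest.approx(
            curve_integral(truth, 0, 900), rel=1e-3
        )

    def test_edge_interpolation(self):
        # constant 600 mL/min sampled away from the window edges
        t = np.array([0.0, 90.0, 210.0, 400.0])
        s = BreathSeries(t=t, vo2=np.full(4, 600.0))
        assert trapezoid_volume(s, 100.0, 300.0) == pytest.approx(600.0 * 200 / 60000)

    def test_relative_without_mass_raises(self):
        t = np.linspace(0, 300, 31)
        s = BreathSeries(t=t, vo2=np.full(31, 40.0), unit_mode="relative")
        with pytest.raises(UnitError):
            trapezoid_volume(s, 0, 300)

    def test_window_beyond_data_raises(self):
        t = np.linspace(0, 300, 31)
        s = BreathSeries(t=t, vo2=np.full(31, 400.0))
        with pytest.raises(InsufficientDataError):
            trapezoid_volume(s, 400.0, 500.0)

    def test_interior_window_with_sparse_samples(self):
        # both edges interpolated; constant signal integrates exactly
        t = np.linspace(0, 300, 31)
        s = BreathSeries(t=t, vo2=np.full(31, 400.0))
        assert trapezoid_volume(s, 290.5, 299.5) == pytest.approx(400.0 * 9 / 60000)


class TestModelVolume:
    def test_analytic_equals_grid_within_0p1_percent(self, truth):
        fit = _fake_fit(truth)
        a = model_volume(fit, 0, 900, "analytic")
        g = model_volume(fit, 0, 900, "grid")
        assert g == pytest.approx(a, rel=1e-3)


class TestAlacticEnergy:
    def test_bi_cohort_mean_arithmetic(self):
        p = BiParams(baseline=384.4, A1=2505.5, td=2.7, tau1=65.3, A2=840.7, tau2=742.9)
        rep = alactic_energy(_fake_fit(p))
        assert rep.o2_fast == pytest.approx(2505.5 * 65.3 / 60000, rel=1e-9)  # 2.727 L
        assert rep.energy_kj == pytest.approx(2.727 * 20.92, abs=0.02)  # ~57.05 kJ
        assert rep.energy_kcal == pytest.approx(rep.energy_kj / 4.184)

    def test_mono_cohort_mean_arithmetic(self):
        p = MonoParams(baseline=384.4, A=2760.6, td=3.69, tau=162.3)
        rep = alactic_energy(_fake_fit(p))
        assert rep.o2_fast == pytest.approx(7.467, abs=1e-3)

    def test_zero_amplitude_gives_zero_energy(self):
        p = BiParams(baseline=400, A1=0.0, td=0, tau1=60, A2=500, tau2=600)
        rep = alactic_energy(_fake_fit(p))
        assert rep.energy_kj == 0.0 and rep.energy_kcal == 0.0

    def test_fast_phase_volume_equals_fast_component_integral(self, truth):
        """A1·tau1 equals the integral of the fast component alone from the
        delay onward (numerically, to the quadrature tolerance)."""
        fast_only = BiParams(baseline=0.0, A1=truth.A1, td=truth.td,
                             tau1=truth.tau1, A2=0.0, tau2=truth.tau2)
        vol = curve_integral(fast_only, truth.td, truth.td + 200 * truth.tau1)
        assert vol == pytest.approx(truth.A1 * truth.tau1 / 60000, rel=1e-9)

    def test_unit_round_trip_relative_vs_absolute(self, grid_series):
        """The same physiology expressed in mL/kg/min with a body mass yields
        the identical energy report as the absolute series."""
        mass = 70.0
        fr_abs = fit_model(grid_series, "bi", 390.0)
        rel = BreathSeries(t=grid_series.t, vo2=grid_series.vo2 / mass,
                           unit_mode="relative", body_mass_kg=mass)
        fr_rel = fit_model(rel, "bi", 390.0 / mass)
        rep_abs = alactic_energy(fr_abs)
        rep_rel = alactic_energy(fr_rel)
        assert rep_rel.o2_fast == pytest.approx(rep_abs.o2_fast, rel=1e-3)
        assert rep_rel.energy_kj == pytest.approx(rep_abs.energy_kj, rel=1e-3)


class TestIntegralReport:
    def test_fifteen_exceeds_five_minutes(self, noisy_series):
        fr = fit_model(noisy_series, "bi", 390.0)
        rep = integral_report(noisy_series, fr)
        assert rep.real_15min >= rep.real_5min >= 0
        assert rep.model_15min >= rep.model_5min >= 0
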