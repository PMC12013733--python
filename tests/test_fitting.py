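import numpy as np
import pytest

from vo2fit import (
    BiExponentialRegressor,
    BreathSeries,
    ConfigError,
    DegenerateSeriesError,
    MonoExponentialRegressor,
    SimSpec,
    baseline_sweep,
    default_bounds,
    fit_model,
    initial_guess,
    simulate_series,
)
from vo2fit.models import eval_mono, eval_params


class TestDefaultBounds:
    def test_amplitude_ceiling_scales_with_peak(self):
        t = np.arange(20.0)
        s = BreathSeries(t=t, vo2=np.full(20, 3200.0))
        fb = default_bounds("mono", "absolute", s)
        assert fb["A"][1] == 8000.0  # max(8000, 1.5*3200)
        s_hi = s.replace(vo2=np.full(20, 7000.0))
        assert default_bounds("mono", "absolute", s_hi)["A"][1] == 10500.0

    def test_relative_mode_amplitude_ceiling(self):
        fb = default_bounds("bi", "relative")
        assert fb["A1"][1] == 100.0
        assert fb["A2"][1] == 100.0

    def test_override_passthrough_and_validation(self):
        fb = default_bounds("bi", "absolute", overrides={"tau2": (120.0, 1000.0)})
        assert fb["tau2"] == (120.0, 1000.0)
        with pytest.raises(ConfigError):
            default_bounds("bi", "absolute", overrides={"tau2": (500.0, 100.0)})
        with pytest.raises(ConfigError):
            default_bounds("bi", "absolute", overrides={"nope": (0.0, 1.0)})

    def test_phase_ordering_is_structural(self):
        fb = default_bounds("bi", "absolute")
        assert fb["tau1"][1] <= fb["tau2"][0]


class TestInitialGuess:
    def test_mono_amplitude_is_peak_minus_baseline(self, noisy_series):
        s = BreathSeries(t=np.arange(200.0), vo2=np.full(200, 3145.0))
        s.vo2[0] = 3145.0
        g = initial_guess("mono", s, 384.4)
        assert g["A"] == pytest.approx(2760.6)

    def test_bi_split_75_25(self):
        s = BreathSeries(t=np.arange(200.0), vo2=np.full(200, 3145.0))
        g = initial_guess("bi", s, 384.4)
        assert g["A1"] == pytest.approx(2070.45)
        assert g["A2"] == pytest.approx(690.15)

    def test_degenerate_when_baseline_exceeds_peak(self):
        s = BreathSeries(t=np.arange(200.0), vo2=np.full(200, 3000.0))
        with pytest.raises(DegenerateSeriesError):
            initial_guess("mono", s, 3200.0)


class TestRecovery:
    def test_noiseless_grid_recovery_to_1e4(self, grid_series, truth):
        """On a noiseless 1-s grid (samples before the delay pin td) the
        bi-exponential fit recovers every free parameter to 1e-4 relative."""
        fr = fit_model(grid_series, "bi", truth.baseline)
        for name in ("A1", "td", "tau1", "A2", "tau2"):
            got, want = getattr(fr.params, name), getattr(truth, name)
            assert got == pytest.approx(want, rel=1e-4), name

    def test_noiseless_mono_recovery(self):
        from vo2fit.models import MonoParams

        p = MonoParams(baseline=400.0, A=2600.0, td=4.0, tau=150.0)
        t = np.arange(0.0, 901.0)
        s = BreathSeries(t=t, vo2=eval_mono(p, t))
        fr = fit_model(s, "mono", 400.0)
        for name in ("A", "td", "tau"):
            assert getattr(fr.params, name) == pytest.approx(getattr(p, name), rel=1e-4)

    def test_determinism_bit_identical(self, noisy_series):
        a = fit_model(noisy_series, "bi", 390.0)
        b = fit_model(noisy_series, "bi", 390.0)
        assert a.params == b.params
        assert a.rss == b.rss and a.n_iterations == b.n_iterations

    def test_fixed_baseline_never_worse_than_free_for_tau1(self):
        """Fixing the baseline at its true value does not increase tau1
        estimation RMSE versus letting the optimizer calibrate it."""
        err_fixed, err_free = [], []
        for seed in range(30):
            s, tr = simulate_series(SimSpec(seed=seed))
            tau1 = tr["params"]["tau1"]
            err_fixed.append(fit_model(s, "bi", 390.0).params.tau1 - tau1)
            err_free.append(fit_model(s, "bi", "free").params.tau1 - tau1)
        rmse = lambda e: float(np.sqrt(np.mean(np.square(e))))
        assert rmse(err_fixed) <= rmse(err_free)

    def test_all_equal_series_is_degenerate(self):
        s = BreathSeries(t=np.arange(200.0), vo2=np.full(200, 500.0))
        with pytest.raises(DegenerateSeriesError):
            fit_model(s, "mono", 390.0)

    def test_short_series_refused(self):
        from vo2fit import InsufficientDataError

        s = BreathSeries(t=np.arange(0, 60, 2.0), vo2=np.linspace(3000, 2000, 30))
        with pytest.raises(InsufficientDataError):
            fit_model(s, "mono", 390.0)


class TestNestingAndOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 7, 19])
    def test_bi_rss_never_exceeds_mono(self, seed):
        s, _ = simulate_series(SimSpec(seed=seed))
        mono = fit_model(s, "mono", 390.0)
        bi = fit_model(s, "bi", 390.0)
        assert bi.rss <= mono.rss * (1 + 1e-6)

    def test_fitted_rss_beats_coarse_parameter_grid(self):
        """The optimizer result is at least as good as the best of ~10^4
        grid points spanning the mono bounds on a small fixture."""
        s, _ = simulate_series(SimSpec(seed=4, duration_s=600.0))
        assert len(s) <= 320
        fr = fit_model(s, "mono", 390.0)
        A = np.linspace(0.0, 8000.0, 22)
        td = np.linspace(0.0, 30.0, 21)
        tau = np.linspace(10.0, 600.0, 22)
        best = np.inf
        for a in A:
            base = 390.0 + a * np.exp(
                -np.maximum(s.t[None, :] - td[:, None], 0.0)[None, :, :]
                / tau[:, None, None]
            )
            rss = np.sum((base - s.vo2) ** 2, axis=-1)
            best = min(best, float(rss.min()))
        assert fr.rss <= best


class TestSklearnApi:
    def test_estimator_fit_predict_score(self, grid_series):
        X = grid_series.t.reshape(-1, 1)
        est = BiExponentialRegressor(baseline=390.0).fit(X, grid_series.vo2)
        assert est.score(X, grid_series.vo2) > 0.999999
        np.testing.assert_allclose(
            est.predict(X), eval_params(est.params_, grid_series.t), rtol=1e-12
        )

    def test_get_set_params_clone(self):
        from sklearn.base import clone

        est = MonoExponentialRegressor(baseline=400.0, multistart=True)
        est2 = clone(est)
        assert est2.get_params()["baseline"] == 400.0
        est2.set_params(baseline=None)
        assert est2.baseline is None

    def test_free_parameter_count(self, grid_series):
        X = grid_series.t.reshape(-1, 1)
        fixed = BiExponentialRegressor(baseline=390.0).fit(X, grid_series.vo2)
        free = BiExponentialRegressor(baseline=None).fit(X, grid_series.vo2)
        assert fixed.k_ == 5 and free.k_ == 6


class TestBaselineSweep:
    def test_sweep_shape_and_fixed_baselines(self, noisy_series):
        values = [300.0, 450.0, 600.0, 750.0]
        tab = baseline_sweep(noisy_series, "mono", values)
        assert list(tab["baseline"]) == values
        assert tab["ok"].all()
        for col in ("tau", "r2", "aicc", "alactic_kj", "model_integral_300s_l",
                    "model_integral_900s_l"):
            assert col in tab.columns
        # the fixed baseline must be echoed in the fitted parameters
        np.testing.assert_allclose(tab["baseline"], values)

    def test_empty_sweep_rejected(self, noisy_series):
        with pytest.raises(ConfigError):
            baseline_sweep(noisy_series, "mono", [])
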