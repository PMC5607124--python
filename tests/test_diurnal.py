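import numpy as np
import pandas as pd
import pytest

from sessionfatigue import diurnal
from sessionfatigue.diurnal import (
    BIN_MIDS,
    N_BINS,
    BinnedDaySeries,
    HarmonicModel,
    bin_day,
    design_matrix,
    fit_day_model,
    oos_rmse,
    select_model,
    waic_from_draws,
)


def sessions_frame(times, accuracies=None, lengths=None):
    n = len(times)
    return pd.DataFrame(
        {
            "user_id": [f"u{i}" for i in range(n)],
            "session_id": [f"s{i}" for i in range(n)],
            "start_local_time": times,
            "n_trials": lengths if lengths is not None else [50] * n,
            "n_test_trials": [40] * n,
            "duration_minutes": [15.0] * n,
            "mean_accuracy": accuracies if accuracies is not None else [0.8] * n,
        }
    )


class TestBinning:
    def test_half_open_bin_assignment(self):
        series = bin_day(sessions_frame([0.25, 0.75]), "login_fraction")
        assert series.weights[0] == 1 and series.weights[1] == 1
        assert series.weights[2:].sum() == 0

    def test_login_fraction_normalized(self):
        series = bin_day(sessions_frame([13.1] * 10), "login_fraction")
        b = int(13.1 / 0.5)
        assert series.values[b] == pytest.approx(1.0)
        assert np.nansum(series.values) == pytest.approx(1.0)

    def test_bin_mean_accuracy(self):
        series = bin_day(
            sessions_frame([10.1, 10.2], accuracies=[0.4, 0.6]), "session_accuracy"
        )
        b = int(10.1 / 0.5)
        assert series.values[b] == pytest.approx(0.5)
        assert series.weights[b] == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bin_day(sessions_frame([]), "session_accuracy")

    def test_value_missing_where_weight_zero(self):
        series = bin_day(sessions_frame([5.1]), "session_length")
        assert np.isnan(series.values[0])
        assert series.weights[0] == 0


class TestFitting:
    def test_noise_free_first_harmonic_interpolation(self):
        t = BIN_MIDS
        y = 0.8 + 0.1 * np.sin(2 * np.pi * t / 24)
        s = BinnedDaySeries("session_accuracy", y, np.ones(N_BINS))
        model, _ = fit_day_model(s, "harmonic:1", inference="weighted_least_squares")
        assert model.coef == pytest.approx([0.8, 0.1, 0.0], abs=1e-8)

    def test_constant_series_intercept_is_weighted_mean(self):
        y = np.concatenate([np.full(24, 0.4), np.full(24, 0.8)])
        w = np.concatenate([np.full(24, 1), np.full(24, 3)])
        s = BinnedDaySeries("session_accuracy", y, w)
        model, _ = fit_day_model(s, "intercept", inference="weighted_least_squares")
        assert model.coef[0] == pytest.approx(np.average(y, weights=w))

    def test_phase_shift_equivariance(self):
        """Shifting a noise-free series by delta hours shifts the fitted
        phase by delta and nothing else."""
        delta = 3.0
        t = BIN_MIDS
        for shift in (0.0, delta):
            y = 0.5 + 0.2 * np.cos(2 * np.pi * (t - 14.0 - shift) / 24)
            s = BinnedDaySeries("session_accuracy", y, np.ones(N_BINS))
            model, _ = fit_day_model(s, "harmonic:1", inference="weighted_least_squares")
            h = model.to_harmonic()
            phase = np.degrees(np.arctan2(h.a[0], h.c[0])) / 15.0  # hours
            if shift == 0.0:
                base = phase
        assert (phase - base) % 24 == pytest.approx(delta, abs=1e-8)

    def test_bayesian_posterior_mean_close_to_wls(self, rng):
        t = BIN_MIDS
        y = 0.8 + 0.05 * np.sin(2 * np.pi * t / 24) + 0.01 * rng.standard_normal(N_BINS)
        s = BinnedDaySeries("session_accuracy", y, np.full(N_BINS, 30))
        wls, _ = fit_day_model(s, "harmonic:1", inference="weighted_least_squares")
        bay, rep = fit_day_model(s, "harmonic:1", inference="bayesian", seed=1)
        assert bay.coef == pytest.approx(wls.coef, abs=2e-3)
        assert rep.p_waic >= 0
        assert rep.waic == pytest.approx(-2 * (rep.lppd - rep.p_waic))

    def test_lppd_non_decreasing_in_harmonic_order(self, rng):
        t = BIN_MIDS
        y = 0.8 + 0.05 * np.sin(2 * np.pi * t / 24) + 0.01 * rng.standard_normal(N_BINS)
        s = BinnedDaySeries("session_accuracy", y, np.full(N_BINS, 30))
        lppds = []
        for k in (0, 1, 2, 3):
            _, rep = fit_day_model(s, f"harmonic:{k}", seed=k)
            lppds.append(rep.lppd)
        # nested models gain pointwise fit; sampling noise allowed at 0.1
        assert all(b >= a - 0.1 for a, b in zip(lppds, lppds[1:]))

    def test_too_few_bins_rejected(self):
        y = np.full(N_BINS, np.nan)
        w = np.zeros(N_BINS, dtype=int)
        y[:5], w[:5] = 0.8, 1
        s = BinnedDaySeries("session_accuracy", y, w)
        with pytest.raises(ValueError, match="non-missing bins"):
            fit_day_model(s, "harmonic:2")

    def test_rank_deficiency_detected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(diurnal.RankDeficientDesignError):
            diurnal._check_design(X, "quadratic")


class TestWaic:
    def test_constant_draws_degenerate_waic(self):
        """If every posterior draw gives the same log-density c at a single
        point, then lppd = c, p_waic = 0 and WAIC = -2c."""
        y = np.array([0.3])
        X = np.ones((1, 1))
        w = np.ones(1)
        draws = np.tile([0.1, 2.0], (50, 1))  # same (beta, sigma) everywhere
        lppd, p_waic, waic = waic_from_draws(y, X, w, draws)
        from scipy.stats import norm

        c = norm.logpdf(0.3, loc=0.1, scale=2.0)
        assert lppd == pytest.approx(c, abs=1e-12)
        assert p_waic == pytest.approx(0.0, abs=1e-12)
        assert waic == pytest.approx(-2 * c, abs=1e-12)

    def test_select_model_margin_rule(self):
        tab = pd.DataFrame(
            {"model": ["harmonic:1", "harmonic:2"], "waic": [-100.0, -95.0]}
        )
        tab["delta_waic"] = tab["waic"] - tab["waic"].min()
        assert select_model(tab) == "harmonic:1"
        tab2 = tab.copy()
        tab2.loc[1, "waic"] = -99.0
        tab2["delta_waic"] = tab2["waic"] - tab2["waic"].min()
        assert select_model(tab2) == "indistinguishable"


class TestRmse:
    def test_constant_model_on_two_points(self):
        y = np.full(N_BINS, np.nan)
        w = np.zeros(N_BINS, dtype=int)
        y[0], y[1] = 0.4, 0.6
        w[0], w[1] = 1, 1
        s = BinnedDaySeries("session_accuracy", y, w)
        frozen = diurnal.DayModel("intercept", np.array([0.5]))
        assert oos_rmse(frozen, s) == pytest.approx(0.1)

    def test_in_sample_consistency(self, rng):
        t = BIN_MIDS
        y = 0.7 + 0.03 * np.cos(2 * np.pi * t / 24) + 0.005 * rng.standard_normal(N_BINS)
        s = BinnedDaySeries("session_accuracy", y, np.full(N_BINS, 10))
        model, rep = fit_day_model(s, "harmonic:1", inference="weighted_least_squares")
        assert oos_rmse(model, s) == pytest.approx(rep.rmse, abs=1e-12)


def test_harmonic_model_periodicity():
    h = HarmonicModel(b0=0.5, a=(0.1, 0.02), c=(-0.05, 0.0))
    t = np.linspace(0, 24, 97)
    assert h.predict(t) == pytest.approx(h.predict(t + 24.0))
    assert h.order == 2
    assert h.amplitude(1) == pytest.approx(np.hypot(0.1, -0.05))


def test_design_matrix_shapes():
    t = np.array([0.0, 6.0, 12.0])
    assert design_matrix(t, "intercept").shape == (3, 1)
    assert design_matrix(t, "linear").shape == (3, 2)
    assert design_matrix(t, "harmonic:3").shape == (3, 7)
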