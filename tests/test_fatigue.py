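import pandas as pd
import pytest

from sessionfatigue import fatigue, io as sio, synth
from sessionfatigue.fatigue import (
    FatigueFit,
    aic,
    compare_fits,
    fit_fatigue,
    quadratic_summary,
    smooth_sessions,
)


def session_frame(correctness, events=None, seconds_per_trial=20.0):
    """Build a one-session record frame; events defaults to all 'test'."""
    n = len(correctness)
    events = events or ["test"] * n
    rows = []
    t0 = pd.Timestamp("2015-09-14T10:00:00Z")
    for i, (ev, corr) in enumerate(zip(events, correctness)):
        rows.append(
            {
                "user_id": "u1",
                "session_id": "s1",
                "trial_index": i + 1,
                "event_type": ev,
                "timestamp_utc": t0 + pd.Timedelta(seconds=i * seconds_per_trial),
                "utc_offset_hours": pd.NA,
                "correct": pd.NA if ev == "learn" else bool(corr),
                "elapsed_seconds": i * seconds_per_trial,
            }
        )
    df = pd.DataFrame(rows)
    df["correct"] = df["correct"].astype("boolean")
    return df


class TestSmoothing:
    def test_twelve_trials_two_bins_trailing_dropped(self):
        rec = session_frame([1, 1, 1, 0, 0, 1, 0, 1, 1, 1, 0, 1])
        out, skipped = smooth_sessions(rec)
        assert skipped == 0
        assert out["accuracy"].tolist() == [0.6, 0.8]
        assert out["n_in_bin"].tolist() == [5, 5]
        assert out["axis_value"].tolist() == [3.0, 8.0]

    def test_learn_only_session_skipped(self):
        rec = session_frame([None] * 4, events=["learn"] * 4)
        out, skipped = smooth_sessions(rec)
        assert len(out) == 0
        assert skipped == 1

    def test_learn_interleaving_preserves_bins_but_shifts_axis(self):
        """Inserting learn trials never changes bin membership or accuracy;
        the trial-order axis keeps the gaps the removed trials leave."""
        base = [1, 1, 0, 1, 0, 1, 1, 1, 0, 0]
        plain = session_frame(base)
        events = ["test"] * 3 + ["learn", "learn"] + ["test"] * 7
        correct = base[:3] + [None, None] + base[3:]
        gapped = session_frame(correct, events=events)
        a, _ = smooth_sessions(plain)
        b, _ = smooth_sessions(gapped)
        assert a["accuracy"].tolist() == b["accuracy"].tolist()
        assert a["n_in_bin"].tolist() == b["n_in_bin"].tolist()
        # gaps preserved: second bin's mean trial index moves by 2
        assert b["axis_value"].iloc[1] == a["axis_value"].iloc[1] + 2

    def test_elapsed_time_axis_in_minutes(self):
        rec = session_frame([1] * 5 + [0] * 5, seconds_per_trial=60.0)
        out, _ = smooth_sessions(rec, axis="elapsed_time")
        # trials 1..5 start at minutes 0..4; 6..10 at 5..9
        assert out["axis_value"].tolist() == [2.0, 7.0]
        assert out["axis"].unique().tolist() == ["elapsed_time"]


def polynomial_series(beta, n_users=5, bins_per_user=12):
    """Noise-free smoothed series whose accuracy is an exact polynomial."""
    rows = []
    for u in range(n_users):
        for b in range(bins_per_user):
            x = 3.0 + 5.0 * b
            y = beta[0] + beta[1] * x + beta[2] * x**2
            rows.append(
                {
                    "user_id": f"u{u}",
                    "session_id": f"u{u}-s1",
                    "bin_index": b + 1,
                    "axis": "trial_order",
                    "axis_value": x,
                    "accuracy": y,
                    "n_in_bin": 5,
                }
            )
    return pd.DataFrame(rows)


class TestFitting:
    def test_noise_free_constant_linear_fit(self):
        series = polynomial_series((0.7, 0.0, 0.0))
        fit = fit_fatigue(series, "linear")
        assert fit.converged
        assert fit.params["beta0"] == pytest.approx(0.7, abs=1e-8)
        assert abs(fit.params["beta1"]) < 1e-6

    def test_noise_free_quadratic_recovery(self):
        beta = (0.82, 1.2e-3, -7.5e-6)
        fit = fit_fatigue(polynomial_series(beta), "quadratic")
        assert fit.converged
        assert fit.params["beta0"] == pytest.approx(beta[0], abs=1e-8)
        assert fit.params["beta1"] == pytest.approx(beta[1], abs=1e-8)
        assert fit.params["beta2"] == pytest.approx(beta[2], abs=1e-8)

    def test_too_few_groups_rejected(self):
        series = polynomial_series((0.8, 0, 0), n_users=1)
        with pytest.raises(ValueError, match="2 groups"):
            fit_fatigue(series, "linear")

    def test_axes_agree_on_curvature_sign(self):
        """With constant seconds per trial, trial-order and elapsed-time
        fits see the same (rescaled) quadratic and agree on its sign."""
        cfg = synth.GeneratorConfig(
            n_users=80,
            sessions_per_user_mean=5,
            sessions_per_user_sd=2,
            session_length_base=90,
            session_length_shape=4,
            learn_fraction=0.25,
            fatigue_curve=(0.8, 1.333e-3, -8.889e-6),
            seconds_per_trial_sd=0.0,
            seed=21,
        )
        records, _ = synth.generate_log(cfg)
        for axis in ("trial_order", "elapsed_time"):
            series, _ = smooth_sessions(records, axis=axis)
            fit = fit_fatigue(series, "quadratic")
            assert fit.converged
            assert fit.params["beta2"] < 0, axis


class TestComparison:
    def test_winner_with_margin(self):
        fits = [
            FatigueFit(form="null", axis="trial_order", grouping="user",
                       aic=310.0, converged=True),
            FatigueFit(form="linear", axis="trial_order", grouping="user",
                       aic=306.0, converged=True),
            FatigueFit(form="quadratic", axis="trial_order", grouping="user",
                       aic=300.0, converged=True),
        ]
        sel = compare_fits(fits)
        assert sel.winner == "quadratic"
        assert sel.margin == pytest.approx(6.0)

    def test_indistinguishable_below_margin(self):
        fits = [
            FatigueFit(form="linear", axis="trial_order", grouping="user",
                       aic=300.0, converged=True),
            FatigueFit(form="quadratic", axis="trial_order", grouping="user",
                       aic=299.0, converged=True),
        ]
        assert compare_fits(fits).winner == "indistinguishable"

    def test_aic_formula(self):
        assert aic(-100.0, 3) == 206.0

    def test_requires_two_converged_fits(self):
        fits = [
            FatigueFit(form="linear", axis="trial_order", grouping="user",
                       aic=300.0, converged=True),
            FatigueFit(form="quadratic", axis="trial_order", grouping="user",
                       aic=200.0, converged=False),
        ]
        with pytest.raises(ValueError, match="converged"):
            compare_fits(fits)


class TestQuadraticSummary:
    def quad_fit(self, beta):
        return FatigueFit(
            form="quadratic",
            axis="trial_order",
            grouping="user",
            params={"beta0": beta[0], "beta1": beta[1], "beta2": beta[2]},
            converged=True,
        )

    def test_vertex_formula(self):
        fit = self.quad_fit((0.8, 0.002, -1e-5))
        vertex, _ = quadratic_summary(fit, horizon=200)
        assert vertex == pytest.approx(100.0)

    def test_drop_by_direct_evaluation(self):
        beta = (0.8, 0.002, -1.333e-5)
        fit = self.quad_fit(beta)
        vertex, drop = quadratic_summary(fit, horizon=150)
        # independent evaluation of the fitted curve at vertex and horizon
        def curve(x):
            return beta[0] + beta[1] * x + beta[2] * x**2

        v = -beta[1] / (2 * beta[2])
        assert drop == pytest.approx(curve(v) - curve(150.0), abs=1e-12)
        assert drop == pytest.approx(0.075, abs=5e-4)

    def test_positive_curvature_rejected(self):
        fit = self.quad_fit((0.8, 0.002, 1e-6))
        with pytest.raises(ValueError, match="no interior maximum"):
            quadratic_summary(fit, horizon=150)

    def test_non_quadratic_rejected(self):
        lin = FatigueFit(form="linear", axis="trial_order", grouping="user",
                         params={"beta0": 0.8, "beta1": 0.001}, converged=True)
        with pytest.raises(ValueError, match="quadratic"):
            quadratic_summary(lin, horizon=150)
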