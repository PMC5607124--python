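import numpy as np
import pandas as pd
import pytest

from sessionfatigue import fatigue, io as sio, moderation, synth
from sessionfatigue.moderation import (
    ModerationReport,
    extract_session_coefs,
    moderate_by_time,
    moderation_battery,
)


def synthetic_coefs(rng, n=500, amplitude=0.0, peak_hour=14.0, noise_sd=0.02):
    """Coefficient tables straight from a known truth (no model fitting)."""
    t = rng.uniform(0, 24, n)
    base = 0.8 + amplitude * np.cos(2 * np.pi * (t - peak_hour) / 24)
    return pd.DataFrame(
        {
            "user_id": [f"u{i % 50}" for i in range(n)],
            "session_id": [f"s{i}" for i in range(n)],
            "start_local_time": t,
            "intercept": base + noise_sd * rng.standard_normal(n),
            "linear": 1e-3 + 1e-4 * rng.standard_normal(n),
            "quadratic": -8e-6 + 1e-6 * rng.standard_normal(n),
        }
    )


@pytest.fixture(scope="module")
def zero_variance_coefs():
    cfg = synth.GeneratorConfig(
        n_users=40,
        sessions_per_user_mean=6,
        sessions_per_user_sd=2,
        session_length_base=80,
        fatigue_curve=(0.8, 1.333e-3, -8.889e-6),
        user_intercept_sd=0.0,
        user_slope_sd=0.0,
        learn_fraction=0.25,
        seed=11,
    )
    records, _ = synth.generate_log(cfg)
    sessions = sio.summarize_sessions(sio.localize_times(records, "none"))
    series, _ = fatigue.smooth_sessions(records)
    return extract_session_coefs(series, sessions)


class TestExtraction:
    def test_zero_variance_collapses_to_fixed_effects(self, zero_variance_coefs):
        coefs = zero_variance_coefs
        for col in ("intercept", "linear", "quadratic"):
            dev = (coefs[col] - coefs[col].mean()).abs().max()
            assert dev < 1e-6, col

    def test_one_row_per_session_with_local_time(self, zero_variance_coefs):
        coefs = zero_variance_coefs
        assert coefs[["user_id", "session_id"]].duplicated().sum() == 0
        assert ((coefs["start_local_time"] >= 0) & (coefs["start_local_time"] < 24)).all()

    def test_user_intercept_variance_recovered(self):
        """Between-session spread of extracted intercepts reflects the
        generator's user-level intercept SD of 0.05."""
        cfg = synth.GeneratorConfig(
            n_users=120,
            sessions_per_user_mean=6,
            sessions_per_user_sd=2,
            session_length_base=80,
            fatigue_curve=(0.8, 1.333e-3, -8.889e-6),
            user_intercept_sd=0.05,
            learn_fraction=0.25,
            seed=12,
        )
        records, _ = synth.generate_log(cfg)
        sessions = sio.summarize_sessions(sio.localize_times(records, "none"))
        series, _ = fatigue.smooth_sessions(records)
        coefs = extract_session_coefs(series, sessions)
        assert len(coefs) > 500
        assert 0.03 <= float(coefs["intercept"].std()) <= 0.07

    def test_determinism(self, zero_variance_coefs):
        cfg = synth.GeneratorConfig(
            n_users=40,
            sessions_per_user_mean=6,
            sessions_per_user_sd=2,
            session_length_base=80,
            fatigue_curve=(0.8, 1.333e-3, -8.889e-6),
            learn_fraction=0.25,
            seed=11,
        )
        records, _ = synth.generate_log(cfg)
        sessions = sio.summarize_sessions(sio.localize_times(records, "none"))
        series, _ = fatigue.smooth_sessions(records)
        again = extract_session_coefs(series, sessions)
        pd.testing.assert_frame_equal(zero_variance_coefs, again)


class TestModeration:
    def test_threshold_rule_p_009_not_significant(self):
        rep = ModerationReport(
            component="intercept",
            n=100,
            pvalues={"sin": 0.009, "cos": 0.5},
            alpha=0.008,
        )
        assert rep.verdicts == {"sin": False, "cos": False}
        rep2 = ModerationReport(
            component="intercept",
            n=100,
            pvalues={"sin": 0.0079, "cos": 0.5},
            alpha=0.008,
        )
        assert rep2.verdicts["sin"] is True

    def test_power_against_true_modulation(self, rng):
        """An amplitude-0.02 first-harmonic modulation of the intercept is
        detected at alpha = .008 in nearly all replicates at n = 5000."""
        hits = 0
        for _ in range(20):
            coefs = synthetic_coefs(rng, n=5000, amplitude=0.02, noise_sd=0.2)
            rep = moderate_by_time(coefs, "intercept")
            hits += rep.f_pvalue < 0.008
        assert hits >= 16

    def test_amplitude_recovery(self, rng):
        coefs = synthetic_coefs(rng, n=8000, amplitude=0.03, noise_sd=0.05)
        rep = moderate_by_time(coefs, "intercept")
        assert rep.amplitude == pytest.approx(0.03, abs=0.005)

    def test_degenerate_time_spread_rejected(self, rng):
        coefs = synthetic_coefs(rng, n=100)
        coefs["start_local_time"] = 12.0
        with pytest.raises(ValueError, match="degenerate time spread"):
            moderate_by_time(coefs, "intercept")

    def test_too_few_sessions_rejected(self, rng):
        coefs = synthetic_coefs(rng, n=20)
        with pytest.raises(ValueError, match="at least 50"):
            moderate_by_time(coefs, "intercept")

    def test_battery_layout(self, rng):
        coefs = synthetic_coefs(rng, n=300)
        tab = moderation_battery(coefs)
        assert len(tab) == 6
        assert set(tab["component"]) == {"intercept", "linear", "quadratic"}
        assert set(tab["term"]) == {"sin", "cos"}
        assert (tab["alpha"] == 0.008).all()

    def test_cluster_robust_option_runs(self, rng):
        coefs = synthetic_coefs(rng, n=300)
        rep = moderate_by_time(coefs, "linear", cluster_by_user=True)
        assert np.isfinite(rep.pvalues["sin"])
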