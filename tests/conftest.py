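import numpy as np
import pytest

from sessionfatigue import synth


@pytest.fixture(scope="session")
def small_log():
    """A small synthetic cohort shared by read-only tests."""
    cfg = synth.GeneratorConfig(
        n_users=25,
        sessions_per_user_mean=5.0,
        sessions_per_user_sd=2.0,
        session_length_base=50.0,
        learn_fraction=0.3,
        fatigue_curve=(0.8, 1.0e-3, -8.0e-6),
        user_intercept_sd=0.05,
        seed=42,
    )
    records, truth = synth.generate_log(cfg)
    return records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_flat_series(value=0.8, weight=10):
    """Constant binned day series helper."""
    from sessionfatigue.diurnal import BinnedDaySeries, N_BINS

    return BinnedDaySeries(
        "session_accuracy",
        np.full(N_BINS, float(value)),
        np.full(N_BINS, int(weight)),
    )
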