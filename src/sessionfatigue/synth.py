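"""Synthetic session-log generator with fully exposed ground truth.

Emulates the statistical structure of naturalistic learning-session logs:
over-dispersed per-user session counts, heavy-tailed session lengths, mixed
learn/test trials, a quadratic within-session fatigue curve on the accuracy
scale, an early-session difficulty handicap, a small additive diurnal
accuracy modulation, diurnal login intensity with a late-evening peak,
user-level random intercepts/slopes, and integer UTC offsets per user.

Every latent draw (user effects, session start bins, session-level diurnal
terms) is recorded in a :class:`TruthRecord`, so downstream fitting stages
can be validated by parameter recovery rather than against proprietary
data.

Accuracy is modelled on the probability scale with additive components and
then clamped to [0.01, 0.99] before Bernoulli sampling, because the
downstream models are linear in accuracy; recovery targets therefore live
on the same scale the fits report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import numpy as np
import pandas as pd

from .diurnal import BIN_MIDS, BIN_WIDTH, N_BINS, HarmonicModel

#: fixed calendar anchor for generated timestamps (start of a study term)
EPOCH = pd.Timestamp("2015-09-14T00:00:00Z")

#: e-folding scale (in test trials) of the early-session difficulty handicap
DIFFICULTY_TAU = 3.0

#: the handicap is applied to roughly the first 10 test trials
DIFFICULTY_SPAN = 10


class GeneratorConfigError(ValueError):
    """Raised when a generator configuration is infeasible."""


def harmonic_from_peak(
    amplitude: float, peak_hour: float, intercept: float = 0.0, k: int = 1
) -> HarmonicModel:
    """A single-harmonic curve ``intercept + amplitude*cos(2*pi*k*(t-peak)/24)``."""
    w = 2.0 * np.pi * k * peak_hour / 24.0
    a = [0.0] * k
    c = [0.0] * k
    a[k - 1] = amplitude * np.sin(w)
    c[k - 1] = amplitude * np.cos(w)
    return HarmonicModel(b0=intercept, a=tuple(a), c=tuple(c))


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic session-log generator.

    ``fatigue_curve`` is (beta0, beta1, beta2) on the accuracy-versus-trial-
    order scale; ``difficulty_gradient`` is the additive accuracy handicap
    applied to the first few test trials, decaying with e-folding scale
    :data:`DIFFICULTY_TAU`; harmonic models modulate login intensity
    (unnormalized, floored at zero), session length (multiplicative) and
    session-level accuracy (additive).
    """

    n_users: int = 200
    study_days: int = 119  # 17 weeks
    login_density: HarmonicModel = field(
        default_factory=lambda: HarmonicModel(b0=1.0)
    )
    sessions_per_user_mean: float = 6.0
    sessions_per_user_sd: float = 4.0
    session_length_base: float = 60.0
    session_length_shape: float = 2.0  # gamma shape of the NB mixture
    session_length_diurnal: HarmonicModel = field(
        default_factory=lambda: HarmonicModel(b0=1.0)
    )
    learn_fraction: float = 0.3
    fatigue_curve: tuple[float, float, float] = (0.8, 0.0, 0.0)
    difficulty_gradient: float = 0.0
    accuracy_diurnal: HarmonicModel = field(
        default_factory=lambda: HarmonicModel(b0=0.0)
    )
    user_intercept_sd: float = 0.0
    user_slope_sd: float = 0.0
    seconds_per_trial_mean: float = 17.2
    seconds_per_trial_sd: float = 5.0
    utc_offset_choices: tuple[tuple[int, float], ...] = ((-8, 0.4), (-5, 0.6))
    seed: int = 0

    def validate(self) -> None:
        if self.n_users < 1:
            raise GeneratorConfigError("n_users must be positive")
        if self.study_days < 1:
            raise GeneratorConfigError("study_days must be positive")
        if self.sessions_per_user_mean <= 0:
            raise GeneratorConfigError("sessions_per_user_mean must be positive")
        if self.sessions_per_user_sd < 0:
            raise GeneratorConfigError("sessions_per_user_sd must be non-negative")
        if self.session_length_base <= 0:
            raise GeneratorConfigError("session_length_base must be positive")
        if self.session_length_shape <= 0:
            raise GeneratorConfigError("session_length_shape must be positive")
        if not (0.0 <= self.learn_fraction <= 1.0):
            raise GeneratorConfigError("learn_fraction must lie in [0, 1]")
        if self.user_intercept_sd < 0 or self.user_slope_sd < 0:
            raise GeneratorConfigError("random-effect sds must be non-negative")
        if self.seconds_per_trial_mean <= 0:
            raise GeneratorConfigError("seconds_per_trial_mean must be positive")
        if not self.utc_offset_choices:
            raise GeneratorConfigError("utc_offset_choices must be non-empty")
        if any(w < 0 for _, w in self.utc_offset_choices):
            raise GeneratorConfigError("offset weights must be non-negative")
        if sum(w for _, w in self.utc_offset_choices) <= 0:
            raise GeneratorConfigError("offset weights must not all be zero")
        if np.all(self.login_probabilities() == 0):
            raise GeneratorConfigError("login_density is zero everywhere")

    def login_probabilities(self) -> np.ndarray:
        """48-bin start-time probabilities: intensity floored at 0, normalized."""
        intensity = np.maximum(self.login_density.predict(BIN_MIDS), 0.0)
        total = intensity.sum()
        return intensity / total if total > 0 else intensity


@dataclass
class TruthRecord:
    """Every latent quantity sampled during generation, plus the config."""

    config: GeneratorConfig
    users: pd.DataFrame  # user_id, utc_offset_hours, n_sessions, intercept_dev, slope_dev
    sessions: pd.DataFrame  # session_id, user_id, day, start_bin, start_local_hour,
    #                         n_trials, n_test_trials, diurnal_term
    login_probabilities: np.ndarray = field(default_factory=lambda: np.zeros(N_BINS))


def _overdispersed_counts(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Integer counts with the requested mean/sd (negative binomial when
    over-dispersed, Poisson otherwise), clipped to >= 1."""
    var = sd**2
    if var > mean:
        r = mean**2 / (var - mean)
        p = r / (r + mean)
        draws = rng.negative_binomial(r, p, size=size)
    else:
        draws = rng.poisson(mean, size=size)
    return np.maximum(draws, 1)


def generate_log(config: GeneratorConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate a session log and its ground truth; deterministic given seed.

    All sampling draws from a single :class:`numpy.random.Generator` keyed
    by ``config.seed`` in a fixed order (users, then sessions in user
    order, then trials in session order), so logs are bit-reproducible.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    probs = config.login_probabilities()
    offsets = np.array([o for o, _ in config.utc_offset_choices])
    ow = np.array([w for _, w in config.utc_offset_choices], dtype=float)
    ow = ow / ow.sum()

    n_u = config.n_users
    width = len(str(n_u))
    user_ids = [f"u{idx:0{width}d}" for idx in range(1, n_u + 1)]
    user_offsets = rng.choice(offsets, size=n_u, p=ow)
    n_sessions = _overdispersed_counts(
        rng, config.sessions_per_user_mean, config.sessions_per_user_sd, n_u
    )
    intercept_dev = (
        rng.normal(0.0, config.user_intercept_sd, size=n_u)
        if config.user_intercept_sd > 0
        else np.zeros(n_u)
    )
    slope_dev = (
        rng.normal(0.0, config.user_slope_sd, size=n_u)
        if config.user_slope_sd > 0
        else np.zeros(n_u)
    )

    b0, b1, b2 = config.fatigue_curve
    epoch_ns = EPOCH.value
    col_user, col_sess = [], []
    col_idx, col_learn, col_stamp, col_off, col_corr, col_elapsed = [], [], [], [], [], []
    sess_rows = []
    for ui, uid in enumerate(user_ids):
        for s in range(int(n_sessions[ui])):
            sid = f"{uid}-s{s + 1:03d}"
            day = int(rng.integers(config.study_days))
            start_bin = int(rng.choice(N_BINS, p=probs))
            start_local = start_bin * BIN_WIDTH + float(rng.uniform(0.0, BIN_WIDTH))
            modulation = max(
                float(config.session_length_diurnal.predict(start_local)), 0.1
            )
            lam = config.session_length_base * modulation
            # gamma-Poisson mixture: heavy-tailed lengths with mean lam
            g = rng.gamma(config.session_length_shape, lam / config.session_length_shape)
            n_trials = max(int(rng.poisson(g)), 1)

            is_learn = rng.random(n_trials) < config.learn_fraction
            n_test = int(np.sum(~is_learn))
            trial_idx = np.arange(1, n_trials + 1)
            diurnal_term = float(config.accuracy_diurnal.predict(start_local))

            p = (
                b0
                + b1 * trial_idx
                + b2 * trial_idx.astype(float) ** 2
                + diurnal_term
                + intercept_dev[ui]
                + slope_dev[ui] * trial_idx
            )
            if config.difficulty_gradient != 0.0 and n_test > 0:
                test_order = np.cumsum(~is_learn)  # 1-based among test trials
                handicap = np.where(
                    (~is_learn) & (test_order <= DIFFICULTY_SPAN),
                    config.difficulty_gradient
                    * np.exp(-(test_order - 1) / DIFFICULTY_TAU),
                    0.0,
                )
                p = p - handicap
            p = np.clip(p, 0.01, 0.99)
            correct = rng.random(n_trials) < p

            secs = rng.normal(
                config.seconds_per_trial_mean,
                config.seconds_per_trial_sd,
                size=n_trials,
            )
            secs = np.maximum(secs, 0.5)
            elapsed = np.round(np.concatenate(([0.0], np.cumsum(secs[:-1]))), 3)

            start_ns = (
                epoch_ns
                + day * 86_400_000_000_000
                + int(start_local * 3.6e12) // 1_000_000_000 * 1_000_000_000
                - int(user_offsets[ui]) * 3_600_000_000_000
            )
            stamp_ns = start_ns + np.floor(elapsed).astype(np.int64) * 1_000_000_000

            col_user.append(np.full(n_trials, uid, dtype=object))
            col_sess.append(np.full(n_trials, sid, dtype=object))
            col_idx.append(trial_idx)
            col_learn.append(is_learn)
            col_stamp.append(stamp_ns)
            col_off.append(np.full(n_trials, int(user_offsets[ui]), dtype=np.int64))
            col_corr.append(correct)
            col_elapsed.append(elapsed)
            sess_rows.append(
                {
                    "session_id": sid,
                    "user_id": uid,
                    "day": day,
                    "start_bin": start_bin,
                    "start_local_hour": start_local,
                    "n_trials": n_trials,
                    "n_test_trials": n_test,
                    "diurnal_term": diurnal_term,
                }
            )

    is_learn_all = np.concatenate(col_learn)
    correct_all = pd.array(np.concatenate(col_corr), dtype="boolean")
    correct_all[is_learn_all] = pd.NA
    records = pd.DataFrame(
        {
            "user_id": np.concatenate(col_user),
            "session_id": np.concatenate(col_sess),
            "trial_index": np.concatenate(col_idx).astype(np.int64),
            "event_type": np.where(is_learn_all, "learn", "test"),
            "timestamp_utc": pd.to_datetime(np.concatenate(col_stamp), utc=True),
            "utc_offset_hours": pd.array(np.concatenate(col_off), dtype="Int64"),
            "correct": correct_all,
            "elapsed_seconds": np.concatenate(col_elapsed),
        }
    )
    records = records.sort_values(
        ["user_id", "session_id", "trial_index"], kind="mergesort"
    ).reset_index(drop=True)

    users = pd.DataFrame(
        {
            "user_id": user_ids,
            "utc_offset_hours": user_offsets.astype(int),
            "n_sessions": n_sessions.astype(int),
            "intercept_dev": intercept_dev,
            "slope_dev": slope_dev,
        }
    )
    truth = TruthRecord(
        config=config,
        users=users,
        sessions=pd.DataFrame(sess_rows),
        login_probabilities=probs,
    )
    return records, truth


def expected_session_length(config: GeneratorConfig) -> float:
    """Analytic expectation of trials per session under the config
    (marginalized over the start-time distribution; truncation at one trial
    is ignored, a negligible correction at realistic lengths)."""
    probs = config.login_probabilities()
    # expectation of the diurnal modulation given a uniform start within a bin
    fine = np.linspace(0.0, 24.0, 4801)[:-1]
    mod = np.maximum(config.session_length_diurnal.predict(fine + 0.0025), 0.1)
    per_bin = mod.reshape(N_BINS, -1).mean(axis=1)
    return float(config.session_length_base * np.sum(probs * per_bin))


def fatigue_vertex(config: GeneratorConfig) -> float:
    """Trial index -beta1/(2*beta2) at which the latent fatigue curve peaks."""
    _, b1, b2 = config.fatigue_curve
    if b2 >= 0:
        raise ValueError("fatigue curve has no interior maximum (beta2 >= 0)")
    return -b1 / (2.0 * b2)


def fatigue_drop(config: GeneratorConfig, horizon: float) -> float:
    """Latent accuracy drop from the curve's peak to ``horizon`` trials."""
    b0, b1, b2 = config.fatigue_curve
    v = fatigue_vertex(config)
    peak = b0 + b1 * v + b2 * v**2
    return float(peak - (b0 + b1 * horizon + b2 * horizon**2))


def _cohort_login_density() -> HarmonicModel:
    """Login intensity with a morning rise, steady day, late-evening peak
    and deep night trough (floored at zero before normalization)."""
    h1 = harmonic_from_peak(1.0, 20.5, k=1)
    h2 = harmonic_from_peak(0.30, 21.0, k=2)
    h3 = harmonic_from_peak(0.15, 21.0, k=3)
    return HarmonicModel(
        b0=1.0,
        a=(h1.a[0], h2.a[1], h3.a[2]),
        c=(h1.c[0], h2.c[1], h3.c[2]),
    )


def make_cohort_preset(n_users: int = 300, seed: int = 0) -> GeneratorConfig:
    """A documented preset emulating the second study cohort's descriptives.

    Session counts are over-dispersed with mean 16.81 / SD 15.71; expected
    session length is ~58.6 trials at ~17.2 s per trial (~16.8 min); the
    fatigue curve peaks at trial 75 with a 5% latent drop by trial 150; the
    diurnal accuracy modulation has a ~1% peak-to-trough range peaking near
    14:00; login intensity peaks late in the evening; session length is
    ~15% longer around 21:00.  ``n_users`` defaults to a desk-scale cohort;
    the real cohorts were one to two orders of magnitude larger.
    """
    drop, vertex, horizon = 0.05, 75.0, 150.0
    b2 = -drop / (horizon - vertex) ** 2
    b1 = -2.0 * b2 * vertex
    base = GeneratorConfig(
        n_users=n_users,
        study_days=119,
        login_density=_cohort_login_density(),
        sessions_per_user_mean=16.81,
        sessions_per_user_sd=15.71,
        session_length_base=58.63,
        session_length_shape=2.0,
        session_length_diurnal=harmonic_from_peak(0.15, 21.0, intercept=1.0),
        learn_fraction=0.3,
        fatigue_curve=(0.80, b1, b2),
        difficulty_gradient=0.08,
        accuracy_diurnal=harmonic_from_peak(0.005, 14.0),
        user_intercept_sd=0.06,
        user_slope_sd=1e-4,
        seconds_per_trial_mean=17.2,
        seconds_per_trial_sd=5.0,
        utc_offset_choices=((-9, 0.05), (-8, 0.35), (-7, 0.10), (-6, 0.20), (-5, 0.30)),
        seed=seed,
    )
    # rescale so the analytic expected length matches the target despite the
    # diurnal modulation interacting with the start-time distribution
    target = 58.63
    scale = target / expected_session_length(base)
    from dataclasses import replace

    return replace(base, session_length_base=base.session_length_base * scale)


def make_recovery_config(n_users: int = 500, seed: int = 0) -> GeneratorConfig:
    """Preset for fatigue-curve parameter recovery: same latent quadratic
    as the cohort preset (vertex 75, 5% drop by trial 150) but with the
    difficulty handicap and diurnal modulation switched off, so the latent
    curve is exactly the quadratic being recovered, and with longer
    sessions so bins cover the region around the vertex."""
    drop, vertex, horizon = 0.05, 75.0, 150.0
    b2 = -drop / (horizon - vertex) ** 2
    b1 = -2.0 * b2 * vertex
    return GeneratorConfig(
        n_users=n_users,
        study_days=119,
        sessions_per_user_mean=6.0,
        sessions_per_user_sd=3.0,
        session_length_base=90.0,
        session_length_shape=4.0,
        learn_fraction=0.25,
        fatigue_curve=(0.80, b1, b2),
        difficulty_gradient=0.0,
        user_intercept_sd=0.05,
        user_slope_sd=1e-4,
        seconds_per_trial_mean=17.2,
        seconds_per_trial_sd=5.0,
        utc_offset_choices=((-8, 0.4), (-5, 0.6)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Config / truth serialization (plain text sidecars)
# ---------------------------------------------------------------------------

def _harmonic_to_dict(h: HarmonicModel) -> dict:
    return {"b0": h.b0, "a": list(h.a), "c": list(h.c)}


def _harmonic_from_dict(d: dict) -> HarmonicModel:
    return HarmonicModel(b0=d["b0"], a=tuple(d["a"]), c=tuple(d["c"]))


def config_to_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    for key in ("login_density", "session_length_diurnal", "accuracy_diurnal"):
        d[key] = _harmonic_to_dict(getattr(config, key))
    d["fatigue_curve"] = list(config.fatigue_curve)
    d["utc_offset_choices"] = [list(x) for x in config.utc_offset_choices]
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    kw = dict(d)
    for key in ("login_density", "session_length_diurnal", "accuracy_diurnal"):
        if key in kw and isinstance(kw[key], dict):
            kw[key] = _harmonic_from_dict(kw[key])
    if "fatigue_curve" in kw:
        kw["fatigue_curve"] = tuple(kw["fatigue_curve"])
    if "utc_offset_choices" in kw:
        kw["utc_offset_choices"] = tuple(
            (int(o), float(w)) for o, w in kw["utc_offset_choices"]
        )
    return GeneratorConfig(**kw)


def write_truth(truth: TruthRecord, path) -> None:
    """Write the truth record as a JSON sidecar next to a generated log."""
    import json

    payload = {
        "config": config_to_dict(truth.config),
        "login_probabilities": truth.login_probabilities.tolist(),
        "users": truth.users.to_dict(orient="records"),
        "sessions": truth.sessions.to_dict(orient="records"),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
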