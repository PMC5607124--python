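"""Moderation of within-session fatigue by time of day.

A multilevel quadratic model grouped by session yields an intercept,
linear and quadratic coefficient realization for every session (empirical
Bayes: fixed effect plus the session's predicted deviation).  Each of the
three components is then regressed on first-harmonic time-of-day terms
``sin(2*pi*t/24)`` and ``cos(2*pi*t/24)``; with two terms per component the
battery comprises six tests, so the critical p-value is lowered to .008
(~ .05 / 6, Bonferroni logic) to control the family-wise error rate.

This analysis is exploratory in spirit: regressions are unweighted by
default, with an optional cluster-robust (by user) covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .fatigue import AXIS_SCALE, _fixed_design

COMPONENTS = ("intercept", "linear", "quadratic")
DEFAULT_ALPHA = 0.008


class ModerationConvergenceError(RuntimeError):
    """Raised when the session-grouped quadratic model does not converge.

    The caller should fall back to the user-grouped fatigue model (which
    cannot provide per-session coefficients) and report the moderation
    analysis as unavailable rather than substituting silently.
    """


def extract_session_coefs(
    series: pd.DataFrame,
    sessions: pd.DataFrame,
    min_bins: int = 2,
) -> pd.DataFrame:
    """Per-session fatigue-curve coefficients from a session-grouped fit.

    ``series`` is the smoothed accuracy table (axis ``trial_order``) from
    :func:`sessionfatigue.fatigue.smooth_sessions`; ``sessions`` the
    localized session summaries supplying ``start_local_time``.  The model
    is accuracy ~ quadratic(axis) with random intercept, linear and
    quadratic deviations per session; per-session coefficients are the
    fixed effects plus the session's empirical-Bayes deviations.

    Sessions contributing fewer than ``min_bins`` bins are excluded.
    """
    df = series.copy()
    df["_group"] = df["user_id"].astype(str) + "::" + df["session_id"].astype(str)
    sizes = df.groupby("_group").size()
    df = df[df["_group"].map(sizes) >= min_bins]
    if df["_group"].nunique() < 2:
        raise ValueError("need at least 2 sessions with enough bins")

    y = df["accuracy"].to_numpy(dtype=float)
    x_s = df["axis_value"].to_numpy(dtype=float) / AXIS_SCALE
    X = _fixed_design(x_s, "quadratic")
    exog_re = X  # random intercept + linear + quadratic per session
    model = sm.MixedLM(y, X, groups=df["_group"].to_numpy(), exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            # the near-singular 3x3 random-effect covariance defeats
            # gradient-based optimizers here; Powell is slower but reliable
            result = model.fit(reml=False, method=["powell"], maxiter=1000)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise ModerationConvergenceError(
                f"session-grouped quadratic model failed ({exc}); "
                "fall back to the user-grouped fatigue model"
            ) from None
    if not getattr(result, "converged", False):
        raise ModerationConvergenceError(
            "session-grouped quadratic model did not converge; "
            "fall back to the user-grouped fatigue model"
        )

    fe = np.asarray(result.fe_params, dtype=float)
    re = result.random_effects
    rows = []
    lookup = sessions.set_index(["user_id", "session_id"])["start_local_time"]
    for (uid, sid), grp in df.groupby(["user_id", "session_id"], sort=True):
        dev = re[grp["_group"].iloc[0]]
        b0 = fe[0] + float(dev.iloc[0])
        b1 = (fe[1] + float(dev.iloc[1])) / AXIS_SCALE
        b2 = (fe[2] + float(dev.iloc[2])) / AXIS_SCALE**2
        rows.append(
            {
                "user_id": uid,
                "session_id": sid,
                "start_local_time": float(lookup.loc[(uid, sid)]),
                "intercept": b0,
                "linear": b1,
                "quadratic": b2,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ModerationReport:
    """One component's first-harmonic time-of-day regression."""

    component: str
    n: int
    estimates: dict = field(default_factory=dict)  # intercept, sin, cos
    bse: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)  # sin, cos (two-sided t)
    f_pvalue: float = np.nan  # joint sin+cos F-test
    alpha: float = DEFAULT_ALPHA
    amplitude: float = np.nan  # sqrt(sin^2 + cos^2) of the fitted modulation

    @property
    def verdicts(self) -> dict:
        """Per-term significance at the corrected threshold; a missing
        p-value (degenerate regression) is never significant."""
        out = {}
        for term in ("sin", "cos"):
            p = self.pvalues.get(term, np.nan)
            out[term] = bool(np.isfinite(p) and p < self.alpha)
        return out


def moderate_by_time(
    coefs: pd.DataFrame,
    component: str,
    alpha: float = DEFAULT_ALPHA,
    cluster_by_user: bool = False,
    min_sessions: int = 50,
) -> ModerationReport:
    """Regress one fatigue component on sin/cos of session start time."""
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}; expected one of {COMPONENTS}")
    if len(coefs) < min_sessions:
        raise ValueError(f"need at least {min_sessions} sessions, got {len(coefs)}")
    t = coefs["start_local_time"].to_numpy(dtype=float)
    w = 2.0 * np.pi * t / 24.0
    s, c = np.sin(w), np.cos(w)
    if np.std(s) < 1e-3 or np.std(c) < 1e-3:
        raise ValueError("degenerate time spread: sessions do not cover the day")
    y = coefs[component].to_numpy(dtype=float)
    X = pd.DataFrame({"const": 1.0, "sin": s, "cos": c})
    if cluster_by_user:
        fit = sm.OLS(y, X).fit(
            cov_type="cluster", cov_kwds={"groups": coefs["user_id"].to_numpy()}
        )
    else:
        fit = sm.OLS(y, X).fit()
    est = {k: float(v) for k, v in fit.params.items()}
    # joint test that both harmonic terms are zero
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            f_p = float(fit.f_test("sin = 0, cos = 0").pvalue)
        except Exception:
            f_p = np.nan
    return ModerationReport(
        component=component,
        n=len(coefs),
        estimates=est,
        bse={k: float(v) for k, v in fit.bse.items()},
        pvalues={"sin": float(fit.pvalues["sin"]), "cos": float(fit.pvalues["cos"])},
        f_pvalue=f_p,
        alpha=alpha,
        amplitude=float(np.hypot(est["sin"], est["cos"])),
    )


def moderation_battery(
    coefs: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    cluster_by_user: bool = False,
) -> pd.DataFrame:
    """The full six-test battery: three components x {sin, cos}.

    Returns a tidy table with one row per test: component, term, estimate,
    standard error, two-sided p-value, and the verdict at ``alpha``.
    """
    rows = []
    for comp in COMPONENTS:
        rep = moderate_by_time(coefs, comp, alpha=alpha, cluster_by_user=cluster_by_user)
        for term in ("sin", "cos"):
            rows.append(
                {
                    "component": comp,
                    "term": term,
                    "estimate": rep.estimates[term],
                    "bse": rep.bse[term],
                    "pvalue": rep.pvalues[term],
                    "significant": rep.verdicts[term],
                    "f_pvalue": rep.f_pvalue,
                    "amplitude": rep.amplitude,
                    "alpha": alpha,
                }
            )
    return pd.DataFrame(rows)
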