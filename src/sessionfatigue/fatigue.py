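"""Within-session fatigue analysis.

Learn trials are removed while test trials keep their original within-
session order (gaps preserved), accuracy is averaged over consecutive
groups of five test trials, and the smoothed series is fitted with
multilevel null / linear / quadratic models of trial order or elapsed
time, with a random intercept and linear slope per group.  Models are
compared by AIC (maximum likelihood, not REML) with the usual rule that a
difference of two or more constitutes meaningful support.

The quadratic's vertex ``-beta1/(2*beta2)`` locates the performance peak
and the fixed-effect curve evaluated at the vertex and at a later horizon
gives the fatigue drop.  Because harder items tend to be scheduled early
in a session, these estimates of fatigue are conservative; the analysis
deliberately does not model item difficulty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

BIN_SIZE = 5

#: internal rescaling of the axis for well-conditioned optimization;
#: coefficients are transformed back to the raw axis scale afterwards
AXIS_SCALE = 100.0

FORMS = ("null", "linear", "quadratic")
AXES = ("trial_order", "elapsed_time")
GROUPINGS = ("user", "user_and_session")


def smooth_sessions(
    records: pd.DataFrame,
    axis: str = "trial_order",
    bin_size: int = BIN_SIZE,
    drop_partial: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Smooth test-trial accuracy over consecutive bins of ``bin_size``.

    Learn events are dropped but test events keep their original
    ``trial_index``, so the axis value reflects true session progress
    including the gaps left by removed learn trials.  Trailing partial
    bins are dropped by default to keep bin variance homogeneous.

    Returns
    -------
    (smoothed, n_skipped)
        ``smoothed`` has one row per bin with columns ``user_id``,
        ``session_id``, ``bin_index``, ``axis``, ``axis_value`` (mean trial
        number, or mean minutes from session start), ``accuracy`` and
        ``n_in_bin``; ``n_skipped`` counts sessions without test trials.
    """
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")
    key = ["user_id", "session_id"]
    n_sessions = len(records[key].drop_duplicates())
    test = records[records["event_type"] == "test"].copy()
    n_skipped = n_sessions - len(test[key].drop_duplicates())
    if len(test) == 0:
        empty = pd.DataFrame(
            columns=key + ["bin_index", "axis", "axis_value", "accuracy", "n_in_bin"]
        )
        return empty, n_skipped

    test = test.sort_values(key + ["trial_index"], kind="mergesort")
    test["bin_index"] = test.groupby(key).cumcount() // bin_size + 1
    test["_axis_raw"] = (
        test["trial_index"].astype(float)
        if axis == "trial_order"
        else test["elapsed_seconds"].astype(float) / 60.0
    )
    test["_correct_f"] = test["correct"].astype(float)
    out = (
        test.groupby(key + ["bin_index"], sort=True)
        .agg(
            axis_value=("_axis_raw", "mean"),
            accuracy=("_correct_f", "mean"),
            n_in_bin=("_correct_f", "size"),
        )
        .reset_index()
    )
    if drop_partial:
        out = out[out["n_in_bin"] == bin_size].reset_index(drop=True)
    out.insert(3, "axis", axis)
    return out, n_skipped


@dataclass
class FatigueFit:
    """A fitted multilevel fatigue curve with information criteria."""

    form: str
    axis: str
    grouping: str
    params: dict = field(default_factory=dict)  # beta0/beta1/beta2 on the raw axis
    bse: dict = field(default_factory=dict)
    loglik: float = np.nan
    k_params: int = 0
    aic: float = np.nan
    converged: bool = False
    n_obs: int = 0
    n_groups: int = 0
    message: str = ""
    random_effects: pd.DataFrame | None = None  # per-group BLUPs (scaled back)

    @property
    def beta(self) -> tuple[float, ...]:
        names = ["beta0", "beta1", "beta2"]
        return tuple(self.params[n] for n in names if n in self.params)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, self.params.get("beta0", np.nan))
        if "beta1" in self.params:
            out = out + self.params["beta1"] * x
        if "beta2" in self.params:
            out = out + self.params["beta2"] * x**2
        return out


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion 2k - 2*loglik."""
    return 2.0 * k - 2.0 * loglik


def _fixed_design(x_s: np.ndarray, form: str) -> np.ndarray:
    if form == "null":
        return np.ones((len(x_s), 1))
    if form == "linear":
        return np.column_stack([np.ones_like(x_s), x_s])
    if form == "quadratic":
        return np.column_stack([np.ones_like(x_s), x_s, x_s**2])
    raise ValueError(f"unknown form {form!r}; expected one of {FORMS}")


def _unscale(names: list[str], values: np.ndarray) -> dict:
    # beta_k on the raw axis = scaled coefficient / AXIS_SCALE**k
    out = {}
    for name, v in zip(names, values):
        power = {"beta0": 0, "beta1": 1, "beta2": 2}[name]
        out[name] = float(v) / AXIS_SCALE**power
    return out


def fit_fatigue(
    series: pd.DataFrame,
    form: str,
    axis: str | None = None,
    grouping: str = "user",
) -> FatigueFit:
    """Fit a multilevel model of smoothed accuracy on the session axis.

    The fixed part is the chosen polynomial of ``axis_value``; every group
    (users, or individual sessions under ``user_and_session``) gets a
    random intercept and random linear slope.  No random quadratic term is
    estimated: richer structures routinely fail to converge on data of
    this shape, so the curvature is fixed-effect only.  Estimation is
    maximum likelihood so AIC values are comparable across forms.

    Non-convergence and singular fits are reported honestly via
    ``converged`` / ``message``; there is no silent fallback.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    if axis is None:
        axis = str(series["axis"].iloc[0]) if len(series) else "trial_order"

    df = series.copy()
    if grouping == "user":
        df["_group"] = df["user_id"].astype(str)
    else:
        df["_group"] = df["user_id"].astype(str) + "::" + df["session_id"].astype(str)

    sizes = df.groupby("_group").size()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need at least 2 groups with at least 2 bins each")

    y = df["accuracy"].to_numpy(dtype=float)
    x_s = df["axis_value"].to_numpy(dtype=float) / AXIS_SCALE
    X = _fixed_design(x_s, form)
    names = ["beta0", "beta1", "beta2"][: X.shape[1]]
    n_fe = X.shape[1]
    # random intercept + linear slope: 3 covariance parameters, plus residual
    k = n_fe + 3 + 1

    # Degenerate noise-free limit: when the fixed polynomial interpolates the
    # data exactly, the ML fixed effects equal the least-squares solution and
    # the variance components are indistinguishable from zero; the iterative
    # fit cannot converge there, so return the exact solution directly.
    beta_ls, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted_resid = y - X @ beta_ls
    msr = float(np.mean(fitted_resid**2))
    scale_y = max(float(np.mean(y**2)), 1e-300)
    if msr / scale_y < 1e-18:
        return FatigueFit(
            form=form,
            axis=axis,
            grouping=grouping,
            params=_unscale(names, beta_ls),
            bse={n: 0.0 for n in names},
            loglik=np.inf,
            k_params=k,
            aic=-np.inf,
            converged=True,
            n_obs=len(y),
            n_groups=int(df["_group"].nunique()),
            message="noise-free data: exact least-squares solution, "
            "variance components degenerate at zero",
        )

    exog_re = np.column_stack([np.ones_like(x_s), x_s])
    model = sm.MixedLM(y, X, groups=df["_group"].to_numpy(), exog_re=exog_re)
    converged = True
    message = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            # variance components near zero put the MLE on the boundary,
            # where gradient methods stall; fall through to Powell then
            result = model.fit(
                reml=False, method=["lbfgs", "cg", "powell"], maxiter=500
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            return FatigueFit(
                form=form,
                axis=axis,
                grouping=grouping,
                converged=False,
                n_obs=len(y),
                n_groups=int(df["_group"].nunique()),
                message=f"fit failed: {exc}",
            )
    conv_warnings = [
        str(w.message) for w in caught if issubclass(w.category, ConvergenceWarning)
    ]
    if not getattr(result, "converged", False):
        converged = False
        message = "optimizer did not converge"
    elif conv_warnings:
        message = "; ".join(sorted(set(conv_warnings)))

    params = _unscale(names, result.fe_params)
    bse = _unscale(names, result.bse_fe)
    ll = float(result.llf)

    re_frame = None
    try:
        re_dict = result.random_effects
        re_frame = pd.DataFrame(
            {
                "group": list(re_dict.keys()),
                "intercept_dev": [float(v.iloc[0]) for v in re_dict.values()],
                "slope_dev": [float(v.iloc[1]) / AXIS_SCALE for v in re_dict.values()],
            }
        )
    except Exception:  # pragma: no cover - BLUP extraction is best-effort
        pass

    return FatigueFit(
        form=form,
        axis=axis,
        grouping=grouping,
        params=params,
        bse=bse,
        loglik=ll,
        k_params=k,
        aic=aic(ll, k),
        converged=converged,
        n_obs=len(y),
        n_groups=int(df["_group"].nunique()),
        message=message,
        random_effects=re_frame,
    )


@dataclass
class SelectionReport:
    """Delta-AIC table and winner under the margin-of-2 rule."""

    table: pd.DataFrame
    winner: str
    margin: float


def compare_fits(fits: list[FatigueFit], margin: float = 2.0) -> SelectionReport:
    """Rank converged fits by AIC; name a winner only at margin >= 2."""
    usable = [f for f in fits if f.converged]
    if len(usable) < 2:
        raise ValueError("need at least 2 converged fits to compare")
    axes = {f.axis for f in usable}
    if len(axes) > 1:
        raise ValueError(f"fits mix axes: {sorted(axes)}")
    tab = pd.DataFrame(
        {
            "form": [f.form for f in usable],
            "aic": [f.aic for f in usable],
            "loglik": [f.loglik for f in usable],
            "k": [f.k_params for f in usable],
        }
    ).sort_values("aic", kind="mergesort").reset_index(drop=True)
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    gap = tab["delta_aic"].iloc[1] if len(tab) > 1 else np.inf
    winner = str(tab["form"].iloc[0]) if gap >= margin else "indistinguishable"
    return SelectionReport(table=tab, winner=winner, margin=float(gap))


def quadratic_summary(fit: FatigueFit, horizon: float) -> tuple[float, float]:
    """Peak location and accuracy drop of a fitted quadratic fatigue curve.

    Returns ``(vertex, drop)`` where ``vertex = -beta1/(2*beta2)`` is the
    axis value of maximum accuracy and ``drop`` is the fixed-effect curve
    evaluated at the vertex minus its value at ``horizon``.
    """
    if fit.form != "quadratic":
        raise ValueError("quadratic_summary requires a quadratic fit")
    b2 = fit.params["beta2"]
    if b2 >= 0:
        raise ValueError("no interior maximum: beta2 >= 0")
    b1 = fit.params["beta1"]
    vertex = -b1 / (2.0 * b2)
    drop = float(fit.predict(vertex) - fit.predict(horizon))
    return float(vertex), drop
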