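"""Time-of-day analyses: half-hour binning, harmonic regression, WAIC, RMSE.

Session-level metrics (mean session accuracy, login fraction, mean session
length) are aggregated into 48 half-hour bins over the 24-h day and fitted
with sinusoidal (cosinor) regressions of harmonic order K = 1..5 plus
intercept-only, linear and quadratic baselines.  Model comparison uses the
widely applicable information criterion (WAIC) computed from posterior
draws of a Bayesian weighted normal regression; replication across cohorts
uses out-of-sample RMSE of a frozen model.

The weighted likelihood convention treats each bin mean as ``w`` replicated
observations: ``y_b ~ Normal(mu(t_b), sigma^2 / w_b)``, which coincides
with weighted least squares at the posterior mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

PERIOD_HOURS = 24.0
N_BINS = 48
BIN_WIDTH = PERIOD_HOURS / N_BINS
BIN_STARTS = np.arange(N_BINS) * BIN_WIDTH
BIN_MIDS = BIN_STARTS + BIN_WIDTH / 2.0

METRICS = ("session_accuracy", "login_fraction", "session_length")

#: canonical candidate set used in the cohort analyses
DEFAULT_CANDIDATES = (
    "intercept",
    "linear",
    "quadratic",
    "harmonic:1",
    "harmonic:2",
    "harmonic:3",
    "harmonic:4",
    "harmonic:5",
)


# ---------------------------------------------------------------------------
# Model descriptors and design matrices
# ---------------------------------------------------------------------------

def parse_descriptor(descriptor: str) -> tuple[str, int]:
    """Normalize a model descriptor to ``(family, order)``.

    ``"harmonic:K"`` -> ("harmonic", K); ``"intercept"`` is harmonic order 0;
    ``"linear"``/``"quadratic"`` are polynomials in clock time of degree 1/2.
    """
    if descriptor == "intercept":
        return ("harmonic", 0)
    if descriptor == "linear":
        return ("poly", 1)
    if descriptor == "quadratic":
        return ("poly", 2)
    if descriptor.startswith("harmonic:"):
        k = int(descriptor.split(":", 1)[1])
        if k < 0:
            raise ValueError("harmonic order must be >= 0")
        return ("harmonic", k)
    raise ValueError(f"unknown model descriptor {descriptor!r}")


def design_matrix(t: np.ndarray, descriptor: str) -> np.ndarray:
    """Design matrix at local hours ``t`` for the given descriptor."""
    family, order = parse_descriptor(descriptor)
    t = np.asarray(t, dtype=float)
    cols = [np.ones_like(t)]
    if family == "harmonic":
        for k in range(1, order + 1):
            w = 2.0 * np.pi * k * t / PERIOD_HOURS
            cols.append(np.sin(w))
            cols.append(np.cos(w))
    else:
        for d in range(1, order + 1):
            cols.append(t**d)
    return np.column_stack(cols)


def design_column_names(descriptor: str) -> list[str]:
    family, order = parse_descriptor(descriptor)
    names = ["intercept"]
    if family == "harmonic":
        for k in range(1, order + 1):
            names += [f"sin{k}", f"cos{k}"]
    else:
        for d in range(1, order + 1):
            names.append(f"t^{d}")
    return names


@dataclass
class HarmonicModel:
    """Intercept plus K sine/cosine pairs with a 24-hour period.

    ``a[k-1]`` multiplies ``sin(2*pi*k*t/24)`` and ``c[k-1]`` multiplies
    ``cos(2*pi*k*t/24)``.  Used both as a fitted regression curve and as a
    ground-truth intensity/modulation inside the synthetic generator.
    """

    b0: float
    a: tuple[float, ...] = ()
    c: tuple[float, ...] = ()
    fitted: bool = False

    def __post_init__(self):
        if len(self.a) != len(self.c):
            raise ValueError("sine and cosine coefficient lists must have equal length")
        self.a = tuple(float(x) for x in self.a)
        self.c = tuple(float(x) for x in self.c)

    @property
    def order(self) -> int:
        return len(self.a)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.b0, dtype=float)
        for k in range(1, self.order + 1):
            w = 2.0 * np.pi * k * t / PERIOD_HOURS
            out = out + self.a[k - 1] * np.sin(w) + self.c[k - 1] * np.cos(w)
        return out

    def amplitude(self, k: int = 1) -> float:
        """Peak deviation sqrt(a_k^2 + c_k^2) of harmonic ``k``."""
        return float(np.hypot(self.a[k - 1], self.c[k - 1]))

    def coefficients(self) -> np.ndarray:
        out = [self.b0]
        for ak, ck in zip(self.a, self.c):
            out += [ak, ck]
        return np.asarray(out)


@dataclass
class DayModel:
    """A fitted curve over the 24-h day: harmonic or polynomial baseline."""

    descriptor: str
    coef: np.ndarray
    draws: np.ndarray | None = None  # (S, p+1): coefficients + residual sd
    fitted: bool = True

    def predict(self, t) -> np.ndarray:
        X = design_matrix(np.atleast_1d(t), self.descriptor)
        return X @ self.coef

    def to_harmonic(self) -> HarmonicModel:
        family, order = parse_descriptor(self.descriptor)
        if family != "harmonic":
            raise ValueError(f"{self.descriptor!r} is not a harmonic model")
        return HarmonicModel(
            b0=float(self.coef[0]),
            a=tuple(self.coef[1 : 1 + 2 * order : 2]),
            c=tuple(self.coef[2 : 2 + 2 * order : 2]),
            fitted=self.fitted,
        )


@dataclass
class FitReport:
    """Fit summary for one candidate day-curve model."""

    descriptor: str
    n_obs: int
    loglik: float
    lppd: float | None = None
    p_waic: float | None = None
    waic: float | None = None
    rmse: float | None = None


@dataclass
class BinnedDaySeries:
    """48 half-hour bins of a session metric with per-bin weights.

    ``values`` is NaN where ``weights`` is zero.  For ``login_fraction`` the
    non-missing values sum to 1 (fraction of overall daily activity), which
    makes cohorts of different size directly comparable.
    """

    metric: str
    values: np.ndarray
    weights: np.ndarray
    timezone_mode: str = "none"
    bin_starts: np.ndarray = field(default_factory=lambda: BIN_STARTS.copy())

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights)
        if self.values.shape != (N_BINS,) or self.weights.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    @property
    def bin_mids(self) -> np.ndarray:
        return self.bin_starts + BIN_WIDTH / 2.0

    def observed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(t_mid, value, weight) over bins with positive weight."""
        m = self.weights > 0
        return self.bin_mids[m], self.values[m], self.weights[m].astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_hour": self.bin_starts,
                "value": self.values,
                "weight": self.weights,
            }
        )


def bin_day(
    sessions: pd.DataFrame, metric: str, timezone_mode: str = "none"
) -> BinnedDaySeries:
    """Aggregate session summaries into 48 half-hour bins.

    Sessions are assigned to bins by start time under the half-open
    convention [k*0.5, (k+1)*0.5).  ``session_accuracy`` and
    ``session_length`` take the mean over sessions starting in the bin;
    ``login_fraction`` is the session count divided by the daily total.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if len(sessions) == 0:
        raise ValueError("cannot bin an empty session collection")
    t = np.mod(sessions["start_local_time"].to_numpy(dtype=float), PERIOD_HOURS)
    idx = np.minimum((t / BIN_WIDTH).astype(int), N_BINS - 1)
    counts = np.bincount(idx, minlength=N_BINS)
    values = np.full(N_BINS, np.nan)
    if metric == "login_fraction":
        values = np.where(counts > 0, counts / counts.sum(), np.nan)
    else:
        col = "mean_accuracy" if metric == "session_accuracy" else "n_trials"
        y = sessions[col].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        sums = np.bincount(idx[ok], weights=y[ok], minlength=N_BINS)
        n_ok = np.bincount(idx[ok], minlength=N_BINS)
        with np.errstate(invalid="ignore"):
            values = np.where(n_ok > 0, sums / np.maximum(n_ok, 1), np.nan)
        counts = n_ok
    return BinnedDaySeries(metric, values, counts, timezone_mode)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class RankDeficientDesignError(np.linalg.LinAlgError):
    def __init__(self, descriptor: str, columns: list[str]):
        self.columns = columns
        super().__init__(
            f"rank-deficient design for {descriptor!r}; collinear columns: {columns}"
        )


def _check_design(X: np.ndarray, descriptor: str) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns involved in the deficiency via QR pivoting
        names = design_column_names(descriptor)
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise RankDeficientDesignError(descriptor, bad or names)


def _weighted_loglik(y, mu, w, sigma2) -> float:
    return float(
        np.sum(-0.5 * np.log(2 * np.pi * sigma2 / w) - w * (y - mu) ** 2 / (2 * sigma2))
    )


def fit_day_model(
    series: BinnedDaySeries,
    descriptor: str,
    inference: str = "bayesian",
    n_draws: int = 2000,
    n_burn: int = 200,
    seed: int | np.random.Generator | None = 0,
) -> tuple[DayModel, FitReport]:
    """Fit one candidate curve to a binned day series.

    ``inference="weighted_least_squares"`` gives the classical point fit.
    ``inference="bayesian"`` runs a conjugate Gibbs sampler for the weighted
    normal regression under weakly-informative priors
    (``beta ~ N(0, (10*sd(y))^2)``, ``sigma^2 ~ Scaled-Inv-chi^2(1, sd(y)^2)``)
    and computes lppd, p_waic and WAIC = -2*(lppd - p_waic) from the draws.
    """
    t, y, w = series.observed()
    X = design_matrix(t, descriptor)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} non-missing bins, got {n}")
    _check_design(X, descriptor)

    XtW = X.T * w
    XtWX = XtW @ X
    XtWy = XtW @ y
    beta_wls = np.linalg.solve(XtWX, XtWy)
    resid = y - X @ beta_wls
    sse = float(np.sum(w * resid**2))
    sigma2_hat = sse / max(n - p, 1)

    if inference == "weighted_least_squares":
        model = DayModel(descriptor, beta_wls)
        ll = _weighted_loglik(y, X @ beta_wls, w, max(sigma2_hat, 1e-300))
        rep = FitReport(descriptor, n, ll, rmse=_series_rmse(y, X @ beta_wls, w))
        return model, rep
    if inference != "bayesian":
        raise ValueError(f"unknown inference {inference!r}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd_y = float(np.sqrt(np.average((y - np.average(y, weights=w)) ** 2, weights=w)))
    sd_y = sd_y if sd_y > 0 else 1.0
    tau2 = (10.0 * sd_y) ** 2
    nu0, s02 = 1.0, sd_y**2

    S = n_draws
    draws = np.empty((S, p + 1))
    sigma2 = sigma2_hat if sigma2_hat > 0 else s02
    prior_prec = np.eye(p) / tau2
    for it in range(n_burn + S):
        prec = XtWX / sigma2 + prior_prec
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, XtWy / sigma2)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(L.T, z)
        r = y - X @ beta
        nu = nu0 + n
        ssq = nu0 * s02 + float(np.sum(w * r**2))
        sigma2 = ssq / rng.chisquare(nu)
        if it >= n_burn:
            draws[it - n_burn, :p] = beta
            draws[it - n_burn, p] = np.sqrt(sigma2)

    coef = draws[:, :p].mean(axis=0)
    model = DayModel(descriptor, coef, draws=draws)
    lppd, p_waic, waic = waic_from_draws(y, X, w, draws)
    ll = _weighted_loglik(y, X @ coef, w, float(np.mean(draws[:, p] ** 2)))
    rep = FitReport(
        descriptor,
        n,
        ll,
        lppd=lppd,
        p_waic=p_waic,
        waic=waic,
        rmse=_series_rmse(y, X @ coef, w),
    )
    return model, rep


def pointwise_loglik(
    y: np.ndarray, X: np.ndarray, w: np.ndarray, draws: np.ndarray
) -> np.ndarray:
    """(S, n) matrix of log p(y_i | theta_s) under the weighted normal model."""
    beta = draws[:, :-1]
    sigma = draws[:, -1]
    mu = beta @ X.T  # (S, n)
    var = sigma[:, None] ** 2 / w[None, :]
    return -0.5 * np.log(2 * np.pi * var) - (y[None, :] - mu) ** 2 / (2 * var)


def waic_from_draws(
    y: np.ndarray, X: np.ndarray, w: np.ndarray, draws: np.ndarray
) -> tuple[float, float, float]:
    """Compute (lppd, p_waic, WAIC) from posterior draws.

    lppd_i = log mean_s p(y_i|theta_s); p_waic_i = Var_s log p(y_i|theta_s)
    (sample variance); WAIC = -2 * (lppd - p_waic).
    """
    ll = pointwise_loglik(y, X, w, draws)
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    if S > 1:
        p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    else:
        p_waic = 0.0
    waic = -2.0 * (lppd - p_waic)
    return lppd, p_waic, waic


def _series_rmse(y, pred, w) -> float:
    return float(np.sqrt(np.average((y - pred) ** 2, weights=w)))


def oos_rmse(frozen: DayModel, new_series: BinnedDaySeries) -> float:
    """Weighted RMSE of a frozen model on a fresh series (no refitting)."""
    t, y, w = new_series.observed()
    return _series_rmse(y, frozen.predict(t), w)


# ---------------------------------------------------------------------------
# Model comparison and the two-cohort replication protocol
# ---------------------------------------------------------------------------

def waic_table(reports: Iterable[FitReport]) -> pd.DataFrame:
    """WAIC comparison table sorted best-first with delta to the minimum."""
    rows = [
        {
            "model": r.descriptor,
            "waic": r.waic,
            "lppd": r.lppd,
            "p_waic": r.p_waic,
            "rmse": r.rmse,
        }
        for r in reports
    ]
    df = pd.DataFrame(rows).sort_values("waic").reset_index(drop=True)
    df["delta_waic"] = df["waic"] - df["waic"].min()
    return df


def select_model(table: pd.DataFrame, margin: float = 2.0) -> str:
    """Name the winner when its WAIC margin over the runner-up is >= margin,
    else ``"indistinguishable"``."""
    if len(table) < 2:
        return str(table["model"].iloc[0])
    if table["delta_waic"].iloc[1] >= margin:
        return str(table["model"].iloc[0])
    return "indistinguishable"


@dataclass
class ReplicationReport:
    """Three-stage cohort replication: explore, frozen transfer, refit."""

    metric: str
    stage1_waic: pd.DataFrame
    stage1_winner: str
    stage2_rmse: pd.DataFrame
    stage2_best: str
    stage3_waic: pd.DataFrame
    stage3_winner: str


def replication_protocol(
    sample1_sessions: pd.DataFrame,
    sample2_sessions: pd.DataFrame,
    metric: str,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    seed: int = 0,
    n_draws: int = 2000,
    stage3_timezone_mode: str = "per_user_offset",
) -> ReplicationReport:
    """Run the exploratory / frozen-replication / adjusted-refit pipeline.

    Stage (i) fits every candidate to cohort 1 (uncorrected clock time) and
    ranks by WAIC.  Stage (ii) evaluates each frozen stage-(i) model on
    cohort 2 binned the same way, by out-of-sample RMSE.  Stage (iii)
    refits all candidates to cohort 2 after timezone adjustment.

    ``sample*_sessions`` are session summaries that already carry
    ``start_local_time`` in the appropriate timezone convention: sample 1
    uncorrected; sample 2 must provide both conventions via the columns
    ``start_local_time`` (uncorrected) and, when stage 3 adjusts timezones,
    ``start_local_time_adjusted``.
    """
    rng = np.random.default_rng(seed)
    s1 = bin_day(sample1_sessions, metric, timezone_mode="none")
    fits1: dict[str, DayModel] = {}
    reports1 = []
    for d in candidates:
        m, r = fit_day_model(s1, d, inference="bayesian", n_draws=n_draws, seed=rng)
        fits1[d] = m
        reports1.append(r)
    tab1 = waic_table(reports1)
    winner1 = select_model(tab1)

    s2_direct = bin_day(sample2_sessions, metric, timezone_mode="none")
    rows = [
        {"model": d, "rmse": oos_rmse(fits1[d], s2_direct)} for d in candidates
    ]
    tab2 = pd.DataFrame(rows).sort_values("rmse").reset_index(drop=True)
    best2 = str(tab2["model"].iloc[0])

    if stage3_timezone_mode == "per_user_offset":
        adj = sample2_sessions.copy()
        if "start_local_time_adjusted" not in adj.columns:
            raise ValueError(
                "sample 2 sessions need a start_local_time_adjusted column for stage 3"
            )
        adj["start_local_time"] = adj["start_local_time_adjusted"]
    else:
        adj = sample2_sessions
    s2_adj = bin_day(adj, metric, timezone_mode=stage3_timezone_mode)
    reports3 = []
    for d in candidates:
        _, r = fit_day_model(s2_adj, d, inference="bayesian", n_draws=n_draws, seed=rng)
        reports3.append(r)
    tab3 = waic_table(reports3)
    winner3 = select_model(tab3)

    return ReplicationReport(metric, tab1, winner1, tab2, best2, tab3, winner3)
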