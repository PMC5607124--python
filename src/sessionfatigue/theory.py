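"""Theoretical daily-behavior models and negative log-likelihood scoring.

Three competing accounts of how engagement or ability should vary over the
24-h day are realized as mean +/- SD curves on a standardized [0, 1]
scale:

``limited_sc``
    Self-control drawn from a central finite reservoir: ability peaks
    shortly after waking and declines monotonically until sleep onset,
    with a deep overnight trough.
``unlimited_sc``
    The null account: a flat plateau across waking hours, low only during
    typical sleeping hours.
``evening_preference``
    A flat daytime plateau with a monotone rise after an evening onset
    (daytime obligations push voluntary learning into the evening),
    followed by the overnight trough.

Each curve is a smoothed piecewise-linear function of local hour,
24-h-periodic, with a strictly positive SD ribbon.  Observed data are
scored by the Gaussian negative log-likelihood

    NLL = sum_i [ ln sigma(t_i) + 0.5 ln(2 pi) + (y_i - mu(t_i))^2 / (2 sigma(t_i)^2) ]

where smaller values mean less deviance.  The exact anchor parameters of
the original pre-registered curves are not recoverable, so every anchor
(wake, sleep onset, evening onset, levels, ribbon width) is exposed in
:class:`TheoryParams`; the scoring machinery, not one fixed set of curves,
is the substance of this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diurnal import BinnedDaySeries

THEORY_NAMES = ("limited_sc", "unlimited_sc", "evening_preference")

_GRID = np.linspace(0.0, 24.0, 2401)[:-1]  # 0.01-h resolution
_SMOOTH_SD_HOURS = 0.35


@dataclass(frozen=True)
class TheoryParams:
    """Anchor parameters shared by the three theory curves.

    Levels are on the standardized [0, 1] metric scale.  ``sd_fraction``
    sets the ribbon width as a fraction of the waking plateau level.
    """

    wake_hour: float = 7.0
    sleep_onset_hour: float = 25.0  # 01:00 next day
    evening_onset_hour: float = 18.0
    night_level: float = 0.05
    plateau_level: float = 0.60
    peak_level: float = 1.00
    decline_end_level: float = 0.30  # limited_sc level reached at sleep onset
    sd_fraction: float = 0.15
    transition_hours: float = 1.0

    def validate(self) -> None:
        if self.sleep_onset_hour <= self.wake_hour:
            raise ValueError("sleep onset must come after wake time")
        if self.sd_fraction <= 0:
            raise ValueError("SD ribbon must be strictly positive")
        if not (self.wake_hour < self.evening_onset_hour < self.sleep_onset_hour):
            raise ValueError("evening onset must fall between wake and sleep onset")
        for lv in (
            self.night_level,
            self.plateau_level,
            self.peak_level,
            self.decline_end_level,
        ):
            if lv < 0:
                raise ValueError("levels must be non-negative")


def _circular_smooth(y: np.ndarray) -> np.ndarray:
    """Smooth a 24-h-periodic curve with a circular Gaussian kernel."""
    step = _GRID[1] - _GRID[0]
    half = int(np.ceil(4 * _SMOOTH_SD_HOURS / step))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) * step / _SMOOTH_SD_HOURS) ** 2)
    k /= k.sum()
    ext = np.concatenate([y[-half:], y, y[:half]])
    return np.convolve(ext, k, mode="valid")


def _piecewise(nodes: Sequence[tuple[float, float]]) -> np.ndarray:
    """Piecewise-linear interpolation of (hour, level) nodes on the wrapped
    24-h grid.  Node hours may exceed 24 to express next-day times."""
    hours = np.array([h for h, _ in nodes], dtype=float)
    levels = np.array([lv for _, lv in nodes], dtype=float)
    order = np.argsort(hours)
    hours, levels = hours[order], levels[order]
    # tile one period to the left and right so interpolation wraps cleanly
    h_ext = np.concatenate([hours - 24.0, hours, hours + 24.0])
    l_ext = np.tile(levels, 3)
    return np.interp(_GRID, h_ext, l_ext)


@dataclass
class TheoreticalModel:
    """A named mean +/- SD daily curve usable for NLL deviance scoring."""

    name: str
    metric: str
    params: TheoryParams
    _mu_grid: np.ndarray | None = None
    _sd: float = 0.0

    def mu(self, t) -> np.ndarray:
        t = np.mod(np.asarray(t, dtype=float), 24.0)
        return np.interp(t, _GRID, self._mu_grid, period=24.0)

    def sigma(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.full_like(t, self._sd, dtype=float)

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"hour": _GRID, "mu": self._mu_grid, "sd": self._sd})


def build_theory(name: str, metric: str, params: TheoryParams | None = None) -> TheoreticalModel:
    """Construct one of the three theory curves for a given metric."""
    params = params or TheoryParams()
    params.validate()
    p = params
    w, s = p.wake_hour, p.sleep_onset_hour
    tr = p.transition_hours
    if name == "limited_sc":
        nodes = [
            (w - tr / 2, p.night_level),
            (w + tr / 2, p.peak_level),
            (s, p.decline_end_level),
            (s + tr, p.night_level),
        ]
    elif name == "unlimited_sc":
        nodes = [
            (w - tr / 2, p.night_level),
            (w + tr / 2, p.plateau_level),
            (s, p.plateau_level),
            (s + tr, p.night_level),
        ]
    elif name == "evening_preference":
        nodes = [
            (w - tr / 2, p.night_level),
            (w + tr / 2, p.plateau_level),
            (p.evening_onset_hour, p.plateau_level),
            (s, p.peak_level),
            (s + tr / 2, p.peak_level / 2),
            (s + tr, p.night_level),
        ]
    else:
        raise ValueError(f"unknown theory {name!r}; expected one of {THEORY_NAMES}")
    mu_grid = _circular_smooth(_piecewise(nodes))
    sd = p.sd_fraction * p.plateau_level
    return TheoreticalModel(name=name, metric=metric, params=params, _mu_grid=mu_grid, _sd=sd)


def build_all_theories(
    metric: str, params: TheoryParams | None = None
) -> list[TheoreticalModel]:
    return [build_theory(n, metric, params) for n in THEORY_NAMES]


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def standardize(values: np.ndarray) -> np.ndarray:
    """Min-max standardize observations to [0, 1] (constant input -> 0.5).

    One curve family serves accuracy, login fraction and session length
    because every metric is mapped to this common scale before scoring;
    the transform is affine and therefore reversible.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)


def gaussian_nll(y, mu, sigma, weights=None) -> float:
    """Sum of Gaussian negative log-densities, optionally weighted."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    per = np.log(sigma) + 0.5 * np.log(2 * np.pi) + (y - mu) ** 2 / (2 * sigma**2)
    if weights is not None:
        per = per * np.asarray(weights, dtype=float)
    return float(np.sum(per))


def score_data(
    observations: BinnedDaySeries | tuple[np.ndarray, np.ndarray],
    model: TheoreticalModel,
    standardize_values: bool = True,
) -> float:
    """Negative log-likelihood of observations under a theory curve.

    ``observations`` is either a :class:`BinnedDaySeries` (each bin's
    contribution weighted by its session count) or a ``(times, values)``
    pair of per-session local hours and metric values (each session
    weighted once).  Values are min-max standardized to the model's [0, 1]
    scale unless ``standardize_values=False`` (for data already on it).
    """
    if isinstance(observations, BinnedDaySeries):
        if observations.metric != model.metric:
            raise ValueError(
                f"metric mismatch: data {observations.metric!r} vs model {model.metric!r}"
            )
        t, y, w = observations.observed()
    else:
        t, y = observations
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        w = None
    if standardize_values:
        y = standardize(y)
    return gaussian_nll(y, model.mu(t), model.sigma(t), weights=w)


@dataclass
class DevianceTable:
    """Theory-by-dataset table of NLL deviances (smaller = better)."""

    table: pd.DataFrame  # rows = theory names, columns = dataset labels
    winners: dict  # dataset label -> winning theory name

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [self.table.round(2).to_string()]
        for label, win in self.winners.items():
            lines.append(f"winner[{label}] = {win}")
        return "\n".join(lines)


def theory_table(
    datasets: Mapping[str, BinnedDaySeries | tuple[np.ndarray, np.ndarray]],
    models: Iterable[TheoreticalModel],
    standardize_values: bool = True,
) -> DevianceTable:
    """Score every labelled dataset under every theory model.

    Mirrors the published deviance-table layout: three theory rows by up
    to three dataset columns, each cell the NLL of that dataset given that
    model, plus the per-dataset winner (lowest NLL).
    """
    models = list(models)
    metrics = {m.metric for m in models}
    if len(metrics) > 1:
        raise ValueError(f"models mix metrics: {sorted(metrics)}")
    cells = {
        label: {
            m.name: score_data(obs, m, standardize_values=standardize_values)
            for m in models
        }
        for label, obs in datasets.items()
    }
    tab = pd.DataFrame(cells)
    tab = tab.reindex([m.name for m in models])
    winners = {label: str(tab[label].idxmin()) for label in tab.columns}
    return DevianceTable(table=tab, winners=winners)


def sample_from_theory(
    model: TheoreticalModel,
    times: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw observations ``y ~ Normal(mu(t), sigma(t))`` at given times
    (used by the self-consistency and confusion-matrix simulations)."""
    t = np.asarray(times, dtype=float)
    return model.mu(t) + model.sigma(t) * rng.standard_normal(t.shape)
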