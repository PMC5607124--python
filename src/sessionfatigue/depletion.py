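"""Population-level simulation of daily self-control depletion.

Each agent carries a self-control reservoir in [0, 1].  While asleep the
reservoir recovers toward full at a fixed hourly rate.  While awake,
effortful tasks arrive as a Bernoulli process per time step; each task
depletes the reservoir by a truncated-normal demand, and idle awake steps
recover (with some probability) at the sleep recovery rate.  Aggregating
over a population yields the half-hourly mean reservoir among awake
agents — the quantity a finite-resource account of self-control predicts
should decline from shortly after wake across the whole day, even in
lenient environments with sparse demands and ample rest.

The simulator is a minimal, fully parameterized realization of that
argument; its claims are property-based (flatness without demands,
monotone decline without recovery, early decline under the lenient
preset), not reproductions of any particular figure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diurnal import BIN_STARTS, N_BINS


@dataclass(frozen=True)
class DepletionConfig:
    """Agent and environment parameters for one simulated day."""

    n_agents: int = 1000
    wake_mean_hour: float = 7.5
    wake_sd_hour: float = 1.0
    sleep_onset_hour: float = 23.0
    reservoir_max: float = 1.0
    task_rate_per_hour: float = 1.0
    task_demand_mean: float = 0.05
    task_demand_sd: float = 0.02
    recovery_per_hour: float = 0.05
    rest_probability: float = 0.3
    time_step_minutes: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be positive")
        if 60 % self.time_step_minutes != 0:
            raise ValueError("time step must divide 60 minutes")
        if self.task_rate_per_hour < 0 or self.recovery_per_hour < 0:
            raise ValueError("rates must be non-negative")
        if not (0.0 <= self.rest_probability <= 1.0):
            raise ValueError("rest_probability must lie in [0, 1]")
        if self.task_demand_mean < 0 or self.task_demand_sd < 0:
            raise ValueError("task demand parameters must be non-negative")
        step_h = self.time_step_minutes / 60.0
        if self.task_rate_per_hour * step_h > 1.0:
            raise ValueError("task rate times step exceeds one arrival per step")


def make_lenient_config(n_agents: int = 10_000, seed: int = 0) -> DepletionConfig:
    """A deliberately forgiving environment: sparse, small demands and
    frequent opportunities to rest while awake.  Used to show that the
    population decline predicted by a finite-reservoir account appears
    even when individuals are rarely taxed."""
    return DepletionConfig(
        n_agents=n_agents,
        wake_mean_hour=7.5,
        wake_sd_hour=1.0,
        sleep_onset_hour=23.0,
        task_rate_per_hour=0.5,
        task_demand_mean=0.05,
        task_demand_sd=0.02,
        recovery_per_hour=0.02,
        rest_probability=0.5,
        time_step_minutes=5,
        seed=seed,
    )


@dataclass
class PopulationCurve:
    """48 half-hour bins of population reservoir state."""

    mean_reservoir: np.ndarray  # NaN where nobody is awake
    sd_reservoir: np.ndarray
    fraction_awake: np.ndarray
    bin_starts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_hour": self.bin_starts,
                "mean_reservoir": self.mean_reservoir,
                "sd_reservoir": self.sd_reservoir,
                "fraction_awake": self.fraction_awake,
            }
        )


def simulate_day(config: DepletionConfig) -> PopulationCurve:
    """Simulate one day for the whole population; deterministic given seed.

    Time runs from 00:00 to 24:00 in fixed steps.  An agent is awake from
    its (truncated to [4, 12]) sampled wake hour until the common sleep
    onset.  Reservoirs start the day full.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_agents
    step_h = config.time_step_minutes / 60.0
    n_steps = int(round(24.0 / step_h))

    wake = np.clip(
        rng.normal(config.wake_mean_hour, config.wake_sd_hour, size=n), 4.0, 12.0
    )
    reservoir = np.full(n, config.reservoir_max)
    p_task = config.task_rate_per_hour * step_h
    rec = config.recovery_per_hour * step_h

    sums = np.zeros(N_BINS)
    sqsums = np.zeros(N_BINS)
    counts = np.zeros(N_BINS)
    awake_counts = np.zeros(N_BINS)
    steps_per_bin = np.zeros(N_BINS)

    for i in range(n_steps):
        t = i * step_h
        awake = (t >= wake) & (t < config.sleep_onset_hour)
        asleep = ~awake
        # sleeping agents recover toward full
        reservoir[asleep] = np.minimum(
            reservoir[asleep] + rec, config.reservoir_max
        )
        if awake.any():
            u = rng.random(n)
            task = awake & (u < p_task)
            if task.any():
                demand = np.maximum(
                    rng.normal(
                        config.task_demand_mean, config.task_demand_sd, size=n
                    ),
                    0.0,
                )
                reservoir[task] = np.maximum(reservoir[task] - demand[task], 0.0)
            idle = awake & ~task
            if idle.any() and config.rest_probability > 0 and rec > 0:
                r = rng.random(n)
                resting = idle & (r < config.rest_probability)
                reservoir[resting] = np.minimum(
                    reservoir[resting] + rec, config.reservoir_max
                )
        b = int(t // 0.5)
        vals = reservoir[awake]
        sums[b] += vals.sum()
        sqsums[b] += np.square(vals).sum()
        counts[b] += len(vals)
        awake_counts[b] += awake.sum()
        steps_per_bin[b] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / counts, np.nan)
        var = np.where(counts > 0, sqsums / np.maximum(counts, 1) - mean**2, np.nan)
        sd = np.sqrt(np.maximum(var, 0.0))
        frac = awake_counts / (steps_per_bin * n)
    return PopulationCurve(
        mean_reservoir=mean,
        sd_reservoir=sd,
        fraction_awake=frac,
        bin_starts=BIN_STARTS.copy(),
    )


def decline_summary(curve: PopulationCurve, wake_hour: float) -> dict:
    """Onset and magnitude of the population decline.

    ``onset_hour`` is the start of the first bin at or after ``wake_hour``
    where the awake-population mean drops below 99% of its level in the
    wake bin; ``None`` when no such bin exists.  ``total_decline`` is the
    wake-bin mean minus the daily minimum over later bins.
    """
    start_bin = int(wake_hour // 0.5)
    ref = curve.mean_reservoir[start_bin]
    onset = None
    later = curve.mean_reservoir[start_bin:]
    valid = np.isfinite(later)
    if np.isfinite(ref):
        below = valid & (later < 0.99 * ref)
        if below.any():
            onset = float(curve.bin_starts[start_bin + int(np.argmax(below))])
    total = float(ref - np.nanmin(later)) if np.isfinite(ref) else np.nan
    min_hour = (
        float(curve.bin_starts[start_bin + int(np.nanargmin(later))])
        if valid.any()
        else np.nan
    )
    return {"onset_hour": onset, "total_decline": total, "minimum_hour": min_hour}


def sweep(configs: list[DepletionConfig]) -> pd.DataFrame:
    """Run several configurations and summarize each decline.

    One row per config: end-of-day mean reservoir, decline onset (NaN when
    the population never drops below 99% of its wake level) and total
    decline from wake to the daily minimum.
    """
    if not configs:
        raise ValueError("need at least one config")
    rows = []
    for cfg in configs:
        curve = simulate_day(cfg)
        summ = decline_summary(curve, cfg.wake_mean_hour)
        awake_bins = np.where(np.isfinite(curve.mean_reservoir))[0]
        end_mean = (
            float(curve.mean_reservoir[awake_bins[-1]]) if len(awake_bins) else np.nan
        )
        rows.append(
            {
                "task_rate_per_hour": cfg.task_rate_per_hour,
                "recovery_per_hour": cfg.recovery_per_hour,
                "rest_probability": cfg.rest_probability,
                "n_agents": cfg.n_agents,
                "seed": cfg.seed,
                "end_of_day_mean": end_mean,
                "decline_onset_hour": (
                    np.nan if summ["onset_hour"] is None else summ["onset_hour"]
                ),
                "total_decline": summ["total_decline"],
                "minimum_hour": summ["minimum_hour"],
            }
        )
    return pd.DataFrame(rows)
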