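"""End-to-end two-cohort study protocol.

Mirrors the exploratory / confirmatory structure of the original study:
cohort 1 is analysed freely, the fitted day-curve models are frozen and
evaluated out-of-sample on cohort 2 without timezone correction (so the
two cohorts are comparable), and finally all models are refitted to
cohort 2 after adjusting each user's clock by their UTC offset.  Stages:

1. screening of both cohorts,
2. within-session fatigue (null/linear/quadratic AIC race, peak + drop),
3. diurnal replication protocol per metric (WAIC -> frozen RMSE -> refit),
4. theory deviance tables (limited / unlimited / evening preference),
5. time-of-day moderation of the per-session fatigue coefficients.

Every stage writes plain CSV (plus a human-readable summary) and is
deterministic given the config and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diurnal import DEFAULT_CANDIDATES, bin_day, replication_protocol
from .fatigue import compare_fits, fit_fatigue, quadratic_summary, smooth_sessions
from .io import ScreeningConfig, localize_times, screen, summarize_sessions
from .moderation import extract_session_coefs, moderation_battery
from .synth import GeneratorConfig, generate_log, make_cohort_preset
from .theory import TheoryParams, build_all_theories, theory_table

METRICS = ("session_accuracy", "login_fraction", "session_length")


@dataclass
class StudyConfig:
    """Inputs, thresholds and seeds for one full study run."""

    sample1: GeneratorConfig | str | Path
    sample2: GeneratorConfig | str | Path
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    candidates: tuple = DEFAULT_CANDIDATES
    theory_params: TheoryParams = field(default_factory=TheoryParams)
    metrics: tuple = METRICS
    fatigue_horizon: float = 150.0
    moderation_max_sessions: int = 800
    n_draws: int = 2000
    seed: int = 0


@dataclass
class StudyReport:
    """In-memory results of a study run (everything also lands on disk)."""

    outdir: Path
    fatigue_winners: dict = field(default_factory=dict)  # sample -> form
    fatigue_summaries: dict = field(default_factory=dict)  # sample -> (vertex, drop)
    replication: dict = field(default_factory=dict)  # metric -> ReplicationReport
    theory_winners: dict = field(default_factory=dict)  # metric -> {dataset: theory}
    moderation: pd.DataFrame | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _load_records(source, log) -> pd.DataFrame:
    from .io import read_session_log

    if isinstance(source, GeneratorConfig):
        log.append(f"generating synthetic cohort (seed {source.seed})")
        records, _ = generate_log(source)
        return records
    log.append(f"reading log from {source}")
    return read_session_log(source)


def _csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_study(config: StudyConfig, outdir: str | Path) -> StudyReport:
    """Execute the full protocol; aborts naming the failed stage, keeping
    any partial outputs already written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"sessionfatigue {__version__}", f"study seed {config.seed}"]
    report = StudyReport(outdir=outdir)

    # ---- stage: load + screen -------------------------------------------
    stage = "screening"
    try:
        raw1 = _load_records(config.sample1, log)
        raw2 = _load_records(config.sample2, log)
        rec1, rep1 = screen(raw1, config.screening)
        rec2, rep2 = screen(raw2, config.screening)
        (outdir / "screening_sample1.txt").write_text(str(rep1) + "\n")
        (outdir / "screening_sample2.txt").write_text(str(rep2) + "\n")
        log.append(f"screened cohort 1: {rep1.trials_after}/{rep1.trials_before} trials kept")
        log.append(f"screened cohort 2: {rep2.trials_after}/{rep2.trials_before} trials kept")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # localized views: uncorrected for both cohorts; adjusted for cohort 2
    loc1 = localize_times(rec1, "none")
    loc2_direct = localize_times(rec2, "none")
    loc2_adj = localize_times(rec2, "per_user_offset")
    sess1 = summarize_sessions(loc1)
    sess2 = summarize_sessions(loc2_direct)
    sess2_adj = summarize_sessions(loc2_adj)
    sess2 = sess2.merge(
        sess2_adj[["user_id", "session_id", "start_local_time"]].rename(
            columns={"start_local_time": "start_local_time_adjusted"}
        ),
        on=["user_id", "session_id"],
    )

    # ---- stage: within-session fatigue ----------------------------------
    stage = "fatigue"
    try:
        for label, rec in (("sample1", rec1), ("sample2", rec2)):
            series, n_skip = smooth_sessions(rec, axis="trial_order")
            fits = [fit_fatigue(series, form, grouping="user") for form in
                    ("null", "linear", "quadratic")]
            sel = compare_fits(fits)
            _csv(sel.table, outdir / f"fatigue_aic_{label}.csv")
            report.fatigue_winners[label] = sel.winner
            quad = next(f for f in fits if f.form == "quadratic")
            if quad.converged and quad.params.get("beta2", 0) < 0:
                report.fatigue_summaries[label] = quadratic_summary(
                    quad, config.fatigue_horizon
                )
            log.append(
                f"fatigue {label}: winner {sel.winner}, {n_skip} sessions skipped"
            )
        summ_rows = [
            {"sample": k, "vertex": v[0], "drop_to_horizon": v[1],
             "horizon": config.fatigue_horizon}
            for k, v in report.fatigue_summaries.items()
        ]
        _csv(pd.DataFrame(summ_rows), outdir / "fatigue_quadratic_summary.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: diurnal replication protocol ----------------------------
    stage = "diurnal"
    try:
        for i, metric in enumerate(config.metrics):
            rep = replication_protocol(
                sess1,
                sess2,
                metric,
                candidates=config.candidates,
                seed=config.seed + 1000 + i,
                n_draws=config.n_draws,
            )
            report.replication[metric] = rep
            _csv(rep.stage1_waic, outdir / f"diurnal_{metric}_stage1_waic.csv")
            _csv(rep.stage2_rmse, outdir / f"diurnal_{metric}_stage2_rmse.csv")
            _csv(rep.stage3_waic, outdir / f"diurnal_{metric}_stage3_waic.csv")
            log.append(
                f"diurnal {metric}: stage1 winner {rep.stage1_winner}, "
                f"stage2 best {rep.stage2_best}, stage3 winner {rep.stage3_winner}"
            )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: theory deviance tables ----------------------------------
    stage = "theory"
    try:
        adj_view = sess2.drop(columns="start_local_time").rename(
            columns={"start_local_time_adjusted": "start_local_time"}
        )
        for metric in config.metrics:
            datasets = {
                "sample1": bin_day(sess1, metric, "none"),
                "sample2_direct": bin_day(
                    sess2.drop(columns="start_local_time_adjusted"), metric, "none"
                ),
                "sample2_adjusted": bin_day(adj_view, metric, "per_user_offset"),
            }
            models = build_all_theories(metric, config.theory_params)
            tab = theory_table(datasets, models)
            out = tab.table.copy()
            out.insert(0, "model", out.index)
            _csv(out.reset_index(drop=True), outdir / f"theory_{metric}.csv")
            report.theory_winners[metric] = tab.winners
            log.append(f"theory {metric}: winners {tab.winners}")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: moderation ----------------------------------------------
    stage = "moderation"
    try:
        series2, _ = smooth_sessions(rec2, axis="trial_order")
        keys = series2[["user_id", "session_id"]].drop_duplicates()
        if len(keys) > config.moderation_max_sessions:
            rng = np.random.default_rng(config.seed + 7)
            take = rng.choice(
                len(keys), size=config.moderation_max_sessions, replace=False
            )
            keys = keys.iloc[np.sort(take)]
            series2 = series2.merge(keys, on=["user_id", "session_id"])
            log.append(
                f"moderation: subsampled {config.moderation_max_sessions} sessions"
            )
        coefs = extract_session_coefs(series2, sess2_adj)
        battery = moderation_battery(coefs)
        report.moderation = battery
        _csv(battery, outdir / "moderation.csv")
        sig = battery.loc[battery["significant"], ["component", "term"]]
        log.append(
            "moderation significant terms: "
            + (", ".join(sig["component"] + ":" + sig["term"]) if len(sig) else "none")
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- summary ---------------------------------------------------------
    lines = ["study summary", "============="]
    for label, winner in report.fatigue_winners.items():
        lines.append(f"within-session fatigue ({label}): best form = {winner}")
    for label, (vertex, drop) in report.fatigue_summaries.items():
        lines.append(
            f"  {label}: accuracy peaks near trial {vertex:.1f}; "
            f"drop of {drop:.3f} by trial {config.fatigue_horizon:.0f}"
        )
    for metric, rep in report.replication.items():
        lines.append(
            f"diurnal {metric}: sample1 WAIC winner = {rep.stage1_winner}; "
            f"frozen-model best on sample2 = {rep.stage2_best}; "
            f"sample2 refit winner = {rep.stage3_winner}"
        )
    for metric, winners in report.theory_winners.items():
        lines.append(f"theory {metric}: " + ", ".join(f"{k}->{v}" for k, v in winners.items()))
    if report.moderation is not None:
        nsig = int(report.moderation["significant"].sum())
        lines.append(f"moderation battery: {nsig} of 6 tests significant at alpha=0.008")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return report


# ---------------------------------------------------------------------------
# Deterministic demo on generated cohorts
# ---------------------------------------------------------------------------

def make_demo_config(seed: int = 7, n_users: int = 120) -> StudyConfig:
    """Two synthetic cohorts from the cohort-2-like preset with distinct
    seeds, at desk scale."""
    g1 = replace(make_cohort_preset(n_users=n_users), seed=seed * 2 + 1)
    g2 = replace(make_cohort_preset(n_users=n_users), seed=seed * 2 + 2)
    return StudyConfig(sample1=g1, sample2=g2, seed=seed)


def run_demo(seed: int = 7, outdir: str | Path = "study_demo", n_users: int = 120) -> StudyReport:
    """Generate two cohorts and run the full protocol on them."""
    return run_study(make_demo_config(seed=seed, n_users=n_users), outdir)
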