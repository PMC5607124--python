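"""Event-log data model, CSV dialect, timezone localization and screening.

The in-memory representation of a session log is a :class:`pandas.DataFrame`
with one row per trial event and the columns listed in :data:`LOG_COLUMNS`.
Rows are always sorted by ``(user_id, session_id, trial_index)``.

The on-disk dialect is UTF-8 comma-separated text with ISO 8601 UTC
timestamps (trailing ``Z``), ``true``/``false`` correctness on test events
and an empty correctness field on learn events.  Writing is canonical: any
valid log written twice produces byte-identical files.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

LOG_COLUMNS = [
    "user_id",
    "session_id",
    "trial_index",
    "event_type",
    "timestamp_utc",
    "utc_offset_hours",
    "correct",
    "elapsed_seconds",
]

EVENT_TYPES = ("learn", "test")

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%SZ"


class SessionLogParseError(ValueError):
    """Raised when a session-log file violates the dialect or an invariant.

    Attributes
    ----------
    lines : list of int
        1-based line numbers (including the header line) implicated in the
        failure.
    """

    def __init__(self, message: str, lines: list[int] | None = None):
        self.lines = lines or []
        if self.lines:
            message = f"{message} (line{'s' if len(self.lines) > 1 else ''} {', '.join(map(str, self.lines))})"
        super().__init__(message)


def _parse_bool(tok: str) -> bool:
    if tok == "true":
        return True
    if tok == "false":
        return False
    raise ValueError(f"not a boolean: {tok!r}")


def read_session_log(path: Union[str, Path, _io.TextIOBase]) -> pd.DataFrame:
    """Read a session log CSV, validating every row.

    Parameters
    ----------
    path : str, Path or text stream
        Source of the CSV dialect described in the module docstring.

    Returns
    -------
    pandas.DataFrame
        Records grouped and ordered by ``(user_id, session_id, trial_index)``.

    Raises
    ------
    SessionLogParseError
        On a malformed header, unparseable field, duplicate or
        non-contiguous trial index, negative or decreasing elapsed time, or
        correctness present/absent on the wrong event type.  The error names
        the offending line(s).
    """
    if isinstance(path, (str, Path)):
        with open(path, "r", encoding="utf-8", newline="") as fh:
            return _read_stream(fh)
    return _read_stream(path)


def _read_stream(fh) -> pd.DataFrame:
    header = fh.readline().rstrip("\r\n")
    if header.split(",") != LOG_COLUMNS:
        raise SessionLogParseError(
            f"header mismatch: expected {','.join(LOG_COLUMNS)!r}, got {header!r}", [1]
        )
    rows = []
    for lineno, raw in enumerate(fh, start=2):
        line = raw.rstrip("\r\n")
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != len(LOG_COLUMNS):
            raise SessionLogParseError(
                f"expected {len(LOG_COLUMNS)} fields, got {len(parts)}", [lineno]
            )
        user_id, session_id, trial_index, event_type, ts, offset, correct, elapsed = parts
        try:
            idx = int(trial_index)
            if idx < 1:
                raise ValueError("trial_index must be >= 1")
            if event_type not in EVENT_TYPES:
                raise ValueError(f"unknown event_type {event_type!r}")
            stamp = pd.Timestamp(ts)
            if stamp.tzinfo is None or not ts.endswith("Z"):
                raise ValueError(f"timestamp must be UTC with trailing Z: {ts!r}")
            stamp = stamp.tz_convert("UTC")
            off = int(offset) if offset != "" else None
            if off is not None and not (-12 <= off <= 14):
                raise ValueError(f"utc_offset_hours out of range: {off}")
            corr = _parse_bool(correct) if correct != "" else None
            if event_type == "test" and corr is None:
                raise ValueError("test event missing correctness")
            if event_type == "learn" and corr is not None:
                raise ValueError("learn event carries correctness")
            elapsed_s = float(elapsed)
            if not np.isfinite(elapsed_s) or elapsed_s < 0:
                raise ValueError(f"negative or non-finite elapsed_seconds: {elapsed}")
        except ValueError as exc:
            raise SessionLogParseError(str(exc), [lineno]) from None
        rows.append((user_id, session_id, idx, event_type, stamp, off, corr, elapsed_s, lineno))

    df = pd.DataFrame(rows, columns=LOG_COLUMNS + ["_line"])
    if df.empty:
        return _empty_log()
    _validate_sessions(df)
    df = df.sort_values(["user_id", "session_id", "trial_index"], kind="mergesort")
    df = df.drop(columns="_line").reset_index(drop=True)
    return _coerce_dtypes(df)


def _validate_sessions(df: pd.DataFrame) -> None:
    for (_, _), grp in df.groupby(["user_id", "session_id"], sort=False):
        dup = grp["trial_index"].duplicated(keep=False)
        if dup.any():
            raise SessionLogParseError(
                "duplicate trial_index within session", sorted(grp.loc[dup, "_line"].tolist())
            )
        srt = grp.sort_values("trial_index")
        idx = srt["trial_index"].to_numpy()
        if idx[0] != 1 or not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise SessionLogParseError(
                "trial_index not contiguous from 1 within session",
                sorted(srt["_line"].tolist()),
            )
        el = srt["elapsed_seconds"].to_numpy()
        if np.any(np.diff(el) < 0):
            bad = int(np.argmax(np.diff(el) < 0))
            raise SessionLogParseError(
                "elapsed_seconds decreases within session",
                [int(srt["_line"].iloc[bad]), int(srt["_line"].iloc[bad + 1])],
            )


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["user_id"] = out["user_id"].astype(str)
    out["session_id"] = out["session_id"].astype(str)
    out["trial_index"] = out["trial_index"].astype(np.int64)
    out["event_type"] = out["event_type"].astype(str)
    out["timestamp_utc"] = pd.to_datetime(out["timestamp_utc"], utc=True)
    out["utc_offset_hours"] = out["utc_offset_hours"].astype("Int64")
    out["correct"] = out["correct"].astype("boolean")
    out["elapsed_seconds"] = out["elapsed_seconds"].astype(np.float64)
    return out


def _empty_log() -> pd.DataFrame:
    return _coerce_dtypes(pd.DataFrame({c: pd.Series(dtype=object) for c in LOG_COLUMNS}))


def _format_float(x: float) -> str:
    # shortest round-trippable representation keeps the dialect canonical
    return repr(float(x))


def write_session_log(records: pd.DataFrame, path: Union[str, Path, _io.TextIOBase]) -> None:
    """Write records in the canonical CSV dialect (stable byte-for-byte)."""
    if isinstance(path, (str, Path)):
        with open(path, "w", encoding="utf-8", newline="") as fh:
            _write_stream(records, fh)
    else:
        _write_stream(records, path)


def _write_stream(records: pd.DataFrame, fh) -> None:
    df = records.sort_values(["user_id", "session_id", "trial_index"], kind="mergesort")
    fh.write(",".join(LOG_COLUMNS) + "\n")
    for row in df.itertuples(index=False):
        off = "" if pd.isna(row.utc_offset_hours) else str(int(row.utc_offset_hours))
        corr = "" if pd.isna(row.correct) else ("true" if row.correct else "false")
        ts = pd.Timestamp(row.timestamp_utc).tz_convert("UTC").strftime(TIMESTAMP_FORMAT)
        fh.write(
            f"{row.user_id},{row.session_id},{row.trial_index},{row.event_type},"
            f"{ts},{off},{corr},{_format_float(row.elapsed_seconds)}\n"
        )


# ---------------------------------------------------------------------------
# Timezone localization
# ---------------------------------------------------------------------------

class MissingOffsetError(ValueError):
    """Raised when per-user offsets are requested but absent for some users."""

    def __init__(self, users: list[str]):
        self.users = users
        super().__init__(
            "utc_offset_hours missing for users: " + ", ".join(map(str, users))
        )


def localize_times(records: pd.DataFrame, mode: str = "none") -> pd.DataFrame:
    """Populate a ``local_hour`` column in [0, 24) for every record.

    ``mode="none"`` copies the UTC clock time (the uncorrected analysis of
    either cohort); ``mode="per_user_offset"`` adds each user's integer UTC
    offset modulo 24 (the timezone-adjusted refit).  Record order is
    preserved.
    """
    if mode not in ("none", "per_user_offset"):
        raise ValueError(f"unknown mode {mode!r}")
    out = records.copy()
    stamps = pd.to_datetime(out["timestamp_utc"], utc=True)
    hour = (
        stamps.dt.hour
        + stamps.dt.minute / 60.0
        + stamps.dt.second / 3600.0
        + stamps.dt.microsecond / 3.6e9
    )
    if mode == "per_user_offset":
        missing = out.loc[out["utc_offset_hours"].isna(), "user_id"].unique().tolist()
        if missing:
            raise MissingOffsetError(sorted(missing))
        hour = hour + out["utc_offset_hours"].astype(float)
    out["local_hour"] = np.mod(hour.to_numpy(dtype=float), 24.0)
    return out


def summarize_sessions(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse a localized log to one row per session.

    Columns: ``user_id``, ``session_id``, ``start_local_time`` (local hour
    of the first trial, in [0, 24)), ``n_trials``, ``n_test_trials``,
    ``duration_minutes`` and ``mean_accuracy`` (NaN when the session has no
    test trials).
    """
    if "local_hour" not in records.columns:
        raise ValueError("records must be localized first (call localize_times)")
    grp = records.sort_values(["user_id", "session_id", "trial_index"]).groupby(
        ["user_id", "session_id"], sort=True
    )
    out = grp.agg(
        start_local_time=("local_hour", "first"),
        n_trials=("trial_index", "size"),
        duration_minutes=("elapsed_seconds", lambda s: float(s.max()) / 60.0),
    )
    test = records[records["event_type"] == "test"]
    tg = test.groupby(["user_id", "session_id"])
    out["n_test_trials"] = tg.size().reindex(out.index, fill_value=0).astype(np.int64)
    acc = tg["correct"].mean().astype(float)
    out["mean_accuracy"] = acc.reindex(out.index)
    return out.reset_index()[
        [
            "user_id",
            "session_id",
            "start_local_time",
            "n_trials",
            "n_test_trials",
            "duration_minutes",
            "mean_accuracy",
        ]
    ]


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds for the pre-analysis screening filters.

    The exact screening rules applied to the original cohorts were never
    published; these defaults are deliberately conservative stand-ins and
    every threshold is configurable.
    """

    min_test_trials_per_session: int = 5
    max_session_duration_hours: float = 6.0
    min_sessions_per_user: int = 2


@dataclass
class ScreeningReport:
    """Accounting of every screening removal.

    ``removed`` maps rule name to the number of entities (sessions or
    users) it removed; the ``*_before``/``*_after`` totals are at user,
    session and trial level and always satisfy after = before - removed.
    """

    removed: dict = field(default_factory=dict)
    users_before: int = 0
    users_after: int = 0
    sessions_before: int = 0
    sessions_after: int = 0
    trials_before: int = 0
    trials_after: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = ["screening report:"]
        for rule, n in self.removed.items():
            lines.append(f"  {rule}: removed {n}")
        lines.append(
            f"  users {self.users_before} -> {self.users_after}; "
            f"sessions {self.sessions_before} -> {self.sessions_after}; "
            f"trials {self.trials_before} -> {self.trials_after}"
        )
        return "\n".join(lines)


def screen(
    records: pd.DataFrame, rules: ScreeningConfig | None = None
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Apply screening filters in fixed order and account for every removal.

    Order: trial-level rules (none at present), then session-level rules
    (minimum test trials, maximum duration), then user-level rules (minimum
    session count).  Screening is idempotent: running it on its own output
    removes nothing, because user-level counts are taken after session
    removal.
    """
    rules = rules or ScreeningConfig()
    rep = ScreeningReport()
    rep.users_before = records["user_id"].nunique()
    sess_key = ["user_id", "session_id"]
    rep.sessions_before = len(records[sess_key].drop_duplicates())
    rep.trials_before = len(records)

    df = records
    # session-level
    test_counts = (
        df[df["event_type"] == "test"].groupby(sess_key).size()
        if len(df)
        else pd.Series(dtype=np.int64)
    )
    per_sess = df.groupby(sess_key).agg(duration_h=("elapsed_seconds", lambda s: s.max() / 3600.0))
    per_sess["n_test"] = test_counts.reindex(per_sess.index, fill_value=0)

    few_tests = per_sess.index[per_sess["n_test"] < rules.min_test_trials_per_session]
    rep.removed["session_min_test_trials"] = len(few_tests)
    keep = ~df.set_index(sess_key).index.isin(few_tests)
    df = df[keep]

    per_sess = per_sess.drop(index=few_tests)
    too_long = per_sess.index[per_sess["duration_h"] > rules.max_session_duration_hours]
    rep.removed["session_max_duration"] = len(too_long)
    df = df[~df.set_index(sess_key).index.isin(too_long)]

    # user-level (counts taken after session removal, so screening is idempotent)
    sess_per_user = df[sess_key].drop_duplicates().groupby("user_id").size()
    few_sessions = sess_per_user.index[sess_per_user < rules.min_sessions_per_user]
    rep.removed["user_min_sessions"] = len(few_sessions)
    df = df[~df["user_id"].isin(few_sessions)]

    df = df.reset_index(drop=True)
    rep.users_after = df["user_id"].nunique()
    rep.sessions_after = len(df[sess_key].drop_duplicates())
    rep.trials_after = len(df)
    return df, rep
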