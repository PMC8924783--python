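"""Canonical sensor-record data model and delimited-text I/O.

A *sensor day* is one participant-day of wrist-worn inertial recordings:
50 Hz (default) accelerometer and gyroscope samples plus diary annotations.
Each day is stored as a single CSV named ``<participant>_<YYYY-MM-DD>.csv``
with 18 physical columns; participant id and date ride in the filename,
completing a 20-feature record.

Columns
-------
ts
    Epoch-milliseconds timestamp, strictly increasing within a day.
tod
    Seconds since local midnight.
sesid
    Session identifier; a session is a maximal contiguous recording
    period, and a day may contain several.
accl_x/accl_y/accl_z
    Linear acceleration in g.
gyro_x/gyro_y/gyro_z
    Rotation rate in rad/s.
fork/knife/spoon/glass/chopstick/hand
    Binary utensil flags, set during meals eaten with that utensil.
tag / tagTimely / tagRetro
    Diary labels: any eating tag; tags entered while eating; tags entered
    retrospectively after the meal. ``tagTimely <= tag`` always holds.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import re
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA_COLUMNS",
    "MOTION_COLUMNS",
    "UTENSIL_COLUMNS",
    "SchemaError",
    "DataError",
    "SensorDay",
    "MealEvent",
    "read_day",
    "write_day",
    "extract_meals",
    "read_meals",
    "write_meals",
    "day_filename",
    "parse_day_filename",
]

MOTION_COLUMNS = ["accl_x", "accl_y", "accl_z", "gyro_x", "gyro_y", "gyro_z"]
UTENSIL_COLUMNS = ["fork", "knife", "spoon", "glass", "chopstick", "hand"]
TAG_COLUMNS = ["tag", "tagTimely", "tagRetro"]
SCHEMA_COLUMNS = ["ts", "tod", "sesid"] + MOTION_COLUMNS + UTENSIL_COLUMNS + TAG_COLUMNS

#: default gap (seconds) between consecutive samples that starts a new session
SESSION_GAP_SECONDS = 1.0


class SchemaError(ValueError):
    """A file does not conform to the sensor-record schema."""


class DataError(ValueError):
    """A record violates a data invariant (e.g. non-monotone timestamps)."""


@dataclasses.dataclass
class SensorDay:
    """One participant-day of sensor samples with diary annotations."""

    participant_id: str
    date: _dt.date
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SCHEMA_COLUMNS if c not in self.samples.columns]
        if missing:
            raise SchemaError(f"samples missing columns: {missing}")

    # -- derived views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sampling_rate_hz(self) -> float:
        """Median sampling rate inferred from within-session spacing."""
        ts = self.samples["ts"].to_numpy()
        ses = self.samples["sesid"].to_numpy()
        if len(ts) < 2:
            return float("nan")
        dt = np.diff(ts) / 1000.0
        same = ses[1:] == ses[:-1]
        if not same.any():
            return float("nan")
        return float(1.0 / np.median(dt[same]))

    def session_bounds(self) -> list[tuple[int, int, int]]:
        """(sesid, first_row, last_row_exclusive) per session, in order."""
        ses = self.samples["sesid"].to_numpy()
        if len(ses) == 0:
            return []
        change = np.flatnonzero(np.diff(ses) != 0) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(ses)]))
        return [(int(ses[s]), int(s), int(e)) for s, e in zip(starts, ends)]

    def total_duration_hours(self) -> float:
        """Recorded time summed over sessions, in hours."""
        ts = self.samples["ts"].to_numpy()
        total_ms = 0.0
        for _, s, e in self.session_bounds():
            if e - s >= 2:
                total_ms += ts[e - 1] - ts[s]
        return total_ms / 3.6e6

    def validate(self) -> None:
        """Raise :class:`DataError` on invariant violations."""
        df = self.samples
        ts = df["ts"].to_numpy()
        if len(ts) > 1:
            bad = np.flatnonzero(np.diff(ts) <= 0)
            if len(bad):
                raise DataError(f"ts not strictly increasing at row {int(bad[0]) + 1}")
            dses = np.diff(df["sesid"].to_numpy())
            if (dses < 0).any():
                row = int(np.flatnonzero(dses < 0)[0]) + 1
                raise DataError(f"sesid decreases at row {row}")
        for col in UTENSIL_COLUMNS + ["tag", "tagTimely", "tagRetro"]:
            vals = df[col].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise DataError(f"column {col} contains values outside {{0,1}}")
        if (df["tagTimely"].to_numpy() > df["tag"].to_numpy()).any():
            raise DataError("tagTimely exceeds tag")

    def key(self) -> tuple[str, str]:
        return (self.participant_id, self.date.isoformat())


@dataclasses.dataclass(frozen=True)
class MealEvent:
    """A diary-logged eating interval (ground truth)."""

    participant_id: str
    date: _dt.date
    start_ts: int
    end_ts: int
    retrospective: bool = False
    utensils: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.end_ts <= self.start_ts:
            raise DataError(f"meal end_ts {self.end_ts} <= start_ts {self.start_ts}")

    @property
    def duration_seconds(self) -> float:
        return (self.end_ts - self.start_ts) / 1000.0


# ---------------------------------------------------------------------------
# file naming
# ---------------------------------------------------------------------------

_DAY_RE = re.compile(r"^(?P<pid>[^_]+)_(?P<date>\d{4}-\d{2}-\d{2})\.csv$")


def day_filename(participant_id: str, date: _dt.date) -> str:
    return f"{participant_id}_{date.isoformat()}.csv"


def parse_day_filename(name: str) -> tuple[str, _dt.date]:
    m = _DAY_RE.match(Path(name).name)
    if m is None:
        raise SchemaError(f"filename {name!r} is not <participant>_<YYYY-MM-DD>.csv")
    return m.group("pid"), _dt.date.fromisoformat(m.group("date"))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_INT_COLS = ["ts", "sesid"] + UTENSIL_COLUMNS + ["tag", "tagTimely", "tagRetro"]


def write_day(day: SensorDay, directory: str | Path) -> Path:
    """Write one day to ``<dir>/<participant>_<date>.csv``; returns the path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / day_filename(day.participant_id, day.date)
    df = day.samples[SCHEMA_COLUMNS].copy()
    for col in _INT_COLS:
        df[col] = df[col].astype(np.int64)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_day(path: str | Path) -> SensorDay:
    """Read and validate one participant-day CSV."""
    path = Path(path)
    pid, date = parse_day_filename(path.name)
    df = pd.read_csv(path)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {', '.join(missing)}")
    df = df[SCHEMA_COLUMNS]
    # empty tagRetro fields are treated as 0 (not-retrospective)
    df["tagRetro"] = df["tagRetro"].fillna(0)
    for col in _INT_COLS:
        df[col] = df[col].astype(np.int64)
    for col in MOTION_COLUMNS + ["tod"]:
        df[col] = df[col].astype(np.float64)
    day = SensorDay(pid, date, df)
    day.validate()
    return day


def assign_sessions(ts_ms: np.ndarray, gap_seconds: float = SESSION_GAP_SECONDS) -> np.ndarray:
    """Session ids for a raw timestamp stream: a gap > ``gap_seconds`` starts a new session."""
    ts_ms = np.asarray(ts_ms)
    if len(ts_ms) == 0:
        return np.zeros(0, dtype=np.int64)
    gaps = np.diff(ts_ms) > gap_seconds * 1000.0
    return np.concatenate(([0], np.cumsum(gaps))).astype(np.int64)


# ---------------------------------------------------------------------------
# diary extraction
# ---------------------------------------------------------------------------

def extract_meals(day: SensorDay) -> list[MealEvent]:
    """Maximal runs of ``tag == 1`` as :class:`MealEvent` objects.

    A run is retrospective iff any of its ``tagRetro`` values is set; runs
    separated by even one ``tag == 0`` sample are distinct events. Utensils
    are the union of utensil flags observed inside the run.
    """
    df = day.samples
    tag = df["tag"].to_numpy()
    if not tag.any():
        return []
    ts = df["ts"].to_numpy()
    retro = df["tagRetro"].to_numpy()
    padded = np.concatenate(([0], tag, [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    meals = []
    for s, e in zip(starts, ends):
        utensils = frozenset(
            c for c in UTENSIL_COLUMNS if df[c].to_numpy()[s:e].any()
        )
        meals.append(
            MealEvent(
                participant_id=day.participant_id,
                date=day.date,
                start_ts=int(ts[s]),
                # a one-sample run still spans a non-empty interval
                end_ts=int(ts[e - 1]) if e - 1 > s else int(ts[s]) + 1,
                retrospective=bool(retro[s:e].any()),
                utensils=utensils,
            )
        )
    return meals


MEAL_COLUMNS = ["participant", "date", "start_ts", "end_ts", "retro", "utensil"]


def write_meals(meals: list[MealEvent], path: str | Path) -> Path:
    """Write a ground-truth meal sidecar CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "participant": m.participant_id,
            "date": m.date.isoformat(),
            "start_ts": m.start_ts,
            "end_ts": m.end_ts,
            "retro": int(m.retrospective),
            "utensil": "|".join(sorted(m.utensils)),
        }
        for m in meals
    ]
    pd.DataFrame(rows, columns=MEAL_COLUMNS).to_csv(path, index=False)
    return path


def read_meals(path: str | Path) -> list[MealEvent]:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in MEAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"meal sidecar missing column(s) {', '.join(missing)}")
    meals = []
    for row in df.itertuples(index=False):
        utensils = frozenset(u for u in str(row.utensil).split("|") if u)
        meals.append(
            MealEvent(
                participant_id=str(row.participant),
                date=_dt.date.fromisoformat(str(row.date)),
                start_ts=int(row.start_ts),
                end_ts=int(row.end_ts),
                retrospective=bool(int(row.retro)),
                utensils=utensils,
            )
        )
    return meals
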