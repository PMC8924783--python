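"""Shared fixtures: hand-built sensor days and small learnable window sets."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from bitewatch.records import SCHEMA_COLUMNS, UTENSIL_COLUMNS, SensorDay
from bitewatch.windowing import WindowSet

EPOCH0 = int(dt.datetime(2021, 5, 3, tzinfo=dt.timezone.utc).timestamp() * 1000)


def build_day(
    rate_hz: float = 1.0,
    duration_s: float = 3600.0,
    start_tod: float = 8 * 3600.0,
    meal_rows: list[tuple[int, int]] | None = None,
    retro_rows: list[tuple[int, int]] | None = None,
    session_breaks_at: list[int] | None = None,
    gap_s: float = 300.0,
    participant: str = "P01",
    date: dt.date = dt.date(2021, 5, 3),
    noise_sd: float = 0.2,
    seed: int = 0,
) -> SensorDay:
    """Construct a day row-by-row with explicit tag runs and session breaks.

    ``meal_rows``/``retro_rows`` are [start_row, end_row) half-open row
    ranges; ``session_breaks_at`` lists row indices before which a time gap
    of ``gap_s`` is inserted (incrementing sesid).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    dt_s = 1.0 / rate_hz
    tod = start_tod + np.arange(n) * dt_s
    sesid = np.zeros(n, dtype=np.int64)
    if session_breaks_at:
        offset = np.zeros(n)
        for b in session_breaks_at:
            offset[b:] += gap_s
            sesid[b:] += 1
        tod = tod + offset
    ts = EPOCH0 + np.round(tod * 1000).astype(np.int64)
    tag = np.zeros(n, dtype=np.int64)
    retro = np.zeros(n, dtype=np.int64)
    for s, e in meal_rows or []:
        tag[s:e] = 1
    for s, e in retro_rows or []:
        tag[s:e] = 1
        retro[s:e] = 1
    timely = tag * (1 - retro)
    df = pd.DataFrame(
        {
            "ts": ts,
            "tod": tod,
            "sesid": sesid,
            "accl_x": rng.normal(0, noise_sd, n),
            "accl_y": rng.normal(0, noise_sd, n),
            "accl_z": rng.normal(-1.0, noise_sd, n),
            "gyro_x": rng.normal(0, noise_sd, n),
            "gyro_y": rng.normal(0, noise_sd, n),
            "gyro_z": rng.normal(0, noise_sd, n),
            **{c: np.zeros(n, dtype=np.int64) for c in UTENSIL_COLUMNS},
            "tag": tag,
            "tagTimely": timely,
            "tagRetro": retro,
        },
        columns=SCHEMA_COLUMNS,
    )
    return SensorDay(participant, date, df)


def toy_window_set(
    n_pos: int,
    n_neg: int,
    rows: int = 80,
    rate_hz: float = 1.0,
    seed: int = 0,
    participant: str = "P01",
    separable: bool = True,
) -> WindowSet:
    """A small learnable WindowSet: positives carry a sinusoidal burst."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    day = np.asarray(rng.normal(0, 0.3, (n * rows, 6)), dtype=np.float32)
    labels = np.array([1] * n_pos + [0] * n_neg)
    rng.shuffle(labels)
    t = np.arange(rows) / rate_hz
    for i in np.flatnonzero(labels == 1):
        if separable:
            burst = 1.5 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
            day[i * rows : (i + 1) * rows, 3:6] += burst[:, None] * rng.dirichlet([1, 1, 1])
    key = f"{participant}/2021-05-03"
    index = pd.DataFrame(
        {
            "participant": participant,
            "date": "2021-05-03",
            "day_key": key,
            "start_row": np.arange(n) * rows,
            "start_ts": EPOCH0 + np.arange(n) * rows * 1000,
            "label": labels,
            "meal_id": -1,
        }
    )
    return WindowSet(index, {key: day}, rows, rows / rate_hz, rows / rate_hz)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
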