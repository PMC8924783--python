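"""Participant- and day-level exclusion rules.

Noncompliant records are excluded in this order:

1. participants whose fraction of retrospectively tagged meals exceeds
   ``retro_threshold`` (strict ``>``; exactly 50% is retained),
2. days whose total recorded duration (summed over sessions) is below
   ``min_day_hours``,
3. days without any meal events.

Watch-off (near-zero signal) segments are detected and logged for
observability but never auto-removed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .records import MOTION_COLUMNS, SensorDay, extract_meals

__all__ = ["CleaningReport", "clean_cohort", "detect_watch_off"]

REASON_RETRO = "retro>threshold"
REASON_SHORT = "duration<min_hours"
REASON_NO_MEALS = "no-meals"


@dataclasses.dataclass
class CleaningReport:
    """Bookkeeping of what was excluded and why."""

    excluded_participants: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    excluded_days: list[tuple[str, str, str]] = dataclasses.field(default_factory=list)
    retained: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    watch_off_segments: list[tuple[str, str, int, int]] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "excluded_participants": [list(x) for x in self.excluded_participants],
            "excluded_days": [list(x) for x in self.excluded_days],
            "retained": [list(x) for x in self.retained],
            "watch_off_segments": [list(x) for x in self.watch_off_segments],
        }


def detect_watch_off(
    day: SensorDay,
    window_seconds: float = 300.0,
    level: float = 1e-3,
) -> list[tuple[int, int]]:
    """(start_ts, end_ts) spans where the rolling mean of summed |accl|+|gyro|
    over ``window_seconds`` falls below ``level`` — the watch was likely off."""
    df = day.samples
    mag = np.abs(df[MOTION_COLUMNS].to_numpy()).sum(axis=1)
    # gravity keeps |accl| near 1 g when worn, so subtract nothing: worn
    # signal is O(1), watch-off signal is ~0
    rate = day.sampling_rate_hz
    if not np.isfinite(rate):
        return []
    w = max(int(window_seconds * rate), 1)
    if len(mag) < w:
        return []
    csum = np.concatenate(([0.0], np.cumsum(mag)))
    rolling = (csum[w:] - csum[:-w]) / w
    low = rolling < level
    if not low.any():
        return []
    ts = df["ts"].to_numpy()
    padded = np.concatenate(([False], low, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(ts[s]), int(ts[min(e - 1 + w, len(ts) - 1)])) for s, e in zip(starts, ends)]


def clean_cohort(
    days: list[SensorDay],
    retro_threshold: float = 0.5,
    min_day_hours: float = 3.0,
) -> tuple[list[SensorDay], CleaningReport]:
    """Apply the exclusion rules; returns retained days and the report."""
    report = CleaningReport()
    if not days:
        return [], report

    # rule 1: participant-level retrospective-meal fraction (over all days)
    meals_by_pid: dict[str, list] = {}
    meals_by_day: dict[tuple[str, str], list] = {}
    for day in days:
        meals = extract_meals(day)
        meals_by_day[day.key()] = meals
        meals_by_pid.setdefault(day.participant_id, []).extend(meals)
    excluded_pids = set()
    for pid, meals in meals_by_pid.items():
        if not meals:
            continue
        frac = sum(m.retrospective for m in meals) / len(meals)
        if frac > retro_threshold:
            excluded_pids.add(pid)
            report.excluded_participants.append(
                (pid, f"{REASON_RETRO} ({sum(m.retrospective for m in meals)}/{len(meals)})")
            )

    retained: list[SensorDay] = []
    for day in days:
        pid, date = day.key()
        if pid in excluded_pids:
            continue
        if day.total_duration_hours() < min_day_hours:
            report.excluded_days.append((pid, date, REASON_SHORT))
            continue
        if not meals_by_day[day.key()]:
            report.excluded_days.append((pid, date, REASON_NO_MEALS))
            continue
        for s, e in detect_watch_off(day):
            report.watch_off_segments.append((pid, date, s, e))
        report.retained.append((pid, date))
        retained.append(day)
    return retained, report
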