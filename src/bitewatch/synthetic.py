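"""Synthetic free-living sensor-day generator.

The real study data (wrist accelerometer + gyroscope at 50 Hz with eating
diaries) are private, so this module fabricates participant-days with the
statistical structure the downstream analysis assumes:

* recording days of ~8-15 h beginning between 7 and 9 AM and ending between
  7 and 9 PM, optionally split into several sessions;
* 1-7 diary-logged meals per day (mostly 1-4), with ~75% of meal durations
  under 20 minutes and start times peaking at breakfast/lunch/dinner;
* a periodic hand-to-mouth *bite* gesture during meals: a smooth 1-2.5 s
  rotation pulse on a participant-specific gyroscope axis with a correlated
  acceleration component, repeating every few seconds;
* band-limited baseline motion noise plus occasional non-eating arm-swing
  bursts (confusers) so the classification task is not trivially separable;
* retrospective diary tags, session breaks, and watch-off (near-zero
  signal) segments as injectable noncompliance artifacts.

Units: acceleration in g, rotation rate in rad/s; ``tod`` is seconds since
local midnight, ``ts`` epoch-milliseconds.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .records import (
    MOTION_COLUMNS,
    SCHEMA_COLUMNS,
    UTENSIL_COLUMNS,
    MealEvent,
    SensorDay,
)

__all__ = [
    "ConfigurationError",
    "GeneratorConfig",
    "ParticipantProfile",
    "SyntheticCohort",
    "generate_day",
    "inject_noncompliance",
    "generate_cohort",
]

NONCOMPLIANCE_KINDS = ("watch_off", "short_day", "all_retro", "no_meals")


class ConfigurationError(ValueError):
    """A generator configuration field is invalid."""


@dataclasses.dataclass
class GeneratorConfig:
    """Tunable knobs of the synthetic day generator.

    Defaults encode the free-living structure described above; all clock
    quantities are in seconds since midnight, durations in the stated unit.
    """

    sampling_rate_hz: float = 50.0
    day_start_window: tuple[float, float] = (7 * 3600.0, 9 * 3600.0)
    day_end_window: tuple[float, float] = (19 * 3600.0, 21 * 3600.0)
    #: probability of 1..7 meals per day (mode in the 1-4 range)
    meals_per_day_weights: tuple[float, ...] = (0.16, 0.27, 0.26, 0.17, 0.07, 0.04, 0.03)
    #: log-normal meal duration in minutes; ln N(log 13, 0.6) puts ~0.76 of
    #: the mass below 20 minutes
    meal_duration_log_mean: float = float(np.log(13.0))
    meal_duration_log_sd: float = 0.6
    meal_duration_min_minutes: float = 4.0
    meal_duration_max_minutes: float = 75.0
    #: (clock-seconds mean, sd, weight) per peak: breakfast, lunch, dinner
    meal_start_peaks: tuple[tuple[float, float, float], ...] = (
        (8.25 * 3600.0, 2700.0, 0.30),
        (12.5 * 3600.0, 2700.0, 0.40),
        (18.75 * 3600.0, 2700.0, 0.30),
    )
    bite_interval_seconds: tuple[float, float] = (4.0, 9.0)
    bite_duration_seconds: tuple[float, float] = (1.0, 2.5)
    #: peak rotation rate of a bite pulse, rad/s
    gesture_amplitude: float = 2.0
    #: acceleration coupled to a bite pulse, as a fraction of gesture_amplitude (in g per rad/s)
    accl_gesture_gain: float = 0.06
    #: standard deviation of baseline gyroscope noise, rad/s
    baseline_noise_scale: float = 0.25
    #: non-eating arm-swing bursts per hour
    confuser_rate_per_hour: float = 5.0
    session_break_probability: float = 0.3
    retro_fraction: float = 0.10
    watch_off_probability: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be positive")
        for name in ("session_break_probability", "retro_fraction", "watch_off_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if len(self.meals_per_day_weights) != 7 or min(self.meals_per_day_weights) < 0:
            raise ConfigurationError("meals_per_day_weights must be 7 non-negative weights (1..7 meals)")
        if sum(self.meals_per_day_weights) <= 0:
            raise ConfigurationError("meals_per_day_weights must have positive mass")
        for name in ("bite_interval_seconds", "bite_duration_seconds", "day_start_window", "day_end_window"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"{name} must be a positive (lo, hi) range")
        if self.meal_duration_min_minutes <= 0 or self.meal_duration_max_minutes < self.meal_duration_min_minutes:
            raise ConfigurationError("meal duration bounds must be positive and ordered")
        if self.gesture_amplitude <= 0 or self.baseline_noise_scale <= 0:
            raise ConfigurationError("gesture_amplitude and baseline_noise_scale must be positive")


@dataclasses.dataclass
class ParticipantProfile:
    """Per-individual gesture kinematics; jittered so individuals differ."""

    amplitude_scale: float = 1.0
    interval_scale: float = 1.0
    #: unit 3-vector: dominant rotation axis of the bite gesture
    gyro_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    accl_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)

    @staticmethod
    def sample(rng: np.random.Generator) -> "ParticipantProfile":
        g = _random_unit(rng)
        a = _random_unit(rng)
        return ParticipantProfile(
            amplitude_scale=float(rng.uniform(0.75, 1.35)),
            interval_scale=float(rng.uniform(0.8, 1.3)),
            gyro_axis=tuple(g),
            accl_axis=tuple(a),
        )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-9:  # pragma: no cover - astronomically unlikely
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


# ---------------------------------------------------------------------------
# day generation
# ---------------------------------------------------------------------------

def _sample_meals(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    day_start: float,
    day_end: float,
    n_meals: int | None = None,
) -> list[tuple[float, float]]:
    """Non-overlapping (start_tod, end_tod) meal intervals inside the day."""
    if n_meals is None:
        w = np.asarray(cfg.meals_per_day_weights, dtype=float)
        n_meals = int(rng.choice(np.arange(1, 8), p=w / w.sum()))
    peaks = cfg.meal_start_peaks
    pw = np.array([p[2] for p in peaks], dtype=float)
    pw = pw / pw.sum()
    intervals: list[tuple[float, float]] = []
    for _ in range(n_meals):
        dur = float(
            np.clip(
                np.exp(rng.normal(cfg.meal_duration_log_mean, cfg.meal_duration_log_sd)),
                cfg.meal_duration_min_minutes,
                cfg.meal_duration_max_minutes,
            )
            * 60.0
        )
        placed = False
        for _try in range(200):
            k = int(rng.choice(len(peaks), p=pw))
            start = float(rng.normal(peaks[k][0], peaks[k][1]))
            if not (day_start + 300.0 <= start and start + dur <= day_end - 300.0):
                continue
            # 10-minute separation between meals
            if all(start + dur + 600.0 <= s or e + 600.0 <= start for s, e in intervals):
                intervals.append((start, start + dur))
                placed = True
                break
        if not placed:
            continue  # day too crowded; accept fewer meals
    intervals.sort()
    return intervals


def _free_segments(
    day_start: float, day_end: float, occupied: list[tuple[float, float]], margin: float
) -> list[tuple[float, float]]:
    """Maximal sub-intervals of [day_start, day_end] clear of occupied+-margin."""
    edges = [(max(day_start, s - margin), min(day_end, e + margin)) for s, e in sorted(occupied)]
    free = []
    cursor = day_start
    for s, e in edges:
        if s > cursor:
            free.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < day_end:
        free.append((cursor, day_end))
    return free


def _place_in_free(
    rng: np.random.Generator,
    free: list[tuple[float, float]],
    duration: float,
) -> tuple[float, float] | None:
    fits = [(s, e) for s, e in free if e - s >= duration]
    if not fits:
        return None
    lens = np.array([e - s - duration for s, e in fits]) + 1.0
    k = int(rng.choice(len(fits), p=lens / lens.sum()))
    s, e = fits[k]
    start = float(rng.uniform(s, e - duration))
    return (start, start + duration)


def _bandlimited_noise(rng: np.random.Generator, n: int, rate: float, scale: float, ncols: int) -> np.ndarray:
    """Low-pass filtered Gaussian noise with empirical SD equal to ``scale``."""
    white = rng.standard_normal((n, ncols))
    if n < 16:
        return white * scale
    wn = min(0.9, 3.0 / rate)  # ~1.5 Hz cutoff at 50 Hz, clipped below Nyquist
    b, a = _sig.butter(2, wn)
    x = _sig.lfilter(b, a, white, axis=0)
    sd = x.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return x / sd * scale


def generate_day(
    participant_id: str,
    date: _dt.date,
    config: GeneratorConfig,
    rng_state: np.random.Generator,
    profile: ParticipantProfile | None = None,
    n_meals: int | None = None,
) -> tuple[SensorDay, list[MealEvent]]:
    """Generate one labeled participant-day.

    Returns the :class:`SensorDay` together with its ground-truth meal list
    (the truth sidecar). Deterministic given the generator state.
    """
    config.validate()
    rng = rng_state
    if profile is None:
        profile = ParticipantProfile.sample(rng)
    rate = config.sampling_rate_hz
    dt = 1.0 / rate

    day_start = float(rng.uniform(*config.day_start_window))
    day_end = float(rng.uniform(*config.day_end_window))
    meals = _sample_meals(rng, config, day_start, day_end, n_meals=n_meals)
    retro_flags = [bool(rng.random() < config.retro_fraction) for _ in meals]

    # session gaps: 1-3 gaps of 5-40 minutes, clear of meals (1-min margin)
    gaps: list[tuple[float, float]] = []
    if rng.random() < config.session_break_probability:
        for _ in range(int(rng.integers(1, 4))):
            dur = float(rng.uniform(300.0, 2400.0))
            free = _free_segments(day_start + 600.0, day_end - 600.0, meals + gaps, margin=60.0)
            seg = _place_in_free(rng, free, dur)
            if seg is not None:
                gaps.append(seg)
    gaps.sort()

    # watch-off segment: near-zero signal, clear of meals, inside a session
    watch_off: tuple[float, float] | None = None
    if rng.random() < config.watch_off_probability:
        dur = float(rng.uniform(600.0, 2400.0))
        free = _free_segments(day_start, day_end, meals + gaps, margin=60.0)
        watch_off = _place_in_free(rng, free, dur)

    n = int(round((day_end - day_start) * rate))
    tod = day_start + np.arange(n) * dt

    # ---- motion channels -------------------------------------------------
    gyro = _bandlimited_noise(rng, n, rate, config.baseline_noise_scale, 3)
    accl = _bandlimited_noise(rng, n, rate, config.baseline_noise_scale / 5.0, 3)
    accl[:, 2] -= 1.0  # gravity along -z in watch frame, in g

    gyro_axis = np.asarray(profile.gyro_axis)
    accl_axis = np.asarray(profile.accl_axis)

    def _add_pulse(t0: float, dur: float, amp: float, axis: np.ndarray, chans: np.ndarray, gain: float = 1.0) -> None:
        i0 = int(np.searchsorted(tod, t0))
        i1 = int(np.searchsorted(tod, t0 + dur))
        if i1 <= i0:
            return
        phase = (tod[i0:i1] - t0) / dur
        pulse = amp * gain * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
        chans[i0:i1] += pulse[:, None] * axis[None, :]

    # bites: periodic smooth rotation pulses during meals
    for (ms, me) in meals:
        t = ms + float(rng.uniform(1.0, 3.0))
        while t < me - 0.5:
            dur = float(rng.uniform(*config.bite_duration_seconds))
            amp = config.gesture_amplitude * profile.amplitude_scale * float(rng.uniform(0.85, 1.15))
            _add_pulse(t, min(dur, me - t), amp, gyro_axis, gyro)
            _add_pulse(t, min(dur, me - t), amp, accl_axis, accl, gain=config.accl_gesture_gain)
            t += float(rng.uniform(*config.bite_interval_seconds)) * profile.interval_scale

    # confusers: non-eating arm-swing bursts anywhere in the day
    n_conf = int(rng.poisson(config.confuser_rate_per_hour * (day_end - day_start) / 3600.0))
    for _ in range(n_conf):
        t0 = float(rng.uniform(day_start, day_end - 20.0))
        dur = float(rng.uniform(5.0, 20.0))
        freq = float(rng.uniform(0.3, min(1.2, 0.45 * rate)))
        axis = _random_unit(rng)
        amp = 0.6 * config.gesture_amplitude * float(rng.uniform(0.5, 1.2))
        i0 = int(np.searchsorted(tod, t0))
        i1 = int(np.searchsorted(tod, t0 + dur))
        if i1 <= i0:
            continue
        tt = tod[i0:i1] - t0
        env = np.sin(np.pi * tt / dur) ** 2
        burst = amp * env * np.sin(2.0 * np.pi * freq * tt)
        gyro[i0:i1] += burst[:, None] * axis[None, :]
        accl[i0:i1] += 0.04 * burst[:, None] * np.roll(axis, 1)[None, :]

    if watch_off is not None:
        i0 = int(np.searchsorted(tod, watch_off[0]))
        i1 = int(np.searchsorted(tod, watch_off[1]))
        tiny = config.baseline_noise_scale / 1000.0
        gyro[i0:i1] = rng.standard_normal((i1 - i0, 3)) * tiny
        accl[i0:i1] = rng.standard_normal((i1 - i0, 3)) * tiny

    # ---- labels ----------------------------------------------------------
    tag = np.zeros(n, dtype=np.int64)
    tag_retro = np.zeros(n, dtype=np.int64)
    utensil = {c: np.zeros(n, dtype=np.int64) for c in UTENSIL_COLUMNS}
    meal_utensils: list[frozenset[str]] = []
    for (ms, me), retro in zip(meals, retro_flags):
        i0, i1 = int(np.searchsorted(tod, ms)), int(np.searchsorted(tod, me))
        tag[i0:i1] = 1
        if retro:
            tag_retro[i0:i1] = 1
        n_ut = int(rng.integers(1, 3))
        chosen = rng.choice(
            UTENSIL_COLUMNS,
            size=n_ut,
            replace=False,
            p=np.array([0.25, 0.1, 0.2, 0.15, 0.05, 0.25]),
        )
        for c in chosen:
            utensil[c][i0:i1] = 1
        meal_utensils.append(frozenset(str(c) for c in chosen))
    tag_timely = tag * (1 - tag_retro)

    # ---- drop session gaps, assign sesid --------------------------------
    keep = np.ones(n, dtype=bool)
    for (gs, ge) in gaps:
        keep &= ~((tod >= gs) & (tod < ge))
    tod_k = tod[keep]
    sesid = np.zeros(len(tod_k), dtype=np.int64)
    if len(tod_k) > 1:
        sesid[1:] = np.cumsum(np.diff(tod_k) > 1.5 * dt + 1.0)

    midnight_ms = int(
        _dt.datetime(date.year, date.month, date.day, tzinfo=_dt.timezone.utc).timestamp() * 1000
    )
    ts = midnight_ms + np.round(tod_k * 1000.0).astype(np.int64)

    df = pd.DataFrame(
        {
            "ts": ts,
            "tod": tod_k,
            "sesid": sesid,
            "accl_x": accl[keep, 0],
            "accl_y": accl[keep, 1],
            "accl_z": accl[keep, 2],
            "gyro_x": gyro[keep, 0],
            "gyro_y": gyro[keep, 1],
            "gyro_z": gyro[keep, 2],
            **{c: utensil[c][keep] for c in UTENSIL_COLUMNS},
            "tag": tag[keep],
            "tagTimely": tag_timely[keep],
            "tagRetro": tag_retro[keep],
        },
        columns=SCHEMA_COLUMNS,
    )
    day = SensorDay(participant_id, date, df)

    truth = [
        MealEvent(
            participant_id=participant_id,
            date=date,
            start_ts=midnight_ms + int(round(ms * 1000.0)),
            end_ts=midnight_ms + int(round(me * 1000.0)),
            retrospective=retro,
            utensils=ut,
        )
        for (ms, me), retro, ut in zip(meals, retro_flags, meal_utensils)
    ]
    return day, truth


# ---------------------------------------------------------------------------
# noncompliance injection
# ---------------------------------------------------------------------------

def inject_noncompliance(
    day: SensorDay, kind: str, rng_state: np.random.Generator
) -> SensorDay:
    """Return a copy of ``day`` exhibiting a named noncompliance artifact.

    watch_off
        A contiguous >=10-minute segment with all six motion channels near
        zero (the participant took the watch off without stopping recording).
    short_day
        Total recorded duration truncated below 3 hours.
    all_retro
        Every meal marked retrospectively tagged.
    no_meals
        All diary tags stripped.
    """
    if kind not in NONCOMPLIANCE_KINDS:
        raise ValueError(f"unknown noncompliance kind {kind!r}; expected one of {NONCOMPLIANCE_KINDS}")
    df = day.samples.copy()
    rng = rng_state
    if kind == "watch_off":
        n = len(df)
        rate = day.sampling_rate_hz
        seg_rows = max(int(np.ceil(12 * 60 * rate)), 2)  # 12 min > the 10-min floor
        if seg_rows >= n:
            i0, i1 = 0, n
        else:
            tag = df["tag"].to_numpy()
            # prefer a start where the segment avoids meals
            candidates = np.flatnonzero(
                np.convolve(tag, np.ones(seg_rows, dtype=int), mode="valid") == 0
            )
            i0 = int(rng.choice(candidates)) if len(candidates) else int(rng.integers(0, n - seg_rows))
            i1 = i0 + seg_rows
        tiny = 1e-5
        for c in MOTION_COLUMNS:
            df.loc[df.index[i0:i1], c] = rng.standard_normal(i1 - i0) * tiny
    elif kind == "short_day":
        ts = df["ts"].to_numpy()
        cutoff = ts[0] + int(2.5 * 3.6e6)  # keep the first 2.5 hours
        df = df[ts < cutoff].reset_index(drop=True)
    elif kind == "all_retro":
        tag = df["tag"].to_numpy()
        df["tagRetro"] = tag
        df["tagTimely"] = 0
    elif kind == "no_meals":
        df["tag"] = 0
        df["tagTimely"] = 0
        df["tagRetro"] = 0
        for c in UTENSIL_COLUMNS:
            df[c] = 0
    return SensorDay(day.participant_id, day.date, df)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticCohort:
    """A generated cohort: days plus the ground-truth meal sidecar."""

    participants: list[str]
    days: dict[str, list[SensorDay]]
    truth: dict[tuple[str, str], list[MealEvent]]
    profiles: dict[str, ParticipantProfile]
    config: GeneratorConfig

    def all_days(self) -> list[SensorDay]:
        return [d for pid in self.participants for d in self.days[pid]]

    def all_meals(self) -> list[MealEvent]:
        return [m for meals in self.truth.values() for m in meals]

    def meals_for(self, day: SensorDay) -> list[MealEvent]:
        return self.truth.get(day.key(), [])


def generate_cohort(
    n_participants: int,
    days_per_participant: int,
    config: GeneratorConfig,
    seed: int | None = None,
    start_date: _dt.date = _dt.date(2021, 5, 3),
    profiles: dict[str, ParticipantProfile] | None = None,
) -> SyntheticCohort:
    """Generate a multi-participant cohort with per-individual gesture jitter."""
    if n_participants < 1 or days_per_participant < 1:
        raise ConfigurationError("cohort sizes must be >= 1")
    config.validate()
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    pids = [f"P{i + 1:02d}" for i in range(n_participants)]
    p_seqs = root.spawn(n_participants)
    days: dict[str, list[SensorDay]] = {}
    truth: dict[tuple[str, str], list[MealEvent]] = {}
    out_profiles: dict[str, ParticipantProfile] = {}
    for pid, seq in zip(pids, p_seqs):
        prof_rng = np.random.Generator(np.random.PCG64(seq))
        profile = (
            profiles[pid]
            if profiles is not None and pid in profiles
            else ParticipantProfile.sample(prof_rng)
        )
        out_profiles[pid] = profile
        days[pid] = []
        for d, dseq in enumerate(seq.spawn(days_per_participant)):
            date = start_date + _dt.timedelta(days=d)
            rng = np.random.Generator(np.random.PCG64(dseq))
            day, meals = generate_day(pid, date, config, rng, profile=profile)
            days[pid].append(day)
            truth[day.key()] = meals
    return SyntheticCohort(pids, days, truth, out_profiles, config)
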