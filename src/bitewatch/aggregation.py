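"""Meal-level aggregation, call alarms, and hourly false-positive rate.

*Meal scoring*: each diary meal gets the mean of the window scores whose
midpoints fall inside it; an equal number of length-matched negative
regions, sampled away from meals and their 10-minute buffers, gets the same
treatment. Meal-level AUC/F1 compare these region means.

*Call alarms*: scores on a 10-second-step window grid; a window is positive
when its score exceeds ``score_cutoff`` and a *call* is raised whenever a
horizon-length span (5 or 10 minutes) contains strictly more than
``n_windows_to_call`` positive windows. Per-meal recall is the fraction of
meals with at least one call within the first horizon after meal start.

*False positives per hour*: distinct false call regions on meal-free time
(consecutive qualifying spans closer than one horizon merge into a single
region) divided by the evaluated hours. One hour of 10-second-step windows
contributes 360 candidate chunks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .records import MealEvent

__all__ = [
    "RegionScore",
    "CallConfig",
    "sample_matched_negative_regions",
    "score_meals",
    "detect_calls",
    "meal_call_recall",
    "false_positive_rate",
    "candidate_chunks",
]

#: meals closer than this to a negative region disqualify it (ms)
MEAL_BUFFER_MS = 10 * 60 * 1000


@dataclasses.dataclass
class RegionScore:
    """Aggregated score of one region (a meal or a matched negative)."""

    start_ts: int
    end_ts: int
    is_meal: bool
    mean_score: float
    n_windows: int
    participant_id: str = ""
    date: str = ""


@dataclasses.dataclass
class CallConfig:
    """Alarm parameters: 10-s step, >0.3 score, >3 windows per horizon."""

    step_seconds: float = 10.0
    score_cutoff: float = 0.3
    n_windows_to_call: int = 3
    horizon_minutes: float = 10.0

    def validate(self) -> None:
        if not 0.0 < self.score_cutoff < 1.0:
            raise ValueError("score_cutoff must be in (0,1)")
        if self.n_windows_to_call < 1:
            raise ValueError("n_windows_to_call must be >= 1")
        if self.step_seconds <= 0 or self.horizon_minutes <= 0:
            raise ValueError("step and horizon must be positive")

    @property
    def horizon_ms(self) -> int:
        return int(self.horizon_minutes * 60 * 1000)

    @property
    def windows_per_horizon(self) -> int:
        return int(self.horizon_minutes * 60 / self.step_seconds)


def candidate_chunks(total_seconds: float, step_seconds: float = 10.0) -> int:
    """Number of candidate detection chunks when sliding at ``step_seconds``."""
    return int(total_seconds // step_seconds)


# ---------------------------------------------------------------------------
# whole-meal scoring
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"scored-window table missing column(s): {missing}")


def sample_matched_negative_regions(
    meals: list[MealEvent],
    day_bounds: dict[tuple[str, str], tuple[int, int]],
    rng_state: np.random.Generator,
    min_meal_seconds: float = 180.0,
    buffer_ms: int = MEAL_BUFFER_MS,
    extra_avoid: list[MealEvent] | None = None,
    margin_ms: int = 150_000,
) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """Per-day negative regions with the same length multiset as the meals.

    Pure geometry — no scores needed — so callers can sample the regions
    first and then score only the spans they need. ``day_bounds`` maps
    (participant, date) to the day's (first_ts, last_ts) or, for days with
    several sessions, a list of per-session (first_ts, last_ts) intervals —
    regions are then placed inside a single recorded session, trimmed by
    ``margin_ms`` at each end so window midpoints exist throughout.
    Regions avoid every meal with a ``buffer_ms`` margin and avoid each
    other when possible; ``extra_avoid`` lists additional events (e.g.
    retrospective meals) that negative time must also avoid without
    entering the length multiset. Raises listing any unmatchable meal.
    """
    by_day: dict[tuple[str, str], list[MealEvent]] = {}
    for m in meals:
        if m.duration_seconds < min_meal_seconds:
            continue
        by_day.setdefault((m.participant_id, m.date.isoformat()), []).append(m)
    avoid_by_day: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for m in extra_avoid or []:
        avoid_by_day.setdefault((m.participant_id, m.date.isoformat()), []).append(
            (m.start_ts, m.end_ts)
        )
    out: dict[tuple[str, str], list[tuple[int, int]]] = {}
    unmatchable: list[str] = []
    for key, day_meals in by_day.items():
        if key not in day_bounds:
            unmatchable.append(f"{key[0]}/{key[1]} (no day bounds)")
            continue
        bounds = day_bounds[key]
        if isinstance(bounds, tuple):
            bounds = [bounds]
        intervals = [
            (lo + margin_ms, hi - margin_ms) for lo, hi in bounds if hi - lo > 2 * margin_ms
        ]
        meal_iv = [(m.start_ts, m.end_ts) for m in day_meals] + avoid_by_day.get(key, [])
        chosen: list[tuple[int, int]] = []
        for m in day_meals:
            L = m.end_ts - m.start_ts
            fits = [(lo, hi) for lo, hi in intervals if hi - lo > L]
            placed = False
            for allow_overlap in (False, True):
                for _ in range(200):
                    if not fits:
                        break
                    lo, hi = fits[int(rng_state.integers(len(fits)))]
                    s = int(rng_state.integers(lo, hi - L))
                    e = s + L
                    if any(s < ie + buffer_ms and e > is_ - buffer_ms for is_, ie in meal_iv):
                        continue
                    if not allow_overlap and any(s < ce and e > cs for cs, ce in chosen):
                        continue
                    chosen.append((s, e))
                    placed = True
                    break
                if placed:
                    break
            if not placed:
                unmatchable.append(f"{key[0]}/{key[1]} meal@{m.start_ts}")
        out[key] = chosen
    if unmatchable:
        raise ValueError("no negative region fits: " + "; ".join(unmatchable))
    return out


def score_meals(
    meals: list[MealEvent],
    window_scores: pd.DataFrame,
    rng_state: np.random.Generator,
    window_seconds: float = 300.0,
    min_meal_seconds: float = 180.0,
    buffer_ms: int = MEAL_BUFFER_MS,
    negative_regions: dict[tuple[str, str], list[tuple[int, int]]] | None = None,
) -> list[RegionScore]:
    """Positive RegionScores for meals plus length-matched negatives.

    ``window_scores`` needs columns (participant, date, start_ts, score);
    a window belongs to a region when its midpoint lies inside it. Negative
    regions are drawn per day with the same length multiset as that day's
    meals, avoiding all meals with a 10-minute buffer at each end; callers
    may pass pre-sampled ``negative_regions`` (from
    :func:`sample_matched_negative_regions`) instead.
    Raises with the list of unmatchable meals if a day lacks negative time.
    """
    _require_columns(window_scores, ("participant", "date", "start_ts", "score"))
    half_w = int(window_seconds * 500)  # ms
    regions: list[RegionScore] = []
    unmatchable: list[str] = []
    by_day: dict[tuple[str, str], list[MealEvent]] = {}
    for m in meals:
        if m.duration_seconds < min_meal_seconds:
            continue
        by_day.setdefault((m.participant_id, m.date.isoformat()), []).append(m)

    grouped = dict(tuple(window_scores.groupby(["participant", "date"], sort=False)))
    for (pid, date), day_meals in by_day.items():
        day_df = grouped.get((pid, date))
        if day_df is None or len(day_df) == 0:
            unmatchable.extend(f"{pid}/{date} (no scored windows)" for _ in day_meals)
            continue
        mid = day_df["start_ts"].to_numpy() + half_w
        sc = day_df["score"].to_numpy()
        order = np.argsort(mid)
        mid, sc = mid[order], sc[order]
        day_lo, day_hi = int(mid[0]), int(mid[-1])
        meal_iv = [(m.start_ts, m.end_ts) for m in day_meals]

        def region_mean(lo: int, hi: int) -> tuple[float, int]:
            i0, i1 = np.searchsorted(mid, (lo, hi))
            if i1 <= i0:
                return float("nan"), 0
            return float(sc[i0:i1].mean()), int(i1 - i0)

        chosen_negatives: list[tuple[int, int]] = []
        for m in day_meals:
            mean, nw = region_mean(m.start_ts, m.end_ts)
            if nw == 0:
                unmatchable.append(f"{pid}/{date} meal@{m.start_ts} (no windows inside)")
                continue
            regions.append(
                RegionScore(m.start_ts, m.end_ts, True, mean, nw, pid, date)
            )
            if negative_regions is not None:
                continue
            # matched negative of the same length
            L = m.end_ts - m.start_ts
            placed = False
            for allow_overlap in (False, True):
                for _ in range(200):
                    s = int(rng_state.integers(day_lo, max(day_lo + 1, day_hi - L)))
                    e = s + L
                    if any(s < ie + buffer_ms and e > is_ - buffer_ms for is_, ie in meal_iv):
                        continue
                    if not allow_overlap and any(
                        s < ce and e > cs for cs, ce in chosen_negatives
                    ):
                        continue
                    nmean, nnw = region_mean(s, e)
                    if nnw == 0:
                        continue
                    chosen_negatives.append((s, e))
                    regions.append(RegionScore(s, e, False, nmean, nnw, pid, date))
                    placed = True
                    break
                if placed:
                    break
            if not placed:
                unmatchable.append(f"{pid}/{date} meal@{m.start_ts} (no negative region fits)")
        if negative_regions is not None:
            for s, e in negative_regions.get((pid, date), []):
                nmean, nnw = region_mean(s, e)
                if nnw == 0:
                    unmatchable.append(f"{pid}/{date} negative@{s} (no windows inside)")
                    continue
                regions.append(RegionScore(s, e, False, nmean, nnw, pid, date))
    if unmatchable:
        raise ValueError("could not score/match meals: " + "; ".join(unmatchable))
    return regions


# ---------------------------------------------------------------------------
# call alarms
# ---------------------------------------------------------------------------

def _qualifying_mask(scores: np.ndarray, cfg: CallConfig) -> np.ndarray:
    """Per-window flag: the trailing horizon ending here holds > N positives."""
    above = (np.asarray(scores) > cfg.score_cutoff).astype(np.int64)
    w = max(cfg.windows_per_horizon, 1)
    cs = np.concatenate(([0], np.cumsum(above)))
    lo = np.maximum(np.arange(len(above)) + 1 - w, 0)
    counts = cs[1:] - cs[lo]
    return counts > cfg.n_windows_to_call


def detect_calls(stream_scores: pd.DataFrame, cfg: CallConfig) -> np.ndarray:
    """Timestamps (window start_ts) at which a call is raised.

    ``stream_scores`` is one contiguous stream of windows at
    ``cfg.step_seconds`` spacing with columns (start_ts, score), sorted by
    time. A call fires at every window whose trailing horizon contains more
    than ``n_windows_to_call`` above-cutoff windows.
    """
    cfg.validate()
    _require_columns(stream_scores, ("start_ts", "score"))
    df = stream_scores.sort_values("start_ts")
    mask = _qualifying_mask(df["score"].to_numpy(), cfg)
    return df["start_ts"].to_numpy()[mask]


def meal_call_recall(
    meals: list[MealEvent],
    stream_scores: pd.DataFrame,
    cfg: CallConfig,
) -> float:
    """Fraction of meals with a call inside the first horizon after meal start.

    For each meal, the windows starting within ``horizon`` of the meal start
    are examined; the meal is recalled when strictly more than
    ``n_windows_to_call`` of them exceed the cutoff.
    """
    cfg.validate()
    _require_columns(stream_scores, ("participant", "date", "start_ts", "score"))
    if not meals:
        return float("nan")
    grouped = dict(tuple(stream_scores.groupby(["participant", "date"], sort=False)))
    hits = 0
    for m in meals:
        df = grouped.get((m.participant_id, m.date.isoformat()))
        if df is None:
            continue
        ts = df["start_ts"].to_numpy()
        sc = df["score"].to_numpy()
        sel = (ts >= m.start_ts) & (ts <= m.start_ts + cfg.horizon_ms)
        if int((sc[sel] > cfg.score_cutoff).sum()) > cfg.n_windows_to_call:
            hits += 1
    return hits / len(meals)


def false_positive_rate(
    negative_stream_scores: pd.DataFrame | list[pd.DataFrame],
    cfg: CallConfig,
    total_hours: float,
    n_positive_regions: int = 0,
) -> float:
    """Distinct false call regions per hour on meal-free streams.

    A false region is one horizon-length interval of call activity: the
    calls are covered greedily by horizon-length spans (first call opens a
    span, every call inside it belongs to the same region), so one isolated
    burst counts once and the count is monotone nonincreasing in the score
    cutoff. ``n_positive_regions`` supports the literal
    (false regions - positive regions)/hours bookkeeping; on purely
    negative streams it stays 0 and the subtraction is vacuous.
    """
    cfg.validate()
    if total_hours <= 0:
        raise ValueError("total_hours must be positive")
    streams = (
        negative_stream_scores
        if isinstance(negative_stream_scores, list)
        else [negative_stream_scores]
    )
    n_regions = 0
    for df in streams:
        call_ts = detect_calls(df, cfg)
        current_end = -np.inf
        for t in call_ts:
            if t > current_end:
                n_regions += 1
                current_end = t + cfg.horizon_ms
    return max(n_regions - n_positive_regions, 0) / total_hours
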