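"""Fixed-length sliding windows with 1/0/-1 labels and oversampling.

Days are cut into ``window_seconds`` windows advanced by ``step_seconds``
from the first sample of the day across the concatenated sample timeline.
A window is labeled

* ``1``  if strictly more than half of its in-window time is tagged mealtime,
* ``-1`` if it (a) spans two sessions, (b) overlaps any retrospectively
  tagged sample, or (c) overlaps a meal shorter than ``min_meal_seconds`` —
  these are excluded from both training and evaluation but retained for
  auditability,
* ``0``  otherwise.

The -1 conditions take precedence over the mealtime-majority rule, so a
retrospective meal's windows are excluded rather than counted positive.

Training sets are balanced by oversampling: positives are drawn with
replacement until they match the negatives; evaluation keeps the original
class imbalance.

Window channel matrices are materialized lazily from per-day arrays, so a
cohort of hundreds of thousands of windows stores each day's signal once.
"""

from __future__ import annotations

import dataclasses
import warnings

import h5py
import numpy as np
import pandas as pd

from .records import MOTION_COLUMNS, SensorDay

__all__ = [
    "LabeledWindow",
    "WindowSet",
    "make_windows",
    "oversample",
]

_MODALITY_SLICES = {
    "accl": slice(0, 3),
    "gyro": slice(3, 6),
    "both": slice(0, 6),
    "all": slice(0, 6),
}

INDEX_COLUMNS = ["participant", "date", "day_key", "start_row", "start_ts", "label", "meal_id"]


@dataclasses.dataclass
class LabeledWindow:
    """A materialized window: (window_rows x n_channels) matrix plus label."""

    participant_id: str
    date: str
    start_ts: int
    channels: np.ndarray
    label: int
    meal_id: int | None = None


class WindowSet:
    """A collection of windows referencing shared per-day channel arrays.

    ``index`` has one row per window (participant, date, day_key, start_row,
    start_ts, label, meal_id); ``days`` maps day_key to the day's
    (n_rows x 6) motion-channel matrix in schema order (accl_xyz, gyro_xyz).
    """

    def __init__(
        self,
        index: pd.DataFrame,
        days: dict[str, np.ndarray],
        window_rows: int,
        window_seconds: float,
        step_seconds: float,
    ) -> None:
        self.index = index.reset_index(drop=True)
        self.days = days
        self.window_rows = int(window_rows)
        self.window_seconds = float(window_seconds)
        self.step_seconds = float(step_seconds)

    # -- bookkeeping -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.index)

    @property
    def labels(self) -> np.ndarray:
        return self.index["label"].to_numpy()

    @property
    def positives(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def negatives(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def excluded(self) -> int:
        return int((self.labels == -1).sum())

    # -- access ----------------------------------------------------------

    def channels(self, i: int, modality: str = "all") -> np.ndarray:
        row = self.index.iloc[i]
        day = self.days[row["day_key"]]
        s = int(row["start_row"])
        return day[s : s + self.window_rows, _MODALITY_SLICES[modality]]

    def get(self, i: int) -> LabeledWindow:
        row = self.index.iloc[i]
        mid = row["meal_id"]
        return LabeledWindow(
            participant_id=row["participant"],
            date=row["date"],
            start_ts=int(row["start_ts"]),
            channels=self.channels(i).copy(),
            label=int(row["label"]),
            meal_id=None if mid < 0 else int(mid),
        )

    def batch(self, indices: np.ndarray, modality: str = "all") -> np.ndarray:
        """Materialize windows ``indices`` as a (B, window_rows, C) float32 array."""
        sl = _MODALITY_SLICES[modality]
        rows = self.index.iloc[indices]
        n_ch = sl.stop - sl.start
        out = np.empty((len(rows), self.window_rows, n_ch), dtype=np.float32)
        keys = rows["day_key"].to_numpy()
        starts = rows["start_row"].to_numpy()
        for j, (k, s) in enumerate(zip(keys, starts)):
            out[j] = self.days[k][s : s + self.window_rows, sl]
        return out

    # -- derivation ------------------------------------------------------

    def subset(self, sel: np.ndarray) -> "WindowSet":
        """New WindowSet over a boolean mask or integer positions; days are shared."""
        idx = self.index.iloc[sel] if np.asarray(sel).dtype != bool else self.index[sel]
        return WindowSet(idx, self.days, self.window_rows, self.window_seconds, self.step_seconds)

    def labeled(self) -> "WindowSet":
        """Drop the -1 (excluded) windows."""
        return self.subset(self.labels >= 0)

    def for_participants(self, pids) -> "WindowSet":
        return self.subset(self.index["participant"].isin(list(pids)).to_numpy())

    @staticmethod
    def concat(sets: list["WindowSet"]) -> "WindowSet":
        if not sets:
            raise ValueError("cannot concatenate zero WindowSets")
        wr = {s.window_rows for s in sets}
        if len(wr) != 1:
            raise ValueError("WindowSets have differing window_rows")
        days: dict[str, np.ndarray] = {}
        for s in sets:
            days.update(s.days)
        index = pd.concat([s.index for s in sets], ignore_index=True)
        first = sets[0]
        return WindowSet(index, days, first.window_rows, first.window_seconds, first.step_seconds)


def _short_meal_rows(tag: np.ndarray, ts: np.ndarray, min_meal_seconds: float) -> np.ndarray:
    """Boolean mask of rows belonging to a tag-run shorter than the floor."""
    mask = np.zeros(len(tag), dtype=bool)
    padded = np.concatenate(([0], tag, [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        if (ts[e - 1] - ts[s]) / 1000.0 < min_meal_seconds:
            mask[s:e] = True
    return mask


def make_windows(
    day: SensorDay,
    window_seconds: float = 300.0,
    step_seconds: float = 20.0,
    min_meal_seconds: float = 180.0,
) -> WindowSet:
    """Cut one day into labeled windows (see module docstring for the rules).

    A day shorter than one window yields an empty set. Window starts advance
    by ``step_seconds`` worth of samples over the concatenated row timeline;
    windows that straddle a session gap are labeled -1 by rule (a).
    """
    if window_seconds <= 0 or step_seconds <= 0:
        raise ValueError("window_seconds and step_seconds must be positive")
    df = day.samples
    n = len(df)
    rate = day.sampling_rate_hz
    if not np.isfinite(rate):
        rate = 0.0
    wrows = int(round(window_seconds * rate))
    srows = max(int(round(step_seconds * rate)), 1)
    day_key = "/".join(day.key())
    channels = df[MOTION_COLUMNS].to_numpy(dtype=np.float32)
    empty = pd.DataFrame(columns=INDEX_COLUMNS)
    if wrows <= 0 or n < wrows:
        return WindowSet(empty, {day_key: channels}, max(wrows, 0), window_seconds, step_seconds)

    starts = np.arange(0, n - wrows + 1, srows)
    ends = starts + wrows
    tag = df["tag"].to_numpy()
    retro = df["tagRetro"].to_numpy()
    sesid = df["sesid"].to_numpy()
    ts = df["ts"].to_numpy()

    cs_tag = np.concatenate(([0], np.cumsum(tag)))
    cs_retro = np.concatenate(([0], np.cumsum(retro)))
    short = _short_meal_rows(tag, ts, min_meal_seconds)
    cs_short = np.concatenate(([0], np.cumsum(short)))

    tag_rows = cs_tag[ends] - cs_tag[starts]
    has_retro = (cs_retro[ends] - cs_retro[starts]) > 0
    has_short = (cs_short[ends] - cs_short[starts]) > 0
    cross_session = sesid[starts] != sesid[ends - 1]

    labels = np.where(tag_rows * 2 > wrows, 1, 0)
    labels[cross_session | has_retro | has_short] = -1

    # meal id: index (in row order) of the tag-run covering the window middle
    run_id = np.cumsum(np.concatenate(([tag[0]], (np.diff(tag) == 1).astype(int)))) - 1
    mids = starts + wrows // 2
    meal_ids = np.where((labels == 1) & (tag[mids] == 1), run_id[mids], -1)

    index = pd.DataFrame(
        {
            "participant": day.participant_id,
            "date": day.date.isoformat(),
            "day_key": day_key,
            "start_row": starts.astype(np.int64),
            "start_ts": ts[starts].astype(np.int64),
            "label": labels.astype(np.int64),
            "meal_id": meal_ids.astype(np.int64),
        },
        columns=INDEX_COLUMNS,
    )
    return WindowSet(index, {day_key: channels}, wrows, window_seconds, step_seconds)


def oversample(train: WindowSet, rng_state: np.random.Generator) -> WindowSet:
    """Balance classes by appending positives drawn with replacement.

    Appends ``N = #negatives - #positives`` duplicated positives; the
    original windows are left untouched. Requires a -1-free training set.
    """
    labels = train.labels
    if (labels == -1).any():
        raise ValueError("oversample requires the -1 windows to be removed first")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0:
        raise ValueError("cannot balance a training set with zero positives")
    if n_neg == 0:
        raise ValueError("cannot balance a training set with zero negatives")
    if n_pos > n_neg:
        warnings.warn("positives already exceed negatives; oversample is a no-op")
        return train.subset(np.arange(len(train)))
    n_add = n_neg - n_pos
    pos_idx = np.flatnonzero(labels == 1)
    extra = rng_state.choice(pos_idx, size=n_add, replace=True)
    index = pd.concat([train.index, train.index.iloc[extra]], ignore_index=True)
    return WindowSet(index, train.days, train.window_rows, train.window_seconds, train.step_seconds)


# ---------------------------------------------------------------------------
# hierarchical container I/O
# ---------------------------------------------------------------------------

def save_windows(ws: WindowSet, path) -> None:
    """Persist a WindowSet (day arrays + window index) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["window_rows"] = ws.window_rows
        f.attrs["window_seconds"] = ws.window_seconds
        f.attrs["step_seconds"] = ws.step_seconds
        g = f.create_group("days")
        for key, arr in ws.days.items():
            g.create_dataset(key.replace("/", "|"), data=arr, compression="gzip", compression_opts=1)
        idx = f.create_group("index")
        for col in INDEX_COLUMNS:
            vals = ws.index[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            idx.create_dataset(col, data=vals)


def load_windows(path) -> WindowSet:
    with h5py.File(path, "r") as f:
        days = {k.replace("|", "/"): np.asarray(v) for k, v in f["days"].items()}
        data = {}
        for col in INDEX_COLUMNS:
            vals = np.asarray(f["index"][col])
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            data[col] = vals
        index = pd.DataFrame(data, columns=INDEX_COLUMNS)
        return WindowSet(
            index,
            days,
            int(f.attrs["window_rows"]),
            float(f.attrs["window_seconds"]),
            float(f.attrs["step_seconds"]),
        )
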