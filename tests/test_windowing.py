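"""Sliding-window segmentation, the 1/0/-1 labeler, and oversampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bitewatch.windowing import WindowSet, load_windows, make_windows, oversample, save_windows

from conftest import build_day, toy_window_set


class TestWindowCounts:
    def test_single_window_day(self):
        ws = make_windows(build_day(rate_hz=1.0, duration_s=300))
        assert len(ws) == 1
        assert ws.labels.tolist() == [0]

    def test_one_hour_day_has_166_windows(self):
        ws = make_windows(build_day(rate_hz=1.0, duration_s=3600))
        assert len(ws) == 166

    def test_day_shorter_than_window_is_empty(self):
        ws = make_windows(build_day(rate_hz=1.0, duration_s=200))
        assert len(ws) == 0

    @given(L=st.integers(min_value=300, max_value=5000))
    @settings(max_examples=30, deadline=None)
    def test_count_formula(self, L):
        ws = make_windows(build_day(rate_hz=1.0, duration_s=L))
        assert len(ws) == (L - 300) // 20 + 1


class TestLabels:
    def test_majority_rule_strict_at_half(self):
        # 151 tagged seconds -> positive; exactly 150 -> negative
        pos = make_windows(build_day(rate_hz=1.0, duration_s=300, meal_rows=[(0, 151)]),
                           min_meal_seconds=100)
        neg = make_windows(build_day(rate_hz=1.0, duration_s=300, meal_rows=[(0, 150)]),
                           min_meal_seconds=100)
        assert pos.labels.tolist() == [1]
        assert neg.labels.tolist() == [0]

    def test_cross_session_window_excluded(self):
        day = build_day(rate_hz=1.0, duration_s=600, session_breaks_at=[310])
        ws = make_windows(day)
        labels = ws.labels
        # window starting at row 20 spans rows 20..319 -> two sessions
        assert labels[1] == -1
        assert labels[0] == 0

    def test_retro_overlap_excluded(self):
        day = build_day(rate_hz=1.0, duration_s=600, retro_rows=[(200, 500)])
        ws = make_windows(day)
        assert (ws.labels == -1).any()
        # retro precedence: even majority-mealtime windows are excluded
        assert not (ws.labels == 1).any()

    def test_short_meal_overlap_excluded(self):
        day = build_day(rate_hz=1.0, duration_s=600, meal_rows=[(300, 400)])  # 99 s run
        ws = make_windows(day)
        assert (ws.labels == -1).any()

    def test_labels_ignore_channel_values(self):
        day = build_day(rate_hz=1.0, duration_s=900, meal_rows=[(100, 500)], seed=1)
        noisy = build_day(rate_hz=1.0, duration_s=900, meal_rows=[(100, 500)], seed=2, noise_sd=3.0)
        np.testing.assert_array_equal(make_windows(day).labels, make_windows(noisy).labels)

    @pytest.mark.parametrize("seed", range(8))
    def test_labeler_matches_naive_rederivation(self, seed):
        """Vectorized labels equal a per-window literal re-check of the rules."""
        rng = np.random.default_rng(seed)
        meal, retro = [], []
        cursor = 0
        for _ in range(rng.integers(1, 5)):
            cursor += int(rng.integers(50, 400))
            length = int(rng.integers(30, 500))
            (retro if rng.random() < 0.3 else meal).append((cursor, cursor + length))
            cursor += length
        breaks = sorted(rng.choice(np.arange(100, 2000), size=rng.integers(0, 3), replace=False).tolist())
        day = build_day(rate_hz=1.0, duration_s=2400, meal_rows=meal, retro_rows=retro,
                        session_breaks_at=breaks)
        ws = make_windows(day)
        df = day.samples
        tag = df["tag"].to_numpy()
        retro_col = df["tagRetro"].to_numpy()
        ses = df["sesid"].to_numpy()
        ts = df["ts"].to_numpy()
        # independent oracle: explicit run scan + per-window loop
        runs = []
        s = None
        for i, v in enumerate(tag):
            if v and s is None:
                s = i
            elif not v and s is not None:
                runs.append((s, i))
                s = None
        if s is not None:
            runs.append((s, len(tag)))
        short_rows = set()
        for a, b in runs:
            if (ts[b - 1] - ts[a]) / 1000 < 180:
                short_rows.update(range(a, b))
        for w in range(len(ws)):
            a = int(ws.index.loc[w, "start_row"])
            b = a + 300
            if len(set(ses[a:b])) > 1 or retro_col[a:b].any() or any(
                r in short_rows for r in range(a, b)
            ):
                want = -1
            elif tag[a:b].sum() > 150:
                want = 1
            else:
                want = 0
            assert ws.labels[w] == want


class TestOversample:
    def test_balances_exactly(self, rng):
        ws = toy_window_set(10, 100)
        out = oversample(ws, rng)
        assert out.positives == out.negatives == 100
        assert len(out) == 200

    def test_balanced_input_unchanged(self, rng):
        ws = toy_window_set(50, 50)
        assert len(oversample(ws, rng)) == 100

    def test_original_windows_and_distinct_set_preserved(self, rng):
        ws = toy_window_set(7, 31)
        out = oversample(ws, rng)
        assert out.index.iloc[: len(ws)].equals(ws.index)
        key = lambda df: set(zip(df["day_key"], df["start_row"]))
        assert key(out.index) == key(ws.index)

    def test_zero_positives_error(self, rng):
        with pytest.raises(ValueError, match="zero positives"):
            oversample(toy_window_set(0, 10), rng)

    def test_more_positives_warns_noop(self, rng):
        ws = toy_window_set(20, 5)
        with pytest.warns(UserWarning):
            out = oversample(ws, rng)
        assert len(out) == 25

    def test_minus_one_windows_rejected(self, rng):
        ws = toy_window_set(5, 5)
        ws.index.loc[0, "label"] = -1
        with pytest.raises(ValueError, match="-1"):
            oversample(ws, rng)


class TestWindowSetPlumbing:
    def test_bookkeeping_partition(self):
        day = build_day(rate_hz=1.0, duration_s=3600, meal_rows=[(600, 1500)],
                        retro_rows=[(2000, 2400)])
        ws = make_windows(day)
        assert ws.positives + ws.negatives + ws.excluded == len(ws)
        assert ws.excluded > 0 and ws.positives > 0

    def test_channels_shape_and_modality(self):
        ws = toy_window_set(2, 2, rows=40)
        assert ws.channels(0, "all").shape == (40, 6)
        assert ws.channels(0, "gyro").shape == (40, 3)
        np.testing.assert_array_equal(ws.channels(0, "gyro"), ws.channels(0)[:, 3:6])
        batch = ws.batch(np.arange(3), "gyro")
        assert batch.shape == (3, 40, 3) and batch.dtype == np.float32

    def test_concat_and_subset(self):
        a = toy_window_set(2, 3, participant="A")
        b = toy_window_set(1, 4, participant="B", seed=1)
        both = WindowSet.concat([a, b])
        assert len(both) == 10
        onlyb = both.for_participants(["B"])
        assert set(onlyb.index["participant"]) == {"B"}

    def test_h5_round_trip(self, tmp_path):
        ws = make_windows(build_day(rate_hz=1.0, duration_s=1200, meal_rows=[(100, 900)]))
        path = tmp_path / "w.h5"
        save_windows(ws, path)
        back = load_windows(path)
        assert back.window_rows == ws.window_rows
        assert back.index["label"].tolist() == ws.index["label"].tolist()
        np.testing.assert_allclose(back.channels(3), ws.channels(3), atol=1e-7)
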