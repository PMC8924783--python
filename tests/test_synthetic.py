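"""Statistical structure and determinism of the synthetic day generator."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from bitewatch.records import extract_meals
from bitewatch.synthetic import (
    ConfigurationError,
    GeneratorConfig,
    generate_cohort,
    generate_day,
    inject_noncompliance,
)
from bitewatch.windowing import make_windows

DATE = dt.date(2021, 5, 3)


def one_hour_config(rate=50.0, **kw):
    return GeneratorConfig(
        sampling_rate_hz=rate,
        day_start_window=(8 * 3600.0, 8 * 3600.0),
        day_end_window=(9 * 3600.0, 9 * 3600.0),
        session_break_probability=0.0,
        watch_off_probability=0.0,
        **kw,
    )


@pytest.fixture(scope="module")
def cohort_100_days():
    """10 participants x 10 days at 1 Hz — shared for marginal statistics."""
    return generate_cohort(10, 10, GeneratorConfig(sampling_rate_hz=1.0), seed=42)


class TestGenerateDay:
    def test_one_hour_at_50hz_has_180000_samples(self):
        cfg = one_hour_config()
        day, _ = generate_day("P01", DATE, cfg, np.random.default_rng(0), n_meals=1)
        assert day.n_samples == 180_000
        assert day.samples["sesid"].nunique() == 1

    def test_same_seed_identical_day(self):
        cfg = GeneratorConfig(sampling_rate_hz=2.0, seed=5)
        d1, t1 = generate_day("P01", DATE, cfg, np.random.default_rng(99))
        d2, t2 = generate_day("P01", DATE, cfg, np.random.default_rng(99))
        pd.testing.assert_frame_equal(d1.samples, d2.samples)
        assert t1 == t2

    def test_three_meals_non_overlapping(self):
        cfg = GeneratorConfig(sampling_rate_hz=1.0)
        for seed in range(30):
            _, truth = generate_day("P01", DATE, cfg, np.random.default_rng(seed), n_meals=3)
            assert len(truth) == 3
            ordered = sorted(truth, key=lambda m: m.start_ts)
            for a, b in zip(ordered, ordered[1:]):
                assert a.end_ts < b.start_ts

    def test_labels_consistent_with_truth(self):
        cfg = GeneratorConfig(sampling_rate_hz=2.0, retro_fraction=0.5)
        day, truth = generate_day("P01", DATE, cfg, np.random.default_rng(7))
        day.validate()
        df = day.samples
        inside = np.zeros(len(df), dtype=bool)
        ts = df["ts"].to_numpy()
        for m in truth:
            inside |= (ts >= m.start_ts) & (ts <= m.end_ts)
        assert not df["tag"].to_numpy()[~inside].any()
        assert (df["tagTimely"] <= df["tag"]).all()

    def test_extract_meals_inverts_truth_sidecar(self):
        cfg = GeneratorConfig(sampling_rate_hz=2.0)
        day, truth = generate_day("P01", DATE, cfg, np.random.default_rng(11))
        meals = extract_meals(day)
        assert len(meals) == len(truth)
        for got, want in zip(meals, sorted(truth, key=lambda m: m.start_ts)):
            # extraction snaps to the sample grid: within one sample period
            assert abs(got.start_ts - want.start_ts) <= 500
            assert abs(got.end_ts - want.end_ts) <= 500
            assert got.retrospective == want.retrospective

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(sampling_rate_hz=-1).validate()
        with pytest.raises(ConfigurationError):
            GeneratorConfig(retro_fraction=1.5).validate()
        with pytest.raises(ConfigurationError):
            GeneratorConfig(meals_per_day_weights=(1.0,) * 6).validate()


class TestInjectNoncompliance:
    @pytest.fixture()
    def day(self):
        cfg = GeneratorConfig(sampling_rate_hz=2.0)
        d, _ = generate_day("P01", DATE, cfg, np.random.default_rng(3), n_meals=2)
        return d

    def test_short_day_under_three_hours(self, day):
        short = inject_noncompliance(day, "short_day", np.random.default_rng(0))
        assert short.total_duration_hours() < 3.0

    def test_watch_off_segment_scan(self, day):
        cfg_scale = GeneratorConfig().baseline_noise_scale
        off = inject_noncompliance(day, "watch_off", np.random.default_rng(0))
        mag = np.abs(off.samples[["accl_x", "accl_y", "accl_z", "gyro_x", "gyro_y", "gyro_z"]]).max(axis=1).to_numpy()
        quiet = mag < cfg_scale / 100
        # longest quiet run must span >= 10 minutes of samples
        best = run = 0
        for q in quiet:
            run = run + 1 if q else 0
            best = max(best, run)
        assert best >= 10 * 60 * 2  # 10 min at 2 Hz

    def test_no_meals_strips_all_tags(self, day):
        bare = inject_noncompliance(day, "no_meals", np.random.default_rng(0))
        assert bare.samples["tag"].sum() == 0
        assert bare.samples["tagRetro"].sum() == 0

    def test_all_retro_marks_every_meal(self, day):
        retro = inject_noncompliance(day, "all_retro", np.random.default_rng(0))
        meals = extract_meals(retro)
        assert meals and all(m.retrospective for m in meals)

    def test_unknown_kind_rejected(self, day):
        with pytest.raises(ValueError, match="unknown"):
            inject_noncompliance(day, "sabotage", np.random.default_rng(0))


class TestCohort:
    def test_counts_and_distinct_profiles(self):
        cohort = generate_cohort(4, 2, GeneratorConfig(sampling_rate_hz=1.0), seed=1)
        assert len(cohort.all_days()) == 8
        assert len(cohort.participants) == 4
        axes = {c.gyro_axis for c in cohort.profiles.values()}
        assert len(axes) == 4

    def test_seed_reproducibility(self):
        g = GeneratorConfig(sampling_rate_hz=1.0)
        c1 = generate_cohort(2, 2, g, seed=9)
        c2 = generate_cohort(2, 2, g, seed=9)
        for d1, d2 in zip(c1.all_days(), c2.all_days()):
            pd.testing.assert_frame_equal(d1.samples, d2.samples)
        assert c1.truth == c2.truth

    def test_meals_lie_inside_sessions(self, cohort_100_days):
        for day in cohort_100_days.all_days():
            bounds = day.session_bounds()
            ts = day.samples["ts"].to_numpy()
            for m in cohort_100_days.meals_for(day):
                assert any(
                    ts[s] <= m.start_ts and m.end_ts <= ts[e - 1] + 1000
                    for _, s, e in bounds
                )

    def test_meal_duration_distribution(self, cohort_100_days):
        durations = [m.duration_seconds / 60 for m in cohort_100_days.all_meals()]
        frac_short = np.mean(np.asarray(durations) < 20)
        assert 0.65 <= frac_short <= 0.85

    def test_meal_count_range_and_mode(self, cohort_100_days):
        counts = [len(v) for v in cohort_100_days.truth.values()]
        assert min(counts) >= 1 and max(counts) <= 7
        assert np.mean([1 <= c <= 4 for c in counts]) > 0.7

    def test_day_durations_mostly_8_to_15_hours(self, cohort_100_days):
        hours = [d.total_duration_hours() for d in cohort_100_days.all_days()]
        assert np.mean([(8 <= h <= 15) for h in hours]) > 0.7

    def test_start_times_peak_at_mealtimes(self, cohort_100_days):
        tods = []
        for m in cohort_100_days.all_meals():
            tods.append((m.start_ts / 1000) % 86400 / 3600)
        tods = np.asarray(tods)
        near_peak = (
            (np.abs(tods - 8.25) < 2) | (np.abs(tods - 12.5) < 2) | (np.abs(tods - 18.75) < 2)
        )
        assert near_peak.mean() > 0.8


class TestSeparability:
    def test_energy_threshold_floor(self):
        """Gyro-magnitude energy alone separates meal windows (AUC > 0.7)."""
        cfg = GeneratorConfig(sampling_rate_hz=4.0)
        scores, labels = [], []
        for seed in range(3):
            day, _ = generate_day("P01", DATE, cfg, np.random.default_rng(seed))
            ws = make_windows(day).labeled()
            for i in range(len(ws)):
                g = ws.channels(i, "gyro")
                scores.append(float(np.sqrt((g**2).sum(axis=1)).std()))
            labels.extend(ws.labels.tolist())
        assert len(set(labels)) == 2
        assert roc_auc_score(labels, scores) > 0.7
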