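"""Unit and property tests for the bout-feature hierarchy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actibout import bouts
from actibout.bouts import (
    EPOCHS_PER_DAY,
    FEATURE_NAMES,
    LABEL_TO_CODE,
    MISSING_CODE,
    PHASES,
    SLEEP_CODE,
    Bout,
    DayPhases,
    EpochSeries,
    SleepWindowError,
    average_features,
    compute_daily_features,
    detect_sleep_window,
    extract_bouts,
    partition_day,
    wear_time_qc,
)

NOON = pd.Timestamp("2014-03-03 12:00:00")
SED = LABEL_TO_CODE["sedentary"]
WALK = LABEL_TO_CODE["walking"]


def series_from_codes(codes, start=NOON, pid="P0"):
    return EpochSeries(participant_id=pid, start=start, codes=np.asarray(codes, dtype=np.int8))


def rle_oracle(codes):
    """Independent brute-force run-length encoding."""
    out = []
    i = 0
    while i < len(codes):
        j = i
        while j + 1 < len(codes) and codes[j + 1] == codes[i]:
            j += 1
        if codes[i] != MISSING_CODE:
            out.append(Bout(bouts.CODE_TO_LABEL[int(codes[i])], i, j - i + 1))
        i = j + 1
    return out


class TestExtractBouts:
    def test_single_run(self):
        got = extract_bouts(np.full(10, SED, dtype=np.int8))
        assert got == [Bout("sedentary", 0, 10)]

    def test_empty(self):
        assert extract_bouts(np.empty(0, dtype=np.int8)) == []

    def test_missing_breaks_bouts(self):
        codes = [SED, SED, MISSING_CODE, SED]
        assert extract_bouts(np.array(codes, dtype=np.int8)) == [
            Bout("sedentary", 0, 2),
            Bout("sedentary", 3, 1),
        ]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            extract_bouts(np.array([0, 9], dtype=np.int8))

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=0, max_size=100))
    def test_matches_brute_force_oracle(self, codes):
        arr = np.array(codes, dtype=np.int8)
        assert extract_bouts(arr) == rle_oracle(arr)


class TestSleepWindow:
    def _day_with(self, sleep_runs, filler=SED):
        codes = np.full(EPOCHS_PER_DAY, filler, dtype=np.int8)
        for a, b in sleep_runs:
            codes[a:b] = SLEEP_CODE
        return codes

    def test_uninterrupted_identical_nights(self):
        # sleep 23:00-07:00 -> epochs 1320..2280 of a noon-anchored day
        day = self._day_with([(1320, 2280)])
        s = series_from_codes(np.tile(day, 3))
        w = detect_sleep_window(s)
        assert w.onset == pytest.approx(1380.0)
        assert w.offset == pytest.approx(420.0)
        assert w.n_days_used == 3

    def test_gap_within_tolerance_merged(self):
        # sleep 23:00-03:00, 10-min walking gap, sleep 03:10-07:00
        day = self._day_with([(1320, 1800), (1820, 2280)])
        day[1800:1820] = WALK
        w = detect_sleep_window(series_from_codes(day), gap_tolerance_epochs=60)
        assert (w.onset, w.offset) == (pytest.approx(1380.0), pytest.approx(420.0))
        # brute force over all candidate merged blocks confirms the max
        assert w.daily == [(1380.0, 420.0)]

    def test_gap_beyond_tolerance_splits(self):
        # 35-min gap exceeds the 30-min tolerance: blocks stay separate and
        # the larger one (480 epochs, 23:00-03:00) wins
        day = self._day_with([(1320, 1800), (1870, 2280)])
        w = detect_sleep_window(series_from_codes(day), gap_tolerance_epochs=60)
        assert w.daily == [(1380.0, 180.0)]

    def test_equal_blocks_tie_break_earliest(self):
        # 20:00-00:00 and 02:00-06:00, both 480 epochs
        day = self._day_with([(960, 1440), (1680, 2160)])
        w = detect_sleep_window(series_from_codes(day), gap_tolerance_epochs=60)
        assert w.onset == pytest.approx(1200.0)  # 20:00
        assert w.offset == pytest.approx(0.0)

    def test_day_without_sleep_flagged(self):
        day1 = self._day_with([(1320, 2280)])
        day2 = self._day_with([])
        w = detect_sleep_window(series_from_codes(np.concatenate([day1, day2])))
        assert w.n_days_used == 1 and w.n_days_flagged == 1

    def test_all_days_without_sleep_fails(self):
        with pytest.raises(SleepWindowError):
            detect_sleep_window(series_from_codes(self._day_with([])))


class TestPartitionDay:
    def test_midnight_to_eight(self):
        p = partition_day((0.0, 480.0))
        assert p.intervals()["morning"] == (480.0, pytest.approx(800.0))
        assert p.intervals()["afternoon"][0] == pytest.approx(800.0)  # 13:20
        assert p.intervals()["evening"][0] == pytest.approx(1120.0)  # 18:40
        assert p.durations()["sleep"] == 480.0

    def test_wrapping_window(self):
        p = partition_day((22.5 * 60, 6.5 * 60))  # 22:30 -> 06:30
        assert p.durations() == {
            "sleep": 480.0,
            "morning": pytest.approx(320.0),
            "afternoon": pytest.approx(320.0),
            "evening": pytest.approx(320.0),
        }

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            partition_day((600.0, 600.0))

    @settings(max_examples=300, derandomize=True)
    @given(
        onset=st.floats(0, 1439.9),
        dur=st.floats(0.5, 1439.0),
    )
    def test_phases_tile_the_day(self, onset, dur):
        p = partition_day((onset, (onset + dur) % 1440))
        assert sum(p.durations().values()) == pytest.approx(1440.0)
        # every minute of the day lands in exactly one phase
        tod = np.arange(0, 1440, 0.5)
        ph = p.phase_of(tod)
        counts = np.bincount(ph, minlength=4) * 0.5
        for i, name in enumerate(PHASES):
            assert counts[i] == pytest.approx(p.durations()[name], abs=0.51)


def tally_oracle(codes, phases):
    """Independent per-epoch tally of counts/percentages/mean lengths."""
    tod = (720.0 + np.arange(EPOCHS_PER_DAY) * 0.5) % 1440
    ph = phases.phase_of(tod)
    mat = np.zeros((5, 4, 3))
    for a in range(5):
        for p in range(4):
            in_cell = (codes == a) & (ph == p)
            nonmissing = ((codes != MISSING_CODE) & (ph == p)).sum()
            # count maximal runs inside the cell
            runs = 0
            prev = False
            for flag in in_cell:
                if flag and not prev:
                    runs += 1
                prev = flag
            total = in_cell.sum()
            mat[a, p, 0] = runs
            mat[a, p, 1] = 100.0 * total / nonmissing if nonmissing else np.nan
            mat[a, p, 2] = total / runs if runs else 0.0
    return mat


class TestDailyFeatures:
    def test_sedentary_day(self):
        codes = np.full(EPOCHS_PER_DAY, SED, dtype=np.int8)
        codes[1320:2280] = SLEEP_CODE
        phases = partition_day((1380.0, 420.0))
        m = compute_daily_features(codes, phases)
        names = dict(zip(("n_bouts", "pct_time", "mean_len"), range(3)))
        sed = bouts.LABELS.index("sedentary")
        walk = bouts.LABELS.index("walking")
        for p in (1, 2, 3):  # morning / afternoon / evening
            assert m[sed, p, names["pct_time"]] == pytest.approx(100.0)
            assert m[walk, p, names["n_bouts"]] == 0
        assert m[bouts.LABELS.index("sleep"), 0, names["pct_time"]] == pytest.approx(100.0)

    def test_matches_per_epoch_tally_oracle(self, rng):
        codes = rng.integers(0, 6, size=EPOCHS_PER_DAY).astype(np.int8)
        phases = partition_day((1390.0, 400.0))
        got = compute_daily_features(codes, phases)
        want = tally_oracle(codes, phases)
        np.testing.assert_allclose(got, want, rtol=1e-12, equal_nan=True)

    def test_conservation_identity(self, rng):
        for _ in range(5):
            codes = rng.integers(0, 6, size=EPOCHS_PER_DAY).astype(np.int8)
            phases = partition_day((rng.uniform(0, 1440), rng.uniform(0, 1440)))
            m = compute_daily_features(codes, phases)
            tod = (720.0 + np.arange(EPOCHS_PER_DAY) * 0.5) % 1440
            ph = phases.phase_of(tod)
            for p in range(4):
                nonmissing = ((codes != MISSING_CODE) & (ph == p)).sum()
                s = float(np.sum(m[:, p, 0] * m[:, p, 2]))
                assert round(s) == nonmissing
                assert abs(s - nonmissing) < 1e-6

    def test_all_missing_phase_flagged_nan(self):
        codes = np.full(EPOCHS_PER_DAY, SED, dtype=np.int8)
        phases = partition_day((1380.0, 420.0))
        tod = (720.0 + np.arange(EPOCHS_PER_DAY) * 0.5) % 1440
        codes[phases.phase_of(tod) == 1] = MISSING_CODE  # blank out morning
        m = compute_daily_features(codes, phases)
        assert np.isnan(m[:, 1, 1]).all()
        assert np.isfinite(m[:, 2, 1]).all()


class TestAverageFeatures:
    def test_idempotent_on_identical_days(self, rng):
        day = rng.uniform(0, 10, size=(5, 4, 3))
        out = average_features([day] * 7)
        np.testing.assert_allclose(out.to_numpy(), day.reshape(-1))

    def test_sixty_named_features(self, rng):
        out = average_features([rng.uniform(size=(5, 4, 3))])
        assert len(out) == 60
        assert list(out.index) == FEATURE_NAMES

    def test_plain_mean(self):
        a, b = np.full((5, 4, 3), 2.0), np.full((5, 4, 3), 4.0)
        assert (average_features([a, b]) == 3.0).all()

    def test_zero_days_rejected(self):
        with pytest.raises(ValueError):
            average_features([])


class TestWearTimeQC:
    def _series(self, days, missing_mask=None):
        codes = np.full(days * EPOCHS_PER_DAY, SED, dtype=np.int8)
        codes[::7] = SLEEP_CODE
        if missing_mask is not None:
            codes[missing_mask] = MISSING_CODE
        return series_from_codes(codes)

    def test_full_week_passes(self):
        assert wear_time_qc(self._series(7)) == (True, "ok")

    def test_all_missing_fails(self):
        s = self._series(7, missing_mask=np.ones(7 * EPOCHS_PER_DAY, dtype=bool))
        assert wear_time_qc(s) == (False, "insufficient-wear")

    def test_exactly_72h_boundary_inclusive(self):
        # keep 36 h observed in each half (1.5 days at the start of each),
        # everything else missing: exactly 72 h total
        n = 7 * EPOCHS_PER_DAY
        mask = np.ones(n, dtype=bool)
        half = n // 2
        keep = int(36 * 120)
        mask[:keep] = False
        mask[half : half + keep] = False
        ok, reason = wear_time_qc(self._series(7, missing_mask=mask))
        assert ok, reason

    def test_one_sided_wear_fails(self):
        n = 7 * EPOCHS_PER_DAY
        mask = np.zeros(n, dtype=bool)
        mask[n // 2 :] = True  # second half entirely missing
        assert wear_time_qc(self._series(7, missing_mask=mask)) == (False, "uneven-wear")


def test_met_table_and_epoch_length():
    assert bouts.MET_TABLE == {
        "sedentary": 1.5,
        "moderate": 4.9,
        "walking": 3.2,
        "sleep": 1.0,
        "light_tasks": 2.2,
    }
    assert bouts.EPOCH_SECONDS == 30
    assert bouts.EPOCHS_PER_DAY == 2880
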