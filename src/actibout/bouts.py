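"""Bout-level physical-activity features from epoch-labelled traces.

The representation hierarchy goes: 30-second epoch labels -> maximal
activity bouts -> a personalised night-sleep window -> a four-way
partition of the 24-h day (sleep / morning / afternoon / evening) ->
a 5 activities x 4 phases x 3 statistics feature matrix per day ->
the element-wise average over wear days (60 features per participant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the five behavioural classes emitted by epoch-level activity classifiers
LABELS: tuple[str, ...] = ("sedentary", "moderate", "walking", "sleep", "light_tasks")
MISSING_LABEL = "missing"
ALPHABET: tuple[str, ...] = LABELS + (MISSING_LABEL,)

LABEL_TO_CODE = {lab: i for i, lab in enumerate(ALPHABET)}
CODE_TO_LABEL = dict(enumerate(ALPHABET))
SLEEP_CODE = LABEL_TO_CODE["sleep"]
MISSING_CODE = LABEL_TO_CODE[MISSING_LABEL]

#: metabolic equivalent of task (MET) per activity class
MET_TABLE: dict[str, float] = {
    "sedentary": 1.5,
    "moderate": 4.9,
    "walking": 3.2,
    "sleep": 1.0,
    "light_tasks": 2.2,
}

EPOCH_SECONDS = 30
EPOCHS_PER_MINUTE = 2
EPOCHS_PER_DAY = 24 * 60 * EPOCHS_PER_MINUTE  # 2880
NOON_MINUTES = 720.0

PHASES: tuple[str, ...] = ("sleep", "morning", "afternoon", "evening")
STATS: tuple[str, ...] = ("n_bouts", "pct_time", "mean_bout_len")


class SleepWindowError(ValueError):
    """No usable sleep window could be detected for a participant."""


def feature_names() -> list[str]:
    """The 60 stable feature names, activity-major: ``<activity>_<phase>_<stat>``."""
    return [f"{a}_{p}_{s}" for a in LABELS for p in PHASES for s in STATS]


FEATURE_NAMES = feature_names()


@dataclass
class EpochSeries:
    """One participant's epoch-labelled wear-time trace at 30-s cadence."""

    participant_id: str
    start: pd.Timestamp
    codes: np.ndarray  # int8 codes into ALPHABET

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= len(ALPHABET)):
            bad = sorted(set(self.codes.tolist()) - set(range(len(ALPHABET))))
            raise ValueError(f"unknown label codes {bad}")
        sec = self.start.hour * 3600 + self.start.minute * 60 + self.start.second
        if sec % EPOCH_SECONDS:
            raise ValueError("start timestamp not aligned to the 30-s epoch grid")

    def __len__(self) -> int:
        return self.codes.size

    @property
    def labels(self) -> list[str]:
        return [CODE_TO_LABEL[c] for c in self.codes.tolist()]

    @property
    def start_tod_minutes(self) -> float:
        return self.start.hour * 60 + self.start.minute + self.start.second / 60

    def tod_minutes(self, idx: np.ndarray | int) -> np.ndarray | float:
        """Time of day (minutes from midnight) of epoch ``idx``."""
        return (self.start_tod_minutes + np.asarray(idx) * 0.5) % 1440

    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(np.arange(len(self)) * EPOCH_SECONDS, unit="s")

    def day_slices(self) -> list[slice]:
        """Complete noon-to-noon analysis days as slices into ``codes``.

        Anchoring days at noon keeps nocturnal sleep in one piece; partial
        leading/trailing days are dropped.
        """
        delta_min = (NOON_MINUTES - self.start_tod_minutes) % 1440
        k0 = int(round(delta_min * EPOCHS_PER_MINUTE))
        out = []
        while k0 + EPOCHS_PER_DAY <= len(self):
            out.append(slice(k0, k0 + EPOCHS_PER_DAY))
            k0 += EPOCHS_PER_DAY
        return out


@dataclass(frozen=True)
class Bout:
    """A maximal run of consecutive epochs sharing one activity label."""

    activity: str
    start: int
    length: int


@dataclass
class SleepWindow:
    """Personalised night-sleep boundaries (circular minutes from midnight)."""

    onset: float
    offset: float
    daily: list[tuple[float, float]] = field(default_factory=list)
    n_days_used: int = 0
    n_days_flagged: int = 0


@dataclass
class DayPhases:
    """Four half-open time-of-day intervals tiling the 24-h day.

    The wake span (sleep offset -> next onset, circular) is split into
    three equal phases; the sleep window is the fourth phase.
    """

    onset: float
    offset: float

    def __post_init__(self) -> None:
        sleep_dur = (self.offset - self.onset) % 1440
        if sleep_dur == 0:
            raise ValueError("sleep window spans 0 or >= 24 h")
        self.sleep_duration = sleep_dur
        self.wake_duration = 1440.0 - sleep_dur
        self.phase_duration = self.wake_duration / 3.0

    def durations(self) -> dict[str, float]:
        d = self.phase_duration
        return {"sleep": self.sleep_duration, "morning": d, "afternoon": d, "evening": d}

    def intervals(self) -> dict[str, tuple[float, float]]:
        """Half-open [start, end) intervals, ends possibly wrapping past 1440."""
        d = self.phase_duration
        return {
            "sleep": (self.onset % 1440, (self.onset % 1440) + self.sleep_duration),
            "morning": (self.offset % 1440, (self.offset % 1440) + d),
            "afternoon": ((self.offset + d) % 1440, (self.offset + d) % 1440 + d),
            "evening": ((self.offset + 2 * d) % 1440, (self.offset + 2 * d) % 1440 + d),
        }

    def phase_of(self, tod: np.ndarray | float) -> np.ndarray:
        """Phase index per PHASES order (0=sleep..3=evening) for times of day."""
        rel = (np.atleast_1d(np.asarray(tod, dtype=float)) - self.offset) % 1440
        d = self.phase_duration
        out = np.full(rel.shape, 0, dtype=np.int8)
        out[rel < self.wake_duration] = 3
        out[rel < 2 * d] = 2
        out[rel < d] = 1
        return out


def _rle(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode: (starts, lengths, values)."""
    n = codes.size
    if n == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z, codes
    change = np.flatnonzero(codes[1:] != codes[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [n])))
    return starts, lengths, codes[starts]


def extract_bouts(series: EpochSeries | np.ndarray) -> list[Bout]:
    """Maximal activity bouts of a trace; ``missing`` runs break bouts
    and are not returned."""
    codes = series.codes if isinstance(series, EpochSeries) else np.asarray(series, dtype=np.int8)
    if codes.size and (codes.min() < 0 or codes.max() >= len(ALPHABET)):
        raise ValueError("unknown label code in series")
    starts, lengths, values = _rle(codes)
    return [
        Bout(CODE_TO_LABEL[int(v)], int(s), int(l))
        for s, l, v in zip(starts, lengths, values)
        if v != MISSING_CODE
    ]


def circular_mean_minutes(minutes: np.ndarray) -> float:
    """Unit-vector mean of times of day, in minutes from midnight."""
    ang = np.asarray(minutes, dtype=float) / 1440.0 * 2 * np.pi
    m = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi) * 1440.0
    return float(m % 1440.0)


def _merge_sleep_blocks(
    starts: np.ndarray, lengths: np.ndarray, gap_tolerance: int
) -> tuple[int, int, int]:
    """Merge sleep bouts whose gaps are <= tolerance; return the block with
    the most sleep epochs as (block_start, block_end, sleep_total).
    Ties go to the earliest-starting block."""
    best = (-1, -1, -1)
    i = 0
    nb = len(starts)
    while i < nb:
        j = i
        total = int(lengths[i])
        while j + 1 < nb and starts[j + 1] - (starts[j] + lengths[j]) <= gap_tolerance:
            j += 1
            total += int(lengths[j])
        block = (int(starts[i]), int(starts[j] + lengths[j]), total)
        if block[2] > best[2]:
            best = block
        i = j + 1
    return best


def detect_sleep_window(series: EpochSeries, gap_tolerance_epochs: int = 60) -> SleepWindow:
    """Find the participant's night-sleep boundaries.

    Per noon-to-noon day, sleep bouts separated by non-sleep gaps of at most
    ``gap_tolerance_epochs`` (default 60 epochs = 30 min) are merged into
    "nearly continuous" candidate blocks; the block containing the most
    sleep epochs wins (ties: earliest onset).  The participant-level window
    is the circular mean of the daily onsets and offsets.  Days without any
    sleep epoch are flagged and excluded from the average.
    """
    days = series.day_slices()
    if not days:
        raise SleepWindowError("series contains no complete noon-to-noon day")
    daily: list[tuple[float, float]] = []
    flagged = 0
    for sl in days:
        chunk = series.codes[sl]
        starts, lengths, values = _rle(chunk)
        keep = values == SLEEP_CODE
        if not keep.any():
            flagged += 1
            continue
        b0, b1, _ = _merge_sleep_blocks(starts[keep], lengths[keep], gap_tolerance_epochs)
        onset = float(series.tod_minutes(sl.start + b0))
        offset = float(series.tod_minutes(sl.start + b1))
        daily.append((onset, offset))
    if not daily:
        raise SleepWindowError("no day with sleep epochs; cannot personalise sleep window")
    onsets = np.array([d[0] for d in daily])
    offsets = np.array([d[1] for d in daily])
    return SleepWindow(
        onset=circular_mean_minutes(onsets),
        offset=circular_mean_minutes(offsets),
        daily=daily,
        n_days_used=len(daily),
        n_days_flagged=flagged,
    )


def partition_day(window: SleepWindow | tuple[float, float]) -> DayPhases:
    """Split the 24-h day into sleep + three equal wake phases."""
    if isinstance(window, SleepWindow):
        onset, offset = window.onset, window.offset
    else:
        onset, offset = window
    return DayPhases(onset=float(onset), offset=float(offset))


def compute_daily_features(
    series_day: EpochSeries | np.ndarray,
    phases: DayPhases,
    day_start_tod: float = NOON_MINUTES,
) -> np.ndarray:
    """Per-day 5x4x3 feature matrix (activity x phase x statistic).

    Bouts are split at phase boundaries and each fragment counts within its
    own phase, which keeps the conservation identity
    ``sum_a n_bouts * mean_len = non-missing phase epochs`` exact per phase.
    Percentages are phase-relative with non-missing epochs as denominator;
    a phase with every epoch missing has its percentages set to NaN for the
    day.  Cells with zero bouts report (0, 0, 0).
    """
    codes = series_day.codes if isinstance(series_day, EpochSeries) else np.asarray(series_day)
    if isinstance(series_day, EpochSeries):
        day_start_tod = series_day.start_tod_minutes
    if codes.size != EPOCHS_PER_DAY:
        raise ValueError(f"expected one full day of {EPOCHS_PER_DAY} epochs, got {codes.size}")
    tod = (day_start_tod + np.arange(EPOCHS_PER_DAY) * 0.5) % 1440
    phase_idx = phases.phase_of(tod)

    observed = codes != MISSING_CODE
    key = np.where(observed, codes.astype(np.int64) * 4 + phase_idx, -1)
    starts, lengths, values = _rle(key)

    counts = np.zeros((len(LABELS), 4), dtype=np.int64)
    totals = np.zeros((len(LABELS), 4), dtype=np.int64)
    for l, v in zip(lengths, values):
        if v < 0:
            continue
        a, p = divmod(int(v), 4)
        counts[a, p] += 1
        totals[a, p] += int(l)

    nonmissing = np.bincount(phase_idx[observed], minlength=4)
    out = np.zeros((len(LABELS), 4, 3), dtype=float)
    out[:, :, 0] = counts
    with np.errstate(invalid="ignore", divide="ignore"):
        out[:, :, 1] = np.where(nonmissing > 0, 100.0 * totals / np.maximum(nonmissing, 1), np.nan)
        out[:, :, 2] = np.where(counts > 0, totals / np.maximum(counts, 1), 0.0)
    return out


def average_features(daily_matrices: list[np.ndarray]) -> pd.Series:
    """Element-wise mean over valid wear days, flattened to the 60 named
    features. NaN percentage cells (all-missing phases) are skipped; a cell
    undefined on every day becomes 0."""
    if not daily_matrices:
        raise ValueError("no valid days to average")
    stack = np.stack(daily_matrices)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    mean = np.nan_to_num(mean, nan=0.0)
    return pd.Series(mean.reshape(-1), index=FEATURE_NAMES)


def wear_time_qc(
    series: EpochSeries, min_hours: float = 72.0, min_day_hours: float = 12.0
) -> tuple[bool, str]:
    """Adequate-wear check: at least ``min_hours`` of non-missing epochs
    overall (boundary inclusive) and at least one valid day (>= ``min_day_hours``
    observed) in each half of the wear period."""
    observed = series.codes != MISSING_CODE
    hours = observed.sum() / (EPOCHS_PER_MINUTE * 60)
    if hours < min_hours:
        return False, "insufficient-wear"
    half = len(series) // 2
    need = min_day_hours * EPOCHS_PER_MINUTE * 60
    first = second = False
    for sl in series.day_slices():
        valid = observed[sl].sum() >= need
        if not valid:
            continue
        if sl.start < half:
            first = True
        else:
            second = True
    if not (first and second):
        return False, "uneven-wear"
    return True, "ok"


def extract_features(
    series: EpochSeries, gap_tolerance_epochs: int = 60
) -> tuple[pd.Series, DayPhases]:
    """Full per-participant pipeline: sleep window -> phases -> daily
    matrices -> 7-day average. Returns the 60-feature vector and the
    personalised phase partition."""
    window = detect_sleep_window(series, gap_tolerance_epochs)
    phases = partition_day(window)
    dailies = [
        compute_daily_features(series.codes[sl], phases, float(series.tod_minutes(sl.start)))
        for sl in series.day_slices()
    ]
    return average_features(dailies), phases


def occupancy_24h(features: pd.Series, phases: DayPhases) -> dict[str, float]:
    """Aggregate phase-relative percentages to a 24-h occupancy (%) per
    activity class, weighting each phase by its duration."""
    dur = phases.durations()
    out = {}
    for a in LABELS:
        out[a] = sum(features[f"{a}_{p}_pct_time"] * dur[p] for p in PHASES) / 1440.0
    return out


def features_table(
    traces: dict[str, EpochSeries],
    gap_tolerance_epochs: int = 60,
    qc_min_hours: float = 72.0,
) -> tuple[pd.DataFrame, dict[str, DayPhases], pd.DataFrame]:
    """Feature matrix for a cohort of traces.

    Returns (wide feature table indexed by participant, per-participant
    phases, QC report). Participants failing wear-time QC or sleep-window
    detection are reported and omitted from the feature table.
    """
    rows, phase_map, qc_rows = {}, {}, []
    for pid, series in traces.items():
        ok, reason = wear_time_qc(series, min_hours=qc_min_hours)
        if ok:
            try:
                feats, phases = extract_features(series, gap_tolerance_epochs)
                rows[pid] = feats
                phase_map[pid] = phases
            except SleepWindowError:
                ok, reason = False, "no-sleep-window"
        qc_rows.append({"participant_id": pid, "qc_pass": ok, "reason": reason})
    table = pd.DataFrame(rows).T
    if not table.empty:
        table = table[FEATURE_NAMES]
    table.index.name = "participant_id"
    return table, phase_map, pd.DataFrame(qc_rows)
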