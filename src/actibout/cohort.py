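"""Cohort construction: T2D identification, impairment scoring, Norm bands,
and assembly of the two training sets.

Controls are stratified by an activity-impairment severity score derived
from their primary-care events: every relevant condition class maps to a
severity in {0, 1, 2}; a participant's score is the mean severity of events
dated inside a window from six months before wear start to one month after
wear end. Band thresholds (configurable): score < 0.5 -> Norm-0 (no
impairment, clean controls), 0.5 <= score < 1.5 -> Norm-1 (excluded),
score >= 1.5 -> Norm-2 (high impairment).

The shipped severity map is a synthetic stand-in catalogue: real clinical
coding vocabularies (Read v2 / CTV3) are licensed and out of scope; any
mapping with the same shape can be supplied instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import CONDITION_CLASSES, T2D_CLASS

LABEL_T2D = "T2D"
LABEL_NORM0 = "Norm-0"
LABEL_NORM1 = "Norm-1-excluded"
LABEL_NORM2 = "Norm-2"
LABEL_EXCLUDED = "excluded"


@dataclass
class SeverityMap:
    """condition class -> severity score in {0, 1, 2}, plus the set of
    classes that flag incident T2D."""

    scores: dict[str, int]
    t2d_classes: frozenset[str] = frozenset({T2D_CLASS})

    def __post_init__(self) -> None:
        for cls, s in self.scores.items():
            if s not in (0, 1, 2):
                raise ValueError(f"severity for {cls!r} must be in {{0,1,2}}, got {s}")

    def severity_of(self, condition_class: str) -> int:
        if condition_class in self.t2d_classes:
            return 0
        if condition_class not in self.scores:
            warnings.warn(f"unmapped condition class {condition_class!r}; scoring 0")
            return 0
        return self.scores[condition_class]

    @classmethod
    def default(cls) -> "SeverityMap":
        return cls(scores={c: sev for c, (_, sev) in CONDITION_CLASSES.items()})

    @classmethod
    def from_yaml(cls, path) -> "SeverityMap":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            scores={str(k): int(v) for k, v in raw["scores"].items()},
            t2d_classes=frozenset(raw.get("t2d_classes", [T2D_CLASS])),
        )


@dataclass
class ImpairmentScore:
    score: float
    band: str
    window: tuple[pd.Timestamp, pd.Timestamp]
    n_events: int


def assign_band(
    score: float, low: float = 0.5, high: float = 1.5
) -> str:
    """Band from a severity score; the upper boundary is inclusive upward
    (1.5 -> Norm-2)."""
    if not 0 <= score <= 2:
        raise ValueError(f"severity score {score} outside [0, 2]")
    if score < low:
        return LABEL_NORM0
    if score < high:
        return LABEL_NORM1
    return LABEL_NORM2


def severity_score(
    events: pd.DataFrame,
    smap: SeverityMap,
    wear_start: pd.Timestamp,
    wear_end: pd.Timestamp,
    window_before_months: int = 6,
    window_after_months: int = 1,
) -> ImpairmentScore:
    """Mean severity of one participant's events inside the scoring window
    ``[wear_start - 6 months, wear_end + 1 month)``; no in-window events
    scores 0 (Norm-0)."""
    wear_start, wear_end = pd.Timestamp(wear_start), pd.Timestamp(wear_end)
    lo = wear_start - pd.DateOffset(months=window_before_months)
    hi = wear_end + pd.DateOffset(months=window_after_months)
    if hi <= lo:
        raise ValueError("invalid scoring window ordering")
    if len(events):
        dates = pd.to_datetime(events["date"])
        sel = events.loc[(dates >= lo) & (dates < hi)]
    else:
        sel = events
    if len(sel) == 0:
        score = 0.0
    else:
        score = float(np.mean([smap.severity_of(c) for c in sel["condition_class"]]))
    return ImpairmentScore(score=score, band=assign_band(score), window=(lo, hi), n_events=len(sel))


def identify_t2d(
    selfreport: pd.Series | dict,
    events: pd.DataFrame,
    assessment_date: pd.Timestamp,
    wear_start: pd.Timestamp,
    t2d_classes: frozenset[str] = frozenset({T2D_CLASS}),
) -> str:
    """Classify a participant's diabetes status.

    ``positive``: self-reported diabetes at assessment (unless excluded), or
    an incident T2D code dated strictly between assessment and wear start.
    ``excluded``: self-reported with insulin in the first year AND age at
    diagnosis < 35 (likely type 1 / monogenic).  ``negative`` otherwise;
    ``unresolvable`` when required dates are missing.
    """
    sr = selfreport if isinstance(selfreport, (pd.Series, dict)) else dict(selfreport)
    if pd.isna(assessment_date) or pd.isna(wear_start):
        return "unresolvable"
    assessment_date, wear_start = pd.Timestamp(assessment_date), pd.Timestamp(wear_start)
    if assessment_date > wear_start:
        raise ValueError("assessment date after wear start")
    if bool(sr.get("diabetes_diagnosed", False)):
        insulin = bool(sr.get("insulin_first_year", False))
        age_dx = sr.get("age_at_diagnosis", np.nan)
        if insulin and not pd.isna(age_dx) and float(age_dx) < 35:
            return "excluded"
        return "positive"
    if len(events):
        dates = pd.to_datetime(events["date"])
        incident = events["condition_class"].isin(t2d_classes) & (dates > assessment_date) & (
            dates < wear_start
        )
        if incident.any():
            return "positive"
    return "negative"


def build_cohort(
    selfreport: pd.DataFrame,
    ehr: pd.DataFrame,
    wear: pd.DataFrame,
    smap: SeverityMap | None = None,
    coverage: set[str] | None = None,
    window_before_months: int = 6,
    window_after_months: int = 1,
    band_thresholds: tuple[float, float] = (0.5, 1.5),
) -> pd.DataFrame:
    """One cohort label per participant.

    T2D positives keep their impairment score but are never excluded for
    it; negatives are banded Norm-0 / Norm-1 (excluded) / Norm-2.
    ``coverage`` restricts which participants count as EHR-covered —
    uncovered negatives are band-unknown and excluded from control sets.
    When ``coverage`` is None all participants are assumed covered (the
    synthetic generator links everyone to the EHR stream).
    """
    smap = smap or SeverityMap.default()
    ehr_by_pid = dict(tuple(ehr.groupby("participant_id"))) if len(ehr) else {}
    empty = ehr.iloc[0:0]
    wear_idx = wear.set_index("participant_id")
    rows = []
    for _, sr in selfreport.iterrows():
        pid = sr["participant_id"]
        w = wear_idx.loc[pid]
        events = ehr_by_pid.get(pid, empty)
        status = identify_t2d(
            sr, events, sr.get("assessment_date", w.get("assessment_date")), w["wear_start"],
            t2d_classes=smap.t2d_classes,
        )
        imp = severity_score(
            events, smap, w["wear_start"], w["wear_end"],
            window_before_months, window_after_months,
        )
        band = assign_band(imp.score, *band_thresholds)
        if status == "positive":
            label, reason = LABEL_T2D, ""
        elif status == "excluded":
            label, reason = LABEL_EXCLUDED, "insulin-age-exclusion"
        elif status == "unresolvable":
            label, reason = LABEL_EXCLUDED, "unresolvable-dates"
        elif coverage is not None and pid not in coverage:
            label, reason = LABEL_EXCLUDED, "no-ehr-coverage"
        else:
            label = band
            reason = "impairment-band" if band == LABEL_NORM1 else ""
        rows.append(
            {
                "participant_id": pid,
                "label": label,
                "score": imp.score,
                "band": band,
                "exclusion_reason": reason,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TrainingSet:
    """Participant ids with binary outcome labels for one experiment."""

    tag: str  # "TS1" or "TS2"
    table: pd.DataFrame = field(repr=False)  # participant_id, y
    seed: int | None = None

    @property
    def ids(self) -> list[str]:
        return self.table["participant_id"].tolist()

    @property
    def y(self) -> np.ndarray:
        return self.table["y"].to_numpy()


def build_training_sets(
    assignments: pd.DataFrame,
    seed: int = 0,
    norm0_sample_size: int | None = None,
) -> tuple[TrainingSet, TrainingSet]:
    """TS1 = all T2D vs a seeded half-sample of Norm-0 controls (class
    rebalancing); TS2 = all T2D vs all Norm-2 controls.  Norm-1 appears in
    neither; high-impairment T2D positives are retained.  The Norm-0 sample
    size defaults to floor(n/2) and is exposed as a parameter."""
    t2d = assignments.loc[assignments["label"] == LABEL_T2D, "participant_id"]
    norm0 = assignments.loc[assignments["label"] == LABEL_NORM0, "participant_id"]
    norm2 = assignments.loc[assignments["label"] == LABEL_NORM2, "participant_id"]
    for name, grp in (("T2D", t2d), ("Norm-0", norm0), ("Norm-2", norm2)):
        if len(grp) == 0:
            raise ValueError(f"empty class: no {name} participants")
    k = norm0_sample_size if norm0_sample_size is not None else len(norm0) // 2
    rng = np.random.default_rng(seed)
    sampled = sorted(rng.choice(sorted(norm0), size=k, replace=False).tolist())

    def _table(pos, neg):
        return pd.DataFrame(
            {
                "participant_id": list(pos) + list(neg),
                "y": [1] * len(pos) + [0] * len(neg),
            }
        )

    ts1 = TrainingSet(tag="TS1", table=_table(sorted(t2d), sampled), seed=seed)
    ts2 = TrainingSet(tag="TS2", table=_table(sorted(t2d), sorted(norm2)), seed=seed)
    return ts1, ts2
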