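"""Seeded synthetic populations: activity traces, demographics, EHR events.

The generator emulates the statistical structure the downstream analysis
assumes, per participant:

* one dominant nocturnal sleep block per noon-to-noon day, drawn from
  onset/duration distributions and optionally fragmented by brief
  wake interruptions;
* wake time filled by a semi-Markov renewal process — pick an activity by
  occupancy weight, draw a bout length from a shifted negative binomial
  (minimum one epoch), repeat;
* epoch-level completely-at-random missingness.

The default control profile is calibrated analytically so that the
expected 24-h occupancy reproduces the population mix of roughly
5% moderate, 42% sedentary, 38% sleep, 5% light tasks and 10% walking.
The renewal-process identity used for calibration: the long-run time share
of activity *a* is w_a·E[L_a] / Σ_b w_b·E[L_b], so picking weights
w_a ∝ share_a / E[L_a] reproduces the target shares for any bout-length
means.

Case/control contrast is injected through bout *structure* (longer
sedentary bouts, fewer walking bouts, more fragmented sleep), leaving the
aggregate 24-h mix nearly unchanged — mirroring cohorts in which the mix
itself carries little signal — plus shifts on a few demographic variables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bouts import (
    EPOCHS_PER_DAY,
    LABEL_TO_CODE,
    LABELS,
    MISSING_CODE,
    SLEEP_CODE,
    DayPhases,
    EpochSeries,
)

WAKE_ACTIVITIES: tuple[str, ...] = ("sedentary", "moderate", "walking", "light_tasks")
WAKE_PHASES: tuple[str, ...] = ("morning", "afternoon", "evening")

#: population 24-h activity mix the default control profile is calibrated to
TARGET_MIX: dict[str, float] = {
    "sedentary": 0.42,
    "moderate": 0.05,
    "walking": 0.10,
    "sleep": 0.38,
    "light_tasks": 0.05,
}

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class BoutLaw:
    """Shifted negative binomial bout-length law: L = 1 + NB(r, p) epochs,
    parameterised by its mean (>= 1 epoch) and dispersion r (smaller r =
    heavier tail)."""

    mean: float
    dispersion: float = 1.5

    def sample(self, rng: np.random.Generator, size: int | None = None):
        m1 = self.mean - 1.0
        if m1 <= 0:
            return np.ones(size or 1, dtype=np.int64) if size else 1
        p = self.dispersion / (self.dispersion + m1)
        draw = rng.negative_binomial(self.dispersion, p, size=size)
        return 1 + draw


@dataclass(frozen=True)
class Heterogeneity:
    """Between-person random-effect scales.

    Free-living populations are heterogeneous: two healthy adults differ
    far more from each other than one adult differs across days. Person
    effects are drawn once per participant — log-normal multipliers on
    bout-length means, occupancy shares and fragmentation rate, additive
    shifts on habitual sleep onset and duration — on top of the night-to-
    night variation the per-day draws already provide. Setting all scales
    to zero recovers the single-profile population.
    """

    bout_len_log_sd: float = 0.35
    share_log_sd: float = 0.25
    onset_sd_min: float = 35.0
    duration_sd_min: float = 50.0
    frag_log_sd: float = 0.5


@dataclass
class ActivityProfile:
    """Per-group generative parameters for one participant's trace."""

    wake_shares: dict[str, dict[str, float]]  # phase -> activity -> time share
    bout_laws: dict[tuple[str, str], BoutLaw]  # (activity, phase) -> law
    sleep_onset_mean_min: float = 1380.0  # 23:00
    sleep_onset_sd_min: float = 30.0  # night-to-night, within person
    sleep_duration_mean_min: float = 549.2
    sleep_duration_sd_min: float = 45.0
    sleep_frag_rate: float = 2.0  # expected interruptions / night
    interruption_mean_epochs: float = 2.0
    missing_rate: float = 0.02
    heterogeneity: Heterogeneity = field(default_factory=Heterogeneity)

    def validate(self) -> None:
        for phase in WAKE_PHASES:
            shares = self.wake_shares[phase]
            vals = np.array([shares[a] for a in WAKE_ACTIVITIES], dtype=float)
            if (vals < 0).any():
                raise ValueError(f"negative occupancy weight in phase {phase}")
            if not np.isclose(vals.sum(), 1.0, atol=1e-8):
                raise ValueError(f"occupancy weights in phase {phase} must sum to 1")
        for key, law in self.bout_laws.items():
            if law.mean < 1:
                raise ValueError(f"mean bout length < 1 epoch for {key}")
            if law.dispersion <= 0:
                raise ValueError(f"non-positive dispersion for {key}")
        if self.sleep_onset_sd_min < 0 or self.sleep_duration_sd_min < 0:
            raise ValueError("negative SD")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        if self.sleep_frag_rate < 0:
            raise ValueError("fragmentation rate must be >= 0")
        h = self.heterogeneity
        if min(h.bout_len_log_sd, h.share_log_sd, h.onset_sd_min, h.duration_sd_min,
               h.frag_log_sd) < 0:
            raise ValueError("heterogeneity scales must be >= 0")

    def personalized(self, rng: np.random.Generator) -> "ActivityProfile":
        """Draw one participant's own profile around the group profile.

        Log-normal multipliers are mean-one corrected so the population
        expectation of each parameter stays at the group value.
        """
        h = self.heterogeneity

        def lognorm(sd: float) -> float:
            return float(rng.lognormal(-0.5 * sd * sd, sd)) if sd > 0 else 1.0

        len_mult = {a: lognorm(h.bout_len_log_sd) for a in WAKE_ACTIVITIES}
        laws = {
            (a, p): dataclasses.replace(law, mean=1.0 + (law.mean - 1.0) * len_mult[a])
            for (a, p), law in self.bout_laws.items()
        }
        share_mult = {a: lognorm(h.share_log_sd) for a in WAKE_ACTIVITIES}
        shares = {}
        for p in WAKE_PHASES:
            s = {a: self.wake_shares[p][a] * share_mult[a] for a in WAKE_ACTIVITIES}
            tot = sum(s.values())
            shares[p] = {a: v / tot for a, v in s.items()}
        onset = self.sleep_onset_mean_min + (
            rng.normal(0, h.onset_sd_min) if h.onset_sd_min > 0 else 0.0
        )
        dur = self.sleep_duration_mean_min + (
            rng.normal(0, h.duration_sd_min) if h.duration_sd_min > 0 else 0.0
        )
        return dataclasses.replace(
            self,
            wake_shares=shares,
            bout_laws=laws,
            sleep_onset_mean_min=onset,
            sleep_duration_mean_min=max(dur, 120.0),
            sleep_frag_rate=self.sleep_frag_rate * lognorm(h.frag_log_sd),
            heterogeneity=Heterogeneity(0.0, 0.0, 0.0, 0.0, 0.0),
        )

    # -- derived sampling machinery -------------------------------------

    def pick_weights(self, phase: str) -> np.ndarray:
        """Renewal-calibrated picking probabilities for one wake phase."""
        shares = self.wake_shares[phase]
        w = np.array(
            [shares[a] / self.bout_laws[(a, phase)].mean for a in WAKE_ACTIVITIES]
        )
        return w / w.sum()

    def mean_wake_shares(self) -> np.ndarray:
        return np.mean(
            [[self.wake_shares[p][a] for a in WAKE_ACTIVITIES] for p in WAKE_PHASES],
            axis=0,
        )

    def nominal_phases(self) -> DayPhases:
        offset = (self.sleep_onset_mean_min + self.sleep_duration_mean_min) % 1440
        return DayPhases(onset=self.sleep_onset_mean_min % 1440, offset=offset)

    def with_effects(
        self,
        sedentary_bout_len_mult: float = 1.0,
        walking_rate_mult: float = 1.0,
        sleep_frag_mult: float = 1.0,
        sedentary_share_shift: float = 0.0,
    ) -> "ActivityProfile":
        """Return a new profile with group effects applied.

        The sedentary multiplier lengthens sedentary bouts at constant
        occupancy (fewer, longer bouts); the walking multiplier scales the
        walking occupancy share (then renormalised); the fragmentation
        multiplier scales nightly sleep interruptions; the share shift
        moves absolute occupancy into the sedentary class.
        """
        laws = dict(self.bout_laws)
        for p in WAKE_PHASES:
            law = laws[("sedentary", p)]
            laws[("sedentary", p)] = dataclasses.replace(
                law, mean=1.0 + (law.mean - 1.0) * sedentary_bout_len_mult
            )
        shares = {}
        for p in WAKE_PHASES:
            s = {a: self.wake_shares[p][a] for a in WAKE_ACTIVITIES}
            s["walking"] *= walking_rate_mult
            tot = sum(s.values())
            s = {a: v / tot for a, v in s.items()}
            rest = 1.0 - s["sedentary"]
            if sedentary_share_shift and rest > 0:
                shift = min(sedentary_share_shift, rest)
                for a in WAKE_ACTIVITIES:
                    if a != "sedentary":
                        s[a] *= (rest - shift) / rest
                s["sedentary"] += shift
            shares[p] = s
        return dataclasses.replace(
            self,
            wake_shares=shares,
            bout_laws=laws,
            sleep_frag_rate=self.sleep_frag_rate * sleep_frag_mult,
        )


def default_control_profile(missing_rate: float = 0.02) -> ActivityProfile:
    """Control profile calibrated to the target 24-h activity mix.

    Net sleep share 0.38 -> 547.2 min/night; the gross sleep-block duration
    adds back the expected time lost to interruptions (frag_rate x mean
    interruption length) so the net share stays on target.  Wake shares are
    the non-sleep mix renormalised, identical across the three wake phases.
    """
    wake_total = 1.0 - TARGET_MIX["sleep"]
    shares = {a: TARGET_MIX[a] / wake_total for a in WAKE_ACTIVITIES}
    bout_means = {"sedentary": 40.0, "moderate": 8.0, "walking": 6.0, "light_tasks": 10.0}
    frag_rate, interrupt_mean = 2.0, 2.0
    net_sleep = TARGET_MIX["sleep"] * MINUTES_PER_DAY
    gross_sleep = net_sleep + frag_rate * interrupt_mean * 0.5  # epochs -> minutes
    return ActivityProfile(
        wake_shares={p: dict(shares) for p in WAKE_PHASES},
        bout_laws={
            (a, p): BoutLaw(mean=bout_means[a]) for a in WAKE_ACTIVITIES for p in WAKE_PHASES
        },
        sleep_duration_mean_min=gross_sleep,
        sleep_frag_rate=frag_rate,
        interruption_mean_epochs=interrupt_mean,
        missing_rate=missing_rate,
    )


def generate_trace(
    profile: ActivityProfile,
    days: int,
    seed: int | np.random.Generator,
    participant_id: str = "P0",
    start: str | pd.Timestamp = "2014-06-02 12:00:00",
) -> EpochSeries:
    """Simulate one participant's epoch-label trace.

    Each noon-to-noon day gets a sleep block anchored at a drawn onset and
    duration (clamped inside the day), fragmented by Poisson-many brief wake
    interruptions; the remaining wake epochs are filled by the semi-Markov
    renewal draw with phase-dependent picking weights.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    profile.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profile = profile.personalized(rng)

    n = days * EPOCHS_PER_DAY
    codes = np.empty(n, dtype=np.int8)
    phases = profile.nominal_phases()
    wake_codes = np.array([LABEL_TO_CODE[a] for a in WAKE_ACTIVITIES], dtype=np.int8)
    weights = {1: None, 2: None, 3: None}
    for i, p in enumerate(WAKE_PHASES, start=1):
        weights[i] = profile.pick_weights(p)
    mean_shares = profile.mean_wake_shares()
    mean_shares = mean_shares / mean_shares.sum()
    interrupt_law = BoutLaw(mean=profile.interruption_mean_epochs, dispersion=1.0)

    def fill_wake(a: int, b: int) -> None:
        pos = a
        while pos < b:
            tod = (720.0 + (pos % EPOCHS_PER_DAY) * 0.5) % 1440
            ph = int(phases.phase_of(tod)[0])
            w = weights[ph] if ph else mean_shares  # inside nominal sleep: average mix
            act = wake_codes[rng.choice(len(WAKE_ACTIVITIES), p=w)]
            law = profile.bout_laws[(LABELS[act], WAKE_PHASES[ph - 1] if ph else "evening")]
            length = int(law.sample(rng))
            codes[pos : min(pos + length, b)] = act
            pos += length

    for d in range(days):
        base = d * EPOCHS_PER_DAY
        onset = rng.normal(profile.sleep_onset_mean_min, profile.sleep_onset_sd_min)
        dur = rng.normal(profile.sleep_duration_mean_min, profile.sleep_duration_sd_min)
        dur = float(np.clip(dur, 60.0, 1439.0))
        rel = int(round(((onset - 720.0) % 1440) * 2))
        s0 = base + min(rel, EPOCHS_PER_DAY - 1)
        s1 = min(s0 + int(round(dur * 2)), base + EPOCHS_PER_DAY)
        fill_wake(base, s0)
        codes[s0:s1] = SLEEP_CODE
        # fragment the night with brief wake interruptions
        n_frag = rng.poisson(profile.sleep_frag_rate)
        block = s1 - s0
        for _ in range(n_frag):
            if block <= 4:
                break
            pos = s0 + 1 + int(rng.integers(0, block - 2))
            length = int(interrupt_law.sample(rng))
            act = wake_codes[rng.choice(len(WAKE_ACTIVITIES), p=mean_shares)]
            codes[pos : min(pos + length, s1 - 1)] = act
        fill_wake(s1, base + EPOCHS_PER_DAY)

    if profile.missing_rate > 0:
        codes[rng.random(n) < profile.missing_rate] = MISSING_CODE
    return EpochSeries(participant_id=participant_id, start=pd.Timestamp(start), codes=codes)


# ---------------------------------------------------------------------------
# population-level generation


@dataclass
class PopulationConfig:
    """Study-condition knobs for a full synthetic population."""

    n_t2d: int = 100
    n_control: int = 100
    n_impaired_control: int = 50
    days: int = 7
    seed: int = 0
    # trace effects: T2D group (moderate, so discrimination sits in the
    # AUC range typical for free-living actigraphy case/control studies)
    sedentary_bout_len_mult: float = 1.3
    walking_rate_mult: float = 0.8
    sleep_frag_mult: float = 2.0
    # trace effects: impaired controls point the same way as the T2D
    # effects (reduced, more sedentary activity), so the impaired stratum
    # overlaps the case group and adds label noise to TS2
    impaired_sedentary_bout_len_mult: float = 1.25
    impaired_sedentary_share_shift: float = 0.02
    impaired_walking_rate_mult: float = 0.72
    impaired_sleep_frag_mult: float = 1.7
    # demographics
    t2d_demo_shift: dict[str, float] = field(
        default_factory=lambda: {
            "age": 4.0,
            "body_fat_pct": 5.0,
            "waist_cm": 7.0,
            "tv_time_h": 0.5,
            "walking_min_day": -14.0,
            "moderate_min_day": -9.0,
            "vigorous_min_day": -7.0,
            "sleep_duration_h": 0.2,
        }
    )
    impaired_demo_shift: dict[str, float] = field(
        default_factory=lambda: {
            "age": 5.0,
            "body_fat_pct": 3.5,
            "waist_cm": 5.0,
            "tv_time_h": 0.4,
            "walking_min_day": -15.0,
            "moderate_min_day": -7.0,
            "vigorous_min_day": -8.0,
        }
    )
    demo_missing_rate: float = 0.05
    epoch_missing_rate: float = 0.02
    # EHR event rates (expected counts per participant)
    benign_event_rate: float = 1.0  # in-window severity-0
    out_window_event_rate: float = 1.0
    impaired_event_rate: float = 2.0  # extra in-window severity-2 on top of 1
    incident_t2d_frac: float = 0.3

    def validate(self) -> None:
        if min(self.n_t2d, self.n_control, self.n_impaired_control) < 0:
            raise ValueError("group counts must be >= 0")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if not 0 <= self.demo_missing_rate < 1:
            raise ValueError("demographic missing rate must be in [0, 1)")
        for rate in (
            self.benign_event_rate,
            self.out_window_event_rate,
            self.impaired_event_rate,
        ):
            if rate < 0:
                raise ValueError("event rates must be >= 0")

    def null(self) -> "PopulationConfig":
        """A copy with every group effect switched off (no signal)."""
        return dataclasses.replace(
            self,
            sedentary_bout_len_mult=1.0,
            walking_rate_mult=1.0,
            sleep_frag_mult=1.0,
            impaired_sedentary_bout_len_mult=1.0,
            impaired_sedentary_share_shift=0.0,
            impaired_walking_rate_mult=1.0,
            impaired_sleep_frag_mult=1.0,
            t2d_demo_shift={},
            impaired_demo_shift={},
        )


@dataclass
class SyntheticPopulation:
    traces: dict[str, EpochSeries]
    demographics: pd.DataFrame
    ehr: pd.DataFrame
    selfreport: pd.DataFrame
    wear: pd.DataFrame
    labels: pd.Series  # participant_id -> {"t2d", "control", "impaired_control"}
    config: PopulationConfig


NUMERIC_DEMO_COLS = (
    "age",
    "body_fat_pct",
    "waist_cm",
    "sleep_duration_h",
    "tv_time_h",
    "townsend_index",
    "walking_min_day",
    "vigorous_min_day",
    "moderate_min_day",
)
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("Female", "Male"),
    "ethnic_group": ("Asian", "Black", "Other", "White"),
    "alcohol_status": ("Current", "Never", "Previous"),
    "smoking_status": ("Current", "Never", "Previous"),
}
#: the 13 sociodemographic / lifestyle / anthropometry variables
DEMO_COLUMNS = (
    "participant_id",
    "sex",
    "age",
    "ethnic_group",
    "alcohol_status",
    "smoking_status",
    "body_fat_pct",
    "waist_cm",
    "sleep_duration_h",
    "tv_time_h",
    "townsend_index",
    "walking_min_day",
    "vigorous_min_day",
    "moderate_min_day",
)

_DEMO_BASE = {
    "age": (56.0, 8.0),
    "body_fat_pct": (31.0, 7.0),
    "waist_cm": (90.0, 12.0),
    "sleep_duration_h": (7.2, 1.0),
    "tv_time_h": (2.8, 1.5),
    "townsend_index": (-1.0, 3.0),
    "walking_min_day": (60.0, 30.0),
    "vigorous_min_day": (20.0, 20.0),
    "moderate_min_day": (45.0, 25.0),
}
_CAT_PROBS = {
    "sex": (0.5, 0.5),
    "ethnic_group": (0.04, 0.04, 0.02, 0.90),
    "alcohol_status": (0.75, 0.10, 0.15),
    "smoking_status": (0.10, 0.55, 0.35),
}

# toy condition-class catalogue with Read-like code tokens
CONDITION_CLASSES: dict[str, tuple[str, int]] = {
    "routine_review": ("R001.", 0),
    "upper_resp_infection": ("H05z.", 0),
    "skin_rash": ("M21z.", 0),
    "mild_back_pain": ("N142.", 1),
    "depression": ("E2B..", 1),
    "asthma_mild": ("H33..", 1),
    "osteoarthritis_severe": ("N05z.", 2),
    "copd_severe": ("H3z..", 2),
    "hip_fracture": ("S30..", 2),
    "stroke": ("G66..", 2),
}
T2D_CLASS = "t2d_incident"
T2D_CODE = "C10F."


def _draw_demographics(
    rng: np.random.Generator, pids: list[str], shift: dict[str, float]
) -> pd.DataFrame:
    n = len(pids)
    data: dict[str, object] = {"participant_id": pids}
    data["sex"] = rng.choice(CATEGORICAL_LEVELS["sex"], size=n, p=_CAT_PROBS["sex"])
    for col, (mu, sd) in _DEMO_BASE.items():
        vals = rng.normal(mu + shift.get(col, 0.0), sd, size=n)
        if col == "age":
            vals = np.clip(vals, 40, 75)
        if col in ("walking_min_day", "vigorous_min_day", "moderate_min_day", "tv_time_h"):
            vals = np.clip(vals, 0, None)
        data[col] = np.round(vals, 2)
    for col in ("ethnic_group", "alcohol_status", "smoking_status"):
        data[col] = rng.choice(CATEGORICAL_LEVELS[col], size=n, p=_CAT_PROBS[col])
    return pd.DataFrame(data)[list(DEMO_COLUMNS)]


def _apply_mcar(
    rng: np.random.Generator, df: pd.DataFrame, rate: float
) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col == "participant_id":
            continue
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
    return out


def generate_ehr(
    config: PopulationConfig,
    labels: pd.Series,
    wear: pd.DataFrame,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """EHR event stream consistent with the group labels.

    Impaired controls get at least one high-severity (class-2) event dated
    inside the scoring window; clean controls get only severity-0 in-window
    events (plus arbitrary out-of-window history); a fraction of T2D cases
    carry an incident T2D code dated between assessment and wear start.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sev_classes = {s: [c for c, (_, sev) in CONDITION_CLASSES.items() if sev == s] for s in (0, 1, 2)}
    wear_idx = wear.set_index("participant_id")
    rows = []

    def add(pid: str, date: pd.Timestamp, cls: str) -> None:
        code = T2D_CODE if cls == T2D_CLASS else CONDITION_CLASSES[cls][0]
        rows.append(
            {"participant_id": pid, "date": date.normalize(), "code": code, "condition_class": cls}
        )

    for pid in labels.index:
        lab = labels[pid]
        w = wear_idx.loc[pid]
        lo = w["wear_start"] - pd.DateOffset(months=6)
        hi = w["wear_end"] + pd.DateOffset(months=1)
        span = (hi - lo).days

        def in_window_date() -> pd.Timestamp:
            return lo + pd.Timedelta(days=int(rng.integers(0, max(span, 1))))

        # benign in-window history only for non-impaired participants: the
        # impaired stratum is constructed to carry purely high-severity
        # in-window events so its mean severity is exactly 2
        if lab != "impaired_control":
            for _ in range(rng.poisson(config.benign_event_rate)):
                add(pid, in_window_date(), str(rng.choice(sev_classes[0])))
        for _ in range(rng.poisson(config.out_window_event_rate)):
            date = lo - pd.Timedelta(days=int(rng.integers(30, 1500)))
            add(pid, date, str(rng.choice(sev_classes[0] + sev_classes[1] + sev_classes[2])))
        if lab == "impaired_control":
            for _ in range(1 + rng.poisson(config.impaired_event_rate)):
                add(pid, in_window_date(), str(rng.choice(sev_classes[2])))
        if lab == "t2d" and rng.random() < config.incident_t2d_frac:
            gap = (w["wear_start"] - w["assessment_date"]).days
            date = w["assessment_date"] + pd.Timedelta(days=int(rng.integers(1, max(gap, 2))))
            add(pid, date, T2D_CLASS)

    df = pd.DataFrame(rows, columns=["participant_id", "date", "code", "condition_class"])
    if not df.empty:
        df = df.sort_values(["participant_id", "date"], kind="stable").reset_index(drop=True)
    return df


def generate_population(config: PopulationConfig) -> SyntheticPopulation:
    """Simulate a full seeded case/control/impaired-control population.

    One master seed deterministically spawns independent substreams for
    the traces (one per participant), demographics, EHR and dates, so the
    population is byte-identical for a given config and reproducible under
    any generation order.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_t2d + config.n_control + config.n_impaired_control
    children = ss.spawn(n_total + 3)
    rng_demo = np.random.default_rng(children[n_total])
    rng_dates = np.random.default_rng(children[n_total + 1])
    rng_ehr = np.random.default_rng(children[n_total + 2])

    control = default_control_profile(missing_rate=config.epoch_missing_rate)
    t2d_profile = control.with_effects(
        sedentary_bout_len_mult=config.sedentary_bout_len_mult,
        walking_rate_mult=config.walking_rate_mult,
        sleep_frag_mult=config.sleep_frag_mult,
    )
    impaired_profile = control.with_effects(
        sedentary_bout_len_mult=config.impaired_sedentary_bout_len_mult,
        walking_rate_mult=config.impaired_walking_rate_mult,
        sleep_frag_mult=config.impaired_sleep_frag_mult,
        sedentary_share_shift=config.impaired_sedentary_share_shift,
    )

    groups = (
        ["t2d"] * config.n_t2d
        + ["control"] * config.n_control
        + ["impaired_control"] * config.n_impaired_control
    )
    pids = [f"P{i:05d}" for i in range(n_total)]
    labels = pd.Series(groups, index=pids, name="label")
    labels.index.name = "participant_id"

    wear_starts = pd.Timestamp("2014-01-06") + pd.to_timedelta(
        rng_dates.integers(0, 360, size=n_total), unit="D"
    )
    traces: dict[str, EpochSeries] = {}
    profile_of = {"t2d": t2d_profile, "control": control, "impaired_control": impaired_profile}
    for i, pid in enumerate(pids):
        start = wear_starts[i].normalize() + pd.Timedelta(hours=12)
        traces[pid] = generate_trace(
            profile_of[groups[i]],
            days=config.days,
            seed=np.random.default_rng(children[i]),
            participant_id=pid,
            start=start,
        )

    wear = pd.DataFrame(
        {
            "participant_id": pids,
            "wear_start": [t.start.normalize() for t in traces.values()],
            "wear_end": [
                t.start.normalize() + pd.Timedelta(days=config.days) for t in traces.values()
            ],
        }
    )
    wear["assessment_date"] = wear["wear_start"] - pd.to_timedelta(
        rng_dates.integers(600, 1200, size=n_total), unit="D"
    )

    demo_parts = []
    for group, shift_name in (
        ("t2d", "t2d_demo_shift"),
        ("control", None),
        ("impaired_control", "impaired_demo_shift"),
    ):
        gp = [p for p, g in zip(pids, groups) if g == group]
        if not gp:
            continue
        shift = getattr(config, shift_name) if shift_name else {}
        demo_parts.append(_draw_demographics(rng_demo, gp, shift))
    demographics = pd.concat(demo_parts, ignore_index=True) if demo_parts else _draw_demographics(
        rng_demo, [], {}
    )
    demographics = _apply_mcar(rng_demo, demographics, config.demo_missing_rate)

    ehr = generate_ehr(config, labels, wear, rng_ehr)
    incident_pids = set(ehr.loc[ehr["condition_class"] == T2D_CLASS, "participant_id"])
    selfreport = pd.DataFrame(
        {
            "participant_id": pids,
            "diabetes_diagnosed": [
                (g == "t2d") and (p not in incident_pids) for p, g in zip(pids, groups)
            ],
            "insulin_first_year": False,
            "age_at_diagnosis": np.where(
                [g == "t2d" for g in groups],
                np.round(rng_demo.uniform(40, 65, size=n_total), 1),
                np.nan,
            ),
        }
    ).merge(wear[["participant_id", "assessment_date"]], on="participant_id")

    return SyntheticPopulation(
        traces=traces,
        demographics=demographics,
        ehr=ehr,
        selfreport=selfreport,
        wear=wear,
        labels=labels,
        config=config,
    )
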