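"""Real-world physical behavior measures derived from an event series.

Per calendar day the recording is summarized into wear/nonwear time, an
intensity partition of wear time (sedentary / light / moderate-to-vigorous /
primary lying), step counts, and time in stepping bouts of at least one
minute.  A day is *valid* when the monitor was worn at least ``min_wear_h``
hours (default 10, inclusive), and a subject is *included* with at least
``min_valid_days`` valid days (default 4).  Per-subject averages are taken
over valid days only; the two cadence measures (duration-weighted median
cadence of stepping bouts, and peak 30-second cadence) pool bouts and
windows across all valid days rather than averaging per-day values.

Intensity is classified from the event stream alone: sedentary events are
sedentary, standing is light, and stepping is light below the cadence
threshold (default 100 steps/min) and moderate-to-vigorous at or above it.
Primary lying and nonwear are excluded from the intensity classes but
primary lying still counts as wear.

Fragmentation metrics describe how active (upright) and sedentary time are
accumulated: the active-to-sedentary transition probability (ASTP) is the
reciprocal of the mean active-bout duration in minutes, SATP analogously,
and a Gini coefficient over sedentary bout durations captures inequality in
how sedentary time is accrued.  Primary lying and nonwear break bouts and
are excluded, as are day boundaries.

Undefined measures (e.g. cadence with no qualifying bout) propagate as NaN,
never as silently imputed zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime
from typing import Iterable, Sequence

import numpy as np

from .events import (
    DayPartition,
    EventRecord,
    EventSeries,
    UPRIGHT_LABELS,
    partition_days,
)

DEFAULT_MIN_WEAR_H = 10.0
DEFAULT_MIN_VALID_DAYS = 4
DEFAULT_MVPA_CADENCE_SPM = 100.0
DEFAULT_BOUT_MIN_S = 60.0
DEFAULT_WINDOW_S = 30.0


@dataclass(frozen=True)
class Bout:
    """A maximal run of stepping events (total duration >= the minimum)."""

    start: datetime
    duration_s: float
    steps: int

    @property
    def cadence_spm(self) -> float:
        return self.steps / (self.duration_s / 60.0)


@dataclass
class FragmentationSet:
    astp: float  # active-to-sedentary transition probability, per minute
    satp: float
    mean_active_bout_min: float
    mean_sedentary_bout_min: float
    gini_sedentary_bouts: float


@dataclass
class DailyMeasures:
    date: date
    wear_min: float
    nonwear_min: float
    sedentary_min: float
    light_min: float
    mvpa_min: float
    primary_lying_min: float
    steps: int
    bout_time_min: float
    valid: bool


@dataclass
class SubjectBehaviorSummary:
    subject_id: str
    n_valid_days: int
    included: bool
    avg_nonwear_min: float
    avg_sedentary_min: float
    avg_steps: float
    avg_light_min: float
    avg_mvpa_min: float
    avg_bout_time_min: float
    weighted_median_cadence_spm: float
    peak_30s_cadence_spm: float
    fragmentation: FragmentationSet


def wear_minutes(day: DayPartition) -> float:
    """Minutes of all non-nonwear events (primary lying counts as wear)."""
    return sum(ev.duration_s for ev in day.events if ev.activity != "nonwear") / 60.0


def flag_valid_day(day: DayPartition, min_wear_h: float = DEFAULT_MIN_WEAR_H) -> bool:
    return wear_minutes(day) >= min_wear_h * 60.0


def flag_included_subject(
    daily: Sequence[DailyMeasures], min_valid_days: int = DEFAULT_MIN_VALID_DAYS
) -> bool:
    return sum(1 for d in daily if d.valid) >= min_valid_days


def _activity_minutes(day: DayPartition, activity: str) -> float:
    return sum(ev.duration_s for ev in day.events if ev.activity == activity) / 60.0


def sedentary_minutes(day: DayPartition) -> float:
    """Minutes of secondary lying (awake sitting/lying); primary lying excluded."""
    return _activity_minutes(day, "sedentary")


def classify_intensity(
    event: EventRecord, mvpa_cadence_spm: float = DEFAULT_MVPA_CADENCE_SPM
) -> str:
    """Classify one event as sedentary / light / mvpa / excluded."""
    if event.activity == "sedentary":
        return "sedentary"
    if event.activity == "standing":
        return "light"
    if event.activity == "stepping":
        cadence = event.steps / (event.duration_s / 60.0)
        return "mvpa" if cadence >= mvpa_cadence_spm else "light"
    return "excluded"  # primary_lying, nonwear


def daily_steps(day: DayPartition) -> int:
    return sum(ev.steps for ev in day.events if ev.activity == "stepping")


def detect_stepping_bouts(
    day: DayPartition,
    min_duration_s: float = DEFAULT_BOUT_MIN_S,
    max_gap_s: float = 0.0,
) -> list[Bout]:
    """Maximal stepping runs of total duration >= ``min_duration_s``.

    A run is a sequence of consecutive stepping events; non-stepping
    interruptions up to ``max_gap_s`` (default none) are tolerated inside a
    run and count toward its duration.  The duration boundary is inclusive:
    a run of exactly ``min_duration_s`` qualifies.
    """
    bouts: list[Bout] = []
    run_start: datetime | None = None
    run_end: datetime | None = None
    run_steps = 0

    def flush() -> None:
        nonlocal run_start, run_end, run_steps
        if run_start is not None:
            duration = (run_end - run_start).total_seconds()
            if duration >= min_duration_s:
                bouts.append(Bout(run_start, duration, run_steps))
        run_start, run_end, run_steps = None, None, 0

    for ev in day.events:
        if ev.activity == "stepping":
            if run_start is None:
                run_start, run_end, run_steps = ev.start, ev.end, ev.steps
            else:
                run_end, run_steps = ev.end, run_steps + ev.steps
        elif run_start is not None:
            if ev.duration_s <= max_gap_s:
                run_end = ev.end  # tolerated interruption, steps unchanged
            else:
                flush()
    flush()
    return bouts


def weighted_median_cadence(bouts: Iterable[Bout]) -> float:
    """Duration-weighted (lower) median of bout cadences, in steps/min.

    Bouts are sorted by cadence and weighted by duration; the result is the
    smallest cadence at which cumulative weight reaches half the total.
    Returns NaN for an empty bout list (undefined measure).
    """
    bouts = sorted(bouts, key=lambda b: b.cadence_spm)
    if not bouts:
        return math.nan
    total = sum(b.duration_s for b in bouts)
    acc = 0.0
    for b in bouts:
        acc += b.duration_s
        if acc >= total / 2.0:
            return b.cadence_spm
    return bouts[-1].cadence_spm  # numerically unreachable


def _second_grid_step_rates(day: DayPartition) -> np.ndarray:
    """Steps laid out at uniform rate within each stepping event on the
    1-second grid of the day (cell k covers [k, k+1) after midnight)."""
    arr = np.zeros(86400)
    midnight = datetime.combine(day.date, datetime.min.time())
    for ev in day.events:
        if ev.activity != "stepping" or ev.steps == 0:
            continue
        s0 = (ev.start - midnight).total_seconds()
        s1 = s0 + ev.duration_s
        rate = ev.steps / ev.duration_s
        i0, i1 = int(math.floor(s0)), int(math.ceil(s1 - 1e-12))
        if abs(s0 - round(s0)) < 1e-9 and abs(s1 - round(s1)) < 1e-9:
            arr[int(round(s0)) : int(round(s1))] += rate
            continue
        for k in range(i0, min(i1, 86400)):
            overlap = min(k + 1.0, s1) - max(float(k), s0)
            if overlap > 0:
                arr[k] += rate * overlap
    return arr


def peak_30s_cadence(
    series: EventSeries,
    valid_dates: Iterable[date],
    window_s: float = DEFAULT_WINDOW_S,
) -> float:
    """Maximum step total over sliding windows on valid days, as steps/min.

    Windows slide at a 1-second stride over each valid day's 1-second grid;
    the best window's step total is scaled by 60/window_s and reported to
    one decimal.  Returns 0.0 when no stepping occurs on any valid day.
    """
    valid = set(valid_dates)
    w = int(round(window_s))
    best = 0.0
    for day in partition_days(series):
        if day.date not in valid:
            continue
        rates = _second_grid_step_rates(day)
        if not rates.any():
            continue
        csum = np.concatenate([[0.0], np.cumsum(rates)])
        windows = csum[w:] - csum[:-w]
        best = max(best, float(windows.max()))
    return round(best * (60.0 / window_s), 1)


def _gini(values: Sequence[float]) -> float:
    """Gini coefficient by the mean-absolute-difference formula."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0 or x.sum() == 0:
        return math.nan
    i = np.arange(1, n + 1)
    return float((2.0 * np.sum(i * x)) / (n * x.sum()) - (n + 1.0) / n)


def _bout_runs(day: DayPartition) -> tuple[list[float], list[float]]:
    """Active (upright) and sedentary bout durations, in minutes.

    Primary lying and nonwear break bouts; day boundaries break bouts.
    """
    active: list[float] = []
    sedentary: list[float] = []
    cur_kind: str | None = None
    cur_dur = 0.0

    def flush() -> None:
        nonlocal cur_kind, cur_dur
        if cur_kind == "active":
            active.append(cur_dur / 60.0)
        elif cur_kind == "sedentary":
            sedentary.append(cur_dur / 60.0)
        cur_kind, cur_dur = None, 0.0

    for ev in day.events:
        kind = (
            "active"
            if ev.activity in UPRIGHT_LABELS
            else "sedentary"
            if ev.activity == "sedentary"
            else None
        )
        if kind != cur_kind:
            flush()
            cur_kind = kind
        if kind is not None:
            cur_dur += ev.duration_s
    flush()
    return active, sedentary


def fragmentation_metrics(
    series: EventSeries, valid_dates: Iterable[date]
) -> FragmentationSet:
    """ASTP/SATP, mean bout durations, and sedentary-bout Gini on valid days.

    ASTP = number of active bouts / total active minutes, i.e. exactly the
    reciprocal of the mean active bout duration; SATP analogously.  With no
    active or no sedentary bouts the affected fields are NaN.
    """
    valid = set(valid_dates)
    active: list[float] = []
    sedentary: list[float] = []
    for day in partition_days(series):
        if day.date not in valid:
            continue
        a, s = _bout_runs(day)
        active.extend(a)
        sedentary.extend(s)
    astp = len(active) / sum(active) if active else math.nan
    satp = len(sedentary) / sum(sedentary) if sedentary else math.nan
    return FragmentationSet(
        astp=astp,
        satp=satp,
        mean_active_bout_min=sum(active) / len(active) if active else math.nan,
        mean_sedentary_bout_min=(
            sum(sedentary) / len(sedentary) if sedentary else math.nan
        ),
        gini_sedentary_bouts=_gini(sedentary) if sedentary else math.nan,
    )


def daily_measures(
    day: DayPartition,
    min_wear_h: float = DEFAULT_MIN_WEAR_H,
    mvpa_cadence_spm: float = DEFAULT_MVPA_CADENCE_SPM,
    bout_min_s: float = DEFAULT_BOUT_MIN_S,
    bout_max_gap_s: float = 0.0,
) -> DailyMeasures:
    light = mvpa = 0.0
    for ev in day.events:
        cls = classify_intensity(ev, mvpa_cadence_spm)
        if cls == "light":
            light += ev.duration_s
        elif cls == "mvpa":
            mvpa += ev.duration_s
    bouts = detect_stepping_bouts(day, bout_min_s, bout_max_gap_s)
    return DailyMeasures(
        date=day.date,
        wear_min=wear_minutes(day),
        nonwear_min=_activity_minutes(day, "nonwear"),
        sedentary_min=sedentary_minutes(day),
        light_min=light / 60.0,
        mvpa_min=mvpa / 60.0,
        primary_lying_min=_activity_minutes(day, "primary_lying"),
        steps=daily_steps(day),
        bout_time_min=sum(b.duration_s for b in bouts) / 60.0,
        valid=flag_valid_day(day, min_wear_h),
    )


def summarize_subject(
    series: EventSeries,
    *,
    min_wear_h: float = DEFAULT_MIN_WEAR_H,
    min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
    mvpa_cadence_spm: float = DEFAULT_MVPA_CADENCE_SPM,
    bout_min_s: float = DEFAULT_BOUT_MIN_S,
    bout_max_gap_s: float = 0.0,
    window_s: float = DEFAULT_WINDOW_S,
) -> SubjectBehaviorSummary:
    """Average daily measures over valid days; pool cadence across valid days."""
    days = partition_days(series)
    daily = [
        daily_measures(d, min_wear_h, mvpa_cadence_spm, bout_min_s, bout_max_gap_s)
        for d in days
    ]
    valid_days = [d for d in daily if d.valid]
    valid_dates = {d.date for d in valid_days}
    included = flag_included_subject(daily, min_valid_days)

    if not valid_days:
        nan = math.nan
        return SubjectBehaviorSummary(
            series.subject_id, 0, False, nan, nan, nan, nan, nan, nan, nan, nan,
            FragmentationSet(nan, nan, nan, nan, nan),
        )

    def avg(attr: str) -> float:
        return float(np.mean([getattr(d, attr) for d in valid_days]))

    pooled_bouts: list[Bout] = []
    for day in days:
        if day.date in valid_dates:
            pooled_bouts.extend(detect_stepping_bouts(day, bout_min_s, bout_max_gap_s))

    return SubjectBehaviorSummary(
        subject_id=series.subject_id,
        n_valid_days=len(valid_days),
        included=included,
        avg_nonwear_min=avg("nonwear_min"),
        avg_sedentary_min=avg("sedentary_min"),
        avg_steps=avg("steps"),
        avg_light_min=avg("light_min"),
        avg_mvpa_min=avg("mvpa_min"),
        avg_bout_time_min=avg("bout_time_min"),
        weighted_median_cadence_spm=weighted_median_cadence(pooled_bouts),
        peak_30s_cadence_spm=peak_30s_cadence(series, valid_dates, window_s),
        fragmentation=fragmentation_metrics(series, valid_dates),
    )
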