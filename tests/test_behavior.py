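"""Behavior measures against brute-force oracles and boundary rules."""

from __future__ import annotations

import math
from datetime import datetime

import numpy as np
import pytest

from stepfit import (
    Bout,
    detect_stepping_bouts,
    fragmentation_metrics,
    partition_days,
    peak_30s_cadence,
    summarize_subject,
    weighted_median_cadence,
)
from stepfit.behavior import (
    classify_intensity,
    daily_measures,
    daily_steps,
    flag_included_subject,
    flag_valid_day,
    sedentary_minutes,
    wear_minutes,
)

from conftest import T0, make_series, random_series


# --- brute-force oracles -------------------------------------------------

def brute_bouts(day, min_duration_s=60.0):
    """Run-length scan over the raw event list."""
    out, run = [], []
    for ev in day.events + [None]:
        if ev is not None and ev.activity == "stepping":
            run.append(ev)
            continue
        if run:
            dur = (run[-1].end - run[0].start).total_seconds()
            if dur >= min_duration_s:
                out.append((run[0].start, dur, sum(e.steps for e in run)))
            run = []
    return out


def brute_weighted_median(bouts):
    """Expand bouts into 1-second atoms of their cadence and walk the CDF."""
    atoms = sorted(
        (b.cadence_spm, 1.0) for b in bouts for _ in range(int(round(b.duration_s)))
    )
    total = sum(w for _, w in atoms)
    acc = 0.0
    for cad, w in atoms:
        acc += w
        if acc >= total / 2.0:
            return cad
    raise AssertionError("unreachable")


def brute_peak_window(day, window_s=30):
    """Exhaustive max over every 1 s-stride window of the day grid."""
    arr = np.zeros(86400)
    midnight = datetime.combine(day.date, datetime.min.time())
    for ev in day.events:
        if ev.activity != "stepping":
            continue
        s0 = (ev.start - midnight).total_seconds()
        s1 = s0 + ev.duration_s
        for k in range(int(math.floor(s0)), int(math.ceil(s1))):
            overlap = min(k + 1, s1) - max(k, s0)
            if overlap > 0:
                arr[k] += ev.steps / ev.duration_s * overlap
    best = 0.0
    for k in range(0, 86400 - window_s + 1):
        best = max(best, arr[k : k + window_s].sum())
    return best


# --- daily bookkeeping ---------------------------------------------------

def test_wear_minutes_cases():
    all_nonwear = partition_days(make_series([("nonwear", 7200, 0)]))[0]
    assert wear_minutes(all_nonwear) == 0.0
    mixed = partition_days(
        make_series([("sedentary", 14 * 3600, 0), ("nonwear", 10 * 3600, 0)])
    )[0]
    assert wear_minutes(mixed) == 840.0


def test_valid_day_boundary_is_inclusive_at_10_hours():
    def day_with_wear(minutes):
        return partition_days(
            make_series([("sedentary", minutes * 60, 0),
                         ("nonwear", (1300 - minutes) * 60, 0)])
        )[0]

    assert flag_valid_day(day_with_wear(600)) is True
    assert flag_valid_day(day_with_wear(599)) is False
    assert flag_valid_day(day_with_wear(594)) is False  # 9.9 h


def test_subject_inclusion_needs_four_valid_days():
    class D:  # minimal stand-in with .valid
        def __init__(self, valid):
            self.valid = valid

    assert flag_included_subject([D(True)] * 4 + [D(False)] * 3) is True
    assert flag_included_subject([D(True)] * 3 + [D(False)] * 4) is False
    assert flag_included_subject([D(True)] * 13) is True


def test_sedentary_excludes_primary_lying():
    day = partition_days(
        make_series([("primary_lying", 6 * 3600, 0), ("standing", 3600, 0)])
    )[0]
    assert sedentary_minutes(day) == 0.0


def test_intensity_classification_boundaries():
    def ev(activity, dur, steps=0):
        return make_series([(activity, dur, steps)]).events[0]

    assert classify_intensity(ev("standing", 60)) == "light"
    assert classify_intensity(ev("stepping", 60, 120)) == "mvpa"  # 120 spm
    # 99.9 spm sits just under the default threshold
    assert classify_intensity(ev("stepping", 600, 999)) == "light"
    assert classify_intensity(ev("primary_lying", 60)) == "excluded"
    assert classify_intensity(ev("nonwear", 60)) == "excluded"


def test_daily_steps_sums_stepping_only():
    day = partition_days(
        make_series(
            [("stepping", 60, 100), ("standing", 30, 0), ("stepping", 60, 200),
             ("sedentary", 300, 0), ("stepping", 90, 300)]
        )
    )[0]
    assert daily_steps(day) == 600
    empty = partition_days(make_series([("standing", 600, 0)]))[0]
    assert daily_steps(empty) == 0


# --- bouts and cadence ---------------------------------------------------

def test_single_long_stepping_event_is_a_bout():
    day = partition_days(make_series([("stepping", 90, 150)]))[0]
    (bout,) = detect_stepping_bouts(day)
    assert bout.duration_s == 90 and bout.steps == 150
    assert bout.cadence_spm == pytest.approx(100.0)


def test_gap_breaks_run_under_strict_contiguity():
    day = partition_days(
        make_series([("stepping", 30, 50), ("standing", 10, 0), ("stepping", 30, 50)])
    )[0]
    assert detect_stepping_bouts(day, max_gap_s=0) == []
    # with a 10 s tolerance the two halves merge into one 70 s bout
    (bout,) = detect_stepping_bouts(day, max_gap_s=10)
    assert bout.duration_s == 70 and bout.steps == 100


def test_exact_minimum_duration_qualifies():
    day = partition_days(make_series([("stepping", 60, 100)]))[0]
    assert len(detect_stepping_bouts(day, min_duration_s=60)) == 1


def test_weighted_median_examples():
    one = [Bout(T0, 60, 98)]
    assert weighted_median_cadence(one) == pytest.approx(98.0)
    two = [Bout(T0, 60, 80), Bout(T0, 180, 330)]  # 80 spm vs 110 spm
    assert weighted_median_cadence(two) == pytest.approx(110.0)
    assert brute_weighted_median(two) == pytest.approx(110.0)
    same = [Bout(T0, d, int(d * 1.5)) for d in (60, 120, 300)]  # all 90 spm
    assert weighted_median_cadence(same) == pytest.approx(90.0)
    assert math.isnan(weighted_median_cadence([]))


def test_weighted_median_invariant_to_splitting_a_bout():
    rng = np.random.default_rng(3)
    for _ in range(30):
        durs = rng.integers(60, 600, size=6)
        bouts = [Bout(T0, int(d), int(d)) for d in durs]  # 60 spm each? no:
        bouts = [
            Bout(T0, int(d), int(d * c / 60))
            for d, c in zip(durs, rng.integers(60, 140, size=6))
        ]
        i = int(rng.integers(0, len(bouts)))
        b = bouts[i]
        half = int(b.duration_s) // 2
        if half < 1 or b.steps % 2:
            continue
        split = bouts[:i] + [
            Bout(b.start, half, b.steps // 2),
            Bout(b.start, b.duration_s - half, b.steps - b.steps // 2),
        ] + bouts[i + 1 :]
        if abs(split[i].cadence_spm - b.cadence_spm) > 1e-9:
            continue  # only exact same-cadence splits are invariant
        assert weighted_median_cadence(split) == pytest.approx(
            weighted_median_cadence(bouts)
        )


def test_peak_30s_constant_rate_and_empty():
    series = make_series([("stepping", 600, 1000)], start=T0.replace(hour=9))
    dates = {T0.date()}
    assert peak_30s_cadence(series, dates) == pytest.approx(100.0)
    quiet = make_series([("standing", 600, 0)], start=T0.replace(hour=9))
    assert peak_30s_cadence(quiet, dates) == 0.0


def test_fragmentation_trivial_cases():
    # active bouts of exactly 2 min -> astp = 0.5 per minute
    specs = []
    for _ in range(5):
        specs += [("standing", 120, 0), ("sedentary", 300, 0)]
    series = make_series(specs, start=T0.replace(hour=8))
    frag = fragmentation_metrics(series, {T0.date()})
    assert frag.astp == pytest.approx(0.5)
    assert frag.mean_active_bout_min == pytest.approx(2.0)
    # equal sedentary bouts -> gini 0
    assert frag.gini_sedentary_bouts == pytest.approx(0.0, abs=1e-12)
    assert frag.satp == pytest.approx(1 / frag.mean_sedentary_bout_min)


def test_fragmentation_lying_and_nonwear_break_bouts():
    series = make_series(
        [("standing", 60, 0), ("nonwear", 600, 0), ("standing", 60, 0),
         ("primary_lying", 600, 0), ("standing", 60, 0), ("sedentary", 120, 0)],
        start=T0.replace(hour=8),
    )
    frag = fragmentation_metrics(series, {T0.date()})
    assert frag.mean_active_bout_min == pytest.approx(1.0)
    assert frag.astp == pytest.approx(1.0)


# --- fuzzed oracle agreement --------------------------------------------

def test_measures_match_brute_force_on_fuzzed_series():
    rng = np.random.default_rng(101)
    for _ in range(60):
        series = random_series(rng, int(rng.integers(20, 300)),
                               start=T0.replace(hour=int(rng.integers(0, 24))))
        for day in partition_days(series):
            assert daily_steps(day) == sum(
                ev.steps for ev in day.events if ev.activity == "stepping"
            )
            assert sedentary_minutes(day) == pytest.approx(
                sum(ev.duration_s for ev in day.events
                    if ev.activity == "sedentary") / 60
            )
            got = detect_stepping_bouts(day)
            want = brute_bouts(day)
            assert [(b.start, b.duration_s, b.steps) for b in got] == want

            bouts = detect_stepping_bouts(day)
            if bouts:
                assert weighted_median_cadence(bouts) == pytest.approx(
                    brute_weighted_median(bouts)
                )
            # reported to one decimal: within half a reporting unit of the
            # exact oracle value
            peak = peak_30s_cadence(series, {day.date})
            assert peak == pytest.approx(brute_peak_window(day) * 2.0, abs=0.05001)

            frag = fragmentation_metrics(series, {day.date})
            # astp oracle: count/sum over brute-force runs
            runs, cur = [], None
            for ev in day.events + [None]:
                kind = None
                if ev is not None:
                    kind = ("active" if ev.activity in ("standing", "stepping")
                            else "sed" if ev.activity == "sedentary" else None)
                if cur and (ev is None or kind != cur[0]):
                    runs.append(cur)
                    cur = None
                if kind and cur is None:
                    cur = [kind, 0.0]
                if kind and cur:
                    cur[1] += ev.duration_s
            active = [d / 60 for k, d in runs if k == "active"]
            if active:
                assert frag.astp == pytest.approx(len(active) / sum(active))


def test_partition_property_intensity_tiles_the_recorded_day():
    rng = np.random.default_rng(7)
    for _ in range(40):
        series = random_series(rng, int(rng.integers(10, 200)))
        for day in partition_days(series):
            m = daily_measures(day)
            recorded_min = day.total_s / 60
            assert (
                m.sedentary_min + m.light_min + m.mvpa_min
                + m.primary_lying_min + m.nonwear_min
            ) == pytest.approx(recorded_min, abs=1e-6)
            assert m.wear_min + m.nonwear_min == pytest.approx(recorded_min, abs=1e-6)


def test_scaling_steps_scales_counts_and_never_lowers_peak():
    rng = np.random.default_rng(13)
    for _ in range(10):
        series = random_series(rng, 80, start=T0.replace(hour=8))
        dates = {d.date for d in partition_days(series)}
        base_days = [daily_steps(d) for d in partition_days(series)]
        base_peak = peak_30s_cadence(series, dates)
        k = 3
        scaled = make_series(
            [(ev.activity, ev.duration_s, ev.steps * k) for ev in series.events]
        )
        assert [daily_steps(d) for d in partition_days(scaled)] == [
            s * k for s in base_days
        ]
        assert peak_30s_cadence(scaled, dates) >= base_peak


def test_summarize_identical_days_and_exclusions():
    day_spec = [
        ("primary_lying", 8 * 3600, 0), ("sedentary", 6 * 3600, 0),
        ("stepping", 1200, 2000), ("standing", 2 * 3600, 0),
        ("sedentary", 86400 - 8 * 3600 - 6 * 3600 - 1200 - 2 * 3600, 0),
    ]
    series = make_series(day_spec * 7)
    s = summarize_subject(series)
    assert s.n_valid_days == 7 and s.included
    assert s.avg_steps == pytest.approx(2000)
    assert s.avg_sedentary_min == pytest.approx(
        (6 * 3600 + 86400 - 8 * 3600 - 6 * 3600 - 1200 - 2 * 3600) / 60
    )
    assert s.avg_mvpa_min == pytest.approx(20.0)  # 2000 steps / 20 min = 100 spm

    # a subject with 3 valid days is excluded, with measures still computed
    short = make_series(day_spec * 3)
    s3 = summarize_subject(short)
    assert s3.n_valid_days == 3 and not s3.included

    # zero valid days: all measures missing
    nw = make_series([("nonwear", 86400, 0)] * 2)
    s0 = summarize_subject(nw)
    assert s0.n_valid_days == 0 and not s0.included
    assert math.isnan(s0.avg_steps) and math.isnan(s0.weighted_median_cadence_spm)
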