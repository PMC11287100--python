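"""Shared fixtures: series builders, fuzzed recordings, cached cohorts."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from stepfit import EventRecord, EventSeries, SimulationConfig, simulate_cohort

T0 = datetime(2022, 3, 7, 0, 0, 0)


def make_series(
    specs: list[tuple[str, float, int]],
    subject_id: str = "S1",
    start: datetime = T0,
) -> EventSeries:
    """Build a contiguous series from (activity, duration_s, steps) tuples."""
    events = []
    t = start
    for activity, dur, steps in specs:
        events.append(EventRecord(subject_id, t, float(dur), activity, int(steps)))
        t += timedelta(seconds=dur)
    return EventSeries(subject_id, events)


def random_series(
    rng: np.random.Generator,
    n_events: int,
    subject_id: str = "S1",
    start: datetime = T0,
) -> EventSeries:
    """A random valid contiguous series (whole-second events)."""
    activities = ["primary_lying", "sedentary", "standing", "stepping", "nonwear"]
    specs = []
    for _ in range(n_events):
        act = activities[rng.integers(0, len(activities))]
        dur = int(rng.integers(5, 900))
        steps = int(rng.integers(2, max(3, dur * 3))) if act == "stepping" else 0
        specs.append((act, dur, steps))
    return make_series(specs, subject_id, start)


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort reused by pipeline-level tests."""
    return simulate_cohort(SimulationConfig(n_subjects=12, n_days=4, seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort (n=86, 7 days)."""
    return simulate_cohort(SimulationConfig(seed=11))
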