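"""Synthetic cancer-survivor cohort with a known latent structure.

No raw data accompany the study design this package implements, so every
pipeline stage is exercised against a generator that emulates the cohort:
~86 disease-free cancer survivors wearing a thigh accelerometer for 7 days,
answering the FACT-G, and performing a submaximal treadmill test.

Two standard-normal latent traits drive everything: aerobic *fitness* F and
*well-being* W, jointly Gaussian with correlation ``rho_fw`` (default 0.15).
The defaults encode the study's qualitative finding — behavior volume is
coupled to fitness (``b_steps`` = 0.35 on the log step scale) far more than
to well-being (``b_wb_behavior`` = 0.05) — while both couplings are
configurable so null and reversed worlds can be generated for error-rate
studies.

Each simulated day is a contiguous event sequence: an overnight primary
lying block, a waking period tiled by alternating sedentary and upright
runs (upright runs interleave standing segments with stepping events), and
an evening lying block; nonwear blocks with exponential total duration
(mean ``nonwear_min_mean``) are inserted between runs.  Expected daily
steps are exp(log(steps_mean) + b_steps*F + b_wb_behavior*W + noise)
(variance-corrected so the cohort mean lands near ``steps_mean``), clipped
to [1400, 17500]; a configurable fraction of steps is delivered in long
(>= 1 min) stepping bouts whose cadence is Normal(99 + 4 F, 10) truncated
at 40 steps/min, the rest in short sporadic stepping events at lower
cadence.  Between-subject log-step noise defaults to 0.45 so that the
recovered step-fitness and step-wellbeing correlations land near the
magnitudes the design targets (rho ~ 0.5 and ~ 0.1 respectively), rather
than matching the cohort's cross-sectional SD exactly.

FACT-G item responses come from thresholded Gaussians loaded on W, with the
top cut calibrated numerically so the expected fraction of subjects at the
5-item-subset maximum equals ``ceiling_target`` (default 20%), which also
makes the subset distribution strongly left-skewed.  Treadmill duration is
T = clip(t_base + b_t*F + noise, 0.5, 25) minutes, tuned so the predicted
submaximal VO2 cohort mean sits near 29 mL/kg/min.

Identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator
from scipy import optimize, stats as sps

from .events import EventRecord, EventSeries, write_event_series
from .scores import ITEM_BLUEPRINT


class SimulationConfig(BaseModel):
    """All generator knobs; defaults are the emulated study conditions."""

    n_subjects: int = 86
    n_days: int = 7
    seed: int = 0
    start_date: date = date(2022, 3, 7)

    # latent structure
    rho_fw: float = 0.15  # fitness-wellbeing correlation
    b_steps: float = 0.35  # fitness -> log daily steps
    b_wb_behavior: float = 0.05  # wellbeing -> log daily steps
    b_t: float = 4.0  # fitness -> treadmill duration, min per latent SD
    t_base_min: float = 15.1
    t_noise_sd_min: float = 2.0

    # behavior volumes (Table-2-like cohort targets)
    steps_mean: float = 6916.0
    steps_subject_sd_log: float = 0.45
    steps_day_sd_log: float = 0.25
    steps_min: float = 1400.0
    steps_max: float = 17500.0
    bout_step_fraction: float = 0.36
    bout_cadence_mean: float = 99.0
    bout_cadence_fitness_slope: float = 4.0
    bout_cadence_sd: float = 10.0
    sporadic_cadence_mean: float = 85.0
    sporadic_cadence_fitness_slope: float = 3.0
    sporadic_cadence_sd: float = 12.0
    cadence_floor: float = 40.0

    # day structure (hours for clock anchors, minutes for spreads)
    wake_mean_h: float = 7.1
    wake_sd_min: float = 25.0
    sleep_mean_h: float = 22.3
    sleep_sd_min: float = 25.0
    nonwear_min_mean: float = 36.0
    standing_mean_min: float = 215.0
    standing_sd_min: float = 35.0
    upright_runs_mean: float = 14.0

    # questionnaire
    ceiling_target: float = 0.20
    item_loading_physical: float = 0.8
    item_loading_other: float = 0.55
    item_cut_spacing: float = 0.85
    other_cut_shift: float = -0.35

    # demographics (cohort-table moments)
    age_mean: float = 55.4
    age_sd: float = 12.9
    age_min: float = 21.0
    age_max: float = 85.0
    p_female: float = 0.71
    bmi_mean: float = 27.4
    bmi_sd: float = 5.2
    bmi_min: float = 18.0
    bmi_max: float = 43.0
    months_dx_log_mean: float = 3.220  # lognormal matched to mean 32, sd 25.5
    months_dx_log_sd: float = 0.701
    stage_labels: tuple[str, ...] = ("0", "I", "II", "III", "IV", "Unsure")
    stage_counts: tuple[int, ...] = (4, 15, 22, 29, 9, 7)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if not -1.0 < self.rho_fw < 1.0:
            raise ValueError("rho_fw must lie in (-1, 1)")
        for name in (
            "steps_mean", "steps_subject_sd_log", "nonwear_min_mean",
            "standing_mean_min", "t_noise_sd_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.ceiling_target < 1.0:
            raise ValueError("ceiling_target must lie in [0, 1)")
        if len(self.stage_labels) != len(self.stage_counts):
            raise ValueError("stage_labels and stage_counts lengths differ")
        return self


@dataclass
class SubjectLatents:
    subject_id: str
    fitness: float  # F, standard normal
    wellbeing: float  # W, standard normal, corr(F, W) = rho_fw
    steps_log_offset: float  # subject-level log-step noise
    age: float
    sex: str
    bmi: float
    months_since_dx: float
    stage: str


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    latents: list[SubjectLatents]
    event_series: list[EventSeries]
    cohort: pd.DataFrame
    ground_truth: dict


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_latents(
    config: SimulationConfig, rng: np.random.Generator
) -> list[SubjectLatents]:
    """Draw latent traits and demographics for the whole cohort."""
    n = config.n_subjects
    cov = np.array([[1.0, config.rho_fw], [config.rho_fw, 1.0]])
    fw = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    offsets = rng.normal(0.0, config.steps_subject_sd_log, size=n)
    age = _truncated_normal(
        rng, config.age_mean, config.age_sd, config.age_min, config.age_max, n
    )
    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    bmi = _truncated_normal(
        rng, config.bmi_mean, config.bmi_sd, config.bmi_min, config.bmi_max, n
    )
    months = rng.lognormal(config.months_dx_log_mean, config.months_dx_log_sd, size=n)
    probs = np.array(config.stage_counts, dtype=float)
    probs /= probs.sum()
    stage = rng.choice(config.stage_labels, size=n, p=probs)
    width = max(3, len(str(n)))
    return [
        SubjectLatents(
            subject_id=f"S{i + 1:0{width}d}",
            fitness=float(fw[i, 0]),
            wellbeing=float(fw[i, 1]),
            steps_log_offset=float(offsets[i]),
            age=float(round(age[i], 1)),
            sex=str(sex[i]),
            bmi=float(round(bmi[i], 1)),
            months_since_dx=float(round(months[i], 1)),
            stage=str(stage[i]),
        )
        for i in range(n)
    ]


def _int_partition(
    total_s: int, n: int, rng: np.random.Generator, min_s: int
) -> list[int]:
    """Split ``total_s`` into n positive integer parts, each >= min_s."""
    if n <= 0:
        return []
    if total_s < n * min_s:
        base, rem = divmod(total_s, n)
        return [base + (1 if i < rem else 0) for i in range(n)]
    spare = total_s - n * min_s
    w = rng.dirichlet(np.ones(n))
    parts = [min_s + int(math.floor(wi * spare)) for wi in w]
    parts[-1] += total_s - sum(parts)
    return parts


def _expected_daily_steps(lat: SubjectLatents, config: SimulationConfig) -> float:
    """Subject-level expected steps before day noise and clipping."""
    var = (
        config.b_steps**2
        + config.b_wb_behavior**2
        + 2 * config.b_steps * config.b_wb_behavior * config.rho_fw
        + config.steps_subject_sd_log**2
        + config.steps_day_sd_log**2
    )
    mu = math.log(config.steps_mean) - 0.5 * var  # mean-preserving correction
    return math.exp(
        mu
        + config.b_steps * lat.fitness
        + config.b_wb_behavior * lat.wellbeing
        + lat.steps_log_offset
    )


def _stepping_inventory(
    target_steps: float,
    lat: SubjectLatents,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(duration_s, steps) for bout-length and sporadic stepping events."""

    def cadence(mean: float, slope: float, sd: float) -> float:
        return max(
            config.cadence_floor, rng.normal(mean + slope * lat.fitness, sd)
        )

    bouts: list[tuple[int, int]] = []
    bout_target = config.bout_step_fraction * target_steps
    got = 0.0
    while got < bout_target:
        dur = int(np.clip(rng.lognormal(math.log(170.0), 0.5), 60, 1200))
        cad = cadence(
            config.bout_cadence_mean,
            config.bout_cadence_fitness_slope,
            config.bout_cadence_sd,
        )
        steps = max(2, int(math.floor(dur * cad / 60.0 + 0.5)))
        bouts.append((dur, steps))
        got += steps

    sporadic: list[tuple[int, int]] = []
    sporadic_target = target_steps - min(got, target_steps)
    got = 0.0
    while got < sporadic_target:
        dur = int(rng.integers(8, 46))
        cad = cadence(
            config.sporadic_cadence_mean,
            config.sporadic_cadence_fitness_slope,
            config.sporadic_cadence_sd,
        )
        steps = max(2, int(math.floor(dur * cad / 60.0 + 0.5)))
        sporadic.append((dur, steps))
        got += steps
    return bouts, sporadic


def simulate_event_series(
    lat: SubjectLatents, config: SimulationConfig, rng: np.random.Generator
) -> EventSeries:
    """One subject's contiguous 7-day (by default) event recording."""
    sid = lat.subject_id
    events: list[EventRecord] = []
    expected = _expected_daily_steps(lat, config)

    for d in range(config.n_days):
        day = config.start_date + timedelta(days=d)
        midnight = datetime.combine(day, time.min)

        wake_s = int(
            np.clip(
                rng.normal(config.wake_mean_h * 3600, config.wake_sd_min * 60),
                5.0 * 3600,
                9.5 * 3600,
            )
        )
        sleep_s = int(
            np.clip(
                rng.normal(config.sleep_mean_h * 3600, config.sleep_sd_min * 60),
                20.0 * 3600,
                23.8 * 3600,
            )
        )
        waking_s = sleep_s - wake_s

        target = float(
            np.clip(
                expected * math.exp(rng.normal(0.0, config.steps_day_sd_log)),
                config.steps_min,
                config.steps_max,
            )
        )
        bouts, sporadic = _stepping_inventory(target, lat, config, rng)
        stepping = [("bout", d_, s_) for d_, s_ in bouts] + [
            ("spor", d_, s_) for d_, s_ in sporadic
        ]
        t_step = sum(d_ for _, d_, _s in stepping)

        nonwear_total = int(
            min(rng.exponential(config.nonwear_min_mean) * 60, 150 * 60)
        )
        n_nonwear = 0 if nonwear_total < 60 else (1 if nonwear_total < 45 * 60 else 2)
        nonwear_parts = _int_partition(nonwear_total, n_nonwear, rng, 60)

        t_stand = int(
            max(
                45 * 60,
                rng.normal(config.standing_mean_min * 60, config.standing_sd_min * 60),
            )
        )
        n_upright = max(1, int(rng.poisson(config.upright_runs_mean)))
        # sedentary time absorbs the remainder of the waking window
        t_sed = waking_s - sum(nonwear_parts) - t_step - t_stand
        min_sed = 60 * (n_upright + 1)
        if t_sed < min_sed:  # long-stepping day: give back standing time
            t_stand = max(30 * 60, t_stand - (min_sed - t_sed))
            t_sed = waking_s - sum(nonwear_parts) - t_step - t_stand
        if t_sed < min_sed:
            nonwear_parts = []
            t_sed = waking_s - t_step - t_stand

        # distribute stepping events over upright runs
        run_events: list[list[tuple[str, int, int]]] = [[] for _ in range(n_upright)]
        for item in stepping:
            run_events[int(rng.integers(0, n_upright))].append(item)
        n_stand_segments = len(stepping) + n_upright
        stand_parts = _int_partition(t_stand, n_stand_segments, rng, 5)
        sed_parts = _int_partition(t_sed, n_upright + 1, rng, 60)

        # top-level alternation: sed, upright, sed, ..., upright, sed
        blocks: list[tuple[str, int, int]] = []
        si = iter(stand_parts)
        for i in range(n_upright):
            blocks.append(("sedentary", sed_parts[i], 0))
            blocks.append(("standing", next(si), 0))
            for _, dur, steps in run_events[i]:
                blocks.append(("stepping", dur, steps))
                blocks.append(("standing", next(si), 0))
        blocks.append(("sedentary", sed_parts[-1], 0))

        # nonwear blocks slot between top-level blocks
        for part in nonwear_parts:
            pos = int(rng.integers(0, len(blocks) + 1))
            blocks.insert(pos, ("nonwear", part, 0))

        t = midnight
        events.append(EventRecord(sid, t, float(wake_s), "primary_lying"))
        t += timedelta(seconds=wake_s)
        for activity, dur, steps in blocks:
            if dur <= 0:
                continue
            events.append(EventRecord(sid, t, float(dur), activity, steps))
            t += timedelta(seconds=dur)
        tail = 86400 - int((t - midnight).total_seconds())
        events.append(EventRecord(sid, t, float(tail), "primary_lying"))

    return EventSeries(sid, events)


@lru_cache(maxsize=32)
def _ceiling_top_cut(target: float, loading: float) -> float:
    """Top threshold tau with E_W[P(all 5 subset items at max | W)] = target."""
    if target <= 0.0:
        return math.inf
    s = math.sqrt(1.0 - loading**2)
    nodes, weights = np.polynomial.hermite.hermgauss(80)
    w = nodes * math.sqrt(2.0)  # standard-normal quadrature points
    wt = weights / math.sqrt(math.pi)

    def expected_ceiling(tau: float) -> float:
        return float(np.sum(wt * sps.norm.sf((tau - loading * w) / s) ** 5))

    return float(optimize.brentq(lambda t: expected_ceiling(t) - target, -6.0, 6.0))


def simulate_questionnaire(
    lat: SubjectLatents, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, int]:
    """FACT-G raw responses (0-4 per item) driven by the well-being latent.

    Each item discretizes z = loading*W + noise at four ordered cuts; the
    top cut is calibrated so the 5-item-subset ceiling fraction matches
    ``ceiling_target`` in expectation, yielding the strongly left-skewed,
    ceiling-limited score distributions typical of this instrument.
    """
    tau = _ceiling_top_cut(config.ceiling_target, config.item_loading_physical)
    out: dict[str, int] = {}
    for item_id, (subscale, polarity) in ITEM_BLUEPRINT.items():
        if subscale in ("physical", "functional"):
            loading, top = config.item_loading_physical, tau
        else:
            loading, top = (
                config.item_loading_other,
                (tau if math.isfinite(tau) else 6.0) + config.other_cut_shift,
            )
        z = loading * lat.wellbeing + math.sqrt(1.0 - loading**2) * rng.normal()
        good = 0
        for level in range(4, 0, -1):
            if z >= top - config.item_cut_spacing * (4 - level):
                good = level
                break
        out[item_id] = 4 - good if polarity == "negative" else good
    return out


def simulate_treadmill(
    lat: SubjectLatents, config: SimulationConfig, rng: np.random.Generator
) -> float:
    """Submaximal treadmill duration T (minutes to 70% heart-rate reserve)."""
    t = config.t_base_min + config.b_t * lat.fitness + rng.normal(
        0.0, config.t_noise_sd_min
    )
    return float(np.clip(round(t, 2), 0.5, 25.0))


def simulate_cohort(
    config: SimulationConfig | None = None, out_dir: str | Path | None = None
) -> SimulatedCohort:
    """Generate the full cohort; optionally write the file bundle.

    Outputs (under ``out_dir`` when given): one events CSV per subject in
    ``events/``, a ``cohort.csv`` with item responses, demographics and the
    treadmill duration, and ``ground_truth.json`` with the config echo and
    per-subject latent values for recovery tests.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    latents = simulate_latents(config, rng)

    rows = []
    series_list = []
    for lat in latents:
        items = simulate_questionnaire(lat, config, rng)
        t_min = simulate_treadmill(lat, config, rng)
        series_list.append(simulate_event_series(lat, config, rng))
        rows.append(
            {
                "subject_id": lat.subject_id,
                **items,
                "age": lat.age,
                "sex": lat.sex,
                "bmi": lat.bmi,
                "months_since_dx": lat.months_since_dx,
                "stage": lat.stage,
                "treadmill_T_min": t_min,
            }
        )
    cohort = pd.DataFrame(rows)

    ground_truth = {
        "config": json.loads(config.model_dump_json()),
        "subjects": [
            {
                "subject_id": lat.subject_id,
                "fitness": lat.fitness,
                "wellbeing": lat.wellbeing,
                "steps_log_offset": lat.steps_log_offset,
                "expected_daily_steps": _expected_daily_steps(lat, config),
                "treadmill_T_min": float(row["treadmill_T_min"]),
            }
            for lat, row in zip(latents, rows)
        ],
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        events_dir = out_dir / "events"
        events_dir.mkdir(parents=True, exist_ok=True)
        for series in series_list:
            write_event_series(series, events_dir / f"{series.subject_id}.csv")
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        with (out_dir / "ground_truth.json").open("w", encoding="utf-8") as fh:
            json.dump(ground_truth, fh, indent=1, sort_keys=True)

    return SimulatedCohort(config, latents, series_list, cohort, ground_truth)
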