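"""End-to-end analysis: events -> measures -> scores -> associations.

The pipeline mirrors a cross-sectional wearable-sensor analysis: derive
per-subject behavior summaries from event recordings, score the
questionnaire and treadmill data, describe the self-reported score
distributions, correlate behavior with the self-reported measures and with
aerobic fitness (plain and partial Spearman), compare tertile/median splits
with normality-gated tests (Holm-adjusted within each family), and run the
coefficient-equality comparison over the behavior x outcome grid.

Every stage is deterministic given its inputs; subjects excluded for
insufficient valid days are recorded in the run log with reasons.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__ as _version
from .behavior import summarize_subject
from .compare import (
    DegenerateDesignError,
    ModelSpec,
    _encode_sex,
    _encode_stage,
    compare_coefficient_equality,
)
from .events import EventSeries, read_event_series
from .scores import (
    FACTG_TOTAL_MAX,
    ITEM_BLUEPRINT,
    PWB5_MAX,
    PWB_MAX,
    CrosswalkTable,
    link_promis_pf,
    load_crosswalk,
    predict_submax_vo2,
    score_factg,
)
from .stats import (
    adjust_family,
    compare_groups,
    describe_distribution,
    median_split,
    partial_spearman,
    rin_transform,
    spearman,
    tertile_split,
)

log = logging.getLogger("stepfit")

BEHAVIOR_MEASURES = (
    "avg_sedentary_min",
    "avg_steps",
    "avg_light_min",
    "avg_mvpa_min",
    "avg_bout_time_min",
    "wmed_cadence_spm",
    "peak30_cadence_spm",
)
FRAGMENTATION_MEASURES = ("astp", "satp", "gini_sed")
OUTCOMES = ("factg_total", "pwb", "pwb5", "promis_pf_t")
OUTCOME_MAXIMA = {
    "factg_total": FACTG_TOTAL_MAX,
    "pwb": PWB_MAX,
    "pwb5": PWB5_MAX,
    "promis_pf_t": None,  # T metric has no hard instrument maximum
}

SUMMARY_COLUMNS = [
    "subject_id", "n_valid_days", "included", "avg_sedentary_min", "avg_steps",
    "avg_light_min", "avg_mvpa_min", "avg_bout_time_min", "wmed_cadence_spm",
    "peak30_cadence_spm", "astp", "satp", "gini_sed",
]
CORRELATION_COLUMNS = ["measure_x", "measure_y", "rho", "n", "p", "covariates"]
SPLIT_COLUMNS = [
    "behavior_measure", "outcome", "split_a", "split_b", "test", "statistic",
    "p_raw", "p_holm",
]
COMPARISON_COLUMNS = [
    "behavior_measure", "outcome", "n", "beta_outcome", "beta_vo2", "F", "df2",
    "p", "direction",
]


class Thresholds(BaseModel):
    min_wear_h: float = 10.0
    min_valid_days: int = 4
    mvpa_cadence_spm: float = 100.0
    bout_min_s: float = 60.0
    bout_max_gap_s: float = 0.0
    window_s: float = 30.0
    shapiro_alpha: float = 0.05


class AnalysisConfig(BaseModel):
    """One structured configuration object; no hidden defaults elsewhere."""

    events_path: str
    cohort_path: str
    out_dir: str = "stepfit_out"
    crosswalk_path: str | None = None  # None -> packaged synthetic placeholder
    thresholds: Thresholds = Field(default_factory=Thresholds)
    covariates: tuple[str, ...] = ("age", "sex", "bmi", "months_since_dx", "stage")
    behavior_measures: tuple[str, ...] = BEHAVIOR_MEASURES
    outcomes: tuple[str, ...] = OUTCOMES
    fitness: str = "vo2"
    tertile_pairs: str = "all"  # or "extremes": high-vs-medium, high-vs-low
    include_fragmentation_comparisons: bool = False
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with Path(path).open(encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=True)


@dataclass
class ReportBundle:
    subject_summary: pd.DataFrame
    distributions: pd.DataFrame
    correlations: pd.DataFrame
    split_comparisons: pd.DataFrame
    coefficient_comparisons: pd.DataFrame
    run_log: dict


def load_events(path: str | Path) -> list[EventSeries]:
    """Read one events CSV, or every ``*.csv`` in a directory."""
    path = Path(path)
    if path.is_dir():
        series: list[EventSeries] = []
        for f in sorted(path.glob("*.csv")):
            series.extend(read_event_series(f))
        return series
    return read_event_series(path)


def summarize_cohort_behavior(
    series_list: list[EventSeries], thresholds: Thresholds | None = None
) -> pd.DataFrame:
    """Per-subject behavior summary table (documented interface columns)."""
    th = thresholds or Thresholds()
    rows = []
    for series in series_list:
        s = summarize_subject(
            series,
            min_wear_h=th.min_wear_h,
            min_valid_days=th.min_valid_days,
            mvpa_cadence_spm=th.mvpa_cadence_spm,
            bout_min_s=th.bout_min_s,
            bout_max_gap_s=th.bout_max_gap_s,
            window_s=th.window_s,
        )
        rows.append(
            {
                "subject_id": s.subject_id,
                "n_valid_days": s.n_valid_days,
                "included": s.included,
                "avg_sedentary_min": s.avg_sedentary_min,
                "avg_steps": s.avg_steps,
                "avg_light_min": s.avg_light_min,
                "avg_mvpa_min": s.avg_mvpa_min,
                "avg_bout_time_min": s.avg_bout_time_min,
                "wmed_cadence_spm": s.weighted_median_cadence_spm,
                "peak30_cadence_spm": s.peak_30s_cadence_spm,
                "astp": s.fragmentation.astp,
                "satp": s.fragmentation.satp,
                "gini_sed": s.fragmentation.gini_sedentary_bouts,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def score_cohort(
    cohort: pd.DataFrame, crosswalk: CrosswalkTable | None = None
) -> pd.DataFrame:
    """Score FACT-G / subset / linked PROMIS-PF and predicted VO2 per row."""
    crosswalk = crosswalk or load_crosswalk()
    item_ids = [c for c in cohort.columns if c in ITEM_BLUEPRINT]
    rows = []
    for _, row in cohort.iterrows():
        items = {}
        for iid in item_ids:
            v = row[iid]
            items[iid] = None if pd.isna(v) else int(v)
        scores = score_factg(items)
        promis = (
            link_promis_pf(scores.pwb5, crosswalk)
            if not math.isnan(scores.pwb5)
            else math.nan
        )
        t_min = row.get("treadmill_T_min", math.nan)
        sex = row.get("sex", "")
        vo2 = (
            predict_submax_vo2(float(t_min), str(sex))
            if pd.notna(t_min) and float(t_min) > 0 and str(sex) in ("female", "male")
            else math.nan
        )
        rows.append(
            {
                "subject_id": row["subject_id"],
                "factg_total": scores.total,
                "pwb": scores.pwb,
                "pwb5": scores.pwb5,
                "promis_pf_t": promis,
                "vo2": vo2,
                "age": row.get("age", math.nan),
                "sex": sex,
                "bmi": row.get("bmi", math.nan),
                "months_since_dx": row.get("months_since_dx", math.nan),
                "stage": row.get("stage", None),
            }
        )
    return pd.DataFrame(rows)


def describe_selfreport(scored: pd.DataFrame, outcomes=OUTCOMES) -> pd.DataFrame:
    """Distribution summary (mean, sd, range, shape, ceiling) per measure."""
    rows = []
    for m in [*outcomes, "vo2"]:
        if m not in scored.columns:
            continue
        vals = scored[m].to_numpy(dtype=float)
        if np.isfinite(vals).sum() < 3:
            continue
        d = describe_distribution(vals, OUTCOME_MAXIMA.get(m))
        rows.append({"measure": m, **dataclasses.asdict(d)})
    return pd.DataFrame(rows)


def _covariate_frame(merged: pd.DataFrame, covariates) -> pd.DataFrame:
    cov = pd.DataFrame(index=merged.index)
    for c in covariates:
        if c == "sex":
            cov[c] = _encode_sex(merged[c])
        elif c == "stage":
            cov[c] = _encode_stage(merged[c])
        else:
            cov[c] = pd.to_numeric(merged[c], errors="coerce")
    return cov


def correlation_table(merged: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Long-format plain and partial Spearman correlations.

    Behavior measures (and fragmentation metrics) against each self-reported
    outcome and fitness, plus fitness against the self-reported outcomes.
    """
    cov = _covariate_frame(merged, config.covariates)
    cov_label = "+".join(config.covariates)
    xs = [*config.behavior_measures, *FRAGMENTATION_MEASURES]
    pairs = [(x, y) for x in xs for y in [*config.outcomes, config.fitness]]
    pairs += [(config.fitness, y) for y in config.outcomes]
    rows = []
    for x, y in pairs:
        plain = spearman(merged[x], merged[y])
        partial = partial_spearman(merged[x], merged[y], cov)
        rows.append(
            {"measure_x": x, "measure_y": y, "rho": plain.rho, "n": plain.n,
             "p": plain.p, "covariates": ""}
        )
        rows.append(
            {"measure_x": x, "measure_y": y, "rho": partial.rho, "n": partial.n,
             "p": partial.p, "covariates": cov_label}
        )
    return pd.DataFrame(rows, columns=CORRELATION_COLUMNS)


def split_comparison_table(
    merged: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Tertile (self-reported) and median (fitness) split comparisons.

    Within each behavior-measure x self-reported-measure family the pairwise
    p-values are Holm-adjusted; the fitness median split is a single
    comparison per measure.
    """
    alpha = config.thresholds.shapiro_alpha
    tertile_pairs = (
        [("low", "medium"), ("low", "high"), ("medium", "high")]
        if config.tertile_pairs == "all"
        else [("medium", "high"), ("low", "high")]
    )
    rows = []
    for outcome in config.outcomes:
        vals = merged[outcome].to_numpy(dtype=float)
        if np.isfinite(vals).sum() < 3:
            continue
        split = tertile_split(vals)
        for measure in config.behavior_measures:
            results = []
            kept_pairs = []
            for a, b in tertile_pairs:
                ga = merged.loc[split.group(a), measure].dropna()
                gb = merged.loc[split.group(b), measure].dropna()
                if len(ga) < 3 or len(gb) < 3:
                    continue
                results.append(compare_groups(ga, gb, alpha))
                kept_pairs.append((a, b))
            if results:
                adjust_family(results)
            for (a, b), r in zip(kept_pairs, results):
                rows.append(
                    {"behavior_measure": measure, "outcome": outcome,
                     "split_a": a, "split_b": b, "test": r.test,
                     "statistic": r.statistic, "p_raw": r.p_raw,
                     "p_holm": r.p_holm}
                )

    fit_vals = merged[config.fitness].to_numpy(dtype=float)
    if np.isfinite(fit_vals).sum() >= 6:
        split = median_split(fit_vals)
        for measure in config.behavior_measures:
            ga = merged.loc[split.group("low"), measure].dropna()
            gb = merged.loc[split.group("high"), measure].dropna()
            if len(ga) < 3 or len(gb) < 3:
                continue
            r = compare_groups(ga, gb, alpha)
            adjust_family([r])
            rows.append(
                {"behavior_measure": measure, "outcome": config.fitness,
                 "split_a": "low", "split_b": "high", "test": r.test,
                 "statistic": r.statistic, "p_raw": r.p_raw, "p_holm": r.p_holm}
            )
    return pd.DataFrame(rows, columns=SPLIT_COLUMNS)


def coefficient_comparison_table(
    merged: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """The behavior x outcome grid of coefficient-equality F tests."""
    measures = list(config.behavior_measures)
    if config.include_fragmentation_comparisons:
        measures += list(FRAGMENTATION_MEASURES)
    rows = []
    for measure in measures:
        for outcome in config.outcomes:
            spec = ModelSpec(
                response=measure, outcome=outcome, fitness=config.fitness,
                covariates=tuple(config.covariates),
            )
            try:
                t = compare_coefficient_equality(merged, spec)
            except DegenerateDesignError as exc:
                log.warning("comparison %s ~ %s skipped: %s", measure, outcome, exc)
                rows.append(
                    {"behavior_measure": measure, "outcome": outcome, "n": 0,
                     "beta_outcome": math.nan, "beta_vo2": math.nan,
                     "F": math.nan, "df2": 0, "p": math.nan, "direction": ""}
                )
                continue
            rows.append(
                {"behavior_measure": measure, "outcome": outcome, "n": t.n,
                 "beta_outcome": t.beta_outcome, "beta_vo2": t.beta_vo2,
                 "F": t.F, "df2": t.df2, "p": t.p, "direction": t.direction}
            )
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)


def analyze_cohort(
    series_list: list[EventSeries],
    cohort: pd.DataFrame,
    config: AnalysisConfig,
    crosswalk: CrosswalkTable | None = None,
) -> ReportBundle:
    """Run every analysis stage on in-memory inputs."""
    summary = summarize_cohort_behavior(series_list, config.thresholds)
    excluded = summary.loc[~summary["included"], "subject_id"].tolist()
    for sid in excluded:
        n = int(summary.loc[summary["subject_id"] == sid, "n_valid_days"].iloc[0])
        log.info(
            "subject %s excluded: %d valid day(s) < %d required",
            sid, n, config.thresholds.min_valid_days,
        )
    scored = score_cohort(cohort, crosswalk)
    distributions = describe_selfreport(scored, config.outcomes)

    included = summary.loc[summary["included"]]
    merged = included.merge(scored, on="subject_id", how="inner")
    run_log = {
        "stepfit_version": _version,
        "config": json.loads(config.model_dump_json()),
        "n_series": len(series_list),
        "n_cohort_rows": len(cohort),
        "n_included": len(included),
        "excluded_subjects": excluded,
        "n_analyzed": len(merged),
    }
    if merged.empty:
        log.warning("no subjects meet the valid-day inclusion rule; "
                    "association tables will be empty")
        empty_corr = pd.DataFrame(columns=CORRELATION_COLUMNS)
        empty_split = pd.DataFrame(columns=SPLIT_COLUMNS)
        empty_comp = pd.DataFrame(columns=COMPARISON_COLUMNS)
        return ReportBundle(summary, distributions, empty_corr, empty_split,
                            empty_comp, run_log)

    return ReportBundle(
        subject_summary=summary,
        distributions=distributions,
        correlations=correlation_table(merged, config),
        split_comparisons=split_comparison_table(merged, config),
        coefficient_comparisons=coefficient_comparison_table(merged, config),
        run_log=run_log,
    )


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Load inputs from the configured paths and run all stages."""
    series_list = load_events(config.events_path)
    cohort = pd.read_csv(config.cohort_path)
    crosswalk = (
        load_crosswalk(config.crosswalk_path) if config.crosswalk_path else None
    )
    return analyze_cohort(series_list, cohort, config, crosswalk)


def render_report(bundle: ReportBundle, out_dir: str | Path,
                  make_plots: bool = False) -> list[Path]:
    """Write the bundle as CSVs (+ optional plots); remove partial output
    on failure."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tables = {
        "subject_summary.csv": bundle.subject_summary,
        "distributions.csv": bundle.distributions,
        "correlations.csv": bundle.correlations,
        "split_comparisons.csv": bundle.split_comparisons,
        "coefficient_comparisons.csv": bundle.coefficient_comparisons,
    }
    try:
        for name, df in tables.items():
            p = out_dir / name
            df.to_csv(p, index=False)
            written.append(p)
        p = out_dir / "run_log.json"
        with p.open("w", encoding="utf-8") as fh:
            json.dump(bundle.run_log, fh, indent=1, sort_keys=True)
        written.append(p)
        if make_plots:
            written.extend(_render_plots(bundle, out_dir))
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return written


def _render_plots(bundle: ReportBundle, out_dir: Path) -> list[Path]:
    """Convenience figures: correlation heatmap and RIN-transformed MVPA
    split boxplot.  Not part of the analysis surface."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    corr = bundle.correlations
    plain = corr[corr["covariates"] == ""]
    if not plain.empty:
        pivot = plain.pivot_table(index="measure_x", columns="measure_y",
                                  values="rho")
        fig, ax = plt.subplots(figsize=(8, 6))
        im = ax.imshow(pivot.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=90)
        ax.set_yticks(range(len(pivot.index)), pivot.index)
        fig.colorbar(im, ax=ax, label="Spearman rho")
        fig.tight_layout()
        p = out_dir / "correlation_heatmap.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    summary = bundle.subject_summary
    if summary["included"].any():
        vals = summary.loc[summary["included"], "avg_mvpa_min"].to_numpy(float)
        if np.isfinite(vals).sum() >= 3:
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.boxplot([rin_transform(vals)[np.isfinite(vals)]],
                       tick_labels=["included"])
            ax.set_ylabel("MVPA time (RIN-transformed)")
            fig.tight_layout()
            p = out_dir / "mvpa_rin_boxplot.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
    return written
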