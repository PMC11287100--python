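"""FACT-G scoring, PROMIS-PF crosswalk linkage, and submaximal VO2.

The FACT-G is a 27-item health-related quality-of-life instrument with four
subscales: physical well-being (7 items), social/family (7), emotional (6),
and functional (7).  Items are answered 0-4; negatively worded items are
reverse-scored (4 - raw) so that higher always means better.  A subscale is
prorated by the standard rule — score = answered-item sum x (n_items /
n_answered) — when more than half its items are answered, otherwise
missing; the total (0-108) is the sum of the four subscale scores and is
missing if any subscale is.

A 5-item subset of the physical well-being subscale (lack of energy,
trouble meeting family needs, pain, feeling ill, time in bed — i.e. the
subscale minus the nausea and treatment-side-effect items) is summed
without prorating and linked to a PROMIS Physical Function T score by a
monotone lookup table.  The crosswalk shipped with this package
(``resources/promis_pf_crosswalk_synthetic.csv``) is a SYNTHETIC,
non-canonical placeholder spanning T 19-61; supply the published linkage
table for real analyses.

Aerobic fitness is predicted oxygen uptake at 70% heart-rate reserve from
the duration T (minutes) of a submaximal treadmill test:

    women:  VO2 = 1.38 T + 5.22     (mL/kg/min)
    men:    VO2 = 1.44 T + 14.99
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

ITEM_BLUEPRINT: dict[str, tuple[str, str]] = {
    # physical well-being: all negatively worded
    **{f"gp{i}": ("physical", "negative") for i in range(1, 8)},
    # social/family well-being: positively worded
    **{f"gs{i}": ("social", "positive") for i in range(1, 8)},
    # emotional well-being: ge2 ("satisfied with coping") positive, rest negative
    "ge1": ("emotional", "negative"),
    "ge2": ("emotional", "positive"),
    "ge3": ("emotional", "negative"),
    "ge4": ("emotional", "negative"),
    "ge5": ("emotional", "negative"),
    "ge6": ("emotional", "negative"),
    # functional well-being: positively worded
    **{f"gf{i}": ("functional", "positive") for i in range(1, 8)},
}

SUBSCALES = ("physical", "social", "emotional", "functional")
SUBSCALE_ITEMS = {
    sub: tuple(i for i, (s, _) in ITEM_BLUEPRINT.items() if s == sub)
    for sub in SUBSCALES
}
#: physical well-being minus the nausea (gp2) and side-effects (gp5) items
PWB5_ITEMS = ("gp1", "gp3", "gp4", "gp6", "gp7")

FACTG_TOTAL_MAX = 108
PWB_MAX = 28
PWB5_MAX = 20

_SYNTHETIC_CROSSWALK = "promis_pf_crosswalk_synthetic.csv"


class BlueprintError(ValueError):
    """Item set does not match the 27-item FACT-G blueprint."""


@dataclass(frozen=True)
class FactgItemResponse:
    item_id: str
    subscale: str
    polarity: str
    raw: int | None  # 0-4, or None when skipped

    def __post_init__(self) -> None:
        if self.item_id not in ITEM_BLUEPRINT:
            raise BlueprintError(f"unknown item id {self.item_id!r}")
        sub, pol = ITEM_BLUEPRINT[self.item_id]
        if (self.subscale, self.polarity) != (sub, pol):
            raise BlueprintError(
                f"item {self.item_id!r} is ({sub}, {pol}), "
                f"got ({self.subscale}, {self.polarity})"
            )
        if self.raw is not None and self.raw not in (0, 1, 2, 3, 4):
            raise ValueError(f"item {self.item_id!r}: raw response must be 0-4, "
                             f"got {self.raw}")

    @property
    def scored(self) -> int | None:
        """Response on the higher-is-better scale (reversed if negative)."""
        if self.raw is None:
            return None
        return 4 - self.raw if self.polarity == "negative" else self.raw


def make_response(item_id: str, raw: int | None) -> FactgItemResponse:
    """Build a response with subscale/polarity filled from the blueprint."""
    if item_id not in ITEM_BLUEPRINT:
        raise BlueprintError(f"unknown item id {item_id!r}")
    sub, pol = ITEM_BLUEPRINT[item_id]
    if raw is not None:
        raw = int(raw)
    return FactgItemResponse(item_id, sub, pol, raw)


@dataclass
class FactgScoreSet:
    total: float  # 0-108
    pwb: float  # 0-28
    pwb5: float  # 0-20
    promis_pf_t: float = math.nan


def _normalize_items(
    items: Iterable[FactgItemResponse] | Mapping[str, int | None],
) -> dict[str, FactgItemResponse]:
    if isinstance(items, Mapping):
        responses = [make_response(k, v) for k, v in items.items()]
    else:
        responses = list(items)
    by_id: dict[str, FactgItemResponse] = {}
    for r in responses:
        if r.item_id in by_id:
            raise BlueprintError(f"duplicate item id {r.item_id!r}")
        by_id[r.item_id] = r
    missing = set(ITEM_BLUEPRINT) - set(by_id)
    if missing:
        raise BlueprintError(f"item set incomplete; missing {sorted(missing)}")
    return by_id


def score_factg(
    items: Iterable[FactgItemResponse] | Mapping[str, int | None],
    prorate_threshold: float = 0.5,
) -> FactgScoreSet:
    """Score the FACT-G total and subscales with standard prorating.

    ``items`` may be responses or a mapping item_id -> raw (None = skipped).
    The returned score set carries the total, physical well-being, and the
    unprorated 5-item subset; PROMIS linkage is left NaN (see
    :func:`link_promis_pf`).
    """
    by_id = _normalize_items(items)
    subscale_scores: dict[str, float] = {}
    for sub in SUBSCALES:
        ids = SUBSCALE_ITEMS[sub]
        answered = [by_id[i].scored for i in ids if by_id[i].scored is not None]
        if len(answered) / len(ids) > prorate_threshold:
            subscale_scores[sub] = sum(answered) * len(ids) / len(answered)
        else:
            subscale_scores[sub] = math.nan
    total = sum(subscale_scores.values())  # NaN-propagating
    return FactgScoreSet(
        total=total,
        pwb=subscale_scores["physical"],
        pwb5=score_pwb5(by_id),
    )


def score_pwb5(
    items: Iterable[FactgItemResponse] | Mapping[str, int | None],
) -> float:
    """Sum the 5-item physical well-being subset (0-20), no prorating.

    Any skipped subset item makes the score missing; the nausea and
    side-effects items never contribute.
    """
    if not isinstance(items, dict) or not all(
        isinstance(v, FactgItemResponse) for v in items.values()
    ):
        items = _normalize_items(items)
    scored = [items[i].scored for i in PWB5_ITEMS]
    if any(s is None for s in scored):
        return math.nan
    return float(sum(scored))


@dataclass
class CrosswalkTable:
    """Monotone lookup from the 5-item subset sum (0-20) to a PROMIS-PF T."""

    mapping: dict[int, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        if sorted(self.mapping) != list(range(PWB5_MAX + 1)):
            raise ValueError("crosswalk must map every integer score 0-20")
        ts = [self.mapping[i] for i in range(PWB5_MAX + 1)]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("crosswalk T scores must be non-decreasing")


def load_crosswalk(path: str | Path | None = None) -> CrosswalkTable:
    """Load a crosswalk CSV (``pwb5_score,t_score,provenance``).

    With no path, the packaged synthetic placeholder is returned.
    """
    if path is None:
        ref = importlib_resources.files("stepfit.resources") / _SYNTHETIC_CROSSWALK
        text = ref.read_text(encoding="utf-8")
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with Path(path).open(newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    mapping = {int(r["pwb5_score"]): float(r["t_score"]) for r in rows}
    provenance = rows[0].get("provenance", "") if rows else ""
    return CrosswalkTable(mapping=mapping, provenance=provenance)


def link_promis_pf(pwb5: float, crosswalk: CrosswalkTable) -> float:
    """Look up the linked PROMIS-PF T score for an integer subset sum."""
    if isinstance(pwb5, float) and math.isnan(pwb5):
        return math.nan
    if float(pwb5) != int(pwb5):
        raise ValueError(f"pwb5 score must be an integer, got {pwb5}")
    score = int(pwb5)
    if not 0 <= score <= PWB5_MAX:
        raise ValueError(f"pwb5 score must be in 0-{PWB5_MAX}, got {score}")
    return crosswalk.mapping[score]


class CeilingEffect(NamedTuple):
    percent: float  # one-decimal scale retained for analysis
    percent_rounded: int  # integer percent, as conventionally reported
    n_at_max: int
    n: int


def ceiling_effect(scores: Iterable[float], max_possible: float) -> CeilingEffect:
    """Percent of non-missing scores at the maximum possible score."""
    vals = [s for s in scores if not (isinstance(s, float) and math.isnan(s))]
    if not vals:
        return CeilingEffect(math.nan, 0, 0, 0)
    n_at_max = sum(1 for s in vals if s == max_possible)
    pct = 100.0 * n_at_max / len(vals)
    return CeilingEffect(round(pct, 1), int(math.floor(pct + 0.5)), n_at_max, len(vals))


def predict_submax_vo2(T: float, sex: str) -> float:
    """Predicted submaximal VO2 (mL/kg/min) from treadmill duration T (min)."""
    if not T > 0:
        raise ValueError(f"test duration must be positive, got {T}")
    sex = sex.lower()
    if sex == "female":
        return 1.38 * T + 5.22
    if sex == "male":
        return 1.44 * T + 14.99
    raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
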