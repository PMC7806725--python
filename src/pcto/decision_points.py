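"""Decision-point extraction: index dates, observed treatment decisions,
and follow-up outcomes.

A decision point (DP) is an encounter date at which the disease is
measurably uncontrolled, so a treatment change is warranted.  Two rule
families are supported:

``consecutive_uncontrolled_pair``
    the second of two consecutive uncontrolled readings separated by
    1..``pair_max_separation_days`` days is a DP (blood-pressure style);

``diagnosis_then_lab``
    after a disease index date (problem-list diagnosis, with an optional
    consecutive-abnormal-lab fallback), every encounter with a qualifying
    abnormal lab in the preceding ``lab_lookback_days`` is a DP
    (HbA1c / LDL style).

Age, recent-pregnancy, and refill-encounter exclusions apply to both.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from pcto.events import CodeMap, EventKind, PatientTimeline

logger = logging.getLogger(__name__)

DP_COLUMNS = [
    "dp_id",
    "patient_id",
    "index_date",
    "decision_label",
    "outcome",
    "n_meds_after",
]

NO_CHANGE = "no_change"

_OPS = {
    "ge": lambda v, t: v >= t,
    "gt": lambda v, t: v > t,
    "le": lambda v, t: v <= t,
    "lt": lambda v, t: v < t,
}


@dataclass(frozen=True)
class Threshold:
    """``analyte op value`` comparison; True means *not controlled*."""

    analyte: str
    op: str
    value: float

    def violated(self, value: float) -> bool:
        return _OPS[self.op](value, self.value)


@dataclass
class FollowupWindow:
    min_days: int
    max_days: int
    #: alternate window start when the treatment changed at the DP
    alt_min_days: Optional[int] = None

    def start(self, treatment_changed: bool) -> int:
        if treatment_changed and self.alt_min_days is not None:
            return self.alt_min_days
        return self.min_days


@dataclass
class DiseaseConfig:
    disease: str
    study_period: tuple[dt.date, dt.date]
    dp_rule: str  # consecutive_uncontrolled_pair | diagnosis_then_lab
    thresholds: Sequence[Threshold]
    followup: FollowupWindow
    treatment_universe: Sequence[str]  # ingredient codes
    filter_variable_names: Sequence[str] = ()
    pair_max_separation_days: int = 365
    diagnosis_category: Optional[str] = None
    lab_lookback_days: int = 365
    fallback_pair_threshold: Optional[Threshold] = None
    fallback_pair_max_separation_days: int = 365
    min_age: int = 18
    pregnancy_exclusion_days: int = 365
    pregnancy_codes: Sequence[str] = ("DX_PREGNANCY",)
    refill_codes: Sequence[str] = ("refill",)
    decision_buffer_days: int = 14

    def __post_init__(self) -> None:
        if self.followup.min_days >= self.followup.max_days:
            raise ValueError("followup min_days must be < max_days")
        if not self.thresholds:
            raise ValueError("at least one outcome threshold is required")
        if not self.treatment_universe:
            raise ValueError("treatment_universe must be non-empty")
        if self.dp_rule not in ("consecutive_uncontrolled_pair", "diagnosis_then_lab"):
            raise ValueError(f"unknown dp_rule {self.dp_rule!r}")
        if self.dp_rule == "diagnosis_then_lab" and self.diagnosis_category is None:
            raise ValueError("diagnosis_then_lab rule requires diagnosis_category")

    @property
    def analytes(self) -> list[str]:
        seen: list[str] = []
        for t in self.thresholds:
            if t.analyte not in seen:
                seen.append(t.analyte)
        return seen

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DiseaseConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "DiseaseConfig":
        thresholds = [Threshold(**t) for t in raw["thresholds"]]
        fu = raw["followup"]
        fallback = raw.get("fallback_pair_threshold")
        return cls(
            disease=raw["disease"],
            study_period=(
                dt.date.fromisoformat(str(raw["study_period"][0])),
                dt.date.fromisoformat(str(raw["study_period"][1])),
            ),
            dp_rule=raw["dp_rule"],
            thresholds=thresholds,
            followup=FollowupWindow(
                min_days=int(fu["min_days"]),
                max_days=int(fu["max_days"]),
                alt_min_days=fu.get("alt_min_days"),
            ),
            treatment_universe=list(raw["treatment_universe"]),
            filter_variable_names=list(raw.get("filter_variable_names", [])),
            pair_max_separation_days=int(raw.get("pair_max_separation_days", 365)),
            diagnosis_category=raw.get("diagnosis_category"),
            lab_lookback_days=int(raw.get("lab_lookback_days", 365)),
            fallback_pair_threshold=Threshold(**fallback) if fallback else None,
            fallback_pair_max_separation_days=int(raw.get("fallback_pair_max_separation_days", 365)),
            min_age=int(raw.get("min_age", 18)),
            pregnancy_exclusion_days=int(raw.get("pregnancy_exclusion_days", 365)),
            pregnancy_codes=list(raw.get("pregnancy_codes", ["DX_PREGNANCY"])),
            refill_codes=list(raw.get("refill_codes", ["refill"])),
            decision_buffer_days=int(raw.get("decision_buffer_days", 14)),
        )


@dataclass
class ExtractionReport:
    n_candidates: int = 0
    n_excluded_age: int = 0
    n_excluded_pregnancy: int = 0
    n_excluded_refill: int = 0
    n_missing_outcome: int = 0
    n_decision_points: int = 0


# ---------------------------------------------------------------------------
# reading assembly


def _readings(timeline: PatientTimeline, analytes: Sequence[str]) -> list[tuple[dt.date, dict[str, float]]]:
    """Dates on which every required analyte was measured, with the last
    value per analyte per date."""
    per_date: dict[dt.date, dict[str, float]] = {}
    for ev in timeline.events:
        if ev.event_kind is EventKind.MEASUREMENT and ev.code in analytes:
            per_date.setdefault(ev.event_date, {})[ev.code] = float(ev.value)
    return sorted(
        (d, vals) for d, vals in per_date.items() if all(a in vals for a in analytes)
    )


def _not_controlled(values: Mapping[str, float], thresholds: Sequence[Threshold]) -> bool:
    return any(t.violated(values[t.analyte]) for t in thresholds)


def _age_at(timeline: PatientTimeline, day: dt.date) -> Optional[float]:
    birth = timeline.attributes.get("birth_date")
    if birth is None:
        return None
    if isinstance(birth, str):
        birth = dt.date.fromisoformat(birth)
    return (day - birth).days / 365.25


def _pregnant_recently(timeline: PatientTimeline, day: dt.date, config: DiseaseConfig) -> bool:
    lo = day - dt.timedelta(days=config.pregnancy_exclusion_days)
    return any(
        ev.event_kind is EventKind.DIAGNOSIS
        and ev.code in config.pregnancy_codes
        and lo <= ev.event_date <= day
        for ev in timeline.events
    )


def _is_refill_only(timeline: PatientTimeline, day: dt.date, config: DiseaseConfig) -> bool:
    encounters = [
        ev for ev in timeline.events if ev.event_kind is EventKind.ENCOUNTER and ev.event_date == day
    ]
    if not encounters:
        return False
    return all(ev.code in config.refill_codes for ev in encounters)


def _encounter_dates(timeline: PatientTimeline, config: DiseaseConfig) -> list[dt.date]:
    dates = sorted(
        {
            ev.event_date
            for ev in timeline.events
            if ev.event_kind is EventKind.ENCOUNTER and ev.code not in config.refill_codes
        }
    )
    return dates


# ---------------------------------------------------------------------------
# index-date candidates per rule


def _pair_rule_dates(timeline: PatientTimeline, config: DiseaseConfig) -> list[dt.date]:
    readings = _readings(timeline, config.analytes)
    out = []
    for (d1, v1), (d2, v2) in zip(readings, readings[1:]):
        gap = (d2 - d1).days
        if not 1 <= gap <= config.pair_max_separation_days:
            continue
        if _not_controlled(v1, config.thresholds) and _not_controlled(v2, config.thresholds):
            out.append(d2)
    return out


def _disease_index_date(timeline: PatientTimeline, config: DiseaseConfig, codes: Optional[CodeMap]) -> Optional[dt.date]:
    """First problem-list diagnosis date; optionally fall back to the
    earliest consecutive abnormal-lab pair."""
    dx_dates = []
    for ev in timeline.events:
        if ev.event_kind is not EventKind.DIAGNOSIS:
            continue
        category = codes.diagnosis_map.get(ev.code, ev.code) if codes else ev.code
        if category == config.diagnosis_category:
            dx_dates.append(ev.event_date)
    if dx_dates:
        return min(dx_dates)
    fb = config.fallback_pair_threshold
    if fb is None:
        return None
    readings = _readings(timeline, [fb.analyte])
    for (d1, v1), (d2, v2) in zip(readings, readings[1:]):
        gap = (d2 - d1).days
        if 1 <= gap <= config.fallback_pair_max_separation_days and fb.violated(v1[fb.analyte]) and fb.violated(v2[fb.analyte]):
            return d2
    return None


def _lab_rule_dates(timeline: PatientTimeline, config: DiseaseConfig, codes: Optional[CodeMap]) -> list[dt.date]:
    index = _disease_index_date(timeline, config, codes)
    if index is None:
        return []
    lab_threshold = config.thresholds[0]
    labs = _readings(timeline, [lab_threshold.analyte])
    out = []
    for enc in _encounter_dates(timeline, config):
        if enc <= index:
            continue
        lo = enc - dt.timedelta(days=config.lab_lookback_days)
        qualifying = [
            d for d, vals in labs if lo <= d <= enc and lab_threshold.violated(vals[lab_threshold.analyte])
        ]
        if qualifying:
            out.append(enc)
    return out


# ---------------------------------------------------------------------------
# per-DP annotations


def detect_treatment_decision(
    timeline: PatientTimeline,
    dp_date: dt.date,
    config: DiseaseConfig,
    codes: CodeMap,
) -> tuple[str, int]:
    """Observed treatment decision at a DP.

    Compares the active-ingredient set (restricted to the treatment
    universe) on the day before the DP with the set
    ``decision_buffer_days`` after it.  Additions emit
    ``{Class}_{Ingredient}+`` tokens and removals ``{Class}_{Ingredient}-``;
    tokens are sorted and joined with ``|``; an empty delta is
    ``"no_change"``.  Also returns the number of active universe
    medications at the end of the buffer.
    """
    universe = set(config.treatment_universe)
    before = timeline.active_ingredients(dp_date - dt.timedelta(days=1)) & universe
    after_day = dp_date + dt.timedelta(days=config.decision_buffer_days)
    after = timeline.active_ingredients(after_day) & universe

    def label_of(code: str) -> str:
        cls, ingredient = codes.medication_map[code]
        return f"{cls}_{ingredient}"

    tokens = [f"{label_of(c)}+" for c in after - before]
    tokens += [f"{label_of(c)}-" for c in before - after]
    decision = "|".join(sorted(tokens)) if tokens else NO_CHANGE
    return decision, len(after)


def determine_outcome(
    timeline: PatientTimeline,
    dp_date: dt.date,
    decision_label: str,
    config: DiseaseConfig,
) -> str:
    """Outcome of the first qualifying follow-up measurement.

    The window starts ``followup.alt_min_days`` after the DP when the
    treatment changed, else ``followup.min_days``; it ends at
    ``followup.max_days``.  Controlled iff no outcome threshold is
    violated; no measurement in the window yields ``"missing"``.
    """
    n = config.followup.start(decision_label != NO_CHANGE)
    lo = dp_date + dt.timedelta(days=n)
    hi = dp_date + dt.timedelta(days=config.followup.max_days)
    for d, vals in _readings(timeline, config.analytes):
        if d <= dp_date:
            continue
        if lo <= d <= hi:
            return "not_controlled" if _not_controlled(vals, config.thresholds) else "controlled"
        if d > hi:
            break
    return "missing"


def extract_decision_points(
    timelines: Mapping[str, PatientTimeline],
    config: DiseaseConfig,
    codes: CodeMap,
    report: Optional[ExtractionReport] = None,
) -> pd.DataFrame:
    """Extract all decision points for a disease configuration.

    Returns one row per (patient, index date) with the observed decision
    label, follow-up outcome (including ``"missing"``), and the post-DP
    medication count.  Exclusion counts accumulate in ``report``.
    """
    if codes.measurement_map:
        for t in config.thresholds:
            if t.analyte not in codes.measurement_map:
                raise ValueError(f"outcome analyte {t.analyte!r} not present in code map")
    if report is None:
        report = ExtractionReport()
    rows = []
    for pid in sorted(timelines):
        timeline = timelines[pid]
        if config.dp_rule == "consecutive_uncontrolled_pair":
            candidates = _pair_rule_dates(timeline, config)
        else:
            candidates = _lab_rule_dates(timeline, config, codes)
        seen: set[dt.date] = set()
        for day in candidates:
            if day in seen:
                continue
            seen.add(day)
            report.n_candidates += 1
            if not (config.study_period[0] <= day <= config.study_period[1]):
                continue
            age = _age_at(timeline, day)
            if age is not None and age < config.min_age:
                report.n_excluded_age += 1
                continue
            if _pregnant_recently(timeline, day, config):
                report.n_excluded_pregnancy += 1
                continue
            if _is_refill_only(timeline, day, config):
                report.n_excluded_refill += 1
                continue
            decision, n_meds = detect_treatment_decision(timeline, day, config, codes)
            outcome = determine_outcome(timeline, day, decision, config)
            if outcome == "missing":
                report.n_missing_outcome += 1
            rows.append(
                {
                    "dp_id": f"{pid}:{day.isoformat()}",
                    "patient_id": pid,
                    "index_date": day,
                    "decision_label": decision,
                    "outcome": outcome,
                    "n_meds_after": n_meds,
                }
            )
    report.n_decision_points = len(rows)
    df = pd.DataFrame(rows, columns=DP_COLUMNS)
    return df


def drop_missing_outcomes(dps: pd.DataFrame) -> pd.DataFrame:
    """Analysis view: DPs with a determinable controlled/not outcome."""
    return dps[dps["outcome"] != "missing"].reset_index(drop=True)


def split_train_score(
    dps: pd.DataFrame, n_train: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform random split without replacement into training and scoring
    sets; deterministic given the seed."""
    if n_train > len(dps):
        raise ValueError(f"n_train={n_train} exceeds available DPs ({len(dps)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dps))
    train_idx = np.sort(perm[:n_train])
    score_idx = np.sort(perm[n_train:])
    return (
        dps.iloc[train_idx].reset_index(drop=True),
        dps.iloc[score_idx].reset_index(drop=True),
    )
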