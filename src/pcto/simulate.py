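"""Synthetic longitudinal EHR generator with known ground truth.

Simulates per-patient visit streams, repeated disease-control measurements
(a systolic-pressure-like primary analyte plus a correlated paired
analyte), a confounded treatment-initiation policy, and heterogeneous
planted treatment effects.  All randomness flows from one seeded
generator, so outputs are byte-identical for a fixed (config, seed).

The generative model at each visit is

    measurement = patient_baseline + severity - sum(active effects) + noise

with ``patient_baseline ~ N(baseline_measure_mean, baseline_measure_sd)``,
``severity ~ N(0, severity_sd)`` (a latent confounder the policy may look
at), and i.i.d. measurement noise ``N(0, noise_sd)``.  A visit is
"uncontrolled" when the primary measurement is at or above
``control_threshold``; only then may the policy start treatments.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from pcto.events import EventKind, EventRecord, MedAction

DEFAULT_START_DATE = dt.date(2010, 1, 1)


@dataclass
class TreatmentSpec:
    """One plantable treatment with an additive effect on the control measure."""

    ingredient: str
    med_class: str
    effect_size: float
    #: predicate string (over covariates) -> additive extra effect
    subgroup_modifiers: dict[str, float] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.med_class}_{self.ingredient}"


@dataclass
class PolicyRule:
    """Initiate ``ingredient`` with probability ``prob`` at an uncontrolled
    visit for patients whose profile satisfies ``predicate``."""

    predicate: str
    ingredient: str
    prob: float


@dataclass
class CovariateSpec:
    """Static patient attribute: ``bernoulli(p)``, ``normal(mean, sd)`` or
    ``uniform(low, high)``."""

    name: str
    dist: str
    params: tuple[float, ...]


@dataclass
class SimConfig:
    n_patients: int
    horizon_days: int = 3650
    visit_rate: float = 90.0
    baseline_measure_mean: float = 150.0
    baseline_measure_sd: float = 5.0
    severity_sd: float = 10.0
    noise_sd: float = 8.0
    control_threshold: float = 140.0
    primary_analyte: str = "SBP"
    paired_analyte: Optional[str] = "DBP"
    paired_mean: float = 88.0
    paired_coupling: float = 0.4
    paired_noise_sd: float = 5.0
    paired_threshold: float = 90.0
    treatments: Sequence[TreatmentSpec] = ()
    policy: Sequence[PolicyRule] = ()
    covariates: Sequence[CovariateSpec] = (
        CovariateSpec("age", "normal", (58.0, 12.0)),
        CovariateSpec("female", "bernoulli", (0.5,)),
    )
    discontinue_prob: float = 0.05
    diagnosis_code: str = "DX_PRIMARY"
    start_date: dt.date = DEFAULT_START_DATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name, sd in [
            ("baseline_measure_sd", self.baseline_measure_sd),
            ("severity_sd", self.severity_sd),
            ("noise_sd", self.noise_sd),
        ]:
            if sd <= 0:
                raise ValueError(f"{name} must be > 0")
        for rule in self.policy:
            if not 0.0 <= rule.prob <= 1.0:
                raise ValueError("policy probabilities must be in [0, 1]")
        if not 0.0 <= self.discontinue_prob <= 1.0:
            raise ValueError("discontinue_prob must be in [0, 1]")
        if self.n_patients > 0 and not self.treatments:
            raise ValueError("at least one treatment must be configured")

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        return _simconfig_from_dict(raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        return _simconfig_from_dict(yaml.safe_load(Path(path).read_text()))


def _simconfig_from_dict(raw: dict) -> "SimConfig":
    kwargs = dict(raw)
    kwargs["treatments"] = [TreatmentSpec(**t) for t in raw.get("treatments", [])]
    kwargs["policy"] = [PolicyRule(**r) for r in raw.get("policy", [])]
    if "covariates" in raw:
        kwargs["covariates"] = [
            CovariateSpec(c["name"], c["dist"], tuple(c["params"])) for c in raw["covariates"]
        ]
    if "start_date" in raw:
        kwargs["start_date"] = dt.date.fromisoformat(str(raw["start_date"]))
    return SimConfig(**kwargs)


def _eval_predicate(predicate: str, profile: dict[str, float]) -> bool:
    """Evaluate a covariate predicate like ``"age >= 60 and female == 1"``."""
    try:
        return bool(eval(predicate, {"__builtins__": {}}, dict(profile)))  # noqa: S307
    except Exception as exc:  # pragma: no cover - config error path
        raise ValueError(f"cannot evaluate predicate {predicate!r}: {exc}") from exc


@dataclass
class PatientLatent:
    patient_id: str
    baseline: float
    severity: float
    covariates: dict[str, float]
    birth_date: dt.date


@dataclass
class GroundTruth:
    """Latent state and closed-form control probabilities of a simulation."""

    config: SimConfig
    patients: list[PatientLatent]

    def patient_attributes(self) -> dict[str, dict[str, object]]:
        """Static attributes per patient (for timeline construction)."""
        out: dict[str, dict[str, object]] = {}
        for p in self.patients:
            attrs: dict[str, object] = dict(p.covariates)
            attrs["birth_date"] = p.birth_date
            out[p.patient_id] = attrs
        return out

    def treatment_effect(self, patient: PatientLatent, ingredient: Optional[str]) -> float:
        if ingredient is None:
            return 0.0
        spec = next(t for t in self.config.treatments if t.ingredient == ingredient)
        eff = spec.effect_size
        for pred, extra in spec.subgroup_modifiers.items():
            if _eval_predicate(pred, patient.covariates):
                eff += extra
        return eff

    def expected_control_prob(self, predicate: str, ingredient: Optional[str]) -> float:
        """True P(controlled measurement) for subgroup members on exactly
        ``ingredient`` (or on nothing when None), averaged over the
        simulated subgroup."""
        cfg = self.config
        members = [p for p in self.patients if _eval_predicate(predicate, p.covariates)]
        if not members:
            raise ValueError(f"no simulated patient matches predicate {predicate!r}")
        probs = []
        for p in members:
            mu = p.baseline + p.severity - self.treatment_effect(p, ingredient)
            probs.append(norm.cdf((cfg.control_threshold - mu) / cfg.noise_sd))
        return float(np.mean(probs))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.config.seed,
            "control_threshold": self.config.control_threshold,
            "patients": [
                {
                    "patient_id": p.patient_id,
                    "baseline": p.baseline,
                    "severity": p.severity,
                    "covariates": p.covariates,
                    "birth_date": p.birth_date.isoformat(),
                }
                for p in self.patients
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _sample_covariates(rng: np.random.Generator, specs: Sequence[CovariateSpec]) -> dict[str, float]:
    out: dict[str, float] = {}
    for spec in specs:
        if spec.dist == "bernoulli":
            out[spec.name] = float(rng.random() < spec.params[0])
        elif spec.dist == "normal":
            out[spec.name] = float(rng.normal(spec.params[0], spec.params[1]))
        elif spec.dist == "uniform":
            out[spec.name] = float(rng.uniform(spec.params[0], spec.params[1]))
        else:
            raise ValueError(f"unknown covariate distribution {spec.dist!r}")
    return out


def simulate_population(config: SimConfig) -> tuple[list[EventRecord], GroundTruth]:
    """Simulate a population; returns the event table and its ground truth.

    Visit gaps are geometric with mean ``visit_rate`` (minimum 1 day).  At
    each visit an encounter, the primary measurement, and (optionally) the
    paired measurement are emitted; treatment starts/stops are emitted as
    medication events on the visit date.
    """
    rng = np.random.default_rng(config.seed)
    events: list[EventRecord] = []
    patients: list[PatientLatent] = []
    gap_p = min(1.0, 1.0 / max(config.visit_rate, 1.0))
    width = max(5, len(str(max(config.n_patients - 1, 0))))

    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        cov = _sample_covariates(rng, config.covariates)
        age = float(cov.get("age", 50.0))
        birth_date = config.start_date - dt.timedelta(days=int(round(age * 365.25)))
        baseline = float(rng.normal(config.baseline_measure_mean, config.baseline_measure_sd))
        severity = float(rng.normal(0.0, config.severity_sd))
        profile = dict(cov)
        profile["severity"] = severity
        patients.append(PatientLatent(pid, baseline, severity, cov, birth_date))

        effects = {}
        for t in config.treatments:
            eff = t.effect_size
            for pred, extra in t.subgroup_modifiers.items():
                if _eval_predicate(pred, cov):
                    eff += extra
            effects[t.ingredient] = eff

        active: set[str] = set()
        diagnosed = False
        day = int(rng.geometric(gap_p))
        while day < config.horizon_days:
            date = config.start_date + dt.timedelta(days=day)
            events.append(EventRecord(pid, date, EventKind.ENCOUNTER, "visit"))

            total_effect = sum(effects[ing] for ing in active)
            value = baseline + severity - total_effect + float(rng.normal(0.0, config.noise_sd))
            events.append(
                EventRecord(pid, date, EventKind.MEASUREMENT, config.primary_analyte, value=round(value, 2), unit="mmHg")
            )
            if config.paired_analyte:
                paired = (
                    config.paired_mean
                    + config.paired_coupling * (value - config.baseline_measure_mean)
                    + float(rng.normal(0.0, config.paired_noise_sd))
                )
                events.append(
                    EventRecord(pid, date, EventKind.MEASUREMENT, config.paired_analyte, value=round(paired, 2), unit="mmHg")
                )

            for ing in sorted(active):
                if rng.random() < config.discontinue_prob:
                    active.discard(ing)
                    events.append(EventRecord(pid, date, EventKind.MEDICATION, ing, action=MedAction.STOP))

            uncontrolled = value >= config.control_threshold
            if uncontrolled:
                if not diagnosed:
                    events.append(EventRecord(pid, date, EventKind.DIAGNOSIS, config.diagnosis_code))
                    diagnosed = True
                for rule in config.policy:
                    if rule.ingredient in active:
                        continue
                    if _eval_predicate(rule.predicate, profile) and rng.random() < rule.prob:
                        active.add(rule.ingredient)
                        events.append(EventRecord(pid, date, EventKind.MEDICATION, rule.ingredient, action=MedAction.START))

            day += int(rng.geometric(gap_p))

    return events, GroundTruth(config=config, patients=patients)


def default_code_map(config: SimConfig):
    """CodeMap covering every code the simulator can emit."""
    from pcto.events import CodeMap

    med = {
        t.ingredient: (t.med_class, t.ingredient.removeprefix("RX_").capitalize())
        for t in config.treatments
    }
    dx = {config.diagnosis_code: config.diagnosis_code, "DX_PREGNANCY": "PREGNANCY"}
    meas = {config.primary_analyte: (config.primary_analyte, "mmHg")}
    if config.paired_analyte:
        meas[config.paired_analyte] = (config.paired_analyte, "mmHg")
    return CodeMap(medication_map=med, diagnosis_map=dx, measurement_map=meas)


def truth_option_ranking(gt: GroundTruth, predicate: str, atol: float = 1e-12) -> list[list[str]]:
    """Treatment labels ordered by true control probability (descending)
    within the subgroup; equal-probability options share a tie group.
    ``"no_change"`` stands for staying on no treatment.
    """
    options: list[tuple[str, float]] = [("no_change", gt.expected_control_prob(predicate, None))]
    for t in gt.config.treatments:
        options.append((t.label, gt.expected_control_prob(predicate, t.ingredient)))
    options.sort(key=lambda kv: (-kv[1], kv[0]))
    groups: list[list[str]] = []
    last_p: Optional[float] = None
    for label, p in options:
        if last_p is not None and math.isclose(p, last_p, abs_tol=atol):
            groups[-1].append(label)
        else:
            groups.append([label])
        last_p = p
    return groups
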