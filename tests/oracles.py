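"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values with naive enumeration or
closed forms, separate from the package's implementation paths.
"""

import datetime as dt

import numpy as np

from pcto.events import EventKind


def chi2_closed_form(a, b, c, d):
    """Pearson chi-square for [[a, b], [c, d]] via n(ad-bc)^2 / products."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def quadratic_form_distance(W, da):
    """sqrt(da^T W W^T da) computed with explicit element-wise loops."""
    p, d = W.shape
    total = 0.0
    for k in range(d):
        proj = 0.0
        for i in range(p):
            proj += da[i] * W[i][k]
        total += proj * proj
    return np.sqrt(total)


def standardized_bias_by_hand(values, is_change):
    values = list(map(float, values))
    change = [v for v, c in zip(values, is_change) if c]
    nochange = [v for v, c in zip(values, is_change) if not c]
    mean_c = sum(change) / len(change)
    mean_nc = sum(nochange) / len(nochange)
    var = sum((v - mean_c) ** 2 for v in change) / (len(change) - 1)
    return (mean_nc - mean_c) / var**0.5


# ---------------------------------------------------------------------------
# decision-point enumeration


def _full_readings(timeline, analytes):
    per_date = {}
    for ev in timeline.events:
        if ev.event_kind is EventKind.MEASUREMENT and ev.code in analytes:
            per_date.setdefault(ev.event_date, {})[ev.code] = ev.value
    return sorted((d, v) for d, v in per_date.items() if len(v) == len(analytes))


def _violates(vals, thresholds):
    for t in thresholds:
        v = vals[t.analyte]
        if t.op == "ge" and v >= t.value:
            return True
        if t.op == "gt" and v > t.value:
            return True
    return False


def _passes_exclusions(timeline, d, config):
    if not (config.study_period[0] <= d <= config.study_period[1]):
        return False
    birth = timeline.attributes.get("birth_date")
    if birth is not None:
        if isinstance(birth, str):
            birth = dt.date.fromisoformat(birth)
        if (d - birth).days / 365.25 < config.min_age:
            return False
    for ev in timeline.events:
        if (
            ev.event_kind is EventKind.DIAGNOSIS
            and ev.code in config.pregnancy_codes
            and d - dt.timedelta(days=config.pregnancy_exclusion_days) <= ev.event_date <= d
        ):
            return False
    encs = [e for e in timeline.events if e.event_kind is EventKind.ENCOUNTER and e.event_date == d]
    if encs and all(e.code in config.refill_codes for e in encs):
        return False
    return True


def brute_force_pair_dps(timeline, config):
    """All-pairs scan: a DP is the second of two uncontrolled readings that
    are consecutive (no reading strictly between) with gap 1..max days."""
    readings = _full_readings(timeline, [t.analyte for t in config.thresholds])
    dps = set()
    for i in range(len(readings)):
        for j in range(len(readings)):
            d1, v1 = readings[i]
            d2, v2 = readings[j]
            if d2 <= d1:
                continue
            if any(d1 < dm < d2 for dm, _ in readings):
                continue  # not consecutive
            gap = (d2 - d1).days
            if gap < 1 or gap > config.pair_max_separation_days:
                continue
            if _violates(v1, config.thresholds) and _violates(v2, config.thresholds):
                if _passes_exclusions(timeline, d2, config):
                    dps.add(d2)
    return sorted(dps)


def brute_force_lab_dps(timeline, config, codes):
    dx_dates = []
    for ev in timeline.events:
        if ev.event_kind is EventKind.DIAGNOSIS:
            cat = codes.diagnosis_map.get(ev.code, ev.code)
            if cat == config.diagnosis_category:
                dx_dates.append(ev.event_date)
    if dx_dates:
        index = min(dx_dates)
    elif config.fallback_pair_threshold is not None:
        fb = config.fallback_pair_threshold
        readings = _full_readings(timeline, [fb.analyte])
        index = None
        for i in range(len(readings) - 1):
            d1, v1 = readings[i]
            d2, v2 = readings[i + 1]
            gap = (d2 - d1).days
            if (
                1 <= gap <= config.fallback_pair_max_separation_days
                and _violates(v1, [fb])
                and _violates(v2, [fb])
            ):
                index = d2
                break
        if index is None:
            return []
    else:
        return []

    thr = config.thresholds[0]
    labs = _full_readings(timeline, [thr.analyte])
    encs = sorted(
        {
            e.event_date
            for e in timeline.events
            if e.event_kind is EventKind.ENCOUNTER and e.code not in config.refill_codes
        }
    )
    dps = set()
    for d in encs:  # every encounter-lab join
        if d <= index:
            continue
        for dl, vl in labs:
            if (
                d - dt.timedelta(days=config.lab_lookback_days) <= dl <= d
                and _violates(vl, [thr])
                and _passes_exclusions(timeline, d, config)
            ):
                dps.add(d)
    return sorted(dps)


# ---------------------------------------------------------------------------
# random timeline generator for extraction-exactness tests


def random_timelines(seed, n_patients=50, codes=None):
    """Messy random timelines: BP/HbA1c/LDL readings, diagnoses,
    pregnancies, refill-only visits, minors, medication churn."""
    from pcto.events import EventRecord, MedAction, build_timelines

    rng = np.random.default_rng(seed)
    base = dt.date(2010, 1, 1)
    events = []
    attributes = {}
    for i in range(n_patients):
        pid = f"R{i:03d}"
        birth = dt.date(int(rng.integers(1940, 2004)), 1, 1)
        attributes[pid] = {"birth_date": birth}
        n_visits = int(rng.integers(2, 25))
        days = np.sort(rng.choice(np.arange(0, 3000), size=n_visits, replace=False))
        for d in days:
            date = base + dt.timedelta(days=int(d))
            refill_only = rng.random() < 0.1
            events.append(
                EventRecord(pid, date, EventKind.ENCOUNTER, "refill" if refill_only else "visit")
            )
            if rng.random() < 0.8:
                events.append(
                    EventRecord(pid, date, EventKind.MEASUREMENT, "SBP", value=float(rng.normal(145, 15)))
                )
                events.append(
                    EventRecord(pid, date, EventKind.MEASUREMENT, "DBP", value=float(rng.normal(88, 8)))
                )
            if rng.random() < 0.4:
                events.append(
                    EventRecord(pid, date, EventKind.MEASUREMENT, "HBA1C", value=float(rng.normal(7.0, 0.8)))
                )
            if rng.random() < 0.4:
                events.append(
                    EventRecord(pid, date, EventKind.MEASUREMENT, "LDL", value=float(rng.normal(132, 20)))
                )
            if rng.random() < 0.05:
                events.append(EventRecord(pid, date, EventKind.DIAGNOSIS, "DX_T2DM"))
            if rng.random() < 0.05:
                events.append(EventRecord(pid, date, EventKind.DIAGNOSIS, "DX_HL"))
            if rng.random() < 0.03:
                events.append(EventRecord(pid, date, EventKind.DIAGNOSIS, "DX_PREGNANCY"))
            if rng.random() < 0.1:
                events.append(
                    EventRecord(
                        pid,
                        date,
                        EventKind.MEDICATION,
                        str(rng.choice(["RX_LISINOPRIL", "RX_METFORMIN", "RX_SIMVASTATIN"])),
                        action=MedAction("start" if rng.random() < 0.6 else "stop"),
                    )
                )
    return build_timelines(events, codes, attributes=attributes)
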