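import datetime as dt

import pytest

from pcto.events import CodeMap, EventKind, EventRecord, MedAction, build_timelines

D0 = dt.date(2010, 1, 1)


def day(n: int) -> dt.date:
    return D0 + dt.timedelta(days=int(n))


def enc(pid, d, code="visit"):
    return EventRecord(pid, day(d), EventKind.ENCOUNTER, code)


def meas(pid, d, code, value):
    return EventRecord(pid, day(d), EventKind.MEASUREMENT, code, value=float(value))


def med(pid, d, code, action):
    return EventRecord(pid, day(d), EventKind.MEDICATION, code, action=MedAction(action))


def dx(pid, d, code):
    return EventRecord(pid, day(d), EventKind.DIAGNOSIS, code)


def bp(pid, d, sbp, dbp):
    return [enc(pid, d), meas(pid, d, "SBP", sbp), meas(pid, d, "DBP", dbp)]


@pytest.fixture
def codes():
    return CodeMap(
        medication_map={
            "RX_LISINOPRIL": ("ACEI", "Lisinopril"),
            "RX_HYDROCHLOROTHIAZIDE": ("Thiazide", "Hydrochlorothiazide"),
            "RX_GLYBURIDE": ("Sulfonylurea", "Glyburide"),
            "RX_GLIPIZIDE": ("Sulfonylurea", "Glipizide"),
            "RX_METFORMIN": ("Biguanides", "Metformin"),
            "RX_SIMVASTATIN": ("Statin", "Simvastatin"),
        },
        diagnosis_map={
            "DX_T2DM": "T2DM",
            "DX_HL": "HL",
            "DX_PREGNANCY": "PREGNANCY",
            "DX_PRIMARY": "DX_PRIMARY",
        },
        measurement_map={
            "SBP": ("SBP", "mmHg"),
            "DBP": ("DBP", "mmHg"),
            "HBA1C": ("HBA1C", "%"),
            "LDL": ("LDL", "mg/dl"),
        },
    )


def timeline_of(events, codes=None, birth_year=1960, **attrs):
    pid = events[0].patient_id
    attrs.setdefault("birth_date", dt.date(birth_year, 1, 1))
    tls = build_timelines(events, codes, attributes={pid: attrs})
    return tls[pid]


@pytest.fixture
def htn_config():
    import importlib.resources as ir

    from pcto.decision_points import DiseaseConfig

    return DiseaseConfig.from_yaml(ir.files("pcto") / "configs" / "htn.yaml")


@pytest.fixture
def t2dm_config():
    import importlib.resources as ir

    from pcto.decision_points import DiseaseConfig

    return DiseaseConfig.from_yaml(ir.files("pcto") / "configs" / "t2dm.yaml")


@pytest.fixture
def hl_config():
    import importlib.resources as ir

    from pcto.decision_points import DiseaseConfig

    return DiseaseConfig.from_yaml(ir.files("pcto") / "configs" / "hl.yaml")
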