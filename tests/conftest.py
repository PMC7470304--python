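"""Shared fixtures and small hand-built cohort helpers."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from tvmatch.cohort_model import (
    Cohort,
    DailyObservation,
    PatientStatic,
    TreatmentEvent,
)
from tvmatch.synthetic_cohort import default_config, simulate_cohort


def make_patient(pid, sex="male", age=60, discharge=None, death=None, **flags):
    return PatientStatic(
        patient_id=pid,
        sex=sex,
        age=age,
        discharge_day=discharge,
        death_day=death,
        **flags,
    )


def daily_obs(
    pid,
    days,
    spo2=94.0,
    fio2=30.0,
    sbp=120.0,
    dbp=70.0,
    hr=80.0,
    temperature=36.8,
    crp=8.0,
    xray_days=None,
    xray=2,
    device="nasal_prongs",
):
    """Constant daily observations; radiographs only on ``xray_days``
    (defaults to day 0).  ``spo2``/``crp`` may be per-day dicts."""
    if xray_days is None:
        xray_days = [days[0]]
    out = []
    for d in days:
        s = spo2[d] if isinstance(spo2, dict) else spo2
        c = crp[d] if isinstance(crp, dict) else crp
        f = fio2[d] if isinstance(fio2, dict) else fio2
        out.append(
            DailyObservation(
                patient_id=pid,
                day=d,
                spo2=s,
                fio2=f,
                sbp=sbp,
                dbp=dbp,
                hr=hr,
                temperature=temperature,
                crp=c,
                xray_quadrants=xray if d in xray_days else None,
                oxygen_device="room_air" if f == 21 else device,
            )
        )
    return out


def azithro(pid, start, n=3):
    return [
        TreatmentEvent(pid, "azithromycin", start + k, 500.0 if k == 0 else 250.0)
        for k in range(n)
    ]


def drug(pid, name, day, dose=100.0):
    return [TreatmentEvent(pid, name, day, dose)]


def build_cohort(statics, observations=(), treatments=()) -> Cohort:
    return Cohort.from_records(statics, observations, treatments).validate()


@pytest.fixture(scope="session")
def default_cohort_418():
    return simulate_cohort(dataclasses.replace(default_config(), n_patients=418, seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(dataclasses.replace(default_config(), n_patients=120, seed=11))


@pytest.fixture
def three_patient_cohort():
    statics = [
        make_patient("A", discharge=6),
        make_patient("B", sex="female", age=72, death=4, hypertension=True),
        make_patient("C", age=55),
    ]
    obs = (
        daily_obs("A", range(0, 7))
        + daily_obs("B", range(0, 5), fio2=40.0, device="venturi")
        + daily_obs("C", range(0, 10), fio2=21.0)
    )
    treats = azithro("A", 1, n=5) + drug("B", "hydroxychloroquine", 0)
    return build_cohort(statics, obs, treats)


def random_mini_cohort(rng):
    """Random tiny cohort (<= 6 treated, <= 10 controls) for oracle fuzzing."""
    from tvmatch.cohort_model import Cohort, DailyObservation, TreatmentEvent

    n_t = rng.integers(1, 7)
    n_c = rng.integers(1, 11)
    statics, obs, treats = [], [], []
    for i in range(n_t + n_c):
        pid = f"P{i:02d}"
        stay = int(rng.integers(2, 12))
        dead = rng.random() < 0.15
        statics.append(
            make_patient(
                pid,
                sex="male" if rng.random() < 0.6 else "female",
                age=int(rng.integers(40, 90)),
                discharge=None if dead else stay,
                death=stay if dead else None,
                obesity=bool(rng.random() < 0.3),
            )
        )
        xray_days = sorted(
            set(rng.choice(range(0, stay + 1), size=max(1, stay // 3), replace=True).tolist())
        )
        for d in range(stay + 1):
            fio2 = float(rng.choice([21, 28, 35, 60]))
            obs.append(
                DailyObservation(
                    patient_id=pid,
                    day=d,
                    spo2=float(np.round(rng.uniform(70, 100), 1)),
                    fio2=fio2,
                    sbp=float(rng.integers(95, 150)),
                    dbp=float(rng.integers(55, 95)),
                    hr=float(rng.integers(55, 110)),
                    temperature=36.5,
                    crp=None if rng.random() < 0.25 else float(np.round(rng.uniform(1, 25), 1)),
                    xray_quadrants=int(rng.integers(0, 5)) if d in xray_days else None,
                    oxygen_device="room_air" if fio2 == 21 else "venturi",
                )
            )
        if i < n_t:
            start = int(rng.integers(0, 3))
            n_doses = int(min(rng.integers(3, 6), max(stay - start + 1, 0)))
            for k in range(n_doses):
                if start + k <= stay:
                    treats.append(TreatmentEvent(pid, "azithromycin", start + k, 250.0))
        for name in ("hydroxychloroquine", "interferon", "dexamethasone"):
            if rng.random() < 0.4:
                day = int(min(rng.integers(0, 4), stay))
                treats.append(TreatmentEvent(pid, name, day, 100.0))
    return Cohort.from_records(statics, obs, treats).validate()
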