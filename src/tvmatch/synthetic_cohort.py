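"""Synthetic longitudinal hospital cohort generator.

Each patient carries a one-dimensional latent severity score that starts at a
comorbidity- and age-dependent baseline and evolves as a random walk with
drift.  Everything observable is a stated function of the current severity:

* the oxygenation ratio (SpO2%/FiO2%) is ``SAFI_MAX * logistic(-severity)``
  plus noise, clipped to ``[0.5, SAFI_MAX]``;
* the oxygen device escalates through fixed severity thresholds
  (room air -> nasal prongs -> venturi -> reservoir -> NIV -> IMV), each tier
  with a fixed FiO2, and the recorded saturation is the ratio times FiO2;
* CRP is log-normal around a severity-linked mean, missing completely at
  random at a configurable rate;
* radiographs are scheduled every 2-6 days (plus day 0), with the quadrant
  count a monotone step function of severity;
* discharge and death are competing per-day exponential hazards driven by
  current severity.

Treatment assignment is confounded by construction: the probability of the
study drug increases with baseline severity.  A configurable true effect
multiplies the discharge hazard and/or shifts the daily severity drift from
the first dose onward (defaults are null).

The AR(1)/random-walk within-patient correlation structure is a modelling
choice, not an estimated quantity; real longitudinal correlation was not
available to calibrate against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .cohort_model import FOLLOWUP_CAP_DAYS, Cohort
from .preprocessing import SAFI_MAX

__all__ = [
    "DEVICE_FIO2",
    "TrueEffect",
    "BaselineSeverityParams",
    "TrajectoryParams",
    "TreatmentAssignment",
    "CohortConfig",
    "default_config",
    "simulate_cohort",
    "simulate_many",
]

#: Fixed inspired-oxygen percentage per device tier.
DEVICE_FIO2: Mapping[str, float] = {
    "room_air": 21.0,
    "nasal_prongs": 28.0,
    "venturi": 40.0,
    "reservoir": 85.0,
    "niv": 90.0,
    "imv": 100.0,
}

_DEVICE_ORDER = ("room_air", "nasal_prongs", "venturi", "reservoir", "niv", "imv")


@dataclass(frozen=True)
class TrueEffect:
    """Configurable true effect of the study drug, applied from the first
    dose onward.  ``discharge_hazard_ratio=1.0`` and ``safi_drift=0.0`` are
    the null."""

    discharge_hazard_ratio: float = 1.0
    #: Additive shift of the daily oxygenation-ratio drift while exposed;
    #: implemented as a drop in latent severity of the same magnitude
    #: (positive = faster recovery).
    safi_drift: float = 0.0


@dataclass(frozen=True)
class BaselineSeverityParams:
    """Distribution of day-0 latent severity (logit scale)."""

    mean: float = -2.35
    sd: float = 1.05
    #: per standard deviation of age above the cohort mean
    age_coef: float = 0.30
    comorbidity_coefs: Mapping[str, float] = field(
        default_factory=lambda: {
            "obesity": 0.25,
            "chf": 0.45,
            "crf": 0.35,
            "sahs": 0.20,
            "tobacco": 0.10,
            "hypertension": 0.15,
            "diabetes": 0.20,
            "copd": 0.40,
            "other_cardiopathy": 0.20,
        }
    )


@dataclass(frozen=True)
class TrajectoryParams:
    """Daily severity evolution and the competing event hazards."""

    drift: float = -0.30
    #: between-patient SD of the personal drift (0 keeps the process Markov
    #: in current severity, which is what the matched null calibration assumes)
    drift_sd: float = 0.0
    noise_sd: float = 0.15
    #: severity thresholds between successive device tiers, set so that a
    #: device escalation happens roughly when saturation would fall below
    #: the mid-80s on the current device
    device_thresholds: tuple[float, ...] = (-1.82, -0.60, 0.19, 1.31, 2.2)
    #: observation-level noise on the oxygenation ratio (pulse-oximetry is
    #: precise; most variation should come through severity itself)
    safi_noise_sd: float = 0.05
    #: saturation the ward titrates FiO2 toward
    target_sat_mean: float = 92.5
    target_sat_sd: float = 1.5
    #: vitals and CRP carry a persistent per-patient offset plus small daily
    #: noise; purely day-to-day noise would let the matcher select control
    #: days on transient dips, a regression-to-the-mean artefact
    vitals_offset_sd: tuple[float, float, float] = (8.0, 6.0, 7.0)
    vitals_daily_sd: tuple[float, float, float] = (5.0, 4.0, 5.0)
    #: per-day discharge hazard = exp(discharge_log_base - discharge_severity_coef * severity);
    #: the hazard is deliberately a time-homogeneous function of current
    #: severity only (Markov), so that risk-set matching on severity proxies
    #: is unbiased under a null treatment effect
    discharge_log_base: float = -11.2
    discharge_severity_coef: float = 2.2
    #: per-day death hazard = exp(death_log_base + death_severity_coef * severity)
    death_log_base: float = 0.0
    death_severity_coef: float = 1.6
    crp_log_intercept: float = 3.15
    crp_severity_coef: float = 0.45
    #: persistent between-patient and daily within-patient log-CRP noise
    crp_offset_log_sd: float = 0.40
    crp_log_sd: float = 0.25
    crp_missing_rate: float = 0.10
    #: radiograph schedule: day 0, then uniform gaps in [min, max]
    xray_gap_min: int = 2
    xray_gap_max: int = 6
    #: quadrants = clip(2 + round((severity - xray_center) / xray_scale), 0, 4)
    xray_center: float = -2.1
    xray_scale: float = 0.85
    palliative_fraction_of_deaths: float = 0.35


@dataclass(frozen=True)
class TreatmentAssignment:
    """Logistic links from baseline severity/comorbidities to drug use.

    The study drug's probability is
    ``logistic(intercept + severity_coef * (s0 - severity_ref) + sum coefs)``;
    a positive ``severity_coef`` makes sicker patients more likely to be
    treated (severity confounding).  Setting it and ``comorbidity_coefs`` to
    zero randomises assignment.
    """

    intercept: float = 0.55
    severity_coef: float = 0.85
    severity_ref: float = -2.35
    comorbidity_coefs: Mapping[str, float] = field(default_factory=dict)
    #: P(start day = 0, 1, 2) for the study drug
    start_day_probs: tuple[float, ...] = (0.55, 0.30, 0.15)
    n_doses: int = 5
    #: other drugs: name -> (base logit, severity coefficient)
    other_drug_logits: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "interferon": (-2.2, 0.35),
            "tocilizumab": (-2.8, 0.80),
            "methylprednisolone": (-2.9, 0.70),
            "dexamethasone": (-2.0, 0.50),
            "heparin": (0.9, 0.10),
        }
    )
    #: joint probability of the background antiviral pair
    hcq_lpv_both: float = 0.828
    hcq_only: float = 0.05
    lpv_only: float = 0.03


@dataclass(frozen=True)
class CohortConfig:
    """All generator parameters.  ``default_config()`` targets the marginal
    profile of the motivating hospital cohort."""

    n_patients: int = 418
    seed: int = 0
    prop_male: float = 0.569
    age_mean: float = 65.4
    age_sd: float = 16.6
    comorbidity_prevalences: Mapping[str, float] = field(
        default_factory=lambda: {
            "obesity": 0.177,
            "chf": 0.062,
            "crf": 0.146,
            "sahs": 0.081,
            "tobacco": 0.086,
            "hypertension": 0.519,
            "diabetes": 0.237,
            "copd": 0.098,
            "other_cardiopathy": 0.148,
        }
    )
    baseline_severity_params: BaselineSeverityParams = field(
        default_factory=BaselineSeverityParams
    )
    trajectory_params: TrajectoryParams = field(default_factory=TrajectoryParams)
    treatment_assignment: TreatmentAssignment = field(
        default_factory=TreatmentAssignment
    )
    true_effect: TrueEffect = field(default_factory=TrueEffect)
    censor_day: int = FOLLOWUP_CAP_DAYS

    def validate(self) -> "CohortConfig":
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        fractions = {
            "prop_male": self.prop_male,
            **{f"prevalence[{k}]": v for k, v in self.comorbidity_prevalences.items()},
            "hcq_lpv_both": self.treatment_assignment.hcq_lpv_both,
            "crp_missing_rate": self.trajectory_params.crp_missing_rate,
        }
        for name, v in fractions.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.true_effect.discharge_hazard_ratio <= 0:
            raise ValueError("discharge_hazard_ratio must be > 0")
        probs = self.treatment_assignment.start_day_probs
        if abs(sum(probs) - 1) > 1e-9 or any(p < 0 for p in probs):
            raise ValueError("start_day_probs must be a probability vector")
        if self.censor_day < 1:
            raise ValueError("censor_day must be >= 1")
        return self

    # -- (de)serialisation, mirrored field-for-field in YAML -----------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in (
            "comorbidity_prevalences",
            ("baseline_severity_params", "comorbidity_coefs"),
            ("treatment_assignment", "comorbidity_coefs"),
            ("treatment_assignment", "other_drug_logits"),
        ):
            if isinstance(key, tuple):
                d[key[0]][key[1]] = dict(d[key[0]][key[1]])
            else:
                d[key] = dict(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown CohortConfig field(s): {sorted(unknown)}")

        def sub(key, klass):
            if key in d and not isinstance(d[key], klass):
                payload = dict(d[key])
                names = {f.name for f in dataclasses.fields(klass)}
                bad = set(payload) - names
                if bad:
                    raise ValueError(f"unknown {key} field(s): {sorted(bad)}")
                if klass is TreatmentAssignment:
                    if "start_day_probs" in payload:
                        payload["start_day_probs"] = tuple(payload["start_day_probs"])
                    if "other_drug_logits" in payload:
                        payload["other_drug_logits"] = {
                            k: tuple(v)
                            for k, v in payload["other_drug_logits"].items()
                        }
                if klass is TrajectoryParams and "device_thresholds" in payload:
                    payload["device_thresholds"] = tuple(payload["device_thresholds"])
                d[key] = klass(**payload)

        sub("baseline_severity_params", BaselineSeverityParams)
        sub("trajectory_params", TrajectoryParams)
        sub("treatment_assignment", TreatmentAssignment)
        sub("true_effect", TrueEffect)
        return cls(**d).validate()


def default_config() -> CohortConfig:
    """Configuration calibrated to the motivating cohort's marginal profile
    (n=418; 56.9% male; age 65.4 +/- 16.6; ~57% treated; median stay 8 days,
    IQR 5-12; ~19% 30-day mortality; null true effect)."""
    return CohortConfig()


def no_confounding(config: CohortConfig) -> CohortConfig:
    """Copy of ``config`` with randomised treatment assignment (all links
    from severity/comorbidities to treatment zeroed)."""
    ta = replace(
        config.treatment_assignment, severity_coef=0.0, comorbidity_coefs={}
    )
    return replace(config, treatment_assignment=ta)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Draw one cohort.  Deterministic given ``config`` (same seed ->
    identical tables)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    T = int(config.censor_day)
    bp = config.baseline_severity_params
    tp = config.trajectory_params
    ta = config.treatment_assignment
    eff = config.true_effect

    # -- statics -------------------------------------------------------
    male = rng.random(n) < config.prop_male
    age = np.clip(
        np.rint(rng.normal(config.age_mean, config.age_sd, n)), 18, 100
    ).astype(int)
    comorb = {
        name: rng.random(n) < p for name, p in config.comorbidity_prevalences.items()
    }

    s0 = rng.normal(bp.mean, bp.sd, n) + bp.age_coef * (age - config.age_mean) / max(
        config.age_sd, 1e-9
    )
    for name, coef in bp.comorbidity_coefs.items():
        if name in comorb:
            s0 = s0 + coef * comorb[name]

    # -- treatment assignment (confounded by baseline severity) --------
    logit = ta.intercept + ta.severity_coef * (s0 - ta.severity_ref)
    for name, coef in ta.comorbidity_coefs.items():
        if name in comorb:
            logit = logit + coef * comorb[name]
    treated = rng.random(n) < _logistic(logit)
    start_day = rng.choice(
        np.arange(len(ta.start_day_probs)), size=n, p=np.asarray(ta.start_day_probs)
    )
    # exposure active from the first dose onward
    day_grid = np.arange(T + 1)
    active = treated[:, None] & (day_grid[None, :] >= start_day[:, None])

    # -- latent severity paths ------------------------------------------
    sev = np.empty((n, T + 1))
    sev[:, 0] = s0
    personal_drift = rng.normal(tp.drift, tp.drift_sd, n)
    steps = personal_drift[:, None] + rng.normal(0, tp.noise_sd, (n, T))
    for t in range(1, T + 1):
        sev[:, t] = sev[:, t - 1] + steps[:, t - 1] - eff.safi_drift * active[:, t]

    # -- competing discharge/death events -------------------------------
    hr_mult = np.where(active, eff.discharge_hazard_ratio, 1.0)
    h_death = np.exp(tp.death_log_base + tp.death_severity_coef * sev)
    h_disch = (
        np.exp(tp.discharge_log_base - tp.discharge_severity_coef * sev) * hr_mult
    )
    u_death = rng.random((n, T + 1))
    u_disch = rng.random((n, T + 1))
    event_day = np.full(n, -1)
    event_type = np.zeros(n, dtype=int)  # 0 censored, 1 discharge, 2 death
    alive = np.ones(n, dtype=bool)
    for t in range(1, T + 1):
        p_death = -np.expm1(-h_death[:, t])
        p_disch = -np.expm1(-h_disch[:, t])
        dies = alive & (u_death[:, t] < p_death)
        leaves = alive & ~dies & (u_disch[:, t] < p_disch)
        event_day[dies] = t
        event_type[dies] = 2
        event_day[leaves] = t
        event_type[leaves] = 1
        alive &= ~(dies | leaves)
    end_day = np.where(event_day >= 0, event_day, T)

    death_day = np.where(event_type == 2, event_day, -1)
    discharge_day = np.where(event_type == 1, event_day, -1)
    palliative = (event_type == 2) & (
        rng.random(n) < tp.palliative_fraction_of_deaths
    )

    # -- observable matrices --------------------------------------------
    safi = np.clip(
        SAFI_MAX * _logistic(-sev) + rng.normal(0, tp.safi_noise_sd, sev.shape),
        0.5,
        SAFI_MAX,
    )
    # FiO2 is titrated to a per-day target saturation, as on a real ward;
    # the recorded saturation/FiO2 pair therefore reproduces the latent
    # oxygenation ratio up to rounding
    target_sat = np.clip(rng.normal(tp.target_sat_mean, tp.target_sat_sd, sev.shape), 88.0, 97.0)
    fio2 = np.clip(np.round(target_sat / safi), 21.0, 100.0)
    spo2 = np.clip(np.round(safi * fio2, 1), 55.0, 100.0)
    device_edges = np.array([21.5, 30.5, 50.5, 85.5])  # RA/nasal/venturi/reservoir
    tier = np.digitize(fio2, device_edges)
    # ventilated (NIV/IMV) reserved for the severe end
    tier = np.where((tier == 4) & (sev >= tp.device_thresholds[-1]), 5, tier)

    v_off = [rng.normal(0, s, n)[:, None] for s in tp.vitals_offset_sd]
    sbp = np.round(123 - 2.0 * sev + v_off[0] + rng.normal(0, tp.vitals_daily_sd[0], sev.shape), 0)
    dbp = np.round(70 - 1.0 * sev + v_off[1] + rng.normal(0, tp.vitals_daily_sd[1], sev.shape), 0)
    hr = np.round(78 + 4.0 * sev + v_off[2] + rng.normal(0, tp.vitals_daily_sd[2], sev.shape), 0)
    temperature = np.round(rng.normal(36.7 + 0.15 * sev, 0.4), 1)

    crp_off = rng.normal(0, tp.crp_offset_log_sd, n)[:, None]
    crp = np.round(
        np.exp(
            tp.crp_log_intercept
            + tp.crp_severity_coef * np.clip(sev, -4, 4)
            + crp_off
            + rng.normal(0, tp.crp_log_sd, sev.shape)
        ),
        1,
    )
    crp_missing = rng.random(sev.shape) < tp.crp_missing_rate

    # radiograph schedule: day 0 plus uniform gaps in [gap_min, gap_max]
    gaps = rng.integers(tp.xray_gap_min, tp.xray_gap_max + 1, (n, T + 1))
    xray_scheduled = np.zeros((n, T + 1), dtype=bool)
    xray_scheduled[:, 0] = True
    next_day = gaps[:, 0].copy()
    for t in range(1, T + 1):
        due = next_day == t
        xray_scheduled[due, t] = True
        next_day[due] = t + gaps[due, t]
    quadrants = np.clip(2 + np.rint((sev - tp.xray_center) / tp.xray_scale), 0, 4)

    # -- assemble long tables --------------------------------------------
    ids = np.array([f"P{i:05d}" for i in range(n)])
    obs_mask = day_grid[None, :] <= end_day[:, None]
    pi, di = np.nonzero(obs_mask)
    observations = pd.DataFrame(
        {
            "patient_id": ids[pi],
            "day": di,
            "spo2": spo2[pi, di],
            "fio2": fio2[pi, di],
            "sbp": sbp[pi, di],
            "dbp": dbp[pi, di],
            "hr": hr[pi, di],
            "temperature": temperature[pi, di],
            "crp": np.where(crp_missing[pi, di], np.nan, crp[pi, di]),
            "xray_quadrants": np.where(
                xray_scheduled[pi, di], quadrants[pi, di], np.nan
            ),
            "oxygen_device": np.array(_DEVICE_ORDER)[tier[pi, di]],
        }
    )

    treatments = _assign_treatments(
        rng, ids, treated, start_day, end_day, sev, s0, ta, T
    )

    statics = pd.DataFrame(
        {
            "patient_id": ids,
            "sex": np.where(male, "male", "female"),
            "age": age,
            **{name: comorb[name] for name in config.comorbidity_prevalences},
            "admission_day": 0,
            "death_day": pd.array(
                [d if d >= 0 else None for d in death_day], dtype="Int64"
            ),
            "discharge_day": pd.array(
                [d if d >= 0 else None for d in discharge_day], dtype="Int64"
            ),
            "palliative_sedation": palliative,
        }
    )
    return Cohort(statics=statics, observations=observations, treatments=treatments)


def _assign_treatments(rng, ids, treated, start_day, end_day, sev, s0, ta, T):
    rows_pid, rows_drug, rows_day, rows_dose = [], [], [], []

    # study drug: 500 mg loading dose then 250 mg daily, 5 doses total,
    # truncated by the end of stay
    for i in np.nonzero(treated)[0]:
        last = min(int(start_day[i]) + ta.n_doses - 1, int(end_day[i]), T)
        for k, day in enumerate(range(int(start_day[i]), last + 1)):
            rows_pid.append(ids[i])
            rows_drug.append("azithromycin")
            rows_day.append(day)
            rows_dose.append(500.0 if k == 0 else 250.0)

    n = len(ids)
    u = rng.random(n)
    p_both = ta.hcq_lpv_both
    has_hcq = u < p_both + ta.hcq_only
    has_lpv = (u < p_both) | (
        (u >= p_both + ta.hcq_only) & (u < p_both + ta.hcq_only + ta.lpv_only)
    )
    combo_start = rng.integers(0, 2, n)
    nominal_dose = {
        "hydroxychloroquine": 400.0,
        "lopinavir_ritonavir": 800.0,
        "interferon": 250.0,
        "tocilizumab": 600.0,
        "methylprednisolone": 40.0,
        "dexamethasone": 6.0,
        "heparin": 40.0,
    }
    for drug, mask in (("hydroxychloroquine", has_hcq), ("lopinavir_ritonavir", has_lpv)):
        for i in np.nonzero(mask)[0]:
            day = min(int(combo_start[i]), int(end_day[i]))
            rows_pid.append(ids[i])
            rows_drug.append(drug)
            rows_day.append(day)
            rows_dose.append(nominal_dose[drug])

    for drug, (base, coef) in ta.other_drug_logits.items():
        p = _logistic(base + coef * (s0 - ta.severity_ref))
        got = rng.random(n) < p
        drug_start = rng.integers(0, 4, n)
        for i in np.nonzero(got)[0]:
            day = min(int(drug_start[i]), int(end_day[i]))
            rows_pid.append(ids[i])
            rows_drug.append(drug)
            rows_day.append(day)
            rows_dose.append(nominal_dose[drug])

    return pd.DataFrame(
        {
            "patient_id": rows_pid,
            "drug": rows_drug,
            "day": rows_day,
            "dose_mg": rows_dose,
        }
    )


def simulate_many(config: CohortConfig, n_replicates: int) -> Iterator[Cohort]:
    """Independent replicates; replicate ``r`` uses ``seed = base_seed + r``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for r in range(n_replicates):
        yield simulate_cohort(replace(config, seed=config.seed + r))
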