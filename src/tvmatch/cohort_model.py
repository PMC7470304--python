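"""Domain types and delimited-text I/O for longitudinal admission cohorts.

A cohort is three tables:

``patients.csv``
    one row per admission: static covariates, admission/event days.
``observations.csv``
    one row per patient-day: oximetry, vitals, CRP, radiograph quadrants.
``treatments.csv``
    one row per administered dose (or treatment start for non-dosed drugs).

Conventions
-----------
* Day 0 is the day of admission; all day fields are integer offsets from it.
* Hospital stay in days is ``discharge_day - 0``.
* Follow-up is truncated 30 days after admission.
* Missing values are empty CSV fields, never numeric sentinels.
* Booleans are serialised as ``true``/``false``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SEXES",
    "DRUGS",
    "OXYGEN_DEVICES",
    "COMORBIDITIES",
    "FOLLOWUP_CAP_DAYS",
    "CohortError",
    "ValidationError",
    "ReferentialIntegrityError",
    "PatientStatic",
    "DailyObservation",
    "TreatmentEvent",
    "Cohort",
    "read_cohort",
    "write_cohort",
]

SEXES = ("male", "female")

DRUGS = (
    "azithromycin",
    "hydroxychloroquine",
    "lopinavir_ritonavir",
    "interferon",
    "tocilizumab",
    "methylprednisolone",
    "dexamethasone",
    "heparin",
)

OXYGEN_DEVICES = ("room_air", "nasal_prongs", "venturi", "reservoir", "niv", "imv")

#: Binary history covariates carried on the static table.
COMORBIDITIES = (
    "obesity",
    "chf",
    "crf",
    "sahs",
    "tobacco",
    "hypertension",
    "diabetes",
    "copd",
    "other_cardiopathy",
)

#: Follow-up truncation, days after admission.
FOLLOWUP_CAP_DAYS = 30

STATIC_COLUMNS = (
    ["patient_id", "sex", "age"]
    + list(COMORBIDITIES)
    + ["admission_day", "death_day", "discharge_day", "palliative_sedation"]
)

OBS_COLUMNS = [
    "patient_id",
    "day",
    "spo2",
    "fio2",
    "sbp",
    "dbp",
    "hr",
    "temperature",
    "crp",
    "xray_quadrants",
    "oxygen_device",
]

TREAT_COLUMNS = ["patient_id", "drug", "day", "dose_mg"]

_BOOL_STATIC = list(COMORBIDITIES) + ["palliative_sedation"]


class CohortError(ValueError):
    """Base class for cohort construction / validation failures."""


class ValidationError(CohortError):
    """A record violates a domain-type invariant; message names the row."""


class ReferentialIntegrityError(CohortError):
    """An observation or treatment references an unknown patient_id."""


@dataclass(frozen=True)
class PatientStatic:
    """Static covariates and admission outcome for one patient."""

    patient_id: str
    sex: str
    age: int
    obesity: bool = False
    chf: bool = False
    crf: bool = False
    sahs: bool = False
    tobacco: bool = False
    hypertension: bool = False
    diabetes: bool = False
    copd: bool = False
    other_cardiopathy: bool = False
    admission_day: int = 0
    death_day: Optional[int] = None
    discharge_day: Optional[int] = None
    palliative_sedation: bool = False


@dataclass(frozen=True)
class DailyObservation:
    """One calendar day of oximetry, vitals and ancillary findings."""

    patient_id: str
    day: int
    spo2: float
    fio2: float
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    hr: Optional[float] = None
    temperature: Optional[float] = None
    crp: Optional[float] = None
    xray_quadrants: Optional[int] = None
    oxygen_device: str = "room_air"


@dataclass(frozen=True)
class TreatmentEvent:
    """A single administered dose of one drug."""

    patient_id: str
    drug: str
    day: int
    dose_mg: float


@dataclass
class Cohort:
    """Three aligned tables: statics, daily observations, treatment events.

    The tables are plain :class:`pandas.DataFrame` objects with fixed column
    sets; :meth:`validate` enforces every domain invariant with
    row-addressable error messages.
    """

    statics: pd.DataFrame
    observations: pd.DataFrame
    treatments: pd.DataFrame

    def __post_init__(self) -> None:
        self.statics = _coerce_statics(self.statics)
        self.observations = _coerce_observations(self.observations)
        self.treatments = _coerce_treatments(self.treatments)

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(
        cls,
        statics: Iterable[PatientStatic],
        observations: Iterable[DailyObservation] = (),
        treatments: Iterable[TreatmentEvent] = (),
    ) -> "Cohort":
        return cls(
            statics=pd.DataFrame(
                [dataclasses.asdict(s) for s in statics], columns=STATIC_COLUMNS
            ),
            observations=pd.DataFrame(
                [dataclasses.asdict(o) for o in observations], columns=OBS_COLUMNS
            ),
            treatments=pd.DataFrame(
                [dataclasses.asdict(t) for t in treatments], columns=TREAT_COLUMNS
            ),
        )

    # -- basic accessors ----------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.statics)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.statics["patient_id"])

    def patient(self, patient_id: str) -> PatientStatic:
        row = self.statics.loc[self.statics["patient_id"] == patient_id]
        if row.empty:
            raise KeyError(patient_id)
        r = row.iloc[0]
        return PatientStatic(
            patient_id=r["patient_id"],
            sex=r["sex"],
            age=int(r["age"]),
            admission_day=int(r["admission_day"]),
            death_day=None if pd.isna(r["death_day"]) else int(r["death_day"]),
            discharge_day=None if pd.isna(r["discharge_day"]) else int(r["discharge_day"]),
            palliative_sedation=bool(r["palliative_sedation"]),
            **{c: bool(r[c]) for c in COMORBIDITIES},
        )

    def observations_for(self, patient_id: str) -> pd.DataFrame:
        return self.observations.loc[
            self.observations["patient_id"] == patient_id
        ].sort_values("day")

    def treatments_for(self, patient_id: str) -> pd.DataFrame:
        return self.treatments.loc[self.treatments["patient_id"] == patient_id]

    def equals(self, other: "Cohort") -> bool:
        """Value equality, insensitive to row order."""

        def norm(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
            return df.sort_values(keys).reset_index(drop=True)

        return (
            norm(self.statics, ["patient_id"]).equals(norm(other.statics, ["patient_id"]))
            and norm(self.observations, ["patient_id", "day"]).equals(
                norm(other.observations, ["patient_id", "day"])
            )
            and norm(self.treatments, ["patient_id", "drug", "day"]).equals(
                norm(other.treatments, ["patient_id", "drug", "day"])
            )
        )

    # -- validation ---------------------------------------------------

    def validate(self) -> "Cohort":
        """Check every invariant; raise on the first violated one.

        Returns ``self`` so calls can be chained.
        """
        _validate_statics(self.statics)
        ids = set(self.statics["patient_id"])
        _validate_observations(self.observations, ids)
        _validate_treatments(self.treatments, ids, self.statics)
        return self


# ---------------------------------------------------------------------------
# coercion helpers


def _coerce_statics(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reindex(columns=STATIC_COLUMNS).copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["age"] = df["age"].astype("Int64")
    df["admission_day"] = df["admission_day"].astype("Int64")
    for c in ("death_day", "discharge_day"):
        df[c] = df[c].astype("Int64")
    for c in _BOOL_STATIC:
        df[c] = df[c].map(_to_bool)
    return df


def _coerce_observations(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reindex(columns=OBS_COLUMNS).copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["day"] = df["day"].astype("Int64")
    for c in ("spo2", "fio2", "sbp", "dbp", "hr", "temperature", "crp"):
        df[c] = pd.to_numeric(df[c], errors="coerce").astype(float)
    df["xray_quadrants"] = pd.to_numeric(df["xray_quadrants"], errors="coerce").astype(
        "Int64"
    )
    return df


def _coerce_treatments(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reindex(columns=TREAT_COLUMNS).copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["day"] = df["day"].astype("Int64")
    df["dose_mg"] = pd.to_numeric(df["dose_mg"], errors="coerce").astype(float)
    return df


def _to_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, str):
        low = v.strip().lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no", ""):
            return False
        raise ValidationError(f"unparseable boolean value {v!r}")
    if pd.isna(v):
        return False
    return bool(v)


# ---------------------------------------------------------------------------
# validation


def _validate_statics(df: pd.DataFrame) -> None:
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate patient_id {dup.iloc[0]!r} in statics")
    for i, r in df.iterrows():
        where = f"statics row {i} (patient {r['patient_id']})"
        if r["sex"] not in SEXES:
            raise ValidationError(f"{where}: sex {r['sex']!r} not in {SEXES}")
        if pd.isna(r["age"]) or int(r["age"]) < 0:
            raise ValidationError(f"{where}: age must be an integer >= 0")
        adm = r["admission_day"]
        if pd.isna(adm):
            raise ValidationError(f"{where}: admission_day missing")
        death, disch = r["death_day"], r["discharge_day"]
        if not pd.isna(death) and not pd.isna(disch):
            raise ValidationError(f"{where}: both death_day and discharge_day set")
        for name, v in (("death_day", death), ("discharge_day", disch)):
            if pd.isna(v):
                continue
            if int(v) < int(adm):
                raise ValidationError(f"{where}: {name} precedes admission_day")
            if int(v) > int(adm) + FOLLOWUP_CAP_DAYS:
                raise ValidationError(
                    f"{where}: {name} beyond the {FOLLOWUP_CAP_DAYS}-day follow-up cap"
                )


def _validate_observations(df: pd.DataFrame, ids: set) -> None:
    unknown = set(df["patient_id"]) - ids
    if unknown:
        raise ReferentialIntegrityError(
            f"observations reference unknown patient_id(s): {sorted(unknown)[:5]}"
        )
    dup = df.duplicated(subset=["patient_id", "day"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        r = df.iloc[i]
        raise ValidationError(
            f"observations row {df.index[i]}: duplicate day {r['day']} for patient "
            f"{r['patient_id']}"
        )
    for i, r in df.iterrows():
        where = f"observations row {i} (patient {r['patient_id']}, day {r['day']})"
        if pd.isna(r["day"]) or int(r["day"]) < 0:
            raise ValidationError(f"{where}: day must be an integer >= 0")
        if not (0 < r["spo2"] <= 100):
            raise ValidationError(f"{where}: spo2 {r['spo2']} outside (0, 100]")
        if not (21 <= r["fio2"] <= 100):
            raise ValidationError(f"{where}: fio2 {r['fio2']} outside [21, 100]")
        if r["oxygen_device"] not in OXYGEN_DEVICES:
            raise ValidationError(
                f"{where}: oxygen_device {r['oxygen_device']!r} not in {OXYGEN_DEVICES}"
            )
        if r["oxygen_device"] == "room_air" and r["fio2"] != 21:
            raise ValidationError(f"{where}: fio2 must be 21 on room_air")
        q = r["xray_quadrants"]
        if not pd.isna(q) and int(q) not in (0, 1, 2, 3, 4):
            raise ValidationError(f"{where}: xray_quadrants {q} outside 0-4")


def _validate_treatments(df: pd.DataFrame, ids: set, statics: pd.DataFrame) -> None:
    unknown = set(df["patient_id"]) - ids
    if unknown:
        raise ReferentialIntegrityError(
            f"treatments reference unknown patient_id(s): {sorted(unknown)[:5]}"
        )
    dup = df.duplicated(subset=["patient_id", "drug", "day"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        r = df.iloc[i]
        raise ValidationError(
            f"treatments row {df.index[i]}: duplicate dose of {r['drug']} on day "
            f"{r['day']} for patient {r['patient_id']}"
        )
    end = _window_end(statics)
    for i, r in df.iterrows():
        where = f"treatments row {i} (patient {r['patient_id']})"
        if r["drug"] not in DRUGS:
            raise ValidationError(f"{where}: unknown drug {r['drug']!r}")
        if pd.isna(r["day"]) or int(r["day"]) < 0:
            raise ValidationError(f"{where}: day must be an integer >= 0")
        if pd.isna(r["dose_mg"]) or r["dose_mg"] <= 0:
            raise ValidationError(f"{where}: dose_mg must be > 0")
        cap = end.get(r["patient_id"], FOLLOWUP_CAP_DAYS)
        if int(r["day"]) > cap:
            raise ValidationError(
                f"{where}: dose on day {r['day']} after end of admission (day {cap})"
            )


def _window_end(statics: pd.DataFrame) -> dict[str, int]:
    """Last admitted day per patient: event day, else the follow-up cap."""
    out: dict[str, int] = {}
    for _, r in statics.iterrows():
        ev = [int(v) for v in (r["death_day"], r["discharge_day"]) if not pd.isna(v)]
        out[r["patient_id"]] = min(ev) if ev else int(r["admission_day"]) + FOLLOWUP_CAP_DAYS
    return out


# ---------------------------------------------------------------------------
# I/O


def read_cohort(
    static_path, obs_path, treat_path, validate: bool = True
) -> Cohort:
    """Read the three cohort tables from delimited-text files.

    Lines starting with ``#`` (provenance headers written by the pipeline)
    are ignored.  Raises :class:`ValidationError` /
    :class:`ReferentialIntegrityError` on invalid content.
    """
    kw = dict(comment="#", dtype={"patient_id": str})
    cohort = Cohort(
        statics=pd.read_csv(static_path, **kw),
        observations=pd.read_csv(obs_path, **kw),
        treatments=pd.read_csv(treat_path, **kw),
    )
    if validate:
        cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, out_dir, header_comment: str | None = None):
    """Write ``patients.csv``, ``observations.csv`` and ``treatments.csv``.

    Returns the three paths.  Files round-trip exactly through
    :func:`read_cohort`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = (out / "patients.csv", out / "observations.csv", out / "treatments.csv")
    frames = (cohort.statics, cohort.observations, cohort.treatments)
    for path, df in zip(paths, frames):
        df = df.copy()
        for c in df.columns:
            if df[c].dtype == bool or c in _BOOL_STATIC and c in df:
                if df[c].dtype == bool:
                    df[c] = df[c].map({True: "true", False: "false"})
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index=False, float_format="%.10g")
    return paths
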