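"""Derived per-day quantities and matching-covariate selection.

Defines the oxygenation index (SpO2%/FiO2% ratio), the dose-count exposure
rule, the between-radiograph imputation rule, reference-day lookups used to
align a control's clock with a treated patient's, and a data-driven screen
for which baseline comorbidities to match on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import COMORBIDITIES, FOLLOWUP_CAP_DAYS, Cohort

__all__ = [
    "SAFI_MAX",
    "DEFAULT_MATCHING_COVARIATES",
    "SEVERE_DEVICES",
    "ExposureStatus",
    "compute_safi",
    "exposure_status",
    "impute_radiology",
    "reference_crp",
    "reference_xray",
    "build_derived",
    "severe_disease_flags",
    "select_matching_covariates",
]

#: Ceiling of the saturation/FiO2 ratio: 100% saturation on room air (21%).
SAFI_MAX = 100.0 / 21.0

#: Covariate set used for matching when data-driven selection is skipped.
DEFAULT_MATCHING_COVARIATES = ("sex", "age", "obesity", "chf", "crf", "sahs")

#: Oxygen devices that define the severe-disease outcome (high-flow support).
SEVERE_DEVICES = frozenset({"reservoir", "niv", "imv"})

#: Exposure requires at least this many administered doses.
MIN_DOSES_EXPOSED = 3

#: Radiograph gap (days) beyond which no interpolation is done.
XRAY_MAX_GAP = 6

#: Reference radiograph may be up to this many days before the index day.
XRAY_LOOKBACK = 2


@dataclass(frozen=True)
class ExposureStatus:
    """Dose-count exposure summary for one patient and one drug."""

    patient_id: str
    exposed: bool
    first_dose_day: Optional[int]
    n_doses: int


def compute_safi(spo2_percent: float, fio2_percent: float) -> float:
    """Oxygen saturation (%) divided by inspired-oxygen fraction (%).

    Maximum value 100/21 = 4.76 (2 dp), reached at full saturation on room
    air.  Raises ``ValueError`` outside the physiologic domain.
    """
    if not 0 < spo2_percent <= 100:
        raise ValueError(f"spo2 {spo2_percent} outside (0, 100]")
    if not 21 <= fio2_percent <= 100:
        raise ValueError(f"fio2 {fio2_percent} outside [21, 100]")
    return spo2_percent / fio2_percent


def exposure_status(
    treatments: pd.DataFrame | Iterable, drug: str, patient_id: str | None = None
) -> ExposureStatus:
    """Exposure for one patient: exposed iff >= 3 doses of ``drug``.

    ``treatments`` is a single patient's treatment table (DataFrame with
    ``drug``/``day`` columns) or an iterable of
    :class:`~tvmatch.cohort_model.TreatmentEvent`.
    """
    if not isinstance(treatments, pd.DataFrame):
        treatments = pd.DataFrame(
            [(t.patient_id, t.drug, t.day) for t in treatments],
            columns=["patient_id", "drug", "day"],
        )
    if patient_id is None:
        patient_id = (
            str(treatments["patient_id"].iloc[0]) if len(treatments) else ""
        )
    rows = treatments.loc[treatments["drug"] == drug]
    n = int(len(rows))
    first = int(rows["day"].min()) if n else None
    return ExposureStatus(
        patient_id=patient_id,
        exposed=n >= MIN_DOSES_EXPOSED,
        first_dose_day=first,
        n_doses=n,
    )


def impute_radiology(
    observed: Mapping[int, int] | Sequence[tuple[int, int]],
) -> dict[int, tuple[int, str]]:
    """Fill days between two *equal* radiographs taken <= 6 days apart.

    ``observed`` maps day -> affected quadrants (0-4).  Returns
    ``{day: (quadrants, provenance)}`` where provenance is ``"observed"`` or
    ``"imputed"``.  Days between consecutive radiographs with unequal counts,
    or with a gap exceeding 6 days, stay missing.  Observed days are never
    altered; the operation is idempotent.
    """
    pairs = list(observed.items()) if isinstance(observed, Mapping) else list(observed)
    days = [d for d, _ in pairs]
    if len(set(days)) != len(days):
        raise ValueError("duplicate radiograph days")
    items = sorted(pairs)
    out: dict[int, tuple[int, str]] = {d: (int(q), "observed") for d, q in items}
    for (d0, q0), (d1, q1) in zip(items, items[1:]):
        if q0 == q1 and (d1 - d0) <= XRAY_MAX_GAP:
            for d in range(d0 + 1, d1):
                out[d] = (int(q0), "imputed")
    return dict(sorted(out.items()))


def reference_crp(observations: pd.DataFrame, index_day: int) -> Optional[float]:
    """CRP at the index day, else the day before, else missing."""
    if index_day < 0:
        raise ValueError("index_day must be >= 0")
    by_day = observations.set_index("day")["crp"] if "day" in observations else observations["crp"]
    for d in (index_day, index_day - 1):
        if d in by_day.index:
            v = by_day.loc[d]
            if not pd.isna(v):
                return float(v)
    return None


def reference_xray(
    imputed: Mapping[int, tuple[int, str]] | Mapping[int, int], index_day: int
) -> Optional[int]:
    """Most recent (possibly imputed) quadrant count within the 2-day lookback."""
    for d in range(index_day, index_day - XRAY_LOOKBACK - 1, -1):
        if d in imputed:
            v = imputed[d]
            return int(v[0] if isinstance(v, tuple) else v)
    return None


def build_derived(cohort: Cohort) -> pd.DataFrame:
    """Per patient-day derived table.

    Columns: ``patient_id, day, safi, crp, crp_ref, xray_imputed,
    xray_source``.  ``crp_ref`` applies the index-day-else-previous-day rule
    at every day; ``xray_imputed`` is the between-equal-radiograph fill with
    provenance in ``xray_source`` (``observed``/``imputed`` or empty).
    """
    obs = cohort.observations.sort_values(["patient_id", "day"])
    frames = []
    for pid, g in obs.groupby("patient_id", sort=True):
        days = g["day"].astype(int).to_numpy()
        safi = g["spo2"].to_numpy(dtype=float) / g["fio2"].to_numpy(dtype=float)
        crp = g["crp"].to_numpy(dtype=float)
        crp_by_day = dict(zip(days, crp))
        crp_ref = np.array(
            [
                crp_by_day[d]
                if not math.isnan(crp_by_day[d])
                else crp_by_day.get(d - 1, math.nan)
                for d in days
            ]
        )
        xobs = {
            int(d): int(q)
            for d, q in zip(days, g["xray_quadrants"])
            if not pd.isna(q)
        }
        filled = impute_radiology(xobs)
        xval = [filled.get(int(d), (math.nan, ""))[0] for d in days]
        xsrc = [filled.get(int(d), (math.nan, ""))[1] for d in days]
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "day": days,
                    "safi": safi,
                    "crp": crp,
                    "crp_ref": crp_ref,
                    "xray_imputed": xval,
                    "xray_source": xsrc,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "patient_id",
                "day",
                "safi",
                "crp",
                "crp_ref",
                "xray_imputed",
                "xray_source",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def severe_disease_flags(cohort: Cohort) -> pd.Series:
    """Per patient: any day on high-flow support (reservoir mask or
    mechanical ventilation)."""
    severe_ids = set(
        cohort.observations.loc[
            cohort.observations["oxygen_device"].isin(SEVERE_DEVICES), "patient_id"
        ]
    )
    return pd.Series(
        [pid in severe_ids for pid in cohort.statics["patient_id"]],
        index=cohort.statics["patient_id"],
        name="severe_disease",
    )


def select_matching_covariates(
    cohort: Cohort,
    outcomes: Sequence[str] = ("severe_disease", "death"),
    alpha: float = 0.05,
    seed: int = 0,
    antecedents: Sequence[str] = COMORBIDITIES,
) -> list[str]:
    """Data-driven choice of baseline history covariates to match on.

    Per outcome: (1) bivariate screen of each binary antecedent at
    ``p < alpha`` (chi-square, Fisher's exact when an expected cell < 5);
    (2) L1-penalised logistic regression with the penalty chosen by 5-fold
    cross-validation, keeping antecedents with non-zero coefficients;
    (3) unpenalised multivariate logistic refit, keeping those significant
    at ``alpha``.  The union over outcomes is returned, ordered as in
    ``antecedents``.  Deterministic given ``seed``.

    Raises ``ValueError`` if an outcome is degenerate (all patients equal).
    """
    from sklearn.linear_model import LogisticRegressionCV
    import statsmodels.api as sm

    statics = cohort.statics
    y_by_outcome: dict[str, np.ndarray] = {}
    for name in outcomes:
        if name == "severe_disease":
            y = severe_disease_flags(cohort).to_numpy()
        elif name == "death":
            y = (~statics["death_day"].isna()).to_numpy()
        else:
            raise ValueError(f"unknown outcome {name!r}")
        if len(set(y.tolist())) < 2:
            raise ValueError(f"degenerate outcome {name!r}: all values identical")
        y_by_outcome[name] = y.astype(int)

    X_all = statics[list(antecedents)].astype(int)
    selected: set[str] = set()
    for name, y in y_by_outcome.items():
        screened = [
            a for a in antecedents if _bivariate_p(X_all[a].to_numpy(), y) < alpha
        ]
        if not screened:
            continue
        X = X_all[screened].to_numpy(dtype=float)
        model = LogisticRegressionCV(
            Cs=10,
            cv=5,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            random_state=seed,
            max_iter=1000,
        ).fit(X, y)
        kept = [a for a, c in zip(screened, model.coef_[0]) if abs(c) > 1e-8]
        if not kept:
            continue
        refit = sm.Logit(y, sm.add_constant(X_all[kept].to_numpy(dtype=float))).fit(
            disp=0
        )
        pvals = refit.pvalues[1:]
        selected.update(a for a, p in zip(kept, pvals) if p < alpha)
    return [a for a in antecedents if a in selected]


def _bivariate_p(x: np.ndarray, y: np.ndarray) -> float:
    """2x2 association p-value: chi-square, Fisher when a cell is sparse."""
    table = np.array(
        [
            [np.sum((x == 0) & (y == 0)), np.sum((x == 0) & (y == 1))],
            [np.sum((x == 1) & (y == 0)), np.sum((x == 1) & (y == 1))],
        ]
    )
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if expected.min() < 5:
        return float(stats.fisher_exact(table)[1])
    return float(stats.chi2_contingency(table, correction=False)[1])
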