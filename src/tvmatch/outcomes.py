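"""Outcome analyses for the matched and unmatched subcohorts.

Matched subcohort: change in oxygenation (and saturation / FiO2) at 48, 72
and 96 hours from each member's first follow-up day, compared between groups
with Student's t-test; and Kaplan-Meier time to discharge compared with the
log-rank test (deceased patients excluded, administrative censoring 30 days
after admission).

Unmatched subcohorts: patients on both background antivirals, corticosteroid
users dropped, then any other drug distributed significantly asymmetrically
between exposure groups dropped iteratively; time to discharge from day 1 of
admission analysed with a Cox proportional-hazards model adjusted for nine
baseline covariates; mortality as a two-group count comparison with Fisher's
exact test (with an explicit small-event-count caveat).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import Cohort, FOLLOWUP_CAP_DAYS
from .matching import CohortArrays, MatchedPair
from .preprocessing import MIN_DOSES_EXPOSED

__all__ = [
    "SafiChangeResult",
    "TimeToEventResult",
    "CoxResult",
    "MortalityResult",
    "UnmatchedSubcohorts",
    "safi_change",
    "discharge_analysis_matched",
    "select_unmatched_subcohorts",
    "discharge_cox_unmatched",
    "mortality_comparison",
]

#: Cox adjustment set for the unmatched discharge model.
COX_COVARIATES = (
    "sex",
    "age",
    "obesity",
    "chf",
    "crf",
    "sahs",
    "baseline_saturation",
    "baseline_crp",
    "baseline_xray",
)

#: below this total death count the mortality comparison is flagged as
#: insufficient to draw conclusions
MORTALITY_EVENT_CAVEAT = 10


@dataclass(frozen=True)
class SafiChangeResult:
    """Between-group comparison of a change-from-baseline respiratory
    variable at one horizon."""

    variable: str
    horizon_hours: int
    treated_mean: float
    control_mean: float
    mean_difference: float
    ci_low: float
    ci_high: float
    p: float
    n_treated: int
    n_control: int
    n_excluded_palliative: int
    n_excluded_missing: int


@dataclass(frozen=True)
class TimeToEventResult:
    treated_median: float
    control_median: float
    treated_mean: float
    control_mean: float
    logrank_statistic: float
    p: float
    n_treated: int
    n_control: int
    events_treated: int
    events_control: int
    censored_treated: int
    censored_control: int
    n_excluded_deceased: int
    #: step functions: (times, survival) per group
    km_treated: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    km_control: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    events: int
    coefficients: pd.DataFrame = field(repr=False, default=None)


@dataclass(frozen=True)
class MortalityResult:
    deaths_treated: int
    n_treated: int
    deaths_control: int
    n_control: int
    percent_treated: float
    percent_control: float
    p: float
    insufficient_events: bool


@dataclass(frozen=True)
class UnmatchedSubcohorts:
    exposed_ids: list[str]
    control_ids: list[str]
    dropped_corticosteroid: int
    dropped_asymmetric: dict[str, int]


# ---------------------------------------------------------------------------
# matched subcohort


def _mean_diff_ci(a: np.ndarray, b: np.ndarray, welch: bool = False):
    """Two-sample mean difference (b - a) with 95% CI and t-test p."""
    na, nb = len(a), len(b)
    diff = float(np.mean(b) - np.mean(a))
    if welch:
        res = stats.ttest_ind(b, a, equal_var=False)
        se = np.sqrt(np.var(a, ddof=1) / na + np.var(b, ddof=1) / nb)
        dof = res.df if hasattr(res, "df") else na + nb - 2
    else:
        res = stats.ttest_ind(b, a, equal_var=True)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
            na + nb - 2
        )
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        dof = na + nb - 2
    tcrit = stats.t.ppf(0.975, dof)
    p = float(res.pvalue)
    if np.isnan(p) and np.allclose(a, b[0] if nb else 0):
        p = 1.0
    return diff, diff - tcrit * se, diff + tcrit * se, p


def safi_change(
    pairs: Sequence[MatchedPair],
    cohort: Cohort,
    horizon_hours: int,
    variable: str = "safi",
    arrays: CohortArrays | None = None,
    welch: bool = False,
) -> SafiChangeResult:
    """Change in ``variable`` (safi, spo2 or fio2) from follow-up day 1 to
    ``horizon_hours`` later, compared between matched groups.

    Palliative-sedation patients are excluded; members missing either
    measurement are dropped and counted.  Raises ``ValueError`` with fewer
    than two evaluable members per group.
    """
    if horizon_hours not in (48, 72, 96):
        raise ValueError("horizon_hours must be one of 48, 72, 96")
    if variable not in ("safi", "spo2", "fio2"):
        raise ValueError(f"unknown variable {variable!r}")
    if arrays is None:
        arrays = CohortArrays(cohort)
    lag = horizon_hours // 24
    mat = getattr(arrays, variable)

    groups: dict[str, list[float]] = {"treated": [], "control": []}
    n_pall = n_miss = 0
    for p in pairs:
        for group, pid, day in (
            ("treated", p.treated_id, p.treated_index_day),
            ("control", p.control_id, p.control_start_day),
        ):
            i = arrays.index[pid]
            if arrays.palliative[i]:
                n_pall += 1
                continue
            if day + lag > arrays.censor_day:
                n_miss += 1
                continue
            base, later = mat[i, day], mat[i, day + lag]
            if np.isnan(base) or np.isnan(later):
                n_miss += 1
                continue
            groups[group].append(float(later - base))
    t, c = np.array(groups["treated"]), np.array(groups["control"])
    if len(t) < 2 or len(c) < 2:
        raise ValueError(
            f"fewer than 2 evaluable members per group at {horizon_hours} h "
            f"(treated {len(t)}, control {len(c)})"
        )
    diff, lo, hi, p = _mean_diff_ci(t, c, welch=welch)
    return SafiChangeResult(
        variable=variable,
        horizon_hours=horizon_hours,
        treated_mean=float(np.mean(t)),
        control_mean=float(np.mean(c)),
        mean_difference=diff,
        ci_low=lo,
        ci_high=hi,
        p=p,
        n_treated=len(t),
        n_control=len(c),
        n_excluded_palliative=n_pall,
        n_excluded_missing=n_miss,
    )


def discharge_analysis_matched(
    pairs: Sequence[MatchedPair],
    cohort: Cohort,
    arrays: CohortArrays | None = None,
) -> TimeToEventResult:
    """Kaplan-Meier time to discharge from each member's follow-up day 1,
    compared with the log-rank test.  Deceased patients are excluded;
    remaining patients are censored 30 days after admission."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    if arrays is None:
        arrays = CohortArrays(cohort)
    times = {"treated": [], "control": []}
    events = {"treated": [], "control": []}
    n_deceased = 0
    for p in pairs:
        for group, pid, day in (
            ("treated", p.treated_id, p.treated_index_day),
            ("control", p.control_id, p.control_start_day),
        ):
            i = arrays.index[pid]
            if not np.isnan(arrays.death_day[i]):
                n_deceased += 1
                continue
            if not np.isnan(arrays.discharge_day[i]):
                times[group].append(float(arrays.discharge_day[i] - day))
                events[group].append(1)
            else:
                times[group].append(float(arrays.censor_day - day))
                events[group].append(0)
    if sum(events["treated"]) + sum(events["control"]) == 0:
        raise ValueError("no discharge events in the matched subcohorts")
    lr = logrank_test(
        times["treated"],
        times["control"],
        event_observed_A=events["treated"],
        event_observed_B=events["control"],
    )
    km = {}
    medians = {}
    for g in ("treated", "control"):
        fitter = KaplanMeierFitter()
        fitter.fit(times[g], events[g])
        sf = fitter.survival_function_
        km[g] = (sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy())
        medians[g] = float(fitter.median_survival_time_)
    t_arr, c_arr = np.array(times["treated"]), np.array(times["control"])
    t_ev, c_ev = np.array(events["treated"]), np.array(events["control"])
    return TimeToEventResult(
        treated_median=medians["treated"],
        control_median=medians["control"],
        treated_mean=float(np.mean(t_arr[t_ev == 1])) if t_ev.any() else float("nan"),
        control_mean=float(np.mean(c_arr[c_ev == 1])) if c_ev.any() else float("nan"),
        logrank_statistic=float(lr.test_statistic),
        p=float(lr.p_value),
        n_treated=len(t_arr),
        n_control=len(c_arr),
        events_treated=int(t_ev.sum()),
        events_control=int(c_ev.sum()),
        censored_treated=int((t_ev == 0).sum()),
        censored_control=int((c_ev == 0).sum()),
        n_excluded_deceased=n_deceased,
        km_treated=km["treated"],
        km_control=km["control"],
    )


# ---------------------------------------------------------------------------
# unmatched subcohorts


def select_unmatched_subcohorts(
    cohort: Cohort, alpha: float = 0.05
) -> UnmatchedSubcohorts:
    """Second-strategy subcohorts.

    Keep patients who received both background antivirals; drop any
    corticosteroid user; then iteratively test each remaining other drug for
    asymmetry between exposure groups (Fisher, ``p < alpha``) and drop its
    users, most asymmetric first.  Exposure is >= 3 doses of the study drug
    at any time.  Raises ``ValueError`` on an empty subcohort.
    """
    treats = cohort.treatments
    drugs_by_patient: dict[str, set] = {}
    for pid, g in treats.groupby("patient_id"):
        drugs_by_patient[pid] = set(g["drug"])
    az_counts = (
        treats.loc[treats["drug"] == "azithromycin"].groupby("patient_id").size()
    )

    kept = [
        pid
        for pid in cohort.statics["patient_id"]
        if {"hydroxychloroquine", "lopinavir_ritonavir"}
        <= drugs_by_patient.get(pid, set())
    ]
    n0 = len(kept)
    kept = [
        pid
        for pid in kept
        if not ({"methylprednisolone", "dexamethasone"} & drugs_by_patient[pid])
    ]
    dropped_cortico = n0 - len(kept)

    def exposed(pid: str) -> bool:
        return int(az_counts.get(pid, 0)) >= MIN_DOSES_EXPOSED

    if not kept:
        raise ValueError("empty unmatched subcohort after exclusions")

    dropped_asym: dict[str, int] = {}
    testable = ["interferon", "tocilizumab", "heparin"]
    while True:
        worst = None
        for drug in testable:
            has = np.array([drug in drugs_by_patient[p] for p in kept], dtype=bool)
            exp = np.array([exposed(p) for p in kept], dtype=bool)
            table = [
                [int((has & exp).sum()), int((has & ~exp).sum())],
                [int((~has & exp).sum()), int((~has & ~exp).sum())],
            ]
            if has.sum() == 0 or has.all():
                continue
            p = float(stats.fisher_exact(table)[1])
            if p < alpha and (worst is None or p < worst[1]):
                worst = (drug, p)
        if worst is None:
            break
        drug = worst[0]
        before = len(kept)
        kept = [p for p in kept if drug not in drugs_by_patient[p]]
        dropped_asym[drug] = before - len(kept)
        testable.remove(drug)

    exposed_ids = sorted(p for p in kept if exposed(p))
    control_ids = sorted(
        p for p in kept if int(az_counts.get(p, 0)) == 0
    )  # 1-2 doses excluded
    if not exposed_ids or not control_ids:
        raise ValueError("empty unmatched subcohort after exclusions")
    return UnmatchedSubcohorts(
        exposed_ids=exposed_ids,
        control_ids=control_ids,
        dropped_corticosteroid=dropped_cortico,
        dropped_asymmetric=dropped_asym,
    )


def _baseline_frame(cohort: Cohort, ids: Sequence[str]) -> pd.DataFrame:
    """Static covariates plus emergency-room (day 0) saturation, CRP and
    radiograph quadrants."""
    statics = cohort.statics.set_index("patient_id").loc[list(ids)]
    day0 = (
        cohort.observations.loc[cohort.observations["day"] == 0]
        .set_index("patient_id")
        .reindex(list(ids))
    )
    df = pd.DataFrame(index=list(ids))
    df["sex"] = (statics["sex"] == "male").astype(float)
    df["age"] = statics["age"].astype(float)
    for c in ("obesity", "chf", "crf", "sahs"):
        df[c] = statics[c].astype(float)
    df["baseline_saturation"] = day0["spo2"].astype(float)
    df["baseline_crp"] = day0["crp"].astype(float)
    df["baseline_xray"] = day0["xray_quadrants"].astype(float)
    df["death_day"] = statics["death_day"].astype(float)
    df["discharge_day"] = statics["discharge_day"].astype(float)
    return df


def discharge_cox_unmatched(
    subcohorts: UnmatchedSubcohorts,
    cohort: Cohort,
    covariates: Sequence[str] = COX_COVARIATES,
    censor_day: int = FOLLOWUP_CAP_DAYS,
    robust: bool = True,
) -> CoxResult:
    """Cox proportional-hazards model for time to discharge from day 1 of
    admission, adjusted for the listed baseline covariates.

    Deceased patients are excluded; patients still admitted at ``censor_day``
    are right-censored there.  Rows with missing baseline covariates are
    dropped.  Ties are handled by Efron's method; the default sandwich
    (robust) variance guards against misspecification of the linear
    adjustment.  Raises ``ValueError`` on non-convergence.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    ids = list(subcohorts.exposed_ids) + list(subcohorts.control_ids)
    df = _baseline_frame(cohort, ids)
    df["exposed"] = [1.0] * len(subcohorts.exposed_ids) + [0.0] * len(
        subcohorts.control_ids
    )
    df = df.loc[df["death_day"].isna()]
    df["time"] = df["discharge_day"].fillna(censor_day).clip(upper=censor_day)
    df["event"] = (~df["discharge_day"].isna()).astype(int)
    model_cols = ["exposed"] + [c for c in covariates]
    data = df[model_cols + ["time", "event"]].dropna()
    # constant columns carry no information and break the fit
    keep = ["exposed"] + [c for c in covariates if data[c].nunique() > 1]
    data = data[keep + ["time", "event"]]
    if data["event"].sum() == 0:
        raise ValueError("no discharge events in the unmatched subcohort")
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="time", event_col="event", robust=robust)
    except ConvergenceError as exc:
        raise ValueError(f"Cox model did not converge: {exc}") from exc
    summary = cph.summary
    row = summary.loc["exposed"]
    return CoxResult(
        hazard_ratio=float(np.exp(row["coef"])),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        p=float(row["p"]),
        n=int(len(data)),
        events=int(data["event"].sum()),
        coefficients=summary,
    )


def mortality_comparison(
    subcohorts: UnmatchedSubcohorts, cohort: Cohort
) -> MortalityResult:
    """30-day death counts per group with Fisher's exact test; flags the
    comparison when total events are too few to draw conclusions."""
    dead = set(
        cohort.statics.loc[~cohort.statics["death_day"].isna(), "patient_id"]
    )
    dt = sum(1 for p in subcohorts.exposed_ids if p in dead)
    dc = sum(1 for p in subcohorts.control_ids if p in dead)
    nt, nc = len(subcohorts.exposed_ids), len(subcohorts.control_ids)
    if nt == 0 or nc == 0:
        raise ValueError("empty group in mortality comparison")
    p = float(stats.fisher_exact([[dt, nt - dt], [dc, nc - dc]])[1])
    return MortalityResult(
        deaths_treated=dt,
        n_treated=nt,
        deaths_control=dc,
        n_control=nc,
        percent_treated=100.0 * dt / nt,
        percent_control=100.0 * dc / nc,
        p=p,
        insufficient_events=(dt + dc) < MORTALITY_EVENT_CAVEAT,
    )
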