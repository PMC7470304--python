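"""Risk-set matching of treated patients to controls at aligned hospital days.

For every exposed patient (index day = first dose day) the matcher
brute-force enumerates every (control, start-day) combination satisfying the
hard constraints:

* equal sex and obesity status;
* age difference at most 15 years;
* equal (possibly interpolated) radiograph quadrant count at the aligned
  days, looked up with a 2-day lookback;
* the control's oxygenation ratio (SpO2%/FiO2%) between 1.1 points below and
  2.0 points above the treated patient's;
* the control's reference CRP between 6 mg/dL below and 4 mg/dL above the
  treated patient's (missing reference CRP or radiograph on either side
  makes the combination infeasible);
* identical sets of co-treatments (background antivirals, interferon,
  tocilizumab, corticosteroids pooled as a class), each starting within 3
  days of the treated patient's, measured relative to the aligned days;
* the control still in hospital and event-free at its start day and through
  the first follow-up day.

Feasible candidates are then ranked by closeness of a logistic propensity
score fitted on the aligned-day snapshot (oxygenation ratio, systolic and
diastolic pressure, heart rate, CRP), and paired 1:1 greedily without
replacement in ascending treated patient_id order.  An optional
minimum-total-distance assignment mode is provided for sensitivity analysis.

Controls are patients with zero doses of the study drug; patients with one
or two doses are excluded from both arms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import Cohort, FOLLOWUP_CAP_DAYS, COMORBIDITIES
from .preprocessing import (
    MIN_DOSES_EXPOSED,
    XRAY_LOOKBACK,
    impute_radiology,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MatchCriteria",
    "Candidate",
    "MatchedPair",
    "MatchResult",
    "CohortArrays",
    "enumerate_candidates",
    "propensity_refine",
    "match_cohort",
    "balance_table",
    "safi_trend_check",
]

#: snapshot covariates entering the propensity refinement
PS_FEATURES = ("safi", "sbp", "dbp", "hr", "crp")

CORTICOSTEROIDS = ("methylprednisolone", "dexamethasone")


@dataclass(frozen=True)
class MatchCriteria:
    """Hard constraints for candidate enumeration (1:1 ratio)."""

    exact_binary: tuple[str, ...] = ("sex", "obesity")
    age_window: float = 15.0
    #: allowed control - treated oxygenation-ratio difference
    safi_window: tuple[float, float] = (-1.1, 2.0)
    #: allowed control - treated reference-CRP difference, mg/dL
    crp_window: tuple[float, float] = (-6.0, 4.0)
    cotreatment_drugs: tuple[str, ...] = (
        "hydroxychloroquine",
        "lopinavir_ritonavir",
        "interferon",
        "corticosteroids",
        "tocilizumab",
    )
    cotreatment_lag: int = 3
    #: match the two corticosteroids as one class (toggle for per-drug)
    pool_corticosteroids: bool = True
    ratio: int = 1

    def validate(self) -> "MatchCriteria":
        if self.age_window < 0 or self.cotreatment_lag < 0:
            raise ValueError("age_window and cotreatment_lag must be >= 0")
        for name, (lo, hi) in (
            ("safi_window", self.safi_window),
            ("crp_window", self.crp_window),
        ):
            if lo > hi:
                raise ValueError(f"{name} bounds out of order: {lo} > {hi}")
        if self.ratio != 1:
            raise ValueError("only 1:1 matching is supported")
        from .cohort_model import DRUGS

        allowed = set(DRUGS) | {"corticosteroids"} - {"azithromycin"}
        for drug in self.cotreatment_drugs:
            if drug not in allowed:
                raise ValueError(f"unknown co-treatment drug {drug!r}")
        return self


@dataclass(frozen=True)
class Candidate:
    """One feasible (control, start-day) option for a treated patient,
    with the aligned-day covariate snapshot used downstream."""

    treated_id: str
    treated_index_day: int
    control_id: str
    control_start_day: int
    treated_snapshot: dict[str, float]
    control_snapshot: dict[str, float]


@dataclass(frozen=True)
class MatchedPair:
    candidate: Candidate
    ps_distance: float

    @property
    def treated_id(self) -> str:
        return self.candidate.treated_id

    @property
    def control_id(self) -> str:
        return self.candidate.control_id

    @property
    def treated_index_day(self) -> int:
        return self.candidate.treated_index_day

    @property
    def control_start_day(self) -> int:
        return self.candidate.control_start_day


@dataclass
class MatchResult:
    pairs: list[MatchedPair]
    unmatched_treated: list[str]
    #: treated ids with no feasible candidate at all
    infeasible_treated: list[str] = field(default_factory=list)
    ps_fallback: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "treated_id": p.treated_id,
                    "index_day": p.treated_index_day,
                    "control_id": p.control_id,
                    "start_day": p.control_start_day,
                    "ps_distance": p.ps_distance,
                }
                for p in self.pairs
            ],
            columns=["treated_id", "index_day", "control_id", "start_day", "ps_distance"],
        )


# ---------------------------------------------------------------------------
# dense per-day arrays


class CohortArrays:
    """Dense (patient x day) matrices of everything the matcher consults.

    ``end_day`` is the event day (death or discharge) or the censor day; a
    patient is in hospital and event-free on days ``0 .. end_day - 1``.
    """

    def __init__(self, cohort: Cohort, censor_day: int = FOLLOWUP_CAP_DAYS):
        self.cohort = cohort
        self.censor_day = int(censor_day)
        statics = cohort.statics.sort_values("patient_id").reset_index(drop=True)
        self.ids = statics["patient_id"].to_numpy()
        self.index = {pid: i for i, pid in enumerate(self.ids)}
        n, T = len(self.ids), self.censor_day

        self.sex = statics["sex"].to_numpy()
        self.age = statics["age"].to_numpy(dtype=float)
        self.static = {c: statics[c].to_numpy() for c in statics.columns}
        death = statics["death_day"].to_numpy(dtype=float, na_value=np.nan)
        disch = statics["discharge_day"].to_numpy(dtype=float, na_value=np.nan)
        self.death_day = death
        self.discharge_day = disch
        event = np.fmin(death, disch)
        self.event_day = event
        self.end_day = np.where(np.isnan(event), T, np.fmin(event, T)).astype(int)
        self.palliative = statics["palliative_sedation"].to_numpy(dtype=bool)

        shape = (n, T + 1)
        self.safi = np.full(shape, np.nan)
        self.spo2 = np.full(shape, np.nan)
        self.fio2 = np.full(shape, np.nan)
        self.sbp = np.full(shape, np.nan)
        self.dbp = np.full(shape, np.nan)
        self.hr = np.full(shape, np.nan)
        self.temperature = np.full(shape, np.nan)
        self.crp = np.full(shape, np.nan)
        self.has_obs = np.zeros(shape, dtype=bool)

        obs = cohort.observations
        keep = obs["day"].to_numpy(dtype=int) <= T
        obs = obs.loc[keep]
        pi = np.array([self.index[p] for p in obs["patient_id"]], dtype=int)
        di = obs["day"].to_numpy(dtype=int)
        self.has_obs[pi, di] = True
        self.spo2[pi, di] = obs["spo2"].to_numpy(dtype=float)
        self.fio2[pi, di] = obs["fio2"].to_numpy(dtype=float)
        self.safi[pi, di] = self.spo2[pi, di] / self.fio2[pi, di]
        for name in ("sbp", "dbp", "hr", "temperature", "crp"):
            getattr(self, name)[pi, di] = obs[name].to_numpy(dtype=float, na_value=np.nan)

        # reference CRP: index day, else the day before
        self.crp_ref = self.crp.copy()
        nanmask = np.isnan(self.crp_ref[:, 1:])
        self.crp_ref[:, 1:][nanmask] = self.crp[:, :-1][nanmask]

        # radiograph interpolation + lookback-window reference
        self.xray_imputed = np.full(shape, np.nan)
        xobs = obs.loc[~obs["xray_quadrants"].isna()]
        by_patient: dict[int, dict[int, int]] = {}
        for p, d, q in zip(
            (self.index[x] for x in xobs["patient_id"]),
            xobs["day"].astype(int),
            xobs["xray_quadrants"].astype(int),
        ):
            by_patient.setdefault(p, {})[int(d)] = int(q)
        for p, series in by_patient.items():
            for d, (q, _src) in impute_radiology(series).items():
                if d <= T:
                    self.xray_imputed[p, d] = q
        self.xray_ref = self.xray_imputed.copy()
        for back in range(1, XRAY_LOOKBACK + 1):
            nanmask = np.isnan(self.xray_ref[:, back:])
            self.xray_ref[:, back:][nanmask] = self.xray_imputed[:, :-back][nanmask]

        # exposure to the study drug
        az = cohort.treatments.loc[cohort.treatments["drug"] == "azithromycin"]
        counts = az.groupby("patient_id")["day"].agg(["size", "min"])
        self.az_doses = np.zeros(n, dtype=int)
        self.az_first = np.full(n, -1, dtype=int)
        for pid, row in counts.iterrows():
            i = self.index[pid]
            self.az_doses[i] = int(row["size"])
            self.az_first[i] = int(row["min"])

        self.exposed = self.az_doses >= MIN_DOSES_EXPOSED
        self.control = self.az_doses == 0  # 1-2 doses excluded from both arms

        # co-treatment class signature and first start day per class
        self.cotreat_first: list[dict[str, int]] = [dict() for _ in range(n)]
        other = cohort.treatments.loc[cohort.treatments["drug"] != "azithromycin"]
        for (pid, drug), g in other.groupby(["patient_id", "drug"]):
            i = self.index[pid]
            first = int(g["day"].min())
            prev = self.cotreat_first[i].get(drug)
            self.cotreat_first[i][drug] = first if prev is None else min(prev, first)

    def treated_ids(self) -> list[str]:
        return [self.ids[i] for i in np.nonzero(self.exposed)[0]]

    def control_ids(self) -> list[str]:
        return [self.ids[i] for i in np.nonzero(self.control)[0]]

    def cotreat_signature(
        self, i: int, criteria: MatchCriteria
    ) -> dict[str, int]:
        """Class -> first start day, restricted to the criteria drugs."""
        first = self.cotreat_first[i]
        out: dict[str, int] = {}
        for cls in criteria.cotreatment_drugs:
            if cls == "corticosteroids" and criteria.pool_corticosteroids:
                days = [first[d] for d in CORTICOSTEROIDS if d in first]
                if days:
                    out[cls] = min(days)
            elif cls == "corticosteroids":
                for d in CORTICOSTEROIDS:
                    if d in first:
                        out[d] = first[d]
            elif cls in first:
                out[cls] = first[cls]
        return out

    def snapshot(self, i: int, day: int) -> dict[str, float]:
        return {
            "safi": float(self.safi[i, day]),
            "spo2": float(self.spo2[i, day]),
            "fio2": float(self.fio2[i, day]),
            "sbp": float(self.sbp[i, day]),
            "dbp": float(self.dbp[i, day]),
            "hr": float(self.hr[i, day]),
            "temperature": float(self.temperature[i, day]),
            "crp": float(self.crp_ref[i, day]),
            "xray": float(self.xray_ref[i, day]),
        }


# ---------------------------------------------------------------------------
# candidate enumeration


def enumerate_candidates(
    treated_id: str,
    arrays: CohortArrays,
    criteria: MatchCriteria = MatchCriteria(),
) -> list[Candidate]:
    """All feasible (control, start-day) combinations for one treated patient.

    Raises ``ValueError`` if ``treated_id`` is not exposed.
    """
    criteria.validate()
    ti = arrays.index[treated_id]
    if not arrays.exposed[ti]:
        raise ValueError(f"{treated_id} is not exposed to the study drug")
    t_idx = int(arrays.az_first[ti])
    t_safi = arrays.safi[ti, t_idx] if t_idx <= arrays.censor_day else np.nan
    t_crp = arrays.crp_ref[ti, t_idx] if t_idx <= arrays.censor_day else np.nan
    t_xray = arrays.xray_ref[ti, t_idx] if t_idx <= arrays.censor_day else np.nan
    if np.isnan(t_safi) or np.isnan(t_crp) or np.isnan(t_xray):
        return []
    t_sig = arrays.cotreat_signature(ti, criteria)
    t_rel = {cls: day - t_idx for cls, day in t_sig.items()}

    # static screen over controls
    mask = arrays.control.copy()
    for cov in criteria.exact_binary:
        mask &= arrays.static[cov] == arrays.static[cov][ti]
    mask &= np.abs(arrays.age - arrays.age[ti]) <= criteria.age_window
    cand_idx = np.nonzero(mask)[0]
    cand_idx = np.array(
        [
            c
            for c in cand_idx
            if set(arrays.cotreat_signature(int(c), criteria)) == set(t_sig)
        ],
        dtype=int,
    )
    if cand_idx.size == 0:
        return []

    T = arrays.censor_day
    days = np.arange(T + 1)
    # in hospital, event-free at the start day and through follow-up day 1
    valid = days[None, :] < np.minimum(arrays.end_day[cand_idx], T)[:, None]
    valid &= arrays.has_obs[cand_idx]

    dsafi = arrays.safi[cand_idx] - t_safi
    valid &= (dsafi >= criteria.safi_window[0]) & (dsafi <= criteria.safi_window[1])
    dcrp = arrays.crp_ref[cand_idx] - t_crp
    valid &= (dcrp >= criteria.crp_window[0]) & (dcrp <= criteria.crp_window[1])
    valid &= arrays.xray_ref[cand_idx] == t_xray

    # co-treatment start-day lag, relative to the aligned days
    for row, c in enumerate(cand_idx):
        c_sig = arrays.cotreat_signature(int(c), criteria)
        for cls, rel_t in t_rel.items():
            rel_c = c_sig[cls] - days
            valid[row] &= np.abs(rel_c - rel_t) <= criteria.cotreatment_lag

    out: list[Candidate] = []
    t_snap = arrays.snapshot(ti, t_idx)
    for row, c in enumerate(cand_idx):
        for d in np.nonzero(valid[row])[0]:
            out.append(
                Candidate(
                    treated_id=treated_id,
                    treated_index_day=t_idx,
                    control_id=str(arrays.ids[c]),
                    control_start_day=int(d),
                    treated_snapshot=t_snap,
                    control_snapshot=arrays.snapshot(int(c), int(d)),
                )
            )
    out.sort(key=lambda cd: (cd.control_id, cd.control_start_day))
    return out


# ---------------------------------------------------------------------------
# propensity refinement


def _ps_feature_row(arrays: CohortArrays, i: int, day: int) -> np.ndarray:
    """Snapshot features with last-observation-carried-forward (<= 1 day)
    for missing vitals; remaining gaps are mean-imputed at fit time."""
    vals = []
    for name in PS_FEATURES:
        mat = arrays.crp_ref if name == "crp" else getattr(arrays, name)
        v = mat[i, day]
        if np.isnan(v) and name in ("sbp", "dbp", "hr") and day >= 1:
            v = mat[i, day - 1]
            if not np.isnan(v):
                logger.debug(
                    "LOCF vital %s for %s day %d", name, arrays.ids[i], day
                )
        vals.append(v)
    return np.array(vals, dtype=float)


def _fit_propensity(X: np.ndarray, y: np.ndarray):
    """Logistic treated-status model; returns (score_fn, fallback_flag)."""
    import statsmodels.api as sm

    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    Xf = np.where(np.isnan(X), col_mean, X)
    sd = Xf.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xf - Xf.mean(axis=0)) / sd

    if 0 < y.sum() < len(y):
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, sm.add_constant(Z)).fit(disp=0, maxiter=200)
            params = np.asarray(fit.params)
            if np.all(np.isfinite(params)) and np.max(np.abs(params)) < 50:
                def score(row: np.ndarray) -> float:
                    z = (np.where(np.isnan(row), col_mean, row) - Xf.mean(axis=0)) / sd
                    return float(1 / (1 + np.exp(-(params[0] + z @ params[1:]))))

                return score, False
        except Exception:  # separation / singular design
            pass

    logger.warning(
        "propensity fit degenerate; falling back to standardized Euclidean distance"
    )
    mean, std = Xf.mean(axis=0), sd

    def zrow(row: np.ndarray) -> np.ndarray:
        return (np.where(np.isnan(row), col_mean, row) - mean) / std

    return zrow, True


def score_candidates(
    candidates_per_treated: dict[str, list[Candidate]],
    arrays: CohortArrays,
) -> tuple[dict[str, list[tuple[float, Candidate]]], bool]:
    """Distance-sorted candidates per treated patient.

    Distance is |PS(control snapshot) - PS(treated snapshot)| from a logistic
    model of treated status on the aligned-day snapshots of all treated
    patients and all candidate control-days; on a degenerate fit, the
    standardized Euclidean distance over the same five covariates (logged).
    """
    rows, labels = [], []
    treated_rows: dict[str, np.ndarray] = {}
    control_rows: dict[tuple[str, int], np.ndarray] = {}
    for tid, cands in candidates_per_treated.items():
        if not cands:
            continue
        ti = arrays.index[tid]
        treated_rows[tid] = _ps_feature_row(arrays, ti, int(arrays.az_first[ti]))
        for cd in cands:
            key = (cd.control_id, cd.control_start_day)
            if key not in control_rows:
                control_rows[key] = _ps_feature_row(
                    arrays, arrays.index[cd.control_id], cd.control_start_day
                )
    for r in treated_rows.values():
        rows.append(r)
        labels.append(1)
    for r in control_rows.values():
        rows.append(r)
        labels.append(0)
    if not rows:
        return {tid: [] for tid in candidates_per_treated}, False

    score, fallback = _fit_propensity(np.array(rows), np.array(labels))

    out: dict[str, list[tuple[float, Candidate]]] = {}
    for tid, cands in candidates_per_treated.items():
        scored = []
        if cands:
            st = score(treated_rows[tid])
            for cd in cands:
                sc = score(control_rows[(cd.control_id, cd.control_start_day)])
                if fallback:
                    dist = float(np.linalg.norm(sc - st))
                else:
                    dist = abs(sc - st)
                scored.append((dist, cd))
            scored.sort(key=lambda t: (t[0], t[1].control_id, t[1].control_start_day))
        out[tid] = scored
    return out, fallback


def propensity_refine(
    candidates_per_treated: dict[str, list[Candidate]],
    arrays: CohortArrays,
) -> dict[str, Optional[MatchedPair]]:
    """Best (propensity-closest) candidate per treated patient, ignoring
    control reuse.  ``None`` where no candidate exists."""
    scored, _ = score_candidates(candidates_per_treated, arrays)
    return {
        tid: (MatchedPair(lst[0][1], lst[0][0]) if lst else None)
        for tid, lst in scored.items()
    }


# ---------------------------------------------------------------------------
# pairing


def match_cohort(
    cohort: Cohort,
    criteria: MatchCriteria = MatchCriteria(),
    method: str = "greedy",
    arrays: CohortArrays | None = None,
) -> MatchResult:
    """Pair treated patients 1:1 with controls without replacement.

    ``method="greedy"`` (default): treated patients in ascending patient_id
    order each take their propensity-closest candidate among still-unused
    controls.  ``method="optimal"``: minimum-total-distance bipartite
    assignment over the same feasible sets (sensitivity mode).
    """
    if method not in ("greedy", "optimal"):
        raise ValueError(f"unknown method {method!r}")
    criteria.validate()
    if arrays is None:
        arrays = CohortArrays(cohort)
    treated = sorted(arrays.treated_ids())
    cands = {tid: enumerate_candidates(tid, arrays, criteria) for tid in treated}
    scored, fallback = score_candidates(cands, arrays)
    infeasible = [tid for tid in treated if not cands[tid]]

    pairs: list[MatchedPair] = []
    unmatched: list[str] = []
    if method == "greedy":
        used: set[str] = set()
        for tid in treated:
            pick = next(
                ((d, c) for d, c in scored[tid] if c.control_id not in used), None
            )
            if pick is None:
                unmatched.append(tid)
                continue
            used.add(pick[1].control_id)
            pairs.append(MatchedPair(pick[1], pick[0]))
    else:
        pairs, unmatched = _optimal_assignment(treated, scored)
    return MatchResult(
        pairs=pairs,
        unmatched_treated=unmatched,
        infeasible_treated=infeasible,
        ps_fallback=fallback,
    )


def _optimal_assignment(treated, scored):
    from scipy.optimize import linear_sum_assignment

    best: dict[str, dict[str, tuple[float, Candidate]]] = {}
    controls: list[str] = []
    for tid in treated:
        per_control: dict[str, tuple[float, Candidate]] = {}
        for d, c in scored[tid]:
            if c.control_id not in per_control:  # scored is distance-sorted
                per_control[c.control_id] = (d, c)
        best[tid] = per_control
        controls.extend(per_control)
    controls = sorted(set(controls))
    if not controls:
        return [], list(treated)
    cidx = {c: j for j, c in enumerate(controls)}
    BIG = 1e9
    cost = np.full((len(treated), len(controls)), BIG)
    for i, tid in enumerate(treated):
        for cid, (d, _c) in best[tid].items():
            cost[i, cidx[cid]] = d
    ri, cj = linear_sum_assignment(cost)
    pairs, unmatched = [], []
    assigned = {}
    for i, j in zip(ri, cj):
        if cost[i, j] < BIG:
            assigned[treated[i]] = controls[j]
    for tid in treated:
        if tid in assigned:
            d, c = best[tid][assigned[tid]]
            pairs.append(MatchedPair(c, d))
        else:
            unmatched.append(tid)
    return pairs, unmatched


# ---------------------------------------------------------------------------
# balance diagnostics


def _fisher_p(a_yes: int, a_no: int, b_yes: int, b_no: int) -> float:
    return float(stats.fisher_exact([[a_yes, a_no], [b_yes, b_no]])[1])


def _t_p(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def balance_table(
    pairs: Sequence[MatchedPair],
    cohort: Cohort,
    arrays: CohortArrays | None = None,
) -> pd.DataFrame:
    """Per-covariate group comparison of the matched subcohorts.

    Continuous rows report group means and an equal-variance two-sample
    t-test; binary rows report counts/percentages and Fisher's exact test.
    Aligned-day rows (saturation, vitals, oxygenation ratio, CRP,
    radiograph) use each member's own follow-up start day.
    """
    if not pairs:
        raise ValueError("balance_table requires at least one pair")
    if arrays is None:
        arrays = CohortArrays(cohort)
    t_idx = np.array([arrays.index[p.treated_id] for p in pairs])
    c_idx = np.array([arrays.index[p.control_id] for p in pairs])
    t_day = np.array([p.treated_index_day for p in pairs])
    c_day = np.array([p.control_start_day for p in pairs])

    rows = []

    def cont(name, tvals, cvals):
        tvals, cvals = np.asarray(tvals, float), np.asarray(cvals, float)
        rows.append(
            {
                "variable": name,
                "kind": "continuous",
                "treated": float(np.nanmean(tvals)),
                "control": float(np.nanmean(cvals)),
                "treated_n": int(np.sum(~np.isnan(tvals))),
                "control_n": int(np.sum(~np.isnan(cvals))),
                "p": _t_p(tvals, cvals),
            }
        )

    def binary(name, tflags, cflags):
        ty, cy = int(np.sum(tflags)), int(np.sum(cflags))
        rows.append(
            {
                "variable": name,
                "kind": "binary",
                "treated": ty,
                "control": cy,
                "treated_n": len(tflags),
                "control_n": len(cflags),
                "p": _fisher_p(ty, len(tflags) - ty, cy, len(cflags) - cy),
            }
        )

    cont("age", arrays.age[t_idx], arrays.age[c_idx])
    binary("male", arrays.sex[t_idx] == "male", arrays.sex[c_idx] == "male")
    for cov in COMORBIDITIES:
        binary(cov, arrays.static[cov][t_idx].astype(bool), arrays.static[cov][c_idx].astype(bool))
    cont("saturation", arrays.spo2[t_idx, t_day], arrays.spo2[c_idx, c_day])
    cont("sbp", arrays.sbp[t_idx, t_day], arrays.sbp[c_idx, c_day])
    cont("dbp", arrays.dbp[t_idx, t_day], arrays.dbp[c_idx, c_day])
    cont("hr", arrays.hr[t_idx, t_day], arrays.hr[c_idx, c_day])
    cont("temperature", arrays.temperature[t_idx, t_day], arrays.temperature[c_idx, c_day])
    cont("safi", arrays.safi[t_idx, t_day], arrays.safi[c_idx, c_day])

    trend = safi_trend_check(pairs, arrays)
    rows.append(
        {
            "variable": "safi_trend",
            "kind": "continuous",
            "treated": trend.treated_mean,
            "control": trend.control_mean,
            "treated_n": trend.n_pairs_used,
            "control_n": trend.n_pairs_used,
            "p": trend.p,
        }
    )

    cont("xray_quadrants", arrays.xray_ref[t_idx, t_day], arrays.xray_ref[c_idx, c_day])
    cont("crp", arrays.crp_ref[t_idx, t_day], arrays.crp_ref[c_idx, c_day])

    for drug in (
        "hydroxychloroquine",
        "lopinavir_ritonavir",
        "interferon",
        "tocilizumab",
        "methylprednisolone",
        "dexamethasone",
    ):
        has = np.zeros(len(arrays.ids), dtype=bool)
        for i, first in enumerate(arrays.cotreat_first):
            has[i] = drug in first
        binary(drug, has[t_idx], has[c_idx])

    # mean stay from each member's follow-up start among discharged
    t_stay = np.where(
        np.isnan(arrays.discharge_day[t_idx]),
        np.nan,
        arrays.discharge_day[t_idx] - t_day,
    )
    c_stay = np.where(
        np.isnan(arrays.discharge_day[c_idx]),
        np.nan,
        arrays.discharge_day[c_idx] - c_day,
    )
    cont("hospital_stay", t_stay, c_stay)

    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SafiTrendResult:
    """Mean pre-index change of the oxygenation ratio per group: the value
    at follow-up day 1 minus the day before entering the analysis."""

    treated_mean: float
    control_mean: float
    p: float
    n_pairs_used: int
    n_pairs_excluded: int


def safi_trend_check(
    pairs: Sequence[MatchedPair], arrays: CohortArrays
) -> SafiTrendResult:
    """Verify both groups entered follow-up on a similar trajectory.

    Pairs where either member lacks the oxygenation ratio on the start day
    or the day before (e.g. start day 0) are excluded and counted.
    """
    t_ch, c_ch, excluded = [], [], 0
    for p in pairs:
        ti, ci = arrays.index[p.treated_id], arrays.index[p.control_id]
        td, cd = p.treated_index_day, p.control_start_day
        if td < 1 or cd < 1:
            excluded += 1
            continue
        tv = arrays.safi[ti, td] - arrays.safi[ti, td - 1]
        cv = arrays.safi[ci, cd] - arrays.safi[ci, cd - 1]
        if np.isnan(tv) or np.isnan(cv):
            excluded += 1
            continue
        t_ch.append(tv)
        c_ch.append(cv)
    if not t_ch:
        return SafiTrendResult(float("nan"), float("nan"), float("nan"), 0, excluded)
    return SafiTrendResult(
        treated_mean=float(np.mean(t_ch)),
        control_mean=float(np.mean(c_ch)),
        p=_t_p(np.array(t_ch), np.array(c_ch)),
        n_pairs_used=len(t_ch),
        n_pairs_excluded=excluded,
    )
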