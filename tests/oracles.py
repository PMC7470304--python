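"""Independent oracle implementations used only by the test suite.

Everything here is written directly from the stated rules with plain loops,
deliberately sharing no code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# brute-force feasibility (triple loop over treated x control x day)


def oracle_candidates(cohort, criteria=None):
    """All feasible (treated_id, index_day, control_id, day) tuples.

    Reimplements every hard rule independently: >=3-dose exposure, index at
    first dose, zero-dose controls, equal sex/obesity, age window 15,
    radiograph interpolation between equal films <= 6 days apart with 2-day
    lookback, oxygenation-ratio window [-1.1, +2.0], reference-CRP window
    [-6, +4] (day, else previous day), identical co-treatment classes with
    relative start-day lag <= 3, control event-free at the day and through
    the next day, 30-day truncation.
    """
    T = 30
    statics = {r["patient_id"]: r for _, r in cohort.statics.iterrows()}
    obs = {}
    for _, r in cohort.observations.iterrows():
        obs.setdefault(r["patient_id"], {})[int(r["day"])] = r
    doses = {}
    for _, r in cohort.treatments.iterrows():
        doses.setdefault(r["patient_id"], []).append((r["drug"], int(r["day"])))

    def az_days(pid):
        return sorted(d for dr, d in doses.get(pid, []) if dr == "azithromycin")

    def cotreat(pid):
        out = {}
        for dr, d in doses.get(pid, []):
            if dr == "azithromycin" or dr == "heparin":
                continue
            cls = "corticosteroids" if dr in ("methylprednisolone", "dexamethasone") else dr
            out[cls] = min(out.get(cls, d), d)
        return out

    def end_day(pid):
        r = statics[pid]
        ends = []
        for c in ("death_day", "discharge_day"):
            v = r[c]
            if v is not None and not (isinstance(v, float) and np.isnan(v)) and str(v) != "<NA>":
                ends.append(int(v))
        return min(ends) if ends else T

    def xray_series(pid):
        films = {
            d: int(r["xray_quadrants"])
            for d, r in obs.get(pid, {}).items()
            if not _isna(r["xray_quadrants"])
        }
        filled = dict(films)
        days = sorted(films)
        for d0, d1 in zip(days, days[1:]):
            if films[d0] == films[d1] and d1 - d0 <= 6:
                for d in range(d0 + 1, d1):
                    filled[d] = films[d0]
        return filled

    def xray_ref(pid, day):
        filled = xray_series(pid)
        for d in (day, day - 1, day - 2):
            if d in filled:
                return filled[d]
        return None

    def crp_ref(pid, day):
        for d in (day, day - 1):
            if d in obs.get(pid, {}) and not _isna(obs[pid][d]["crp"]):
                return float(obs[pid][d]["crp"])
        return None

    def safi(pid, day):
        if day not in obs.get(pid, {}):
            return None
        r = obs[pid][day]
        return float(r["spo2"]) / float(r["fio2"])

    out = []
    for tid, trow in statics.items():
        adays = az_days(tid)
        if len(adays) < 3:
            continue
        idx = adays[0]
        t_safi, t_crp, t_xray = safi(tid, idx), crp_ref(tid, idx), xray_ref(tid, idx)
        if t_safi is None or t_crp is None or t_xray is None:
            continue
        t_co = cotreat(tid)
        for cid, crow in statics.items():
            if az_days(cid):
                continue  # controls have zero doses
            if crow["sex"] != trow["sex"] or bool(crow["obesity"]) != bool(trow["obesity"]):
                continue
            if abs(int(crow["age"]) - int(trow["age"])) > 15:
                continue
            c_co = cotreat(cid)
            if set(c_co) != set(t_co):
                continue
            for day in range(0, min(end_day(cid), T)):
                if day not in obs.get(cid, {}):
                    continue
                c_safi = safi(cid, day)
                if c_safi is None or not (-1.1 <= c_safi - t_safi <= 2.0):
                    continue
                c_crp = crp_ref(cid, day)
                if c_crp is None or not (-6.0 <= c_crp - t_crp <= 4.0):
                    continue
                c_x = xray_ref(cid, day)
                if c_x is None or c_x != t_xray:
                    continue
                ok = True
                for cls in t_co:
                    if abs((c_co[cls] - day) - (t_co[cls] - idx)) > 3:
                        ok = False
                        break
                if ok:
                    out.append((tid, idx, cid, day))
    return sorted(out)


def _isna(v):
    try:
        return v is None or bool(np.isnan(float(v)))
    except (TypeError, ValueError):
        return str(v) == "<NA>"


# ---------------------------------------------------------------------------
# maximum bipartite matching by augmenting paths


def max_bipartite_matching(edges):
    """Size of a maximum matching over (treated, control) edge pairs."""
    adj = {}
    for t, c in edges:
        adj.setdefault(t, set()).add(c)
    match_of = {}

    def try_augment(t, seen):
        for c in adj.get(t, ()):
            if c in seen:
                continue
            seen.add(c)
            if c not in match_of or try_augment(match_of[c], seen):
                match_of[c] = t
                return True
        return False

    size = 0
    for t in sorted(adj):
        if try_augment(t, set()):
            size += 1
    return size


# ---------------------------------------------------------------------------
# log-rank statistic and permutation p


def logrank_statistic(times, events, group):
    """Two-group log-rank chi-square, standard hypergeometric variance."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(group, int)
    O1 = E1 = V = 0.0
    for u in np.unique(t[e == 1]):
        at_risk = t >= u
        n = at_risk.sum()
        n1 = (at_risk & (g == 1)).sum()
        d = ((t == u) & (e == 1)).sum()
        d1 = ((t == u) & (e == 1) & (g == 1)).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return 0.0 if V == 0 else (O1 - E1) ** 2 / V


def permutation_logrank_p(times, events, group, n_perm, seed=0):
    """Monte-Carlo permutation p of the log-rank statistic."""
    rng = np.random.default_rng(seed)
    g = np.asarray(group, int)
    obs = logrank_statistic(times, events, g)
    hits = 0
    for _ in range(n_perm):
        hits += logrank_statistic(times, events, rng.permutation(g)) >= obs - 1e-12
    return hits / n_perm, obs


# ---------------------------------------------------------------------------
# Fisher's exact via hypergeometric tail sums


def fisher_exact_p(a, b, c, d):
    """Two-sided Fisher p for [[a, b], [c, d]] summing hypergeometric point
    probabilities <= that of the observed table."""
    from math import comb

    row1, col1, n = a + b, a + c, a + b + c + d

    def point(x):
        return comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)

    p_obs = point(a)
    total = 0.0
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        px = point(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)
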