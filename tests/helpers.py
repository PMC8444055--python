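"""Independent oracles used by the test suite.

These deliberately avoid the package's interval arithmetic: coverage is
simulated one day at a time with a supply counter, and the conditional
likelihood is enumerated with plain itertools and maximised by bounded
scalar search.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import minimize_scalar


def day_by_day_coverage(disp_days, amounts, horizon: int):
    """Boolean covered-day array over days [0, horizon) from a supply
    counter: each day the patient takes one DDD if any supply is left;
    new dispensations add floor(amount) days of supply."""
    supply_on = {}
    for d, a in zip(disp_days, amounts):
        supply_on[d] = supply_on.get(d, 0) + int(np.floor(a))
    covered = np.zeros(horizon, dtype=bool)
    stock = 0
    start = min(min(supply_on, default=0), 0)
    for day in range(start, horizon):
        stock += supply_on.get(day, 0)
        if stock > 0:
            if day >= 0:
                covered[day] = True
            stock -= 1
    return covered


def day_by_day_eras(disp_days, amounts, gap_days: int):
    """Era boundaries from the same counter model: a dispensation opens
    a new era when it arrives more than ``gap_days`` after the day the
    supply ran out.  Returns (era_index_per_dispensation, coverage end
    day per era)."""
    era_of = []
    ends = []
    cov_end = None
    for d, a in zip(disp_days, amounts):
        dur = int(np.floor(a))
        if cov_end is None or d - cov_end > gap_days:
            era_of.append(0 if not era_of else era_of[-1] + 1)
            cov_end = d + dur
        else:
            era_of.append(era_of[-1])
            cov_end = max(d, cov_end) + dur
        if len(ends) < era_of[-1] + 1:
            ends.append(cov_end)
        else:
            ends[era_of[-1]] = cov_end
    return era_of, ends


def oracle_covered_days(
    disp_days, amounts, window_start: int, window_end: int,
    stays=(), gap_days: int = 60, bridging: str = "any_prior_era",
):
    """Covered days in [window_start, window_end): drug coverage from
    the day-by-day counter, plus bridged hospital days."""
    shifted = [d - window_start for d in disp_days]
    horizon = window_end - window_start
    covered = day_by_day_coverage(shifted, amounts, horizon)

    if stays:
        era_of, ends = day_by_day_eras(disp_days, amounts, gap_days)
        era_starts = []
        for i, e in enumerate(era_of):
            if e == len(era_starts):
                era_starts.append(disp_days[i])
        for adm, dis in stays:
            if bridging == "any_prior_era":
                ok = any(s < adm for s in era_starts)
            else:
                ok = any(s <= adm <= end for s, end in zip(era_starts, ends))
            if ok:
                for day in range(max(adm, window_start), min(dis, window_end)):
                    covered[day - window_start] = True
    return int(covered.sum())


def brute_conditional_loglik(sets, beta: float) -> float:
    """Exact conditional log-likelihood of an exposure-only model,
    enumerated set by set.  ``sets`` is a list of (y, x) pairs of equal
    length sequences of 0/1."""
    ll = 0.0
    for y, x in sets:
        d = int(sum(y))
        if d == 0 or d == len(y):
            continue
        num = beta * sum(xi for yi, xi in zip(y, x) if yi)
        terms = [
            beta * sum(x[i] for i in comb)
            for comb in combinations(range(len(y)), d)
        ]
        mx = max(terms)
        ll += num - (mx + np.log(sum(np.exp(t - mx) for t in terms)))
    return ll


def brute_fit_beta(sets, bound: float = 8.0) -> float:
    """Argmax of the enumerated conditional likelihood by bounded
    scalar optimisation."""
    res = minimize_scalar(
        lambda b: -brute_conditional_loglik(sets, b),
        bounds=(-bound, bound),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def random_matched_instance(rng, n_sets=30, max_size=5, beta=0.4):
    """Random matched sets with a binary exposure and logistic outcome
    (set effects included), returned as (sets, members-frame columns)."""
    sets = []
    rows = []
    for s in range(n_sets):
        n = int(rng.integers(2, max_size + 1))
        x = [1] + [0] * (n - 1)
        alpha = rng.normal(0.0, 1.0)
        p = 1.0 / (1.0 + np.exp(-(alpha + beta * np.array(x))))
        y = (rng.random(n) < p).astype(int).tolist()
        sets.append((y, x))
        for xi, yi in zip(x, y):
            rows.append((s, bool(xi), bool(yi)))
    return sets, rows
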