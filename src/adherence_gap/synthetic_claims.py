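"""Synthetic healthcare-utilisation claims with known ground truth.

The generator emulates the registry-style tables of a regional
healthcare-utilisation system - demographics, pharmacy dispensations
(in defined-daily-dose units), hospital stays, out-patient services
and a mental-health registry - with the statistical structure the
downstream pipeline is meant to confront:

* exposure (severe mental illness in active care at the index date)
  has configurable prevalence and is confounded with gender, age and
  contact volume;
* each patient carries a latent high-adherence propensity
  ``logit p = alpha + beta * SMI + sum(gamma * matching variables)``
  whose ``beta`` (``true_log_or``) is the conditional log-odds ratio
  the pipeline must recover;
* the latent draw is expressed through the same era machinery the
  pipeline tests: a target covered fraction is drawn from a
  category-conditional Beta mixture and realised as 30-DDD packs
  tiling the follow-up, so a latent "high" patient's realised PDC is
  >= 0.75 and a latent "not high" patient's is < 0.75;
* diabetics (GLUCOSE class) get the five clinical-control services
  driven by an analogous latent propensity with its own planted
  conditional log-odds ratio for the >= 4-of-5 outcome.

Identical config and seed reproduce the tables byte for byte.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._dates import day_number, from_day_number
from .config import CONTROL_TYPES, SMI_DIAGNOSES, ScenarioConfig

__all__ = ["ClaimsTables", "generate_population", "generate_worked_fixture"]

_CONTROL_CODE = {
    "hba1c": "HBA1C",
    "lipid_profile": "LIPID_PANEL",
    "serum_creatinine": "CREATININE",
    "urine_albumin": "URINE_ALB",
    "eye_exam": "EYE_EXAM",
}

#: relative day offsets of the standard pre-index prevalent-user chain
#: (four 30-DDD packs whose coverage ends exactly at the index date)
_CHAIN_OFFSETS = (-120, -90, -60, -30)

TABLE_NAMES = (
    "patients",
    "dispensations",
    "hospital_stays",
    "outpatient_services",
    "mental_health_records",
)


@dataclass
class ClaimsTables:
    """Bundle of the five registry-style tables plus provenance."""

    patients: pd.DataFrame
    dispensations: pd.DataFrame
    hospital_stays: pd.DataFrame
    outpatient_services: pd.DataFrame
    mental_health_records: pd.DataFrame
    config: ScenarioConfig | None = None
    truth: pd.DataFrame | None = None  # latent per-patient ground truth

    def manifest(self) -> dict:
        import hashlib

        m: dict = {"seed": self.config.seed if self.config else None}
        if self.config is not None:
            canon = json.dumps(self.config.to_dict(), sort_keys=True, default=str)
            m["config_hash"] = hashlib.sha256(canon.encode()).hexdigest()[:16]
        m["rows"] = {name: int(len(getattr(self, name))) for name in TABLE_NAMES}
        return m

    def write_csv(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in TABLE_NAMES:
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
        if self.config is not None:
            with open(outdir / "scenario.json", "w") as fh:
                json.dump(self.config.to_dict(), fh, indent=2, sort_keys=True, default=str)

    @classmethod
    def read_csv(cls, indir) -> "ClaimsTables":
        indir = Path(indir)
        kw = {}
        date_cols = {
            "patients": ["birth_date", "residency_start", "death_date", "emigration_date"],
            "dispensations": ["date"],
            "hospital_stays": ["admission_date", "discharge_date"],
            "outpatient_services": ["date"],
            "mental_health_records": ["episode_open", "episode_close"],
        }
        for name in TABLE_NAMES:
            df = pd.read_csv(indir / f"{name}.csv")
            for col in date_cols[name]:
                if col in df.columns:
                    df[col] = pd.to_datetime(df[col])
            kw[name] = df
        return cls(**kw)


def _ragged_dates(rng, counts: np.ndarray, lo: int, hi: int, base_day: int):
    """Repeat patient indices by ``counts`` and draw a uniform day in
    [lo, hi) for each event."""
    total = int(counts.sum())
    owner = np.repeat(np.arange(len(counts)), counts)
    days = base_day + rng.integers(lo, hi, size=total)
    return owner, days


def generate_population(config: ScenarioConfig) -> ClaimsTables:
    """Generate one scenario.  See the module docstring for the model.

    Structural features independent of the headline parameters: 0.5% of
    patients are minors at the index date, 0.5% have under two years of
    residency, 2% lack a qualifying pre-index chain (two dispensations
    only), and 1% of unexposed patients carry a closed historical
    mental-health episode (excluded from the comparator pool without
    being exposed).  These exercise every exclusion path of the
    eligibility screen.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    idx_day = int(day_number(pd.Timestamp(config.index_date)))

    pid = np.array([f"P{i:07d}" for i in range(n)], dtype=object)
    female = rng.random(n) < 0.55
    gender = np.where(female, "F", "M")
    age = np.clip(rng.normal(65.0, 12.0, size=n), 30.0, 95.0)
    minor = rng.random(n) < 0.005
    age = np.where(minor, rng.uniform(8.0, 17.5, size=n), age)
    birth_day = idx_day - np.round(age * 365.25).astype(np.int64)

    residency_day = idx_day - np.round(rng.uniform(3.0, 20.0, size=n) * 365.25).astype(np.int64)
    short_res = rng.random(n) < 0.005
    residency_day = np.where(
        short_res, idx_day - rng.integers(100, 600, size=n), residency_day
    )

    gone = rng.random(n) < config.death_emigration_prob
    gone_day = idx_day + rng.integers(10, 360, size=n)
    death = gone & (rng.random(n) < 0.5)
    emig = gone & ~death

    drug_class = rng.choice(
        list(config.drug_class_mix), size=n, p=list(config.drug_class_mix.values())
    )

    # ---- pre-index events (these define contact volume) ------------------
    non_prevalent = rng.random(n) < 0.02
    chain_n = np.where(non_prevalent, 2, 4)
    chain_owner = np.repeat(np.arange(n), chain_n)
    # keep the last packs of the chain so coverage ends at the index
    offs = np.array(_CHAIN_OFFSETS, dtype=np.int64)
    chain_off = np.concatenate(
        [offs[4 - c:] for c in chain_n]
    ) if n else np.array([], dtype=np.int64)
    chain_days = idx_day + chain_off

    n_visits = rng.negative_binomial(3, 3 / 27, size=n)  # mean ~24 over 2 years
    visit_owner, visit_days = _ragged_dates(rng, n_visits, -730, 0, idx_day)

    n_preadm = rng.poisson(2 * config.hospital_rate, size=n)
    preadm_owner, preadm_days = _ragged_dates(rng, n_preadm, -720, -10, idx_day)
    preadm_len = rng.integers(3, 11, size=len(preadm_days))

    n_postadm = rng.poisson(config.hospital_rate, size=n)
    postadm_owner, postadm_days = _ragged_dates(rng, n_postadm, 0, 356, idx_day)
    postadm_len = rng.integers(2, 8, size=len(postadm_days))

    # cotreatments depend on demographics only (so any association with
    # exposure flows through the shared confounders, as in real claims)
    z_age = (age - 65.0) / 10.0
    p_nsaid = _sigmoid(_logit(0.25) + 0.15 * z_age + 0.2 * female)
    has_nsaid = rng.random(n) < p_nsaid
    nsaid_days = idx_day + rng.integers(-700, -10, size=n)
    p_thromb = _sigmoid(_logit(0.30) + 0.3 * z_age)
    has_thromb = rng.random(n) < p_thromb
    thromb_days = idx_day + rng.integers(-700, -10, size=n)

    n_contacts = (
        np.asarray(chain_n)
        + np.bincount(visit_owner, minlength=n)
        + np.bincount(preadm_owner, minlength=n)
        + has_nsaid.astype(int)
        + has_thromb.astype(int)
    )

    # ---- exposure and latent adherence ----------------------------------
    z_fem = female - 0.55
    z_con = np.log1p(n_contacts) - np.log1p(24)
    eff = config.confounder_effects
    lin_conf = (
        eff.get("gender_female", 0.0) * z_fem
        + eff.get("age_per_decade", 0.0) * z_age
        + eff.get("log_contacts", 0.0) * z_con
    )
    p_smi = _sigmoid(_logit(config.smi_prevalence) + lin_conf)
    exposed = (rng.random(n) < p_smi) & ~minor
    diagnosis = rng.choice(
        np.array(SMI_DIAGNOSES, dtype=object), size=n, p=[0.45, 0.20, 0.20, 0.15]
    )
    episode_open_day = idx_day - rng.integers(365, 3650, size=n)
    closed_history = (~exposed) & (rng.random(n) < 0.01)
    closed_open_day = idx_day - rng.integers(1500, 3650, size=n)
    closed_close_day = idx_day - rng.integers(200, 1400, size=n)

    p_high = _sigmoid(
        _logit(config.baseline_high_adherence_prob)
        + config.true_log_or * exposed
        + lin_conf
    )
    high = rng.random(n) < p_high
    frac = np.where(
        high,
        0.75 + 0.25 * rng.beta(2.0, 2.0, size=n),
        0.74 * rng.beta(1.3, 1.3, size=n),
    )
    packs = np.where(
        high,
        np.clip(np.ceil(frac * 365 / 30), 10, 13),
        np.clip(np.floor(frac * 365 / 30), 0, 9),
    ).astype(np.int64)
    # hospital days inside an uncovered stretch are bridged (counted as
    # covered) downstream; shrink the pack count of latent "not high"
    # patients where bridging would push measured PDC over 75%, so the
    # realised outcome always expresses the latent draw.
    stays_of: dict[int, list[tuple[int, int]]] = {}
    for o, a, ln in zip(postadm_owner, postadm_days - idx_day, postadm_len):
        stays_of.setdefault(int(o), []).append((max(int(a), 0), min(int(a + ln), 365)))
    for i, ivs in stays_of.items():
        if high[i] or packs[i] == 0:
            continue
        k = int(packs[i])
        while k > 0 and _union_days([(0, min(30 * k, 365))] + ivs) * 100 >= 75 * 365:
            k -= 1
        packs[i] = k
    fu_owner = np.repeat(np.arange(n), packs)
    fu_index = np.arange(len(fu_owner)) - np.repeat(np.cumsum(packs) - packs, packs)
    fu_days = idx_day + 30 * fu_index

    # ---- clinical controls for GLUCOSE patients --------------------------
    diabetic = drug_class == "GLUCOSE"
    p_highc = _sigmoid(
        _logit(config.baseline_high_controls_prob)
        + config.effective_control_log_or * exposed
        + lin_conf
    )
    highc = (rng.random(n) < p_highc) & diabetic
    n_sat = np.where(
        highc,
        rng.choice([4, 5], size=n, p=[0.6, 0.4]),
        rng.choice([0, 1, 2, 3], size=n, p=[0.15, 0.25, 0.30, 0.30]),
    )
    n_sat = np.where(diabetic, n_sat, 0)
    # which of the five controls are satisfied: the n_sat lowest ranks
    ranks = rng.random((n, 5)).argsort(axis=1).argsort(axis=1)
    satisfied = ranks < n_sat[:, None]
    base_counts = np.array([2, 1, 1, 1, 1])[None, :]
    extra = rng.poisson(0.4, size=(n, 5))
    miss_hba1c = rng.integers(0, 2, size=n)  # 0 or 1 assay when unsatisfied
    counts = np.where(satisfied, base_counts + extra, 0)
    counts[:, 0] = np.where(satisfied[:, 0], counts[:, 0], miss_hba1c)
    counts = np.where(diabetic[:, None], counts, 0)

    ctl_owner_list, ctl_code_list, ctl_day_list = [], [], []
    for j, ctype in enumerate(CONTROL_TYPES):
        owner_j, days_j = _ragged_dates(rng, counts[:, j], 0, 365, idx_day)
        ctl_owner_list.append(owner_j)
        ctl_day_list.append(days_j)
        ctl_code_list.append(np.full(len(owner_j), _CONTROL_CODE[ctype], dtype=object))
    ctl_owner = np.concatenate(ctl_owner_list) if ctl_owner_list else np.array([], int)
    ctl_days = np.concatenate(ctl_day_list) if ctl_day_list else np.array([], int)
    ctl_codes = np.concatenate(ctl_code_list) if ctl_code_list else np.array([], object)

    mcs_score = rng.poisson(np.exp(0.7 + 0.25 * z_age + 0.10 * z_con))

    # ---- assemble tables --------------------------------------------------
    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "gender": gender,
            "birth_date": from_day_number(birth_day),
            "residency_start": from_day_number(residency_day),
            "death_date": pd.Series(from_day_number(gone_day)).where(death, pd.NaT),
            "emigration_date": pd.Series(from_day_number(gone_day)).where(emig, pd.NaT),
            "n_contacts": n_contacts,
            "mcs_score": mcs_score,
        }
    )

    disp_owner = np.concatenate(
        [
            chain_owner,
            fu_owner,
            np.arange(n)[has_nsaid],
            np.arange(n)[has_thromb],
        ]
    )
    disp_days = np.concatenate(
        [chain_days, fu_days, nsaid_days[has_nsaid], thromb_days[has_thromb]]
    )
    disp_class = np.concatenate(
        [
            drug_class[chain_owner],
            drug_class[fu_owner],
            np.full(int(has_nsaid.sum()), "NSAID", dtype=object),
            np.full(int(has_thromb.sum()), "ANTITHROMBOTIC", dtype=object),
        ]
    )
    dispensations = pd.DataFrame(
        {
            "patient_id": pid[disp_owner],
            "date": from_day_number(disp_days),
            "drug_class": disp_class,
            "amount_ddd": 30.0,
        }
    ).sort_values(["patient_id", "drug_class", "date"], kind="mergesort").reset_index(drop=True)

    hosp_owner = np.concatenate([preadm_owner, postadm_owner])
    hosp_adm = np.concatenate([preadm_days, postadm_days])
    hosp_len = np.concatenate([preadm_len, postadm_len])
    hosp_dx = np.where(
        rng.random(len(hosp_owner)) < 0.3, "CVD", "OTHER"
    ).astype(object)
    hospital_stays = pd.DataFrame(
        {
            "patient_id": pid[hosp_owner],
            "admission_date": from_day_number(hosp_adm),
            "discharge_date": from_day_number(hosp_adm + hosp_len),
            "diagnosis_code": hosp_dx,
        }
    ).sort_values(["patient_id", "admission_date"], kind="mergesort").reset_index(drop=True)

    svc_owner = np.concatenate([visit_owner, ctl_owner])
    svc_days = np.concatenate([visit_days, ctl_days])
    svc_codes = np.concatenate(
        [np.full(len(visit_owner), "GENERIC_VISIT", dtype=object), ctl_codes]
    )
    outpatient_services = pd.DataFrame(
        {
            "patient_id": pid[svc_owner],
            "date": from_day_number(svc_days),
            "service_code": svc_codes,
        }
    ).sort_values(["patient_id", "date", "service_code"], kind="mergesort").reset_index(drop=True)

    mh_rows = []
    for i in np.flatnonzero(exposed):
        mh_rows.append(
            (pid[i], diagnosis[i], from_day_number(episode_open_day[i]), pd.NaT)
        )
    for i in np.flatnonzero(closed_history):
        mh_rows.append(
            (
                pid[i],
                diagnosis[i],
                from_day_number(closed_open_day[i]),
                from_day_number(closed_close_day[i]),
            )
        )
    mental_health_records = pd.DataFrame(
        mh_rows, columns=["patient_id", "diagnosis", "episode_open", "episode_close"]
    ).sort_values(["patient_id", "episode_open"], kind="mergesort").reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "patient_id": pid,
            "exposed": exposed,
            "latent_high_adherence": high,
            "target_fraction": frac,
            "latent_high_controls": highc,
            "drug_class": drug_class,
        }
    )
    return ClaimsTables(
        patients=patients,
        dispensations=dispensations,
        hospital_stays=hospital_stays,
        outpatient_services=outpatient_services,
        mental_health_records=mental_health_records,
        config=config,
        truth=truth,
    )


def _union_days(intervals: list[tuple[int, int]]) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(i for i in intervals if i[1] > i[0]):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        elif e > cur_e:
            cur_e = e
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# Worked fixture
# ---------------------------------------------------------------------------

def generate_worked_fixture() -> ClaimsTables:
    """A fixed, hand-checkable 20-patient bundle (index 2017-01-01).

    Documented facts (verified in the test suite):

    * Eligibility (BP class): 20 in, 3 out - P17 aged 17, P19 under two
      years of residency, P18 dies 200 days post-index - 17 retained.
    * Exposure: P01 depression, P02 bipolar disorder (concurrent open
      depression episode resolved by severity), P03 schizophrenia,
      P04 personality disorder; P20's depression episode closed
      2016-06-30, so P20 is unexposed but barred from the pool.
    * Matching (ratio 3, age +/-1, no contact constraint): P01 gets
      {P05, P06, P07} (P08 is 2 years older); P02 gets {P09, P10}
      (a 1+2 set); P03 gets 3 of {P11..P14}; P04 has no eligible
      comparator and is dropped.
    * Follow-up PDC (365-day window): P05 = 1.0 (full-year coverage);
      P06 = 200/365 (intermediate); P07 = 180/365 after bridging a
      30-day stay inside an uncovered stretch; P01 = 270/365 (not
      high); P09's day-91 dispensation opens a second era (gap 61 >
      60); P10's stream (days 0, 25, 100) stays one era with covered
      days 90.
    * Diabetes controls: P06 has 2 HbA1c + 1 lipid + 1 creatinine,
      nothing else -> 3 of 5 satisfied: high at the 3-of-5 sensitivity
      rule only.
    * Exposure-only conditional fit on the high-PDC outcome has two
      informative sets and the closed-form maximum OR = sqrt(6).
    """
    index = pd.Timestamp("2017-01-01")

    def d(days: int) -> pd.Timestamp:
        return index + pd.Timedelta(days=days)

    genders = {
        "P01": "F", "P02": "M", "P03": "F", "P04": "M",
        "P05": "F", "P06": "F", "P07": "F", "P08": "F",
        "P09": "M", "P10": "M", "P11": "F", "P12": "F",
        "P13": "F", "P14": "F", "P15": "M", "P16": "F",
        "P17": "F", "P18": "M", "P19": "F", "P20": "M",
    }
    ages = {
        "P01": 65, "P02": 70, "P03": 50, "P04": 40,
        "P05": 64, "P06": 65, "P07": 66, "P08": 67,
        "P09": 70, "P10": 71, "P11": 50, "P12": 50,
        "P13": 51, "P14": 49, "P15": 30, "P16": 40,
        "P17": 17, "P18": 65, "P19": 60, "P20": 55,
    }
    mcs = {p: s for p, s in zip(sorted(genders), [3, 1, 0, 2, 1, 4, 0, 1, 2, 0,
                                                  1, 1, 0, 2, 0, 1, 0, 3, 1, 2])}
    patients = pd.DataFrame(
        {
            "patient_id": sorted(genders),
            "gender": [genders[p] for p in sorted(genders)],
            # mid-year birthday so floor(age) is unambiguous at the index
            "birth_date": [index - pd.Timedelta(days=round((ages[p] + 0.5) * 365.25))
                           for p in sorted(genders)],
            "residency_start": [
                pd.Timestamp("2016-01-01") if p == "P19" else pd.Timestamp("2005-01-01")
                for p in sorted(genders)
            ],
            "death_date": [d(200) if p == "P18" else pd.NaT for p in sorted(genders)],
            "emigration_date": [pd.NaT] * 20,
            "mcs_score": [mcs[p] for p in sorted(genders)],
        }
    )

    disp_rows: list[tuple] = []

    def chain(pidd, cls="BP"):
        for off in _CHAIN_OFFSETS:
            disp_rows.append((pidd, d(off), cls, 30.0))

    def packs(pidd, k, cls="BP", start=0, step=30, amount=30.0):
        for j in range(k):
            disp_rows.append((pidd, d(start + step * j), cls, amount))

    for p in sorted(genders):
        chain(p)
    followup_packs = {
        "P01": 9, "P02": 10, "P03": 11, "P04": 10,
        "P05": 13, "P08": 10, "P11": 11, "P12": 11, "P13": 11, "P14": 11,
        "P15": 10, "P16": 10, "P17": 5, "P18": 5, "P19": 5, "P20": 10,
    }
    for p, k in followup_packs.items():
        packs(p, k)
    # P06: 200 covered days (6 x 30 + one 20-DDD pack)
    packs("P06", 6)
    disp_rows.append(("P06", d(180), "BP", 20.0))
    # P07: 150 covered days, stay bridged below adds 30
    packs("P07", 5)
    # P09: second era opened by a 61-day gap after day-0 pack
    disp_rows.append(("P09", d(0), "BP", 30.0))
    disp_rows.append(("P09", d(91), "BP", 30.0))
    # P10: stockpiled refill at day 25 then a 40-day gap
    for off in (0, 25, 100):
        disp_rows.append(("P10", d(off), "BP", 30.0))
    # P06 is also a prevalent glucose user (diabetic)
    chain("P06", "GLUCOSE")
    packs("P06", 10, cls="GLUCOSE")
    # covariate examples: NSAID in lookback for P01, stale NSAID for P05
    disp_rows.append(("P01", d(-100), "NSAID", 10.0))
    disp_rows.append(("P05", d(-1100), "NSAID", 10.0))

    dispensations = pd.DataFrame(
        disp_rows, columns=["patient_id", "date", "drug_class", "amount_ddd"]
    ).sort_values(["patient_id", "drug_class", "date"], kind="mergesort").reset_index(drop=True)

    hospital_stays = pd.DataFrame(
        [
            ("P07", d(200), d(230), "OTHER"),   # 30 days inside P07's uncovered stretch
            ("P02", pd.Timestamp("2016-03-01"), pd.Timestamp("2016-03-06"), "CVD"),
        ],
        columns=["patient_id", "admission_date", "discharge_date", "diagnosis_code"],
    )

    outpatient_services = pd.DataFrame(
        [
            ("P06", d(50), "HBA1C"),
            ("P06", d(200), "HBA1C"),
            ("P06", d(80), "LIPID_PANEL"),
            ("P06", d(120), "CREATININE"),
            ("P06", d(40), "GENERIC_VISIT"),
        ],
        columns=["patient_id", "date", "service_code"],
    )

    mental_health_records = pd.DataFrame(
        [
            ("P01", "depression", pd.Timestamp("2015-03-01"), pd.NaT),
            ("P02", "bipolar disorder", pd.Timestamp("2014-05-01"), pd.NaT),
            ("P02", "depression", pd.Timestamp("2016-02-01"), pd.NaT),
            ("P03", "schizophrenia", pd.Timestamp("2010-01-01"), pd.NaT),
            ("P04", "personality disorder", pd.Timestamp("2016-09-01"), pd.NaT),
            ("P20", "depression", pd.Timestamp("2014-01-01"), pd.Timestamp("2016-06-30")),
        ],
        columns=["patient_id", "diagnosis", "episode_open", "episode_close"],
    )

    patients["n_contacts"] = _fixture_contacts(
        patients, dispensations, hospital_stays, outpatient_services, index
    )
    return ClaimsTables(
        patients=patients,
        dispensations=dispensations,
        hospital_stays=hospital_stays,
        outpatient_services=outpatient_services,
        mental_health_records=mental_health_records,
        config=None,
        truth=None,
    )


def _fixture_contacts(patients, dispensations, hospital_stays, outpatient_services, index):
    """Hand-rule contact counts for the fixture: pre-index events in the
    two-year lookback (same rule the cohort builder re-derives)."""
    lo = index - pd.Timedelta(days=730)
    cnt = pd.Series(0, index=patients["patient_id"])
    for df, col in (
        (dispensations, "date"),
        (hospital_stays, "admission_date"),
        (outpatient_services, "date"),
    ):
        dts = pd.to_datetime(df[col])
        sel = df[(dts >= lo) & (dts < index)]
        cnt = cnt.add(sel.groupby("patient_id").size(), fill_value=0)
    return cnt.astype(int).to_numpy()
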