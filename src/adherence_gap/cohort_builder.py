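"""Cohort eligibility, exposure ascertainment, 1:M matching, covariates
and balance diagnostics.

Eligibility at the index date requires adult age, at least two years of
residency, prevalent use of the drug class (a chain of >= 3
dispensations in the two pre-index years) and at least one year of
post-index observation (no death or emigration during follow-up).
Exposure is an open care episode for one of the four severe mental
disorders at the index date.  For each exposed patient up to
``ratio`` comparators are sampled without replacement from unexposed
patients with no mental-health record, matched on gender, age at index
(+/- 1 year) and contact volume with the health service over the two
pre-index years.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dates import day_number
from .config import (
    CovariateConfig,
    EraConfig,
    MatchingConfig,
    SEVERITY_ORDER,
    SMI_DIAGNOSES,
)
from .drug_eras import prevalent_users
from .exceptions import AnalysisError, ConfigurationError

logger = logging.getLogger(__name__)

_SEVERITY_RANK = {d: i for i, d in enumerate(SEVERITY_ORDER)}


@dataclass
class EligibleCohort:
    """Eligible patients of one drug class plus the exclusion ledger."""

    drug_class: str
    patients: pd.DataFrame  # patient_id, gender, age_at_index, n_contacts, exposed, ...
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return self.exclusions.get("input", len(self.patients))

    def reconciles(self) -> bool:
        removed = sum(v for k, v in self.exclusions.items() if k not in ("input", "retained"))
        return self.n_input == removed + len(self.patients)


@dataclass
class MatchResult:
    """Matched sets in long format plus matching bookkeeping."""

    sets: pd.DataFrame  # set_id, patient_id, exposed
    n_exposed_unmatched: int
    seed: int


def count_contacts(tables, index_date, lookback_days: int = 730) -> pd.Series:
    """Contacts with the health service per patient over the lookback:
    drug dispensations + hospital admissions + out-patient services."""
    idx = day_number(index_date)
    lo = idx - lookback_days
    total: pd.Series | None = None
    for df, col in (
        (tables.dispensations, "date"),
        (tables.hospital_stays, "admission_date"),
        (tables.outpatient_services, "date"),
    ):
        if df is None or len(df) == 0:
            continue
        days = day_number(df[col])
        mask = (days >= lo) & (days < idx)
        cnt = df.loc[mask].groupby("patient_id").size()
        total = cnt if total is None else total.add(cnt, fill_value=0)
    if total is None:
        total = pd.Series(dtype="int64")
    return total.astype("int64")


def ascertain_exposure(mh_records: pd.DataFrame, index_date) -> tuple[bool, str | None]:
    """Exposure status of one patient: an episode for one of the four
    severe mental disorders open at the index date (opened on or before
    it, not yet closed).  Concurrent open episodes are resolved by
    severity: schizophrenia > bipolar > personality disorder >
    depression."""
    if len(mh_records) == 0:
        return False, None
    idx = pd.Timestamp(index_date)
    opened = pd.to_datetime(mh_records["episode_open"]) <= idx
    closes = pd.to_datetime(mh_records["episode_close"])
    still_open = closes.isna() | (closes > idx)
    active = mh_records[opened & still_open]
    active = active[active["diagnosis"].isin(SMI_DIAGNOSES)]
    if len(active) == 0:
        return False, None
    best = min(active["diagnosis"], key=_SEVERITY_RANK.__getitem__)
    return True, best


def exposure_table(mh_records: pd.DataFrame, index_date) -> pd.DataFrame:
    """Vectorised exposure ascertainment: one row per patient appearing
    in the registry, with ``exposed``, ``diagnosis_category`` and
    ``has_mh_record`` (any registry record at all, used to restrict the
    comparator pool)."""
    if len(mh_records) == 0:
        return pd.DataFrame(
            columns=["patient_id", "exposed", "diagnosis_category", "has_mh_record"]
        )
    idx = pd.Timestamp(index_date)
    df = mh_records.copy()
    df["episode_open"] = pd.to_datetime(df["episode_open"])
    df["episode_close"] = pd.to_datetime(df["episode_close"])
    active = (
        (df["episode_open"] <= idx)
        & (df["episode_close"].isna() | (df["episode_close"] > idx))
        & df["diagnosis"].isin(SMI_DIAGNOSES)
    )
    act = df[active].copy()
    act["rank"] = act["diagnosis"].map(_SEVERITY_RANK)
    act = act.sort_values(["patient_id", "rank"]).drop_duplicates("patient_id")
    out = pd.DataFrame({"patient_id": df["patient_id"].unique()})
    out = out.merge(
        act[["patient_id", "diagnosis"]].rename(columns={"diagnosis": "diagnosis_category"}),
        on="patient_id",
        how="left",
    )
    out["exposed"] = out["diagnosis_category"].notna()
    out["has_mh_record"] = True
    return out[["patient_id", "exposed", "diagnosis_category", "has_mh_record"]]


def apply_eligibility(
    tables,
    index_date,
    drug_class: str,
    era: EraConfig | None = None,
    followup_days: int = 365,
    min_age: int = 18,
    residency_days: int = 730,
) -> EligibleCohort:
    """Sequential eligibility screen for one drug class, with a
    flow-chart-style ledger counting removals at each criterion (each
    record is charged to the first criterion it fails)."""
    era = era or EraConfig()
    pts = tables.patients
    idx_day = day_number(index_date)
    idx_ts = pd.Timestamp(index_date)

    ledger: dict[str, int] = {"input": len(pts)}
    remaining = np.ones(len(pts), dtype=bool)

    birth = pd.to_datetime(pts["birth_date"])
    ok = birth.notna().to_numpy()
    ledger["missing_birth_date"] = int((remaining & ~ok).sum())
    remaining &= ok

    age = np.floor((idx_day - day_number(birth.fillna(idx_ts))) / 365.25)
    ok = age >= min_age
    ledger["age_under_18"] = int((remaining & ~ok).sum())
    remaining &= ok

    res = day_number(pd.to_datetime(pts["residency_start"]))
    ok = res <= idx_day - residency_days
    ledger["residency_under_2y"] = int((remaining & ~ok).sum())
    remaining &= ok

    disp = tables.dispensations
    cls_disp = disp[(disp["drug_class"] == drug_class)]
    cls_disp = cls_disp[pd.to_datetime(cls_disp["date"]) < idx_ts]
    prev = prevalent_users(
        cls_disp,
        index_date,
        gap_days=era.gap_days,
        lookback_days=era.lookback_days,
        min_dispensations=era.min_dispensations,
        require_active_at_index=era.require_active_at_index,
    )
    ok = pts["patient_id"].isin(prev).to_numpy()
    ledger["not_prevalent_user"] = int((remaining & ~ok).sum())
    remaining &= ok

    end_day = idx_day + followup_days
    gone = np.zeros(len(pts), dtype=bool)
    for col in ("death_date", "emigration_date"):
        d = pd.to_datetime(pts[col])
        gone |= (d.notna() & (day_number(d.fillna(idx_ts)) < end_day)).to_numpy()
    ledger["death_or_emigration_in_followup"] = int((remaining & gone).sum())
    remaining &= ~gone

    elig = pts.loc[remaining, ["patient_id", "gender"]].copy()
    elig["age_at_index"] = age[remaining].astype(int)
    contacts = count_contacts(tables, index_date, lookback_days=residency_days)
    elig["n_contacts"] = (
        contacts.reindex(elig["patient_id"]).fillna(0).astype("int64").to_numpy()
    )
    expo = exposure_table(tables.mental_health_records, index_date)
    elig = elig.merge(expo, on="patient_id", how="left")
    elig["exposed"] = elig["exposed"].eq(True)
    elig["has_mh_record"] = elig["has_mh_record"].eq(True)
    ledger["retained"] = len(elig)
    for crit, n in ledger.items():
        if crit not in ("input", "retained") and n:
            logger.info("%s: excluded %d on %s", drug_class, n, crit)
    return EligibleCohort(drug_class=drug_class, patients=elig.reset_index(drop=True), exclusions=ledger)


def _contact_bins(pool_contacts: np.ndarray, contacts: np.ndarray) -> np.ndarray:
    """Decile bin of each contact count w.r.t. the pool distribution."""
    edges = np.quantile(pool_contacts, np.arange(0.1, 1.0, 0.1))
    return np.searchsorted(edges, contacts, side="right")


def match_comparators(
    eligible: pd.DataFrame,
    ratio: int = 3,
    seed: int = 0,
    *,
    age_tolerance_years: int = 1,
    contact_binning: str = "decile",
    contact_caliper: float | None = None,
) -> MatchResult:
    """Sample up to ``ratio`` comparators per exposed patient without
    replacement, matched on gender, age at index (within the tolerance)
    and contact volume (same pool decile by default).

    Exposed patients are processed in seeded random order; those with
    no eligible comparator are dropped and logged.  Identical inputs
    and seed reproduce identical sets.
    """
    cfg = MatchingConfig(
        ratio=ratio,
        age_tolerance_years=age_tolerance_years,
        contact_binning=contact_binning,
        contact_caliper=contact_caliper,
    )
    cfg.validate()
    rng = np.random.default_rng(seed)

    exposed = eligible[eligible["exposed"]]
    has_mh = (
        eligible["has_mh_record"]
        if "has_mh_record" in eligible.columns
        else eligible["exposed"]
    )
    pool = eligible[~eligible["exposed"] & ~has_mh]

    if contact_binning == "decile" and len(pool):
        pool_bins = _contact_bins(
            pool["n_contacts"].to_numpy(), pool["n_contacts"].to_numpy()
        )
        exp_bins = _contact_bins(
            pool["n_contacts"].to_numpy(), exposed["n_contacts"].to_numpy()
        )
    else:
        pool_bins = np.zeros(len(pool), dtype=int)
        exp_bins = np.zeros(len(exposed), dtype=int)

    # cells keyed by (gender, bin, age year); membership as sets so
    # removal after sampling is O(1), sampling over a sorted snapshot
    # keeps the draw deterministic.
    cells: dict[tuple, set] = {}
    contacts_of: dict = {}
    for (pid, g, a, c), b in zip(
        pool[["patient_id", "gender", "age_at_index", "n_contacts"]].itertuples(
            index=False, name=None
        ),
        pool_bins,
    ):
        cells.setdefault((g, b, a), set()).add(pid)
        contacts_of[pid] = c

    exp_rows = exposed[["patient_id", "gender", "age_at_index", "n_contacts"]].to_numpy(
        dtype=object
    )
    order = rng.permutation(len(exp_rows))

    records = []
    n_unmatched = 0
    set_id = 0
    for i in order:
        pid, g, a, c = exp_rows[i]
        b = exp_bins[i]
        cand: list = []
        for da in range(-cfg.age_tolerance_years, cfg.age_tolerance_years + 1):
            cand.extend(cells.get((g, b, a + da), ()))
        if contact_binning == "caliper":
            cand = [q for q in cand if abs(contacts_of[q] - c) <= contact_caliper]
        if not cand:
            n_unmatched += 1
            logger.info("no eligible comparator for exposed patient %s", pid)
            continue
        cand_arr = np.array(sorted(cand), dtype=object)
        take = min(cfg.ratio, len(cand_arr))
        chosen = rng.choice(cand_arr, size=take, replace=False)
        records.append((set_id, pid, True))
        for q in chosen:
            records.append((set_id, q, False))
            # remove from whichever age cell it lives in
            for da in range(-cfg.age_tolerance_years, cfg.age_tolerance_years + 1):
                cell = cells.get((g, b, a + da))
                if cell and q in cell:
                    cell.discard(q)
                    break
        set_id += 1

    sets = pd.DataFrame(records, columns=["set_id", "patient_id", "exposed"])
    if n_unmatched:
        logger.info("dropped %d exposed patients with no eligible comparator", n_unmatched)
    return MatchResult(sets=sets, n_exposed_unmatched=n_unmatched, seed=seed)


def standardized_difference(values_exposed, values_reference, kind: str = "continuous") -> float:
    """Absolute standardised difference between two groups.

    binary:     |p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2)
    continuous: |m1 - m2| / sqrt((s1^2 + s2^2) / 2)

    Differences below 0.10 are conventionally negligible.  A zero
    pooled variance with unequal means is flagged as infinite.
    """
    x1 = np.asarray(values_exposed, dtype=float)
    x2 = np.asarray(values_reference, dtype=float)
    if len(x1) == 0 or len(x2) == 0:
        raise AnalysisError("standardized_difference requires non-empty groups")
    if kind == "binary":
        p1, p2 = x1.mean(), x2.mean()
        pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
        diff = abs(p1 - p2)
    elif kind == "continuous":
        pooled = (x1.var(ddof=1) + x2.var(ddof=1)) / 2.0 if (len(x1) > 1 or len(x2) > 1) else 0.0
        diff = abs(x1.mean() - x2.mean())
    else:
        raise ConfigurationError(f"unknown kind {kind!r}")
    if pooled <= 0:
        if diff == 0:
            return 0.0
        logger.warning("zero pooled variance with unequal means; ASD set to inf")
        return float("inf")
    return float(diff / np.sqrt(pooled))


def derive_covariates(
    tables,
    index_date,
    config: CovariateConfig | None = None,
    patient_ids=None,
) -> pd.DataFrame:
    """Baseline covariate flags over the pre-index lookback plus the
    binned comorbidity-score category.

    Each configured codelist raises a boolean flag when the patient has
    at least one matching record dated within the lookback window.  The
    supplied numeric Multisource Comorbidity Score is binned at the
    configured cut-points into ``mcs_category`` (a score exactly at a
    cut-point falls in the lower category).
    """
    config = config or CovariateConfig()
    config.validate()
    idx = day_number(index_date)
    lo = idx - config.lookback_days

    if patient_ids is None:
        patient_ids = tables.patients["patient_id"]
    out = pd.DataFrame({"patient_id": np.asarray(patient_ids)})

    date_col = {"dispensations": "date", "hospital_stays": "admission_date",
                "outpatient_services": "date"}
    for name, spec in config.codelists.items():
        table = getattr(tables, spec["table"], None)
        if table is None:
            raise ConfigurationError(f"codelist {name!r} references unknown table {spec['table']!r}")
        if len(table) == 0:
            out[name] = False
            continue
        days = day_number(table[date_col[spec["table"]]])
        mask = (
            (days >= lo)
            & (days < idx)
            & table[spec["column"]].isin(spec["codes"]).to_numpy()
        )
        flagged = set(table.loc[mask, "patient_id"])
        out[name] = out["patient_id"].isin(flagged)

    if "mcs_score" in tables.patients.columns:
        scores = (
            tables.patients.set_index("patient_id")["mcs_score"]
            .reindex(out["patient_id"])
            .to_numpy(dtype=float)
        )
        cuts = np.asarray(config.mcs_cutpoints, dtype=float)
        # side='left': a score equal to a cut-point stays below it
        out["mcs_category"] = np.searchsorted(cuts, scores, side="left")
    return out


def balance_table(
    eligible: pd.DataFrame,
    sets: pd.DataFrame,
    covariate_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Pre- and post-matching absolute standardised differences for the
    matching variables (and any extra covariate columns), with a flag
    for residual imbalance at the 0.10 threshold."""
    elig = eligible.set_index("patient_id")
    exp_pre = elig[elig["exposed"]]
    has_mh = elig["has_mh_record"] if "has_mh_record" in elig.columns else elig["exposed"]
    ref_pre = elig[~elig["exposed"] & ~has_mh]

    merged = sets.merge(eligible, on="patient_id", how="left", suffixes=("", "_elig"))
    exp_post = merged[merged["exposed"]]
    ref_post = merged[~merged["exposed"]]

    specs = [("age_at_index", "continuous"), ("n_contacts", "continuous"),
             ("gender", "binary")]
    specs += [(c, "binary") for c in covariate_cols]
    rows = []
    for var, kind in specs:
        def col(df):
            v = df[var]
            return (v == "F").astype(float) if var == "gender" else v.astype(float)
        pre = standardized_difference(col(exp_pre), col(ref_pre), kind)
        post = standardized_difference(col(exp_post), col(ref_post), kind)
        rows.append((var, pre, post, post >= 0.10))
    return pd.DataFrame(rows, columns=["variable", "asd_pre", "asd_post", "imbalanced_post"])
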