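"""Follow-up adherence measurement.

Drug adherence is the proportion of days covered (PDC) over a fixed
365-day follow-up window starting at the index date: covered days are
the union of drug-coverage days (with refill stockpiling, including
supply dispensed before the window that spills into it) and hospital
days bridged under the immeasurable-time rule, intersected with the
window.  Hospital days are bridged - counted as covered - when the
patient's regimen for the class was observed before the admission,
because in-hospital dispensing is not recorded in claims.

PDC is categorised as very low (<=25%), low (26-50%), intermediate
(51-74%) and high (>=75%), with the integer-percent labels read as the
half-open intervals (0.25, 0.50], (0.50, 0.75) on the continuous scale.

Clinical-control adherence for people with diabetes scores the five
recommended annual controls (glycated haemoglobin, lipid profile,
serum creatinine, urine albumin excretion, dilated eye examination):
a control is satisfied with >= 2 HbA1c assays or >= 1 of each of the
others; "high" control adherence means >= 4 of 5 satisfied (>= 3 of 5
as a sensitivity definition).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dates import day_number
from .config import CONTROL_TYPES, DEFAULT_CONTROL_CODE_MAP
from .drug_eras import assign_eras, build_eras
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

PDC_CATEGORIES = ("very_low", "low", "intermediate", "high")


@dataclass(frozen=True)
class FollowUpWindow:
    """Half-open follow-up window ``[start, start + days)``."""

    start: pd.Timestamp
    days: int = 365

    def __post_init__(self):
        object.__setattr__(self, "start", pd.Timestamp(self.start))

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(days=self.days)

    @property
    def start_day(self) -> int:
        return day_number(self.start)

    @property
    def end_day(self) -> int:
        return self.start_day + self.days


@dataclass
class AdherenceResult:
    patient_id: object
    drug_class: object
    covered_days: int
    window_days: int
    pdc: float
    category: str
    high_at_70: bool
    high_at_75: bool
    high_at_80: bool


@dataclass
class ControlProfile:
    patient_id: object
    counts: dict[str, int]
    satisfied: dict[str, bool]
    n_satisfied: int
    high_controls_at_4: bool
    high_controls_at_3: bool


def categorize_pdc(pdc: float) -> str:
    """Map a PDC value in [0, 1] to its 4-level category."""
    if not (0.0 <= pdc <= 1.0) or not np.isfinite(pdc):
        raise ValidationError(f"pdc must lie in [0, 1], got {pdc!r}")
    if pdc >= 0.75:
        return "high"
    if pdc > 0.50:
        return "intermediate"
    if pdc > 0.25:
        return "low"
    return "very_low"


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of a union of half-open integer intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        elif e > cur_e:
            cur_e = e
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _validate_stays(adm: np.ndarray, dis: np.ndarray) -> None:
    if np.any(dis < adm):
        raise ValidationError("hospital discharge precedes admission")
    # plausibility bounds: years ~1900-2100 in day numbers
    if len(adm) and (adm.min() < -25567 or dis.max() > 47482):
        raise ValidationError("hospital interval outside plausible dates")


def _bridged_intervals(
    eras, stays: list[tuple[int, int]], window: FollowUpWindow, bridging: str
) -> list[tuple[int, int]]:
    """Hospital intervals eligible for bridging, clipped to the window."""
    out = []
    for adm, dis in stays:
        if bridging == "any_prior_era":
            ok = any(era.start_day < adm for era in eras)
        else:  # overlapping_era
            ok = any(era.start_day <= adm <= era.coverage_end_day for era in eras)
        if ok:
            s = max(adm, window.start_day)
            e = min(dis, window.end_day)
            if e > s:
                out.append((s, e))
    return out


def compute_pdc(
    dispensations: pd.DataFrame,
    window: FollowUpWindow,
    hospital_stays: pd.DataFrame | None = None,
    *,
    gap_days: int = 60,
    include_spillover: bool = True,
    bridging: str = "any_prior_era",
    thresholds: tuple[float, ...] = (0.70, 0.75, 0.80),
) -> AdherenceResult:
    """PDC of one patient for one drug class.

    ``dispensations`` may include a pre-window tail; with
    ``include_spillover`` (default) supply dispensed before the window
    that runs into it counts towards covered days.
    """
    df = dispensations
    if not include_spillover and len(df):
        df = df[pd.to_datetime(df["date"]) >= window.start]
    eras = build_eras(df.sort_values("date"), gap_days=gap_days) if len(df) else []

    intervals: list[tuple[int, int]] = []
    w0, w1 = window.start_day, window.end_day
    for era in eras:
        for s, e in era.coverage_segments:
            s2, e2 = max(s, w0), min(e, w1)
            if e2 > s2:
                intervals.append((s2, e2))

    if hospital_stays is not None and len(hospital_stays):
        adm = day_number(hospital_stays["admission_date"])
        dis = day_number(hospital_stays["discharge_date"])
        adm = np.atleast_1d(adm)
        dis = np.atleast_1d(dis)
        _validate_stays(adm, dis)
        intervals.extend(
            _bridged_intervals(eras, list(zip(adm, dis)), window, bridging)
        )

    covered = _union_length(intervals)
    pdc = covered / window.days
    pid = df["patient_id"].iloc[0] if len(df) and "patient_id" in df.columns else None
    cls = df["drug_class"].iloc[0] if len(df) and "drug_class" in df.columns else None
    flags = {f"high_at_{int(t * 100)}": covered * 100 >= t * 100 * window.days for t in thresholds}
    return AdherenceResult(
        patient_id=pid,
        drug_class=cls,
        covered_days=covered,
        window_days=window.days,
        pdc=pdc,
        category=categorize_pdc(pdc),
        high_at_70=flags.get("high_at_70", pdc >= 0.70),
        high_at_75=flags.get("high_at_75", pdc >= 0.75),
        high_at_80=flags.get("high_at_80", pdc >= 0.80),
    )


def pdc_table(
    dispensations: pd.DataFrame,
    window: FollowUpWindow,
    hospital_stays: pd.DataFrame | None = None,
    patient_ids=None,
    *,
    gap_days: int = 60,
    include_spillover: bool = True,
    bridging: str = "any_prior_era",
) -> pd.DataFrame:
    """Vectorised PDC for many patients on one drug class.

    Patients in ``patient_ids`` with no dispensations get PDC 0.
    Produces one row per patient with covered days, PDC, category and
    the 70/75/80% high-adherence flags.
    """
    w0, w1 = window.start_day, window.end_day
    df = dispensations
    if not include_spillover and len(df):
        df = df[pd.to_datetime(df["date"]) >= window.start]
    ann = assign_eras(df, gap_days=gap_days)
    if len(ann):
        ov = np.minimum(ann["seg_end_day"], w1) - np.maximum(ann["seg_start_day"], w0)
        ann = ann.assign(ov=np.maximum(ov, 0))
        covered = ann.groupby("patient_id", sort=False)["ov"].sum()
    else:
        covered = pd.Series(dtype="int64")

    # hospital bridging: only patients with an eligible stay need the
    # exact interval union; everyone else keeps the segment sum.
    if hospital_stays is not None and len(hospital_stays):
        adm_all = day_number(hospital_stays["admission_date"])
        dis_all = day_number(hospital_stays["discharge_date"])
        _validate_stays(np.atleast_1d(adm_all), np.atleast_1d(dis_all))
        stays = pd.DataFrame(
            {
                "patient_id": hospital_stays["patient_id"].to_numpy(),
                "adm": adm_all,
                "dis": dis_all,
            }
        )
        stays = stays[(stays["dis"] > w0) & (stays["adm"] < w1)]
        if len(stays) and len(ann):
            era_info = ann.groupby(["patient_id", "era_id"], sort=False).agg(
                era_start=("day", "min"), era_end=("seg_end_day", "max")
            )
            segs_by_pid = {
                pid: list(zip(g["seg_start_day"], g["seg_end_day"]))
                for pid, g in ann.groupby("patient_id", sort=False)
            }
            eras_by_pid = {
                pid: list(zip(g["era_start"], g["era_end"]))
                for pid, g in era_info.groupby(level=0, sort=False)
            }
            covered = covered.copy()
            for pid, g in stays.groupby("patient_id", sort=False):
                eras = eras_by_pid.get(pid)
                if not eras:
                    continue  # no prior regimen: stay cannot be bridged
                bridged = []
                for adm, dis in zip(g["adm"], g["dis"]):
                    if bridging == "any_prior_era":
                        ok = any(s < adm for s, _ in eras)
                    else:
                        ok = any(s <= adm <= e for s, e in eras)
                    if ok:
                        bridged.append((max(adm, w0), min(dis, w1)))
                if not bridged:
                    continue
                segs = [
                    (max(s, w0), min(e, w1))
                    for s, e in segs_by_pid.get(pid, [])
                ]
                covered.loc[pid] = _union_length(segs + bridged)

    if patient_ids is None:
        patient_ids = covered.index
    covered = covered.reindex(pd.Index(patient_ids), fill_value=0).astype("int64")
    pdc = covered / window.days
    cat = np.select(
        [pdc >= 0.75, pdc > 0.50, pdc > 0.25],
        ["high", "intermediate", "low"],
        default="very_low",
    )
    out = pd.DataFrame(
        {
            "patient_id": covered.index,
            "covered_days": covered.to_numpy(),
            "window_days": window.days,
            "pdc": pdc.to_numpy(),
            "category": cat,
        }
    )
    for t in (70, 75, 80):
        out[f"pdc_high_{t}"] = out["covered_days"] * 100 >= t * window.days
    return out.reset_index(drop=True)


def assess_clinical_controls(
    services: pd.DataFrame,
    window: FollowUpWindow,
    code_map: dict[str, str | None] | None = None,
    min_counts: dict[str, int] | None = None,
) -> ControlProfile:
    """Score the five diabetes clinical-control recommendations for one
    patient from their out-patient service records."""
    tab = controls_table(
        services,
        window,
        patient_ids=[services["patient_id"].iloc[0]] if len(services) else [None],
        code_map=code_map,
        min_counts=min_counts,
    )
    row = tab.iloc[0]
    return ControlProfile(
        patient_id=row["patient_id"],
        counts={c: int(row[f"n_{c}"]) for c in CONTROL_TYPES},
        satisfied={c: bool(row[f"sat_{c}"]) for c in CONTROL_TYPES},
        n_satisfied=int(row["n_satisfied"]),
        high_controls_at_4=bool(row["controls_high_4"]),
        high_controls_at_3=bool(row["controls_high_3"]),
    )


def controls_table(
    services: pd.DataFrame,
    window: FollowUpWindow,
    patient_ids=None,
    code_map: dict[str, str | None] | None = None,
    min_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-patient control counts, satisfied flags and the 4-of-5 /
    3-of-5 high-control-adherence outcomes.

    Service codes that map to ``None`` in ``code_map`` are recognised
    non-control services and skipped silently; codes absent from the
    map are skipped with a logged warning.
    """
    code_map = dict(DEFAULT_CONTROL_CODE_MAP) if code_map is None else code_map
    min_counts = (
        {"hba1c": 2, "lipid_profile": 1, "serum_creatinine": 1, "urine_albumin": 1, "eye_exam": 1}
        if min_counts is None
        else min_counts
    )
    df = services
    if len(df):
        dts = pd.to_datetime(df["date"])
        df = df[(dts >= window.start) & (dts < window.end)]
    counts = {}
    if len(df):
        unknown = set(df["service_code"]) - set(code_map)
        for code in sorted(unknown):
            n = int((df["service_code"] == code).sum())
            logger.warning("skipping %d record(s) with unknown service code %r", n, code)
        ctrl = df["service_code"].map(code_map)
        df = df[ctrl.notna()]
        ctrl = ctrl[ctrl.notna()]
        counts = df.groupby([df["patient_id"], ctrl]).size()

    if patient_ids is None:
        patient_ids = (
            services["patient_id"].unique() if len(services) else np.array([], dtype=object)
        )
    idx = pd.Index(patient_ids, name="patient_id")
    out = pd.DataFrame(index=idx)
    for c in CONTROL_TYPES:
        if isinstance(counts, pd.Series) and len(counts):
            col = counts.xs(c, level=1).reindex(idx, fill_value=0) if c in counts.index.get_level_values(1) else pd.Series(0, index=idx)
        else:
            col = pd.Series(0, index=idx)
        out[f"n_{c}"] = col.astype("int64")
        out[f"sat_{c}"] = out[f"n_{c}"] >= min_counts[c]
    out["n_satisfied"] = out[[f"sat_{c}" for c in CONTROL_TYPES]].sum(axis=1)
    out["controls_high_4"] = out["n_satisfied"] >= 4
    out["controls_high_3"] = out["n_satisfied"] >= 3
    return out.reset_index()
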