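"""Drug-era construction from dispensation streams.

A *drug era* is a maximal chain of dispensations of one drug class in
which each dispensation begins no more than ``gap_days`` (default 60)
after the coverage end of the supply accumulated so far.  Supply
stockpiles: an early refill extends the coverage end by its full
duration rather than being truncated.  One dispensation's duration in
days equals its dispensed amount expressed in defined daily doses
(DDD), floored to whole days so that all era arithmetic is exact
integer-day arithmetic.

Coverage intervals are half-open ``[start, end)``; the gap between a
coverage end ``e`` and a following dispensation on day ``d`` is
``d - e``, and a dispensation exactly ``gap_days`` after the coverage
end still chains.

A patient is a *prevalent user* of a class at the index date when some
single era contains at least ``min_dispensations`` dispensations all
dated inside the lookback window ``[index - lookback_days, index)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dates import day_number, from_day_number
from .exceptions import ContractViolationError

__all__ = [
    "DrugEra",
    "build_eras",
    "is_prevalent_user",
    "assign_eras",
    "era_table",
    "prevalent_users",
]


@dataclass
class DrugEra:
    """One maximal chain of dispensations with its coverage geometry.

    ``coverage_segments`` are the disjoint, ordered half-open intervals
    (integer day numbers) of days on which supply was available; the
    union of segments over all eras of a patient-class stream is exactly
    the stream's covered-day set (no day lost or double counted).
    """

    patient_id: object
    drug_class: object
    start_day: int
    coverage_end_day: int  # exclusive
    member_days: list[int] = field(default_factory=list)
    coverage_segments: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_dispensations(self) -> int:
        return len(self.member_days)

    @property
    def start(self) -> pd.Timestamp:
        return from_day_number(self.start_day)

    @property
    def coverage_end(self) -> pd.Timestamp:
        return from_day_number(self.coverage_end_day)

    @property
    def covered_days(self) -> int:
        return sum(e - s for s, e in self.coverage_segments)


def _scan_stream(days: np.ndarray, durations: np.ndarray, gap_days: int):
    """One pass over a sorted stream; returns per-row era ids and
    coverage segments ``(era_id, seg_start, seg_end)`` arrays."""
    n = len(days)
    era_id = np.empty(n, dtype=np.int64)
    seg_s = np.empty(n, dtype=np.int64)
    seg_e = np.empty(n, dtype=np.int64)
    eid = -1
    cov_end = -(10**9)
    for i in range(n):
        d = int(days[i])
        if eid < 0 or d - cov_end > gap_days:
            eid += 1
            s = d
        else:
            s = d if d > cov_end else cov_end
        e = s + int(durations[i])
        era_id[i] = eid
        seg_s[i] = s
        seg_e[i] = e
        cov_end = e
    return era_id, seg_s, seg_e


def build_eras(dispensations, gap_days: int = 60) -> list[DrugEra]:
    """Chain one patient-drug dispensation stream into eras.

    Parameters
    ----------
    dispensations
        DataFrame with columns ``date`` and ``amount_ddd`` (optionally
        ``patient_id`` and ``drug_class``), sorted by date.
    gap_days
        Maximum allowed days between a coverage end and the next
        dispensation for the chain to continue.

    Raises
    ------
    ContractViolationError
        If the stream is not sorted by date or an amount is <= 0.
    """
    if gap_days < 0:
        raise ContractViolationError("gap_days must be >= 0")
    df = dispensations
    if len(df) == 0:
        return []
    days = day_number(df["date"])
    amounts = np.asarray(df["amount_ddd"], dtype=float)
    if np.any(np.diff(days) < 0):
        raise ContractViolationError("dispensations must be sorted by date")
    if np.any(amounts <= 0):
        raise ContractViolationError("amount_ddd must be positive")
    durations = np.floor(amounts).astype(np.int64)
    era_id, seg_s, seg_e = _scan_stream(days, durations, gap_days)

    pid = df["patient_id"].iloc[0] if "patient_id" in df.columns else None
    cls = df["drug_class"].iloc[0] if "drug_class" in df.columns else None
    eras: list[DrugEra] = []
    for eid in range(int(era_id[-1]) + 1):
        sel = era_id == eid
        segs = [
            (int(s), int(e))
            for s, e in zip(seg_s[sel], seg_e[sel])
            if e > s
        ]
        eras.append(
            DrugEra(
                patient_id=pid,
                drug_class=cls,
                start_day=int(days[sel][0]),
                coverage_end_day=int(seg_e[sel].max()),
                member_days=[int(d) for d in days[sel]],
                coverage_segments=segs,
            )
        )
    return eras


def is_prevalent_user(
    eras: list[DrugEra],
    index_date,
    lookback_days: int = 730,
    min_dispensations: int = 3,
    gap_days: int = 60,
    require_active_at_index: bool = False,
) -> bool:
    """True iff some era holds >= ``min_dispensations`` dispensations all
    dated within ``[index - lookback_days, index)``.

    With ``require_active_at_index`` the qualifying era must additionally
    still be active at the index date, i.e. its coverage end no more
    than ``gap_days`` before the index.
    """
    idx = day_number(index_date)
    lo = idx - lookback_days
    for era in eras:
        n_in = sum(lo <= d < idx for d in era.member_days)
        if n_in >= min_dispensations:
            if require_active_at_index and idx - era.coverage_end_day > gap_days:
                continue
            return True
    return False


# ---------------------------------------------------------------------------
# Table-level fast paths (one python pass over the sorted claim table)
# ---------------------------------------------------------------------------

def assign_eras(dispensations: pd.DataFrame, gap_days: int = 60) -> pd.DataFrame:
    """Annotate a multi-patient dispensation table with era ids and
    per-dispensation coverage segments.

    Returns a copy sorted by ``(patient_id, drug_class, date)`` with
    integer columns ``day``, ``era_id`` (numbered within each
    patient-class stream), ``seg_start_day`` and ``seg_end_day``.
    Segments of one stream are disjoint, so covered days can be summed
    without interval union.
    """
    df = dispensations.sort_values(
        ["patient_id", "drug_class", "date"], kind="mergesort"
    ).reset_index(drop=True)
    n = len(df)
    out = df.copy()
    if n == 0:
        for col in ("day", "era_id", "seg_start_day", "seg_end_day"):
            out[col] = np.array([], dtype=np.int64)
        return out
    days = day_number(df["date"])
    durs = np.floor(np.asarray(df["amount_ddd"], dtype=float)).astype(np.int64)
    # group change detection on factorised keys
    pid_codes, _ = pd.factorize(df["patient_id"], sort=False)
    cls_codes, _ = pd.factorize(df["drug_class"], sort=False)
    era_id = np.empty(n, dtype=np.int64)
    seg_s = np.empty(n, dtype=np.int64)
    seg_e = np.empty(n, dtype=np.int64)

    prev_key = None
    eid = -1
    cov_end = 0
    d_list = days.tolist()
    dur_list = durs.tolist()
    pid_list = pid_codes.tolist()
    cls_list = cls_codes.tolist()
    for i in range(n):
        key = (pid_list[i], cls_list[i])
        d = d_list[i]
        if key != prev_key:
            prev_key = key
            eid = 0
            s = d
        elif d - cov_end > gap_days:
            eid += 1
            s = d
        else:
            s = d if d > cov_end else cov_end
        e = s + dur_list[i]
        era_id[i] = eid
        seg_s[i] = s
        seg_e[i] = e
        cov_end = e
    out["day"] = days
    out["era_id"] = era_id
    out["seg_start_day"] = seg_s
    out["seg_end_day"] = seg_e
    return out


def era_table(dispensations: pd.DataFrame, gap_days: int = 60) -> pd.DataFrame:
    """Per-era summary (one row per patient-class era), exportable as CSV."""
    ann = assign_eras(dispensations, gap_days=gap_days)
    if len(ann) == 0:
        return pd.DataFrame(
            columns=[
                "patient_id",
                "drug_class",
                "era_id",
                "start_day",
                "coverage_end_day",
                "n_dispensations",
                "covered_days",
            ]
        )
    ann["seg_len"] = ann["seg_end_day"] - ann["seg_start_day"]
    grp = ann.groupby(["patient_id", "drug_class", "era_id"], sort=True)
    tab = grp.agg(
        start_day=("day", "min"),
        coverage_end_day=("seg_end_day", "max"),
        n_dispensations=("day", "size"),
        covered_days=("seg_len", "sum"),
    ).reset_index()
    tab["start"] = from_day_number(tab["start_day"])
    tab["coverage_end"] = from_day_number(tab["coverage_end_day"])
    return tab


def prevalent_users(
    dispensations: pd.DataFrame,
    index_date,
    gap_days: int = 60,
    lookback_days: int = 730,
    min_dispensations: int = 3,
    require_active_at_index: bool = False,
) -> pd.Index:
    """Patient ids that are prevalent users of the (single) class in
    ``dispensations`` at the index date.

    The table may contain dispensations outside the lookback window;
    chains are built on the whole stream but only in-window members
    count towards the threshold.
    """
    if len(dispensations) == 0:
        return pd.Index([])
    ann = assign_eras(dispensations, gap_days=gap_days)
    idx = day_number(index_date)
    lo = idx - lookback_days
    in_window = (ann["day"] >= lo) & (ann["day"] < idx)
    keys = [ann["patient_id"], ann["drug_class"], ann["era_id"]]
    counts = in_window.groupby(keys).sum()
    qualifying = counts[counts >= min_dispensations]
    if require_active_at_index:
        cov_end = ann["seg_end_day"].groupby(keys).max()
        active = cov_end[qualifying.index] >= idx - gap_days
        qualifying = qualifying[active]
    return qualifying.index.get_level_values(0).unique()
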