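"""PDC measurement, categorisation, hospital bridging, clinical controls."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from adherence_gap import (
    FollowUpWindow,
    assess_clinical_controls,
    categorize_pdc,
    compute_pdc,
    controls_table,
    pdc_table,
)
from adherence_gap.exceptions import ValidationError

from helpers import oracle_covered_days

INDEX = pd.Timestamp("2017-01-01")
WINDOW = FollowUpWindow(INDEX)


def disp(offsets, amounts=None):
    amounts = amounts if amounts is not None else [30.0] * len(offsets)
    return pd.DataFrame(
        {
            "patient_id": "A",
            "date": [INDEX + pd.Timedelta(days=int(o)) for o in offsets],
            "drug_class": "BP",
            "amount_ddd": amounts,
        }
    )


def stays(intervals):
    return pd.DataFrame(
        {
            "patient_id": "A",
            "admission_date": [INDEX + pd.Timedelta(days=a) for a, _ in intervals],
            "discharge_date": [INDEX + pd.Timedelta(days=b) for _, b in intervals],
            "diagnosis_code": "OTHER",
        }
    )


@pytest.mark.parametrize(
    "pdc, category",
    [
        (0.0, "very_low"),
        (0.25, "very_low"),
        (0.26, "low"),
        (0.50, "low"),
        (0.51, "intermediate"),
        (0.7499, "intermediate"),
        (0.75, "high"),
        (1.0, "high"),
    ],
)
def test_categorize_boundaries(pdc, category):
    assert categorize_pdc(pdc) == category


@pytest.mark.parametrize("bad", [-0.1, 1.1, float("nan")])
def test_categorize_rejects_out_of_range(bad):
    with pytest.raises(ValidationError):
        categorize_pdc(bad)


def test_full_year_coverage():
    res = compute_pdc(disp(list(range(0, 390, 30))), WINDOW)
    assert res.pdc == 1.0 and res.category == "high" and res.high_at_80


def test_partial_coverage_200_days():
    res = compute_pdc(disp([0, 30, 60, 90, 120, 150] + [180], [30.0] * 6 + [20.0]), WINDOW)
    assert res.covered_days == 200
    assert res.pdc == pytest.approx(200 / 365)
    assert res.category == "intermediate" and not res.high_at_70


def test_hospital_bridging_adds_uncovered_days():
    # 150 covered days, then a 30-day stay inside the uncovered stretch
    res = compute_pdc(disp([0, 30, 60, 90, 120]), WINDOW, stays([(200, 230)]))
    assert res.covered_days == 180
    # a stay overlapping covered days adds only its uncovered part
    res2 = compute_pdc(disp([0, 30, 60, 90, 120]), WINDOW, stays([(140, 170)]))
    assert res2.covered_days == 170


def test_bridging_requires_prior_regimen():
    # stay before the first dispensation of the class: not bridged
    res = compute_pdc(disp([100, 130]), WINDOW, stays([(10, 40)]))
    assert res.covered_days == 60


def test_bridging_rule_switch():
    # era over [0, 60), stay admitted at day 200 after the era ended
    d = disp([0, 30])
    lenient = compute_pdc(d, WINDOW, stays([(200, 210)]), bridging="any_prior_era")
    strict = compute_pdc(d, WINDOW, stays([(200, 210)]), bridging="overlapping_era")
    assert lenient.covered_days == 70
    assert strict.covered_days == 60


def test_spillover_switch():
    # 30-DDD pack 10 days before the window spills 20 days into it
    d = disp([-10])
    assert compute_pdc(d, WINDOW).covered_days == 20
    assert compute_pdc(d, WINDOW, include_spillover=False).covered_days == 0


def test_implausible_stay_rejected():
    with pytest.raises(ValidationError):
        compute_pdc(disp([0]), WINDOW, stays([(40, 10)]))


@given(
    offsets=st.lists(st.integers(-60, 360), min_size=1, max_size=6).map(sorted),
    split_at=st.integers(0, 5),
)
def test_split_dispensation_invariance(offsets, split_at):
    """Splitting one 30-DDD pack into two contiguous 15-DDD halves
    leaves the PDC unchanged."""
    split_at = min(split_at, len(offsets) - 1)
    base = compute_pdc(disp(offsets), WINDOW)
    parts = []
    for i, o in enumerate(offsets):
        if i == split_at:
            parts += [(o, 15.0), (o + 15, 15.0)]
        else:
            parts.append((o, 30.0))
    parts.sort()
    res = compute_pdc(disp([p[0] for p in parts], [p[1] for p in parts]), WINDOW)
    assert res.covered_days == base.covered_days


def test_bridging_monotone(rng=np.random.default_rng(7)):
    """Adding stays never lowers PDC; removing all never raises it."""
    for _ in range(25):
        offs = np.sort(rng.integers(-60, 320, size=rng.integers(1, 6)))
        st_int = sorted(rng.integers(0, 360, size=2))
        if st_int[0] == st_int[1]:
            st_int[1] += 1
        d = disp(offs.tolist())
        bare = compute_pdc(d, WINDOW)
        with_stay = compute_pdc(d, WINDOW, stays([tuple(st_int)]))
        assert with_stay.covered_days >= bare.covered_days


def test_pdc_table_matches_single_patient_path(small_scenario_tables):
    t = small_scenario_tables
    bp = t.dispensations[t.dispensations["drug_class"] == "BP"]
    pids = bp["patient_id"].unique()[:150]
    sub = bp[bp["patient_id"].isin(pids)]
    hosp = t.hospital_stays[t.hospital_stays["patient_id"].isin(pids)]
    table = pdc_table(sub, WINDOW, hospital_stays=hosp, patient_ids=pids).set_index("patient_id")
    for pid in pids:
        res = compute_pdc(
            sub[sub["patient_id"] == pid].sort_values("date"),
            WINDOW,
            hosp[hosp["patient_id"] == pid],
        )
        assert table.loc[pid, "covered_days"] == res.covered_days


# --------------------------------------------------------------------------
# clinical controls
# --------------------------------------------------------------------------

def services(counts: dict[str, int], pid="D1"):
    rows = []
    day = 10
    for code, k in counts.items():
        for _ in range(k):
            rows.append((pid, INDEX + pd.Timedelta(days=day), code))
            day += 7
    return pd.DataFrame(rows, columns=["patient_id", "date", "service_code"])


@pytest.mark.parametrize(
    "counts, n_sat, high4, high3",
    [
        ({"HBA1C": 2, "LIPID_PANEL": 1, "CREATININE": 1, "URINE_ALB": 1}, 4, True, True),
        # only the HbA1c recommendation (>= 2 assays) fails
        ({"HBA1C": 1, "LIPID_PANEL": 1, "CREATININE": 1, "URINE_ALB": 1, "EYE_EXAM": 1}, 4, True, True),
        ({"HBA1C": 2, "LIPID_PANEL": 1, "CREATININE": 1}, 3, False, True),
        ({}, 0, False, False),
        ({"HBA1C": 5, "LIPID_PANEL": 3, "CREATININE": 2, "URINE_ALB": 2, "EYE_EXAM": 1}, 5, True, True),
    ],
)
def test_control_counting_rules(counts, n_sat, high4, high3):
    profile = assess_clinical_controls(services({**counts, "GENERIC_VISIT": 1}), WINDOW)
    assert profile.n_satisfied == n_sat
    assert profile.high_controls_at_4 is high4
    assert profile.high_controls_at_3 is high3


def test_services_outside_window_ignored():
    svc = services({"HBA1C": 2})
    svc.loc[0, "date"] = INDEX - pd.Timedelta(days=5)
    profile = assess_clinical_controls(svc, WINDOW)
    assert profile.counts["hba1c"] == 1 and not profile.satisfied["hba1c"]


def test_unknown_service_code_warns_and_skips(caplog):
    svc = services({"HBA1C": 2, "MYSTERY": 1})
    with caplog.at_level("WARNING", logger="adherence_gap.adherence"):
        tab = controls_table(svc, WINDOW)
    assert "MYSTERY" in caplog.text
    assert tab.loc[0, "n_satisfied"] == 1


# --------------------------------------------------------------------------
# interval arithmetic vs day-by-day oracle (randomised)
# --------------------------------------------------------------------------

def test_covered_days_match_oracle_randomised():
    rng = np.random.default_rng(20250925)
    for _ in range(300):
        k = rng.integers(1, 8)
        offs = np.sort(rng.integers(-200, 360, size=k)).tolist()
        amts = rng.integers(5, 95, size=k).astype(float).tolist()
        n_stay = rng.integers(0, 3)
        ivs = []
        for _ in range(n_stay):
            a = int(rng.integers(0, 360))
            ivs.append((a, a + int(rng.integers(1, 40))))
        res = compute_pdc(disp(offs, amts), WINDOW, stays(ivs) if ivs else None)
        expected = oracle_covered_days(
            [o + 17167 for o in offs],
            amts,
            17167,
            17167 + 365,
            stays=[(a + 17167, b + 17167) for a, b in ivs],
        )
        assert res.covered_days == expected
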