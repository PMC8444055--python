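"""Eligibility, exposure, matching, covariates and balance diagnostics."""
import numpy as np
import pandas as pd
import pytest

from adherence_gap import (
    apply_eligibility,
    ascertain_exposure,
    count_contacts,
    derive_covariates,
    match_comparators,
    standardized_difference,
)
from adherence_gap.config import CovariateConfig
from adherence_gap.exceptions import AnalysisError, ConfigurationError

INDEX = pd.Timestamp("2017-01-01")


class TestEligibility:
    def test_fixture_flow_counts(self, fixture_tables):
        cohort = apply_eligibility(fixture_tables, INDEX, "BP")
        assert cohort.exclusions == {
            "input": 20,
            "missing_birth_date": 0,
            "age_under_18": 1,          # P17
            "residency_under_2y": 1,    # P19
            "not_prevalent_user": 0,
            "death_or_emigration_in_followup": 1,  # P18 dies day 200
            "retained": 17,
        }
        assert cohort.reconciles()
        gone = {"P17", "P18", "P19"}
        assert set(cohort.patients["patient_id"]) == {
            f"P{i:02d}" for i in range(1, 21)
        } - gone

    def test_death_in_followup_excluded(self, fixture_tables):
        cohort = apply_eligibility(fixture_tables, INDEX, "BP")
        assert "P18" not in set(cohort.patients["patient_id"])

    def test_contact_recount_matches_generator_column(self, small_scenario_tables):
        """The generator's precomputed contact volume must equal the
        cohort builder's independent recount from the event tables."""
        recount = count_contacts(small_scenario_tables, INDEX)
        pts = small_scenario_tables.patients.set_index("patient_id")
        recount = recount.reindex(pts.index, fill_value=0)
        assert (recount == pts["n_contacts"]).all()

    def test_fixture_contacts_recount(self, fixture_tables):
        recount = count_contacts(fixture_tables, INDEX)
        pts = fixture_tables.patients.set_index("patient_id")
        assert (recount.reindex(pts.index, fill_value=0) == pts["n_contacts"]).all()
        # hand checks: chain of 4 everywhere, +1 NSAID for P01, +1
        # admission for P02, +4 glucose chain for P06
        assert pts.loc["P01", "n_contacts"] == 5
        assert pts.loc["P02", "n_contacts"] == 5
        assert pts.loc["P06", "n_contacts"] == 8
        assert pts.loc["P05", "n_contacts"] == 4  # stale NSAID outside lookback


class TestExposure:
    def mh(self, rows):
        return pd.DataFrame(
            rows, columns=["patient_id", "diagnosis", "episode_open", "episode_close"]
        )

    def test_open_episode_is_exposed(self):
        rec = self.mh([("X", "depression", pd.Timestamp("2015-01-01"), pd.NaT)])
        assert ascertain_exposure(rec, INDEX) == (True, "depression")

    def test_closed_before_index_not_exposed(self):
        rec = self.mh(
            [("X", "depression", pd.Timestamp("2014-01-01"), pd.Timestamp("2016-06-30"))]
        )
        assert ascertain_exposure(rec, INDEX) == (False, None)

    def test_concurrent_episodes_resolved_by_severity(self):
        rec = self.mh(
            [
                ("X", "depression", pd.Timestamp("2016-02-01"), pd.NaT),
                ("X", "bipolar disorder", pd.Timestamp("2014-05-01"), pd.NaT),
            ]
        )
        assert ascertain_exposure(rec, INDEX) == (True, "bipolar disorder")

    def test_opened_after_index_not_exposed(self):
        rec = self.mh([("X", "schizophrenia", pd.Timestamp("2017-06-01"), pd.NaT)])
        assert ascertain_exposure(rec, INDEX) == (False, None)


class TestMatching:
    def test_fixture_sets(self, fixture_members):
        members, cohort, match = fixture_members
        comps = {
            members.loc[members["exposed"] & (members["set_id"] == s), "patient_id"].iloc[0]:
            set(members.loc[~members["exposed"] & (members["set_id"] == s), "patient_id"])
            for s in members["set_id"].unique()
        }
        assert comps["P01"] == {"P05", "P06", "P07"}  # P08 is 2 years older
        assert comps["P02"] == {"P09", "P10"}         # pool exhausted: a 1+2 set
        assert comps["P03"] <= {"P11", "P12", "P13", "P14"} and len(comps["P03"]) == 3
        assert "P04" not in comps                      # no eligible comparator
        assert match.n_exposed_unmatched == 1
        # P20 is unexposed but has a mental-health record: never a comparator
        assert "P20" not in set(members["patient_id"])

    def test_same_seed_reproduces_sets(self, fixture_tables):
        cohort = apply_eligibility(fixture_tables, INDEX, "BP")
        a = match_comparators(cohort.patients, seed=5, contact_binning="none")
        b = match_comparators(cohort.patients, seed=5, contact_binning="none")
        pd.testing.assert_frame_equal(a.sets, b.sets)

    def test_constraints_hold_post_hoc(self, small_scenario_tables):
        cohort = apply_eligibility(small_scenario_tables, INDEX, "BP")
        res = match_comparators(cohort.patients, seed=3)
        merged = res.sets.merge(cohort.patients, on="patient_id", suffixes=("", "_e"))
        # no reuse
        assert merged["patient_id"].is_unique
        pool = cohort.patients[
            ~cohort.patients["exposed"] & ~cohort.patients["has_mh_record"]
        ]
        edges = np.quantile(pool["n_contacts"], np.arange(0.1, 1.0, 0.1))
        merged["bin"] = np.searchsorted(edges, merged["n_contacts"], side="right")
        for _, grp in merged.groupby("set_id"):
            exp = grp[grp["exposed"]].iloc[0]
            others = grp[~grp["exposed"]]
            assert 1 <= len(others) <= 3
            assert (others["gender"] == exp["gender"]).all()
            assert (abs(others["age_at_index"] - exp["age_at_index"]) <= 1).all()
            assert (others["bin"] == exp["bin"]).all()
            assert not others["exposed_e"].any() if "exposed_e" in others else True

    def test_bad_ratio_rejected(self, fixture_tables):
        cohort = apply_eligibility(fixture_tables, INDEX, "BP")
        with pytest.raises(ConfigurationError):
            match_comparators(cohort.patients, ratio=0)


class TestStandardizedDifference:
    def test_identical_distributions(self):
        x = np.arange(10.0)
        assert standardized_difference(x, x) == 0.0

    def test_binary_formula(self):
        x1 = np.r_[np.ones(3), np.zeros(7)]   # p1 = 0.3
        x2 = np.r_[np.ones(2), np.zeros(8)]   # p2 = 0.2
        assert standardized_difference(x1, x2, "binary") == pytest.approx(
            0.1 / np.sqrt(0.185), rel=1e-12
        )

    def test_continuous_formula(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(0, 1, 500)
        x2 = rng.normal(1, 1, 500)
        expected = abs(x1.mean() - x2.mean()) / np.sqrt(
            (x1.var(ddof=1) + x2.var(ddof=1)) / 2
        )
        assert standardized_difference(x1, x2) == pytest.approx(expected)

    def test_zero_variance_unequal_means_is_infinite(self):
        assert standardized_difference([1.0, 1.0], [0.0, 0.0], "binary") == float("inf")

    def test_empty_group_rejected(self):
        with pytest.raises(AnalysisError):
            standardized_difference([], [1.0])


class TestCovariates:
    def test_fixture_flags_and_mcs(self, fixture_tables):
        cov = derive_covariates(fixture_tables, INDEX).set_index("patient_id")
        assert cov.loc["P01", "nsaid"]           # NSAID 100 days pre-index
        assert not cov.loc["P05", "nsaid"]       # NSAID 3 years pre-index
        # mcs cut-points (1, 3, 5), boundary goes to the lower category
        assert cov.loc["P01", "mcs_category"] == 1  # score 3
        assert cov.loc["P03", "mcs_category"] == 0  # score 0
        assert cov.loc["P06", "mcs_category"] == 2  # score 4

    def test_boundary_scores_fall_in_lower_category(self, fixture_tables):
        cfg = CovariateConfig(mcs_cutpoints=(1.0, 3.0, 5.0))
        cov = derive_covariates(fixture_tables, INDEX, cfg).set_index("patient_id")
        score = fixture_tables.patients.set_index("patient_id")["mcs_score"]
        for pid in score.index:
            expected = int(np.sum(np.array([1.0, 3.0, 5.0]) < score[pid]))
            assert cov.loc[pid, "mcs_category"] == expected

    def test_missing_codelist_key_rejected(self, fixture_tables):
        cfg = CovariateConfig(codelists={"broken": {"table": "dispensations"}})
        with pytest.raises(ConfigurationError):
            derive_covariates(fixture_tables, INDEX, cfg)
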