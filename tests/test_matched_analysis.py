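"""Exact conditional logistic regression and the between-strata tests."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adherence_gap import (
    AnalysisSpec,
    EffectEstimate,
    compare_coefficients_z,
    fit_conditional_logistic,
    homogeneity_test,
    percent_variation,
    sensitivity_suite,
    stratified_estimates,
    trend_test,
)
from adherence_gap.exceptions import AnalysisError, ConvergenceError

from helpers import brute_fit_beta, random_matched_instance


def members_frame(rows, outcome="pdc_high_75", extra=None):
    df = pd.DataFrame(rows, columns=["set_id", "exposed", outcome])
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


def pairs(n_exposed_case, n_comparator_case, n_concordant=0):
    """1:1 sets discordant in either direction plus concordant filler."""
    rows, s = [], 0
    for _ in range(n_exposed_case):
        rows += [(s, True, True), (s, False, False)]
        s += 1
    for _ in range(n_comparator_case):
        rows += [(s, True, False), (s, False, True)]
        s += 1
    for _ in range(n_concordant):
        rows += [(s, True, True), (s, False, True)]
        s += 1
    return members_frame(rows)


class TestConditionalFit:
    def test_discordant_pair_closed_form(self):
        """With 1:1 sets and exposure only, the conditional MLE is the
        ratio of discordant counts: 12/6 -> OR 2."""
        est = fit_conditional_logistic(pairs(12, 6, n_concordant=5))
        assert est.or_value == pytest.approx(2.0, abs=1e-7)
        assert est.beta == pytest.approx(np.log(2.0), abs=1e-7)
        # McNemar-style SE: sqrt(1/12 + 1/6)
        assert est.se == pytest.approx(np.sqrt(1 / 12 + 1 / 6), rel=1e-6)
        assert est.n_sets_informative == 18 and est.n_sets_total == 23

    def test_exposure_constant_within_sets_is_inestimable(self):
        rows = [(0, True, True), (0, True, False), (1, False, True), (1, False, False)]
        with pytest.raises(AnalysisError, match="exposure"):
            fit_conditional_logistic(members_frame(rows))

    def test_no_informative_sets_is_an_error(self):
        rows = [(0, True, True), (0, False, True), (1, True, False), (1, False, False)]
        with pytest.raises(AnalysisError):
            fit_conditional_logistic(members_frame(rows))

    def test_one_sided_discordance_raises_separation(self):
        with pytest.raises(ConvergenceError):
            fit_conditional_logistic(pairs(15, 0))

    def test_matches_brute_force_enumeration(self):
        """Newton optimum equals the enumerated-likelihood argmax to
        1e-6 on random instances with up to 5 members per set."""
        rng = np.random.default_rng(99)
        for rep in range(12):
            sets, rows = random_matched_instance(rng, n_sets=30, beta=0.5)
            members = members_frame(rows)
            try:
                est = fit_conditional_logistic(members)
            except ConvergenceError:
                continue
            assert est.beta == pytest.approx(brute_fit_beta(sets), abs=1e-6)

    def test_matches_statsmodels_conditional_logit(self):
        """Independent cross-check against statsmodels on a two-
        covariate instance."""
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(5)
        _, rows = random_matched_instance(rng, n_sets=80, beta=-0.4)
        members = members_frame(rows)
        members["age_dev"] = rng.normal(0, 1, len(members))
        est = fit_conditional_logistic(members, adjustment_covariates=("age_dev",))
        mod = ConditionalLogit(
            members["pdc_high_75"].astype(int),
            members[["exposed", "age_dev"]].astype(float),
            groups=members["set_id"],
        )
        ref = mod.fit(disp=False)
        # statsmodels' BFGS stops a little earlier than our Newton, so
        # allow its looser tolerance - but our optimum must dominate.
        assert est.beta == pytest.approx(ref.params.iloc[0], abs=5e-4)
        assert est.covariate_coefficients["age_dev"][0] == pytest.approx(
            ref.params.iloc[1], abs=5e-4
        )
        assert est.se == pytest.approx(ref.bse.iloc[0], rel=1e-3)
        ours = np.array([est.beta, est.covariate_coefficients["age_dev"][0]])
        assert mod.loglike(ours) >= mod.loglike(ref.params.values) - 1e-10

    def test_set_constant_covariate_leaves_beta_unchanged(self):
        members = pairs(12, 6)
        base = fit_conditional_logistic(members)
        members2 = members.copy()
        members2["clinic"] = members2["set_id"] % 3  # constant within set
        aug = fit_conditional_logistic(members2, adjustment_covariates=("clinic",))
        assert aug.beta == pytest.approx(base.beta, abs=1e-12)
        assert "clinic" not in aug.covariate_coefficients


class TestPresentation:
    def test_null_or_maps_to_zero_percent(self):
        est = EffectEstimate(beta=0.0, se=0.1, n_sets_informative=10, n_sets_total=10)
        assert est.pct_variation[0] == 0.0
        assert percent_variation(est).direction == "indeterminate"

    def test_reduced_adherence_presentation(self):
        # choose se so the Wald CI is exactly (0.74, 0.78)
        z = stats.norm.ppf(0.975)
        se = (np.log(0.78) - np.log(0.74)) / (2 * z)
        est = EffectEstimate(
            beta=float(np.log(np.sqrt(0.74 * 0.78))), se=float(se),
            n_sets_informative=10, n_sets_total=10,
        )
        pv = percent_variation(est)
        assert pv.low == pytest.approx(-26.0, abs=1e-9)
        assert pv.high == pytest.approx(-22.0, abs=1e-9)
        assert round(pv.point) == -24
        assert pv.direction == "reduced"

    def test_ci_spanning_null_claims_nothing(self):
        est = EffectEstimate(beta=0.01, se=0.01, n_sets_informative=5, n_sets_total=5)
        assert percent_variation(est).direction == "indeterminate"


class TestStratified:
    def test_single_stratum_equals_unstratified(self):
        members = pairs(12, 6).assign(gender="F")
        spec = AnalysisSpec(strata_variable="gender")
        per = stratified_estimates(members, spec)
        flat = fit_conditional_logistic(members)
        assert list(per) == ["F"]
        assert per["F"].beta == pytest.approx(flat.beta, abs=1e-12)

    def test_identical_strata_identical_estimates(self):
        a = pairs(12, 6).assign(region="A")
        b = pairs(12, 6).assign(region="B")
        b["set_id"] += 100
        members = pd.concat([a, b], ignore_index=True)
        per = stratified_estimates(members, AnalysisSpec(strata_variable="region"))
        assert per["A"].beta == pytest.approx(per["B"].beta, abs=1e-12)
        assert per["A"].se == pytest.approx(per["B"].se, abs=1e-12)


class TestBetweenStrataTests:
    def test_homogeneity_equal_betas(self):
        res = homogeneity_test([0.3, 0.3, 0.3], [0.1, 0.2, 0.1])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_homogeneity_hand_computed(self):
        res = homogeneity_test([0.0, 0.5], [0.1, 0.1])
        assert res.statistic == pytest.approx(12.5, rel=1e-12)
        assert res.df == 1
        assert res.pvalue == pytest.approx(stats.chi2.sf(12.5, 1))

    def test_homogeneity_needs_two_strata(self):
        with pytest.raises(AnalysisError):
            homogeneity_test([0.1], [0.1])

    def test_homogeneity_null_calibration(self):
        """Under the null, Q follows chi-square(K-1): the 5%-level
        rejection rate stays within binomial error."""
        rng = np.random.default_rng(11)
        ses = np.array([0.10, 0.15, 0.12])
        n_rep, alpha = 800, 0.05
        rej = sum(
            homogeneity_test(rng.normal(0.2, ses), ses).pvalue < alpha
            for _ in range(n_rep)
        )
        band = 3 * np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rej / n_rep - alpha) < band

    def test_trend_flat_betas(self):
        res = trend_test([0.2, 0.2, 0.2], [0.1, 0.1, 0.1], [0, 1, 2])
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_trend_exact_linear_recovery(self):
        scores = np.array([0.0, 1.0, 2.0, 3.0])
        betas = 0.1 + 0.2 * scores
        res = trend_test(betas, [1e-4] * 4, scores)
        assert res.slope == pytest.approx(0.2, abs=1e-9)
        assert res.pvalue < 1e-10

    def test_trend_score_order_invariance(self):
        perm = [2, 0, 3, 1]
        betas = [0.1, 0.3, 0.5, 0.7]
        ses = [0.1, 0.2, 0.15, 0.1]
        scores = [0.0, 1.0, 2.0, 3.0]
        a = trend_test(betas, ses, scores)
        b = trend_test(
            [betas[i] for i in perm], [ses[i] for i in perm], [scores[i] for i in perm]
        )
        assert a.slope == pytest.approx(b.slope, rel=1e-12)

    def test_trend_constant_scores_rejected(self):
        with pytest.raises(AnalysisError):
            trend_test([0.1, 0.2], [0.1, 0.1], [1.0, 1.0])

    def test_z_test_equal_coefficients(self):
        z, p = compare_coefficients_z(0.3, 0.1, 0.3, 0.2)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_z_test_hand_computed(self):
        z, p = compare_coefficients_z(-0.288, 0.05, -0.105, 0.06)
        assert z == pytest.approx(-0.183 / np.sqrt(0.05**2 + 0.06**2), rel=1e-12)
        assert z == pytest.approx(-2.3431, abs=1e-4)
        assert p == pytest.approx(2 * stats.norm.sf(2.3431), abs=1e-4)

    def test_z_test_antisymmetry(self):
        z1, _ = compare_coefficients_z(0.4, 0.1, 0.1, 0.2)
        z2, _ = compare_coefficients_z(0.1, 0.2, 0.4, 0.1)
        assert z1 == pytest.approx(-z2, rel=1e-12)

    def test_z_test_bad_se_rejected(self):
        with pytest.raises(AnalysisError):
            compare_coefficients_z(0.1, 0.0, 0.2, 0.1)


class TestSensitivitySuite:
    def test_concordant_outcomes_reported_as_errors(self):
        members = pairs(10, 5)
        members["always_high"] = True
        tab = sensitivity_suite(members, outcomes=("always_high",))
        assert tab.loc[0, "error"] != "" and np.isnan(tab.loc[0, "beta"])

    def test_main_threshold_column_equals_main_fit(self, fixture_members):
        members, _, _ = fixture_members
        tab = sensitivity_suite(members).set_index("outcome")
        main = fit_conditional_logistic(members, outcome="pdc_high_75")
        assert tab.loc["pdc_high_75", "beta"] == pytest.approx(main.beta, abs=1e-12)
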