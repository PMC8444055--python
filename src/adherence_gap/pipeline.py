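"""End-to-end orchestration: generate -> eras -> eligibility -> match ->
adherence -> analyse, with a flow-count manifest.

Everything here is thin glue over the other modules; the functions are
importable individually so analysis scripts, the test suite and the
acceptance script can run any slice of the pipeline.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adherence import FollowUpWindow, controls_table, pdc_table
from .cohort_builder import (
    apply_eligibility,
    balance_table,
    derive_covariates,
    match_comparators,
)
from .config import PipelineConfig
from .exceptions import AnalysisError
from .matched_analysis import (
    AnalysisSpec,
    EffectEstimate,
    fit_conditional_logistic,
    homogeneity_test,
    sensitivity_suite,
    stratified_estimates,
    trend_test,
)
from .synthetic_claims import ClaimsTables, generate_population

logger = logging.getLogger(__name__)

AGE_CLASS_EDGES = (60, 70, 80)  # 18-59, 60-69, 70-79, 80+


@dataclass
class RunManifest:
    """Per-stage record counts and the exclusion ledger of one run."""

    config_hash: str
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)

    def reconciles(self) -> bool:
        """input N = retained + sum of per-criterion removals, per class."""
        for ledger in self.exclusions.values():
            removed = sum(
                v for k, v in ledger.items() if k not in ("input", "retained")
            )
            if ledger["input"] != ledger["retained"] + removed:
                return False
        return True

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
            "exclusions": self.exclusions,
        }


def age_class(age: np.ndarray) -> np.ndarray:
    """Ordinal age category used for stratified/trend analyses."""
    return np.searchsorted(np.asarray(AGE_CLASS_EDGES), np.asarray(age), side="right")


def build_members(
    tables: ClaimsTables,
    drug_class: str,
    config: PipelineConfig,
    match_seed: int,
):
    """Run eligibility, exposure, matching, covariates and adherence for
    one drug class; return the matched members table (one row per set
    member with outcomes and covariates) plus bookkeeping."""
    index_date = pd.Timestamp(config.scenario.index_date)
    cohort = apply_eligibility(
        tables,
        index_date,
        drug_class,
        era=config.era,
        followup_days=config.adherence.followup_days,
    )
    elig = cohort.patients
    match = match_comparators(
        elig,
        ratio=config.matching.ratio,
        seed=match_seed,
        age_tolerance_years=config.matching.age_tolerance_years,
        contact_binning=config.matching.contact_binning,
        contact_caliper=config.matching.contact_caliper,
    )
    members = match.sets.merge(
        elig.drop(columns=["exposed"]), on="patient_id", how="left"
    )
    members["age_class"] = age_class(members["age_at_index"])

    window = FollowUpWindow(index_date, days=config.adherence.followup_days)
    member_ids = members["patient_id"]
    disp = tables.dispensations
    cls_disp = disp[
        (disp["drug_class"] == drug_class) & disp["patient_id"].isin(set(member_ids))
    ]
    hosp = tables.hospital_stays
    hosp = hosp[hosp["patient_id"].isin(set(member_ids))] if len(hosp) else hosp
    pdc = pdc_table(
        cls_disp,
        window,
        hospital_stays=hosp,
        patient_ids=member_ids.unique(),
        gap_days=config.era.gap_days,
        include_spillover=config.adherence.include_spillover,
        bridging=config.adherence.bridging,
    )
    members = members.merge(pdc, on="patient_id", how="left")

    if drug_class == "GLUCOSE":
        svc = tables.outpatient_services
        svc = svc[svc["patient_id"].isin(set(member_ids))]
        ctl = controls_table(
            svc,
            window,
            patient_ids=member_ids.unique(),
            code_map=config.adherence.control_code_map,
            min_counts=config.adherence.control_min_counts,
        )
        members = members.merge(
            ctl[["patient_id", "n_satisfied", "controls_high_4", "controls_high_3"]],
            on="patient_id",
            how="left",
        )

    cov = derive_covariates(
        tables,
        index_date,
        config.covariates,
        patient_ids=members["patient_id"],
    )
    members = members.merge(cov.drop_duplicates("patient_id"), on="patient_id", how="left")
    return members, cohort, match


def analyse_members(members: pd.DataFrame, config: PipelineConfig, drug_class: str):
    """Main, stratified and sensitivity estimates for one class."""
    acfg = config.analysis
    adj = tuple(acfg.adjustment_covariates)
    results: dict = {}

    main = fit_conditional_logistic(
        members, outcome=acfg.main_outcome, adjustment_covariates=adj
    )
    results["main"] = main

    strata_rows = []
    for var in acfg.strata_variables:
        if var not in members.columns or members[var].dropna().nunique() < 2:
            continue
        per = stratified_estimates(
            members,
            AnalysisSpec(outcome=acfg.main_outcome, adjustment_covariates=adj,
                         strata_variable=var),
        )
        if len(per) < 2:
            continue
        levels = sorted(per)
        betas = [per[k].beta for k in levels]
        ses = [per[k].se for k in levels]
        if var in acfg.trend_strata:
            test = trend_test(betas, ses, scores=list(range(len(levels))))
            test_name, stat, p = "trend", test.slope, test.pvalue
        else:
            test = homogeneity_test(betas, ses)
            test_name, stat, p = "homogeneity", test.statistic, test.pvalue
        for k in levels:
            est = per[k]
            point, lo, hi = est.pct_variation
            strata_rows.append(
                dict(
                    drug_class=drug_class, variable=var, stratum=k,
                    beta=est.beta, se=est.se, pct=point, pct_low=lo, pct_high=hi,
                    n_sets=est.n_sets_informative,
                    test=test_name, statistic=stat, pvalue=p,
                )
            )
    results["strata"] = pd.DataFrame(strata_rows)

    outcomes = list(acfg.sensitivity_outcomes)
    if drug_class == "GLUCOSE":
        outcomes += [oc for oc in acfg.control_outcomes if oc in members.columns]
    results["sensitivity"] = sensitivity_suite(
        members, outcomes=tuple(outcomes), adjustment_covariates=adj
    )
    if drug_class == "GLUCOSE" and "controls_high_4" in members.columns:
        try:
            results["controls"] = fit_conditional_logistic(
                members, outcome="controls_high_4", adjustment_covariates=adj
            )
        except AnalysisError as err:
            logger.warning("controls analysis inestimable: %s", err)
    return results


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None):
    """Execute all stages for each requested drug class and write the
    result tables; fully deterministic given config + seed."""
    config.validate()
    if seed is not None:
        config.scenario.seed = seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(config_hash=config.config_hash(), seed=config.scenario.seed)
    logger.info("generating synthetic claims (n=%d)", config.scenario.n_patients)
    tables = generate_population(config.scenario)
    tables.write_csv(outdir / "tables")
    manifest.stages["generated"] = tables.manifest()["rows"]

    effect_rows, all_strata, all_sens = [], [], []
    for k, cls in enumerate(config.drug_classes):
        logger.info("building %s cohort", cls)
        members, cohort, match = build_members(
            tables, cls, config, match_seed=config.scenario.seed * 7919 + k
        )
        manifest.exclusions[cls] = cohort.exclusions
        manifest.stages[f"{cls}_members"] = {
            "sets": int(members["set_id"].nunique()),
            "members": int(len(members)),
            "exposed_unmatched": match.n_exposed_unmatched,
        }
        members.to_csv(outdir / f"members_{cls}.csv", index=False)

        bal = balance_table(cohort.patients, match.sets)
        bal.to_csv(outdir / f"balance_{cls}.csv", index=False)

        dist = (
            members.groupby(["exposed", "category"], sort=True)
            .size()
            .rename("n")
            .reset_index()
        )
        dist.to_csv(outdir / f"adherence_distribution_{cls}.csv", index=False)

        res = analyse_members(members, config, cls)
        est: EffectEstimate = res["main"]
        point, lo, hi = est.pct_variation
        effect_rows.append(
            dict(
                drug_class=cls, outcome=config.analysis.main_outcome,
                beta=est.beta, se=est.se, or_value=est.or_value,
                pct=point, pct_low=lo, pct_high=hi,
                n_sets_informative=est.n_sets_informative,
                n_sets_total=est.n_sets_total,
            )
        )
        if "controls" in res:
            c = res["controls"]
            point, lo, hi = c.pct_variation
            effect_rows.append(
                dict(
                    drug_class=cls, outcome="controls_high_4",
                    beta=c.beta, se=c.se, or_value=c.or_value,
                    pct=point, pct_low=lo, pct_high=hi,
                    n_sets_informative=c.n_sets_informative,
                    n_sets_total=c.n_sets_total,
                )
            )
        if len(res["strata"]):
            all_strata.append(res["strata"])
        sens = res["sensitivity"].assign(drug_class=cls)
        all_sens.append(sens)

    pd.DataFrame(effect_rows).to_csv(outdir / "effects.csv", index=False)
    if all_strata:
        pd.concat(all_strata, ignore_index=True).to_csv(
            outdir / "stratified_effects.csv", index=False
        )
    pd.concat(all_sens, ignore_index=True).to_csv(
        outdir / "sensitivity_effects.csv", index=False
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
    with open(outdir / "flow_report.txt", "w") as fh:
        fh.write(flow_report(manifest))
    if not manifest.reconciles():
        raise AnalysisError("manifest exclusion counts do not reconcile")
    return manifest


def flow_report(manifest: RunManifest) -> str:
    """Flow-chart-style text ledger of exclusions per drug class."""
    lines = [f"run {manifest.config_hash} (seed {manifest.seed})", ""]
    for cls, ledger in manifest.exclusions.items():
        lines.append(f"[{cls}]")
        lines.append(f"  candidates: {ledger['input']}")
        for crit, v in ledger.items():
            if crit in ("input", "retained"):
                continue
            lines.append(f"  excluded ({crit.replace('_', ' ')}): {v}")
        lines.append(f"  retained: {ledger['retained']}")
        lines.append("")
    return "\n".join(lines)


def run_recovery_scenario(
    scenario,
    drug_class: str,
    outcome: str = "pdc_high_75",
    config: PipelineConfig | None = None,
    adjustment_covariates: tuple[str, ...] = (),
) -> tuple[EffectEstimate, pd.DataFrame]:
    """Generate one scenario, run the full pipeline for one class and
    fit one outcome: the parameter-recovery workhorse used by the
    acceptance checks and simulation studies."""
    cfg = config or PipelineConfig()
    cfg.scenario = scenario
    tables = generate_population(scenario)
    members, _, _ = build_members(
        tables, drug_class, cfg, match_seed=scenario.seed * 7919 + 1
    )
    est = fit_conditional_logistic(
        members, outcome=outcome, adjustment_covariates=adjustment_covariates
    )
    return est, members
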