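import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import adherence_gap as ag
from adherence_gap.config import MatchingConfig, PipelineConfig, ScenarioConfig
from adherence_gap.pipeline import build_members

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_tables():
    """The 20-patient worked fixture (hand-checkable ground truth)."""
    return ag.generate_worked_fixture()


@pytest.fixture(scope="session")
def fixture_pipeline_config():
    """Pipeline settings the fixture's documented facts assume: contact
    matching disabled so only gender/age constrain the tiny pool."""
    cfg = PipelineConfig()
    cfg.matching = MatchingConfig(contact_binning="none")
    cfg.drug_classes = ("BP",)
    return cfg


@pytest.fixture(scope="session")
def fixture_members(fixture_tables, fixture_pipeline_config):
    return build_members(fixture_tables, "BP", fixture_pipeline_config, match_seed=1)


@pytest.fixture(scope="session")
def small_scenario_tables():
    """A moderately sized confounded scenario with a planted protective
    effect, shared by tests that only need realistic generated tables."""
    cfg = ScenarioConfig(
        n_patients=6000,
        smi_prevalence=0.2,
        true_log_or=float(np.log(0.76)),
        seed=424241,
        drug_class_mix={"BP": 0.5, "LIPID": 0.0, "GLUCOSE": 0.5},
    )
    return ag.generate_population(cfg)
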