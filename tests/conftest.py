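import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from markovcea import (
    LifeTable,
    ScenarioConfig,
    WeibullParams,
    calibrate_scale_to_median,
    load_config,
    make_life_table_fixture,
    packaged_config_path,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def zero_mortality_table() -> LifeTable:
    return LifeTable(age=np.arange(18, 101), q_annual=np.zeros(83))


@pytest.fixture
def make_config():
    """Factory for small, fully-specified two-arm scenarios."""

    def _make(
        survival=None,
        life_table=None,
        drug_cost=None,
        imaging=0.0,
        bsc=0.0,
        ae_unit_cost=None,
        ae_incidence=None,
        utility_pfs=0.86,
        utility_pd=0.71,
        discount_rate=0.03,
        horizon_years=10.0,
        wtp=150_000.0,
        **kwargs,
    ) -> ScenarioConfig:
        if survival is None:
            survival = {
                "TXT": {
                    "pfs": calibrate_scale_to_median(7.8, 1.1),
                    "os": calibrate_scale_to_median(21.9, 1.1),
                },
                "TX": {
                    "pfs": calibrate_scale_to_median(5.6, 1.1),
                    "os": calibrate_scale_to_median(17.4, 1.1),
                },
            }
        if drug_cost is None:
            drug_cost = {"tucatinib": 12950.0, "trastuzumab": 3669.08, "capecitabine": 955.50}
        cfg = ScenarioConfig(
            country="TEST",
            wtp=wtp,
            drug_cost=dict(drug_cost),
            arm_drugs={
                "TXT": [d for d in drug_cost],
                "TX": [d for d in drug_cost if d != "tucatinib"],
            },
            imaging_cost_per_cycle=imaging,
            bsc_cost_per_cycle=bsc,
            ae_unit_cost=dict(ae_unit_cost or {}),
            ae_incidence=ae_incidence or {"TXT": {}, "TX": {}},
            utility_pfs=utility_pfs,
            utility_pd=utility_pd,
            survival=survival,
            life_table=life_table or zero_mortality_table(),
            discount_rate=discount_rate,
            horizon_years=horizon_years,
            **kwargs,
        )
        return cfg.validate()

    return _make


def exponential_params(p_per_cycle: float, cycle_months: float = 21 / 30.4375) -> WeibullParams:
    """Monthly-scale exponential whose per-cycle exit probability is exactly p."""
    lam_cycle = -np.log(1.0 - p_per_cycle)
    return WeibullParams(scale_lambda=lam_cycle / cycle_months, shape_gamma=1.0)


@pytest.fixture(scope="session")
def usa_config():
    return load_config(packaged_config_path("usa_base"))


@pytest.fixture(scope="session")
def china_config():
    return load_config(packaged_config_path("china_base"))
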