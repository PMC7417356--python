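"""Cohort engine: transition matrices, propagation, correction, accrual."""

import numpy as np
import pytest

from markovcea import (
    CohortTrace,
    ConfigError,
    InsufficientDataError,
    LifeTable,
    WeibullParams,
    accrue_outcomes,
    background_mortality_cycle,
    build_transition_matrix,
    discount_factor,
    half_cycle_corrected_occupancy,
    make_life_table_fixture,
    run_arm,
    run_cohort,
)
from conftest import exponential_params, zero_mortality_table

CYCLES_PER_YEAR = 365.25 / 21


def tiny_params():
    """Near-zero hazards for 'nothing happens' scenarios."""
    eps = WeibullParams(1e-12, 1.0)
    return {"TXT": {"pfs": eps, "os": eps}, "TX": {"pfs": eps, "os": eps}}


class TestBackgroundMortality:
    def test_zero_q_gives_zero(self):
        lt = zero_mortality_table()
        assert background_mortality_cycle(lt, 60, 21.0) == 0.0

    def test_direct_evaluation(self):
        lt = LifeTable(age=np.array([60]), q_annual=np.array([0.0365]))
        p = background_mortality_cycle(lt, 60, 21.0)
        assert p == pytest.approx(1 - (1 - 0.0365) ** (21 / 365.25), abs=1e-15)
        assert p == pytest.approx(0.002136, abs=1e-6)

    def test_capped_q_stays_below_one(self):
        lt = make_life_table_fixture(40, 200, q0=0.5, doubling_years=5)
        p = background_mortality_cycle(lt, 200, 21.0)
        assert p < 1.0


class TestTransitionMatrix:
    def test_zero_hazards_identity(self, make_config):
        cfg = make_config(survival=tiny_params())
        m = build_transition_matrix(0, "TXT", cfg)
        assert np.allclose(m, np.eye(3), atol=1e-10)

    def test_rows_stochastic_and_death_absorbing(self, make_config):
        cfg = make_config(life_table=make_life_table_fixture(18, 100, 0.0003, 8))
        for k in (0, 10, 100):
            m = build_transition_matrix(k, "TX", cfg, current_age=55 + k / CYCLES_PER_YEAR)
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= 0).all()
            assert np.allclose(m[2], [0, 0, 1])

    def test_exponential_hazards_are_time_homogeneous(self, make_config):
        surv = {
            arm: {"pfs": exponential_params(0.1), "os": exponential_params(0.05)}
            for arm in ("TXT", "TX")
        }
        cfg = make_config(survival=surv)
        mats = [build_transition_matrix(k, "TXT", cfg) for k in range(5)]
        for m in mats[1:]:
            assert np.allclose(m, mats[0], atol=1e-12)

    def test_competing_overflow_rescaled_proportionally(self, make_config):
        # PFS hazard near-certain plus heavy background mortality must still
        # give a probability row, with the two exits in their hazard ratio.
        surv = {
            arm: {"pfs": WeibullParams(8.0, 1.0), "os": WeibullParams(0.05, 1.0)}
            for arm in ("TXT", "TX")
        }
        lt = LifeTable(age=np.array([55]), q_annual=np.array([0.999]))
        cfg = make_config(survival=surv, life_table=lt)
        m = build_transition_matrix(0, "TXT", cfg)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert (m >= 0).all()


class TestRunCohort:
    def test_zero_hazards_cohort_stays_put(self, make_config):
        cfg = make_config(survival=tiny_params())
        trace = run_cohort("TX", cfg)
        assert np.allclose(trace.pfs, 1.0, atol=1e-9)

    def test_conservation_and_monotonicity(self, make_config):
        cfg = make_config(life_table=make_life_table_fixture(18, 100, 0.0003, 8))
        trace = run_cohort("TXT", cfg)
        assert trace.occupancy.shape == (cfg.n_cycles + 1, 3)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        assert (np.diff(trace.death) >= -1e-15).all()
        assert (np.diff(trace.pfs) <= 1e-15).all()
        assert (trace.occupancy >= -1e-15).all()

    def test_exponential_pfs_matches_geometric_closed_form(self, make_config):
        p = 0.1
        surv = {
            arm: {"pfs": exponential_params(p), "os": exponential_params(0.05)}
            for arm in ("TXT", "TX")
        }
        cfg = make_config(survival=surv)
        trace = run_cohort("TXT", cfg)
        k = np.arange(cfg.n_cycles + 1)
        assert np.allclose(trace.pfs, (1 - p) ** k, atol=1e-10)


class TestHalfCycleCorrection:
    def test_constant_trace_identity(self):
        occ = np.tile([0.5, 0.3, 0.2], (5, 1))
        trace = CohortTrace(occupancy=occ, times_years=np.arange(5.0))
        assert np.allclose(half_cycle_corrected_occupancy(trace), occ[:-1])

    def test_midpoint_of_a_drop(self):
        occ = np.array([[1.0, 0.0, 0.0], [0.8, 0.15, 0.05]])
        trace = CohortTrace(occupancy=occ, times_years=np.arange(2.0))
        hc = half_cycle_corrected_occupancy(trace)
        assert np.allclose(hc[0], [0.9, 0.075, 0.025])

    def test_row_sums_preserved(self, make_config):
        trace = run_cohort("TX", make_config())
        hc = half_cycle_corrected_occupancy(trace)
        assert np.allclose(hc.sum(axis=1), 1.0, atol=1e-12)

    def test_single_row_rejected(self):
        trace = CohortTrace(occupancy=np.array([[1.0, 0.0, 0.0]]), times_years=np.zeros(1))
        with pytest.raises(InsufficientDataError):
            half_cycle_corrected_occupancy(trace)


class TestDiscounting:
    def test_cycle_zero_undiscounted(self, make_config):
        assert discount_factor(0, make_config()) == 1.0

    def test_zero_rate_never_discounts(self, make_config):
        cfg = make_config(discount_rate=0.0)
        assert np.allclose(discount_factor(np.arange(100), cfg), 1.0)

    def test_one_year_equals_annual_factor(self, make_config):
        cfg = make_config(discount_rate=0.03)
        assert discount_factor(CYCLES_PER_YEAR, cfg) == pytest.approx(1 / 1.03, rel=1e-12)


class TestAccrual:
    def test_all_zero_inputs_accrue_nothing(self, make_config):
        cfg = make_config(
            survival=tiny_params(),
            drug_cost={"tucatinib": 0.0, "trastuzumab": 0.0, "capecitabine": 0.0},
            utility_pfs=0.0,
            utility_pd=0.0,
        )
        out = run_arm("TXT", cfg)
        assert out.cost == 0.0 and out.qaly == 0.0
        assert out.life_years > 0  # cohort is alive, just worth nothing

    def test_stationary_cohort_qaly_is_utility_times_person_years(self, make_config):
        cfg = make_config(survival=tiny_params(), discount_rate=0.0, utility_pfs=0.86)
        out = run_arm("TXT", cfg)
        person_years = cfg.n_cycles * cfg.cycle_years
        assert out.qaly == pytest.approx(0.86 * person_years, rel=1e-9)

    def test_exponential_drug_cost_matches_geometric_closed_form(self, make_config):
        p, c = 0.08, 1000.0
        surv = {
            arm: {"pfs": exponential_params(p), "os": exponential_params(0.05)}
            for arm in ("TXT", "TX")
        }
        cfg = make_config(
            survival=surv,
            drug_cost={"tucatinib": c, "trastuzumab": 0.0, "capecitabine": 0.0},
            discount_rate=0.03,
        )
        out = run_arm("TXT", cfg)
        beta = (1 + 0.03) ** (-cfg.cycle_years)
        a = beta * (1 - p)
        n = cfg.n_cycles
        # sum_k beta^k * c * ((1-p)^k + (1-p)^(k+1)) / 2  = c (2-p)/2 * (1-a^n)/(1-a)
        closed = c * (2 - p) / 2 * (1 - a**n) / (1 - a)
        assert out.cost == pytest.approx(closed, abs=1e-8)

    def test_discounted_totals_decrease_with_rate(self, make_config):
        outs = [run_arm("TXT", make_config(discount_rate=r)) for r in (0.0, 0.02, 0.05)]
        assert outs[0].cost > outs[1].cost > outs[2].cost
        assert outs[0].qaly > outs[1].qaly > outs[2].qaly

    def test_qaly_monotone_in_utilities(self, make_config):
        a = run_arm("TXT", make_config(utility_pfs=0.7, utility_pd=0.5))
        b = run_arm("TXT", make_config(utility_pfs=0.9, utility_pd=0.5))
        c = run_arm("TXT", make_config(utility_pfs=0.9, utility_pd=0.6))
        assert a.qaly < b.qaly < c.qaly

    def test_cost_strictly_increasing_in_per_cycle_cost(self, make_config):
        lo = run_arm("TXT", make_config(bsc=100.0))
        hi = run_arm("TXT", make_config(bsc=200.0))
        assert hi.cost > lo.cost

    def test_discounted_never_exceeds_undiscounted(self, make_config):
        out = run_arm("TXT", make_config(discount_rate=0.03, bsc=500.0, imaging=100.0))
        assert out.cost <= out.cost_undiscounted
        assert out.qaly <= out.qaly_undiscounted
        assert out.qaly <= out.life_years  # utilities <= 1

    def test_missing_drug_cost_is_a_config_error(self, make_config):
        cfg = make_config()
        cfg.arm_drugs["TXT"].append("unobtainium")
        with pytest.raises(ConfigError):
            run_arm("TXT", cfg)
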