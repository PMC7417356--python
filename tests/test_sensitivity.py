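"""Tornado analysis, moment-matched distributions, PSA and CEAC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from markovcea import (
    InsufficientDataError,
    InvalidParameterError,
    ParamSpec,
    beta_from_mean_se,
    build_param_specs,
    ceac,
    default_range,
    evaluate_scenario,
    gamma_from_mean_se,
    one_way_sa,
    run_psa,
    sample_psa_draw,
    subgroup_run,
)
from markovcea.sensitivity import se_from_range


class TestDefaultRange:
    def test_published_tucatinib_ranges(self):
        assert default_range(12_950.0) == (9_065.0, 16_835.0)
        low, high = default_range(1_002.03)
        assert (round(low, 2), round(high, 2)) == (701.42, 1_302.64)

    def test_zero_base(self):
        assert default_range(0.0) == (0.0, 0.0)

    def test_invalid_fraction(self):
        with pytest.raises(InvalidParameterError):
            default_range(10.0, fraction=1.0)

    def test_se_reads_range_as_95_interval(self):
        assert se_from_range(0.0, 3.919927969080108) == pytest.approx(1.0)


class TestMomentMatching:
    def test_gamma_by_hand(self):
        shape, rate = gamma_from_mean_se(4.0, 2.0)
        assert (shape, rate) == (4.0, 1.0)

    def test_gamma_moments_recovered(self):
        shape, rate = gamma_from_mean_se(2_933.0, 450.0)
        dist = stats.gamma(a=shape, scale=1 / rate)
        assert dist.mean() == pytest.approx(2_933.0, rel=1e-12)
        assert dist.std() == pytest.approx(450.0, rel=1e-12)
        draws = stats.gamma(a=shape, scale=1 / rate).rvs(
            200_000, random_state=np.random.default_rng(0)
        )
        assert np.mean(draws) == pytest.approx(2_933.0, rel=0.01)

    def test_gamma_concentrates_as_se_shrinks(self):
        rng = np.random.default_rng(1)
        shape, rate = gamma_from_mean_se(10.0, 1e-3)
        draws = rng.gamma(shape, 1 / rate, size=1_000)
        assert np.std(draws) < 0.01

    def test_gamma_invalid_inputs(self):
        for mean, se in [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)]:
            with pytest.raises(InvalidParameterError):
                gamma_from_mean_se(mean, se)

    def test_beta_uniform_case(self):
        a, b = beta_from_mean_se(0.5, np.sqrt(1 / 12))
        assert a == pytest.approx(1.0) and b == pytest.approx(1.0)

    def test_beta_moments_recovered(self):
        a, b = beta_from_mean_se(0.86, 0.05)
        dist = stats.beta(a, b)
        assert dist.mean() == pytest.approx(0.86, rel=1e-12)
        assert dist.std() == pytest.approx(0.05, rel=1e-12)
        draws = dist.rvs(200_000, random_state=np.random.default_rng(2))
        assert np.mean(draws) == pytest.approx(0.86, rel=0.01)

    def test_beta_infeasible_moments(self):
        with pytest.raises(InvalidParameterError):
            beta_from_mean_se(0.86, 0.5)


def all_fixed_specs(config):
    return [
        ParamSpec(s.name, s.base, s.base, s.base, "fixed") for s in build_param_specs(config)
    ]


class TestSampling:
    def test_all_fixed_returns_base(self, china_config):
        specs = all_fixed_specs(china_config)
        draw = sample_psa_draw(specs, np.random.default_rng(0))
        assert draw == {s.name: s.base for s in specs}

    def test_fixed_seed_identical_draws(self, china_config):
        specs = build_param_specs(china_config)
        a = sample_psa_draw(specs, np.random.default_rng(7))
        b = sample_psa_draw(specs, np.random.default_rng(7))
        assert a == b

    def test_backbone_drugs_never_vary(self, china_config):
        specs = build_param_specs(china_config)
        rng = np.random.default_rng(3)
        draws = [sample_psa_draw(specs, rng) for _ in range(200)]
        for name in ("cost.drug.trastuzumab", "cost.drug.capecitabine", "discount_rate"):
            assert len({d[name] for d in draws}) == 1
        assert len({d["cost.drug.tucatinib"] for d in draws}) == 200


class TestRunPSA:
    def test_degenerate_psa_equals_base_case(self, china_config):
        base = evaluate_scenario(china_config)
        psa = run_psa(china_config, all_fixed_specs(china_config), n_draws=1, seed=0)
        assert psa.loc[0, "delta_cost"] == base.delta_cost
        assert psa.loc[0, "delta_qaly"] == base.delta_effect

    def test_same_seed_reproduces(self, china_config):
        specs = build_param_specs(china_config)
        a = run_psa(china_config, specs, n_draws=20, seed=11)
        b = run_psa(china_config, specs, n_draws=20, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_effect_concentrates_near_base(self, china_config):
        # cost draws do not move QALYs, so with utility uncertainty only the
        # PSA's mean effect should sit near the deterministic base effect
        base = evaluate_scenario(china_config)
        psa = run_psa(china_config, n_draws=200, seed=5)
        assert np.mean(psa["delta_qaly"]) == pytest.approx(base.delta_effect, rel=0.05)


class TestCEAC:
    def test_step_at_the_common_icer(self):
        psa = pd.DataFrame({"draw": range(5), "delta_cost": 10.0, "delta_qaly": 0.2})
        curve = ceac(psa, [0.0, 49.0, 51.0, 1_000.0])
        assert curve["probability"].tolist() == [0.0, 0.0, 1.0, 1.0]

    def test_zero_wtp_counts_cost_saving_draws(self):
        psa = pd.DataFrame(
            {"draw": range(4), "delta_cost": [-5.0, -1.0, 2.0, 7.0], "delta_qaly": 0.1}
        )
        assert ceac(psa, [0.0])["probability"].iloc[0] == 0.5

    def test_monotone_and_equal_to_brute_force(self, china_config):
        psa = run_psa(china_config, n_draws=100, seed=9)
        assert (psa["delta_qaly"] > 0).all()
        grid = np.linspace(0, 2 * china_config.wtp, 40)
        curve = ceac(psa, grid)
        assert (np.diff(curve["probability"]) >= 0).all()
        for w, p in zip(curve["wtp"], curve["probability"]):
            brute = np.mean(
                [w * e - c > 0 for c, e in zip(psa["delta_cost"], psa["delta_qaly"])]
            )
            assert p == brute

    def test_empty_results_rejected(self):
        with pytest.raises(InsufficientDataError):
            ceac(pd.DataFrame(columns=["draw", "delta_cost", "delta_qaly"]), [0.0])


class TestOneWaySA:
    def test_covers_every_parameter_sorted_by_width(self, china_config):
        specs = build_param_specs(china_config)
        entries = one_way_sa(china_config, specs)
        assert sorted(e.parameter for e in entries) == sorted(s.name for s in specs)
        widths = [e.width for e in entries]
        assert widths == sorted(widths, reverse=True)

    def test_equal_incidence_ae_cost_has_zero_width(self, china_config):
        # neutropenia management costs the same and occurs equally in both
        # arms, so varying its unit cost cannot move the ICER
        entries = one_way_sa(china_config)
        by_name = {e.parameter: e for e in entries}
        assert by_name["cost.ae.neutropenia"].width == pytest.approx(0.0, abs=1e-9)

    def test_addon_drug_price_is_the_widest_bar(self, usa_config):
        entries = one_way_sa(usa_config)
        assert entries[0].parameter == "cost.drug.tucatinib"


class TestSubgroup:
    def test_identity_substitution_is_a_noop(self, china_config):
        base = evaluate_scenario(china_config)
        same = subgroup_run(china_config, china_config.survival)
        assert same.icer == pytest.approx(base.icer, rel=1e-12)

    def test_brain_metastasis_subgroup_lowers_icer(self, china_config):
        res = subgroup_run(china_config, china_config.subgroups["brain_metastases"])
        base = evaluate_scenario(china_config)
        assert res.delta_effect > base.delta_effect
        assert res.icer < base.icer
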