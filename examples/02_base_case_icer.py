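"""Base-case cost-effectiveness of the triplet vs the doublet regimen.

Loads the packaged US and China payer scenarios (costs per 3-week cycle,
utilities 0.86/0.71, 3% annual discounting, survival pinned to the trial's
median PFS/OS), runs the three-state cohort model over 10 years for both
arms, and prints discounted totals and the incremental cost-effectiveness
ratio against each country's willingness-to-pay threshold.
"""

from markovcea import (
    evaluate_scenario,
    icer,
    load_config,
    packaged_config_path,
    run_arm,
    subgroup_run,
    wtp_decision,
)

for name in ("usa_base", "china_base"):
    config = load_config(packaged_config_path(name))
    print(f"\n=== {config.country} (WTP ${config.wtp:,.2f}/QALY) ===")
    outcomes = {arm: run_arm(arm, config) for arm in config.arms()}
    for arm, o in outcomes.items():
        print(f"  {arm:3s}: cost ${o.cost:>10,.2f}   QALYs {o.qaly:.3f}   LYs {o.life_years:.3f}")
    res = icer(outcomes[config.comparator_arm], outcomes[config.intervention_arm])
    dec = wtp_decision(res.delta_cost, res.delta_effect, config.wtp)
    print(
        f"  incremental: ${res.delta_cost:,.2f} for {res.delta_effect:.3f} QALYs "
        f"-> ICER ${res.icer:,.2f}/QALY ({'' if dec.cost_effective else 'not '}cost-effective)"
    )
    sub = subgroup_run(config, config.subgroups["brain_metastases"])
    print(f"  brain-metastasis subgroup ICER: ${sub.icer:,.2f}/QALY")
# An ICER above the threshold means the added survival of the triplet costs
# more per quality-adjusted life-year than the payer is willing to spend.
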