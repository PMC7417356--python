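"""Simulate a trial arm, digitize its KM curve, and recover the Weibull fit.

Builds a 5,000-patient cohort from a known Weibull survival law (median 7.8
months, mild wear-out), estimates its Kaplan-Meier curve, samples 50 evenly
spaced points with small vertical noise the way a plot digitizer would, and
fits the Weibull back — the same route the cohort model uses to turn a
published survival figure into transition probabilities.
"""

import numpy as np

from markovcea import (
    calibrate_scale_to_median,
    emulate_digitization,
    fit_weibull,
    kaplan_meier,
    median_survival,
    numbers_at_risk,
    reconstruct_interval_counts,
    simulate_survival_times,
)

true = calibrate_scale_to_median(7.8, 1.1)
print(f"true parameters: lambda={true.scale_lambda:.5f}, gamma={true.shape_gamma}")

ipd = simulate_survival_times(true, n=5_000, max_follow_up=24.0, censor_rate=0.01, seed=7)
km = kaplan_meier(ipd)
digitized = emulate_digitization(km, n_points=50, noise_sd=0.005, seed=8)
risk = numbers_at_risk(ipd, np.linspace(0.0, 24.0, 9))

counts = reconstruct_interval_counts(digitized, risk)
print(f"events: {int(ipd.event.sum())} true, {int(counts.events.sum())} reconstructed")

weights = np.concatenate([[0.0], counts["events"].to_numpy(float)])
fit = fit_weibull(digitized, weights=weights)
print(
    f"fitted:  lambda={fit.params.scale_lambda:.5f}, gamma={fit.params.shape_gamma:.4f}, "
    f"median={median_survival(fit.params):.2f} months"
)
# The fitted median should land within a few percent of the generating 7.8
# months — the digitization step loses very little information at this size.
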