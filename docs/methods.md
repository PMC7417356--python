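# Methods

## Model structure

A cohort-level state-transition (Markov) model with three states:
progression-free survival (PFS), progressed disease (PD), and death. The
cycle length is 21 days (matching the treatment schedule); a 10-year horizon
gives ⌈10 · 365.25 / 21⌉ = 174 cycles, accrued half-open over cycles
0..173. The cohort enters 100% progression-free.

Transitions per cycle k, with Weibull survivor functions
S(t) = exp(−λt^γ) re-expressed on the cycle timescale:

- **PFS → PD**: p = 1 − exp(λ k^γ − λ(k+1)^γ) from the arm's PFS curve.
  This identity equals 1 − S(k+1)/S(k), the conditional exit probability,
  and telescopes so that the product of survivals over cycles reproduces
  S(k) exactly (tested to 1e−10).
- **PFS → death**: background mortality from a life table,
  1 − (1 − q_annual(⌊age⌋))^(21/365.25), with age advancing by 21/365.25
  years per cycle (start age 55 by default; configurable — the source
  analysis does not state it).
- **PD → death**: the same transition formula applied to the arm's OS curve,
  indexed by model time.

If PFS→PD plus background mortality exceed 1 (possible only under extreme
configurations), the pair is rescaled proportionally, preserving the hazard
ratio. Death is absorbing.

**Structural approximation.** Driving PD→death with the *marginal* OS curve
ignores (a) that OS hazard conditional on progression exceeds the marginal
hazard, and (b) the PFS→death pathway's contribution to OS. Consequently
the model's all-cause death accrual is slower than the OS curve itself and
life-year totals exceed the trial's restricted means. This is the
conventional simplification in three-state oncology models built from
published survival figures; its effect is quantified below under
*Calibration and what it reproduces*.

## Timescale convention

Kaplan–Meier axes are in months; the transition formula indexes cycles.
Fits are performed in months and rescaled once via λ_cycle = λ_month · c^γ
with c = 21/30.4375 months per cycle, so cycle indices can be used bare.
`rescale_time` carries the exact identity S_cycle(k) = S_month(ck).

## Survival inputs and fitting

Published survival figures are turned into parameters by:

1. **Digitization emulation** (`emulate_digitization`): 50 points (default)
   on an even time grid, survival read from the step function with additive
   Gaussian noise (sd 0.005 by default) on the vertical axis only — the
   dominant plot-digitizer error mode — then clipped to [0,1] and made
   non-increasing. The point count and noise level of real digitization are
   not knowable from a published figure; both are configurable.
2. **Interval-count reconstruction** (`reconstruct_interval_counts`): events
   per inter-point interval ≈ n_at_risk · (S_start − S_end)/S_start, with
   censorings allocated at the printed numbers-at-risk anchors so the
   running risk set matches the figure's risk table.
3. **Weighted cloglog regression** (`fit_weibull`): ln(−ln S) is linear in
   ln t with intercept ln λ and slope γ; weighted least squares
   (statsmodels WLS) with weights proportional to reconstructed events.
   Points with S ∈ {0, 1} or t = 0 are dropped (transform undefined).
   Noiseless curves are recovered exactly; at 5,000 patients / 50 points /
   sd 0.005 both parameters come back within 10% (seeded test).
   Curves are repaired by pool-adjacent-violators isotonic regression
   before fitting; a point needing more than 0.10 of adjustment marks the
   curve malformed rather than noisy.

Synthetic cohorts use inverse-CDF Weibull sampling with independent
exponential censoring plus administrative censoring at end of follow-up
(the simplest mechanism that produces realistic risk tables; the source
analysis says nothing about censoring structure). Kaplan–Meier estimation
is delegated to lifelines. The life-table fixture is Gompertz-like
(q doubling every 8 years from 3·10⁻⁴ at age 18, capped at 0.999) and
loads through the same reader interface as a real national table.

## Calibration and what it reproduces

The source analysis never reports its four fitted (λ, γ) pairs, so exact
base-case totals are not recoverable. The packaged scenarios fix γ = 1.1
(mild wear-out) and solve λ from the published medians — PFS 7.8 vs 5.6
months, OS 21.9 vs 17.4 months (brain-metastasis subgroup: PFS 7.6 vs 5.4,
OS 18.1 vs 12.0). Under this calibration the pipeline reproduces the
published *qualitative* findings (both countries' ICERs above threshold,
P(cost-effective) = 0 at base thresholds, the add-on price dominating the
tornado, the subgroup ICER below base) and the China incremental cost to
within about a third, but yields ΔE ≈ 0.47 QALYs and a US incremental cost
of ≈ $232k against the published 0.21 / $147k: a Weibull with γ = 1.1 has
mean ≈ 1.35 × median, so mean time on treatment is far longer than the
published totals imply, and the marginal-OS simplification slows death
accrual further. The corresponding approximate-reproduction tests assert
the documented bands and record this known divergence; the calibration is
not tuned to close it, because any γ chosen to match the published totals
would be unsupported by published evidence.

## Costs, utilities, discounting

All costs in USD (Chinese costs converted at ¥6.9851/$, February 2020;
`inflate_cost` adjusts historical prices by CPI ratio). Per 21-day cycle:
drug acquisition (tucatinib + trastuzumab + capecitabine in the triplet
arm; the backbone pair in the doublet) and CT imaging accrue in PFS only —
treatment runs until progression; best supportive care accrues in PD.
Grade 3–4 adverse-event management is a one-time expected cost
(Σ incidence × unit cost) at model entry, undiscounted — the convention in
similar published models; the source states no timing. The trial's AE
incidences are not printed in the analysis; the fixtures carry documented
assumptions (e.g. hand-foot syndrome 13.1%/9.1%, diarrhea 12.9%/8.6%).
Utilities 0.86 (PFS) and 0.71 (PD). Costs and QALYs discount at 3%/year as
(1+r)^(−k·21/365.25); half-cycle correction is trapezoidal averaging of
boundary occupancies (the correction is named in the source but not its
method).

## Sensitivity analysis

- **One-way (tornado)**: every parameter in the registry (drug, BSC,
  imaging and AE unit costs; both utilities; discount rate over 0–5%) is
  set to its low and high — published interval where one exists, else ±30%
  — with everything else at base; the full pipeline re-runs and entries are
  sorted by ICER range width. A failed single run flags that entry (NaN)
  without aborting.
- **Probabilistic**: 1,000 Monte-Carlo draws (default). Costs sample gamma,
  utilities beta, both moment-matched with shape/rate and α/β solved from
  (mean, se); se = (high − low)/(2·1.96), reading ranges as 95% intervals
  (the source gives ranges, never standard errors). The backbone drugs
  flagged "fixed in PSA" and the survival parameters (no distribution is
  given for them) stay at base; draws are mutually independent (no
  correlation structure is described); each draw gets its own RNG
  substream spawned from one user seed, so results are order-independent.
  Draw failures are excluded with a recorded count, capped at 1% of draws.
- **CEAC**: fraction of draws with WTP·ΔE − ΔC > 0 per grid point; the
  default grid spans 0 to twice the largest threshold in 200 points.
- **Subgroup**: identical pipeline with substituted survival inputs.

The discount-rate row of the published parameter table nominally carries a
beta mark; the sensitivity-analysis prose assigns beta to probabilities and
utilities only, so the rate is varied one-way (0–5%) and fixed in PSA.

## Numerical choices and degenerate inputs

- Trace conservation is maintained to 1e−12 over the full horizon
  (property-tested on 100 random configurations).
- Transition probabilities are clipped to [0, 1] after the exponential
  identity (guards only against floating-point underflow at extreme λ).
- KM estimation requires ≥ 1 event; fitting requires ≥ 4 usable points and
  a positive fitted slope; beta moment-matching rejects se² ≥ mean(1−mean).
- ICERs carry an explicit dominance taxonomy (dominant / dominated / ratio
  / undefined with signed infinity at ΔE = 0); the base analysis only
  occupies the ΔC > 0, ΔE > 0 quadrant.
- Reproducibility: identical configuration + seed produce byte-identical
  CSVs; every run writes a manifest with config digest, seed and outputs.

## What the synthetic data does and does not show

The generator emulates digitized survival figures with known ground truth,
exercising reconstruction and fitting end-to-end. It does not emulate:
reading error on the *time* axis, correlated operator error, risk tables
printed at coarse or irregular intervals, informative censoring, or cure
fractions. Passing tests therefore demonstrate correctness of the pipeline
mechanics and calibration-level fidelity, not agreement with any particular
trial's unpublished patient-level data.

## Known limitations

- No microsimulation, tunnel states, or treatment switching; post-
  progression care is best supportive care only.
- Single Weibull family (no log-logistic/log-normal/spline alternatives,
  no AIC machinery) — the modelled analysis used Weibull only.
- The marginal-OS PD→death simplification described above.
- Budget impact is a generic four-factor product
  (population · incidence · eligible fraction · ΔC); published national
  budget figures depend on uptake assumptions that are not printed and are
  not reproduced.
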