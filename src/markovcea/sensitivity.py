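"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis moves each parameter to the ends of its range (a published
confidence interval where available, otherwise ±30% of the base value) with
everything else at base, re-runs the whole pipeline and records the ICER.

Probabilistic analysis draws every uncertain parameter from a distribution
matched to its mean and standard error by the method of moments — gamma for
costs, beta for utilities and probabilities — re-runs the pipeline per draw
and summarises the (ΔCost, ΔQALY) cloud as cost-effectiveness acceptability
curves.  Parameters flagged as fixed (e.g. backbone drugs priced identically
in both arms, or the survival inputs, for which no distribution is given)
stay at base in every draw.  Standard errors derive from the ranges as
(high − low) / (2·1.96), i.e. ranges are read as 95% intervals.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .econ import ICERResult, icer, net_monetary_benefit
from .errors import InsufficientDataError, InvalidParameterError
from .markov import ScenarioConfig, run_arm
from .weibull import WeibullParams

__all__ = [
    "CEACPoint",
    "ParamSpec",
    "TornadoEntry",
    "default_range",
    "se_from_range",
    "build_param_specs",
    "apply_param",
    "evaluate_scenario",
    "one_way_sa",
    "gamma_from_mean_se",
    "beta_from_mean_se",
    "sample_psa_draw",
    "run_psa",
    "ceac",
    "default_wtp_grid",
    "subgroup_run",
]


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain input: base value, range and sampling distribution."""

    name: str
    base: float
    low: float
    high: float
    distribution: str  # 'gamma' | 'beta' | 'fixed'

    def __post_init__(self):
        if not (self.low <= self.base <= self.high):
            raise InvalidParameterError(
                f"{self.name}: need low <= base <= high, got {self.low}, {self.base}, {self.high}"
            )
        if self.distribution not in ("gamma", "beta", "fixed"):
            raise InvalidParameterError(f"{self.name}: unknown distribution {self.distribution!r}")
        if self.distribution == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise InvalidParameterError(f"{self.name}: beta requires values in [0, 1]")

    @property
    def se(self) -> float:
        return se_from_range(self.low, self.high)


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability: float

    def __post_init__(self):
        if not (0.0 <= self.probability <= 1.0):
            raise InvalidParameterError("probability must lie in [0, 1]")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_low: float
    icer_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def default_range(base: float, fraction: float = 0.30) -> tuple[float, float]:
    """Symmetric ±fraction range around the base value."""
    if base < 0:
        raise InvalidParameterError(f"base must be >= 0, got {base}")
    if not (0.0 <= fraction < 1.0):
        raise InvalidParameterError(f"fraction must be in [0, 1), got {fraction}")
    return (base * (1.0 - fraction), base * (1.0 + fraction))


def se_from_range(low: float, high: float) -> float:
    """Standard error implied by reading (low, high) as a 95% interval."""
    if high < low:
        raise InvalidParameterError("high must be >= low")
    return (high - low) / (2.0 * 1.959963984540054)


# -- parameter registry ----------------------------------------------------
#
# Every uncertain scalar gets a dotted name and a setter acting on a deep
# copy of the config; tornado and PSA both walk this registry so a parameter
# added here is automatically covered by both analyses.

def _set_drug(cfg: ScenarioConfig, drug: str, v: float) -> None:
    cfg.drug_cost[drug] = v


def _set_ae(cfg: ScenarioConfig, event: str, v: float) -> None:
    cfg.ae_unit_cost[event] = v


_SCALAR_FIELDS = {
    "cost.bsc": ("bsc_cost_per_cycle", "gamma"),
    "cost.imaging": ("imaging_cost_per_cycle", "gamma"),
    "utility.pfs": ("utility_pfs", "beta"),
    "utility.pd": ("utility_pd", "beta"),
    "discount_rate": ("discount_rate", "fixed"),
}


def apply_param(config: ScenarioConfig, name: str, value: float) -> None:
    """Set parameter ``name`` to ``value`` in-place (use on a deep copy)."""
    if name in _SCALAR_FIELDS:
        setattr(config, _SCALAR_FIELDS[name][0], value)
    elif name.startswith("cost.drug."):
        _set_drug(config, name.removeprefix("cost.drug."), value)
    elif name.startswith("cost.ae."):
        _set_ae(config, name.removeprefix("cost.ae."), value)
    else:
        raise InvalidParameterError(f"unknown parameter name {name!r}")


def build_param_specs(config: ScenarioConfig) -> list[ParamSpec]:
    """Enumerate the scenario's uncertain parameters as ParamSpecs.

    Ranges come from ``config.ranges`` (verbatim published intervals) when
    present, otherwise ±30%.  Cost parameters sample gamma; utilities beta;
    the discount rate and the drugs named in ``config.psa_fixed`` are varied
    one-way only and held fixed in PSA.
    """
    specs: list[ParamSpec] = []

    def rng_for(name: str, base: float) -> tuple[float, float]:
        return config.ranges.get(name, default_range(base))

    for drug, cost in sorted(config.drug_cost.items()):
        name = f"cost.drug.{drug}"
        low, high = rng_for(name, cost)
        dist = "fixed" if drug in config.psa_fixed else "gamma"
        specs.append(ParamSpec(name, cost, low, high, dist))
    for event, cost in sorted(config.ae_unit_cost.items()):
        name = f"cost.ae.{event}"
        low, high = rng_for(name, cost)
        specs.append(ParamSpec(name, cost, low, high, "gamma"))
    for name, (attr, dist) in _SCALAR_FIELDS.items():
        base = getattr(config, attr)
        if name == "discount_rate":
            low, high = config.ranges.get(name, (0.0, 0.05))
        else:
            low, high = rng_for(name, base)
            if dist == "beta":
                high = min(high, 1.0)
        specs.append(ParamSpec(name, base, low, high, dist))
    return specs


def evaluate_scenario(config: ScenarioConfig) -> ICERResult:
    """Run both arms through the cohort model and return the ICER."""
    comp = run_arm(config.comparator_arm, config)
    intv = run_arm(config.intervention_arm, config)
    return icer(comp, intv)


def one_way_sa(
    config: ScenarioConfig,
    specs: list[ParamSpec] | None = None,
    runner=evaluate_scenario,
) -> list[TornadoEntry]:
    """Tornado analysis: one entry per parameter, sorted by descending width.

    A failing single run flags the entry with NaN ICERs instead of aborting
    the whole analysis.
    """
    if specs is None:
        specs = build_param_specs(config)
    entries = []
    for spec in specs:
        icers = []
        for v in (spec.low, spec.high):
            cfg = copy.deepcopy(config)
            apply_param(cfg, spec.name, v)
            try:
                icers.append(runner(cfg).icer)
            except Exception:
                icers.append(float("nan"))
        entries.append(
            TornadoEntry(
                parameter=spec.name,
                low_value=spec.low,
                high_value=spec.high,
                icer_low=icers[0],
                icer_high=icers[1],
            )
        )
    entries.sort(key=lambda e: (np.isnan(e.width), -(0 if np.isnan(e.width) else e.width)))
    return entries


def gamma_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Method of moments for a gamma law: shape = mean²/se², rate = mean/se²."""
    if not (mean > 0 and se > 0):
        raise InvalidParameterError(f"gamma moments need mean > 0 and se > 0, got {mean}, {se}")
    return (mean**2 / se**2, mean / se**2)


def beta_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Method of moments for a beta law on (0, 1); requires se² < mean(1−mean)."""
    if not (0.0 < mean < 1.0):
        raise InvalidParameterError(f"beta mean must be in (0, 1), got {mean}")
    if not se > 0:
        raise InvalidParameterError(f"se must be positive, got {se}")
    v = mean * (1.0 - mean)
    if se**2 >= v:
        raise InvalidParameterError(
            f"infeasible beta moments: se^2 = {se**2:.5g} >= mean(1-mean) = {v:.5g}"
        )
    nu = v / se**2 - 1.0
    return (mean * nu, (1.0 - mean) * nu)


def sample_psa_draw(specs: list[ParamSpec], rng: np.random.Generator) -> dict[str, float]:
    """One independent draw of every sampled parameter; fixed ones stay at base."""
    out: dict[str, float] = {}
    for spec in specs:
        if spec.distribution == "fixed" or spec.se == 0.0:
            out[spec.name] = spec.base
        elif spec.distribution == "gamma":
            if spec.base == 0.0:
                out[spec.name] = 0.0
                continue
            shape, rate = gamma_from_mean_se(spec.base, spec.se)
            out[spec.name] = float(rng.gamma(shape, 1.0 / rate))
        else:  # beta
            a, b = beta_from_mean_se(spec.base, spec.se)
            out[spec.name] = float(rng.beta(a, b))
    return out


def run_psa(
    config: ScenarioConfig,
    specs: list[ParamSpec] | None = None,
    n_draws: int = 1000,
    seed: int | None = None,
    runner=evaluate_scenario,
) -> pd.DataFrame:
    """Monte-Carlo PSA: n_draws full pipeline evaluations under sampled inputs.

    Returns a frame with columns ``draw, delta_cost, delta_qaly``.  Each draw
    uses its own RNG substream spawned from the single user seed, so results
    do not depend on evaluation order.  Failed draws (at most 1%) are dropped;
    ``frame.attrs['n_failed']`` records how many.
    """
    if specs is None:
        specs = build_param_specs(config)
    streams = np.random.SeedSequence(seed).spawn(n_draws)
    rows, n_failed = [], 0
    for i, ss in enumerate(streams):
        assignment = sample_psa_draw(specs, np.random.default_rng(ss))
        cfg = copy.deepcopy(config)
        for name, v in assignment.items():
            apply_param(cfg, name, v)
        try:
            res = runner(cfg)
        except Exception:
            n_failed += 1
            if n_failed > max(1, n_draws // 100):
                raise
            continue
        rows.append((i, res.delta_cost, res.delta_effect))
    df = pd.DataFrame(rows, columns=["draw", "delta_cost", "delta_qaly"])
    df.attrs["n_failed"] = n_failed
    return df


def ceac(psa_results: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Probability of positive net monetary benefit at each WTP value."""
    if len(psa_results) == 0:
        raise InsufficientDataError("PSA produced no results")
    dc = psa_results["delta_cost"].to_numpy(dtype=float)
    de = psa_results["delta_qaly"].to_numpy(dtype=float)
    grid = np.asarray(wtp_grid, dtype=float)
    prob = [(net_monetary_benefit(dc, de, w) > 0).mean() for w in grid]
    return pd.DataFrame({"wtp": grid, "probability": prob})


def default_wtp_grid(max_wtp: float, n_points: int = 200) -> np.ndarray:
    """0 to twice the largest threshold analysed, evenly spaced."""
    return np.linspace(0.0, 2.0 * max_wtp, n_points)


def subgroup_run(
    config: ScenarioConfig, subgroup_survival: dict[str, dict[str, WeibullParams]]
) -> ICERResult:
    """Re-run the pipeline with substituted survival inputs (e.g. a trial subgroup)."""
    return evaluate_scenario(config.with_survival(subgroup_survival))
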