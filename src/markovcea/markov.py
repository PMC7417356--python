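"""Three-state cohort model: progression-free (PFS), progressed (PD), death.

The cohort starts 100% progression-free and is propagated in fixed treatment
cycles (3 weeks by default) over a multi-year horizon.  Transitions per cycle:

* PFS -> PD   from the arm's PFS Weibull via the time-dependent formula
              p(t) = 1 - exp(lam t^gamma - lam (t+1)^gamma), t = cycle index;
* PFS -> death from a life table (background, age-advancing mortality);
* PD  -> death from the arm's OS Weibull via the same formula.

Death is absorbing.  Using the marginal OS law for the PD->death hazard is a
deliberate simplification (it ignores the small contribution of PFS-state
deaths to overall survival); the methods note discusses the consequences.

Costs and utilities accrue per cycle against half-cycle-corrected occupancy
(trapezoidal average of the occupancy at the two cycle boundaries) and are
discounted at an annual rate.  Drug acquisition and imaging costs accrue in
the PFS state only (treatment runs until progression); best supportive care
accrues in PD; adverse-event management is a one-time expected cost at entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDataError
from .synthetic import LifeTable
from .weibull import WeibullParams, cycle_transition_probability, rescale_time

__all__ = [
    "DAYS_PER_YEAR",
    "DAYS_PER_MONTH",
    "STATES",
    "ScenarioConfig",
    "CohortTrace",
    "ArmOutcome",
    "background_mortality_cycle",
    "build_transition_matrix",
    "run_cohort",
    "half_cycle_corrected_occupancy",
    "discount_factor",
    "accrue_outcomes",
    "run_arm",
]

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0  # 30.4375
STATES = ("pfs", "pd", "death")


@dataclass
class ScenarioConfig:
    """All inputs for one country scenario.

    Costs are in USD.  Drug costs are per treatment cycle; ``arm_drugs`` maps
    an arm label to the drugs it administers, so the triplet arm carries the
    doublet's backbone costs plus the add-on drug.  ``survival`` maps
    arm -> endpoint ('pfs'|'os') -> WeibullParams on the *month* timescale;
    the engine rescales them to cycles internally.
    """

    country: str
    wtp: float
    drug_cost: dict[str, float]
    arm_drugs: dict[str, list[str]]
    imaging_cost_per_cycle: float
    bsc_cost_per_cycle: float
    ae_unit_cost: dict[str, float]
    ae_incidence: dict[str, dict[str, float]]
    utility_pfs: float
    utility_pd: float
    survival: dict[str, dict[str, WeibullParams]]
    life_table: LifeTable
    cycle_length_days: float = 21.0
    horizon_years: float = 10.0
    start_age: float = 55.0
    discount_rate: float = 0.03
    intervention_arm: str = "TXT"
    comparator_arm: str = "TX"
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    psa_fixed: tuple[str, ...] = ("trastuzumab", "capecitabine")
    #: optional named survival substitutions, e.g. a brain-metastasis subgroup
    subgroups: dict[str, dict[str, dict[str, WeibullParams]]] = field(default_factory=dict)

    # -- derived quantities --------------------------------------------
    @property
    def n_cycles(self) -> int:
        return math.ceil(self.horizon_years * DAYS_PER_YEAR / self.cycle_length_days)

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    @property
    def cycle_months(self) -> float:
        return self.cycle_length_days / DAYS_PER_MONTH

    def arms(self) -> tuple[str, str]:
        return (self.comparator_arm, self.intervention_arm)

    def drug_cost_per_cycle(self, arm: str) -> float:
        try:
            drugs = self.arm_drugs[arm]
        except KeyError:
            raise ConfigError(f"arm_drugs: no drug list for arm {arm!r}")
        try:
            return float(sum(self.drug_cost[d] for d in drugs))
        except KeyError as exc:
            raise ConfigError(f"drug_cost: missing cost for drug {exc.args[0]!r} (arm {arm!r})")

    def ae_expected_cost(self, arm: str) -> float:
        try:
            inc = self.ae_incidence[arm]
        except KeyError:
            raise ConfigError(f"ae_incidence: no entry for arm {arm!r}")
        total = 0.0
        for name, p in inc.items():
            if name not in self.ae_unit_cost:
                raise ConfigError(f"ae_unit_cost: missing unit cost for event {name!r}")
            total += p * self.ae_unit_cost[name]
        return float(total)

    def survival_params_cycle(self, arm: str, endpoint: str) -> WeibullParams:
        """Arm/endpoint Weibull re-expressed on the cycle timescale."""
        try:
            monthly = self.survival[arm][endpoint]
        except KeyError:
            raise ConfigError(f"survival: missing params for arm {arm!r}, endpoint {endpoint!r}")
        return rescale_time(monthly, self.cycle_months)

    def validate(self) -> "ScenarioConfig":
        if not (0.0 <= self.discount_rate <= 0.05):
            raise ConfigError(f"discount_rate: must be in [0, 0.05], got {self.discount_rate}")
        for key, u in (("utility_pfs", self.utility_pfs), ("utility_pd", self.utility_pd)):
            if not (0.0 <= u <= 1.0):
                raise ConfigError(f"{key}: utility must be in [0, 1], got {u}")
        if not self.horizon_years > 0:
            raise ConfigError(f"horizon_years: must be positive, got {self.horizon_years}")
        if not self.cycle_length_days > 0:
            raise ConfigError(f"cycle_length_days: must be positive, got {self.cycle_length_days}")
        if self.wtp < 0:
            raise ConfigError(f"wtp: must be >= 0, got {self.wtp}")
        for name, c in self.drug_cost.items():
            if c < 0:
                raise ConfigError(f"drug_cost.{name}: must be >= 0, got {c}")
        for name, c in self.ae_unit_cost.items():
            if c < 0:
                raise ConfigError(f"ae_unit_cost.{name}: must be >= 0, got {c}")
        for key, c in (
            ("imaging_cost_per_cycle", self.imaging_cost_per_cycle),
            ("bsc_cost_per_cycle", self.bsc_cost_per_cycle),
        ):
            if c < 0:
                raise ConfigError(f"{key}: must be >= 0, got {c}")
        for arm in self.arms():
            self.drug_cost_per_cycle(arm)
            self.ae_expected_cost(arm)
            for endpoint in ("pfs", "os"):
                self.survival_params_cycle(arm, endpoint)
        return self

    def with_survival(self, survival: dict[str, dict[str, WeibullParams]]) -> "ScenarioConfig":
        """Copy with substituted survival inputs (subgroup re-runs)."""
        return replace(self, survival=survival)


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy at each cycle boundary; rows sum to one."""

    occupancy: np.ndarray  # (n_cycles + 1, 3) in STATES order
    times_years: np.ndarray

    @property
    def pfs(self) -> np.ndarray:
        return self.occupancy[:, 0]

    @property
    def pd(self) -> np.ndarray:
        return self.occupancy[:, 1]

    @property
    def death(self) -> np.ndarray:
        return self.occupancy[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.times_years)),
                "time_years": self.times_years,
                "pfs": self.pfs,
                "pd": self.pd,
                "death": self.death,
            }
        )


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted and undiscounted totals for one arm."""

    arm: str
    cost: float
    qaly: float
    life_years: float
    cost_undiscounted: float
    qaly_undiscounted: float
    life_years_undiscounted: float


def background_mortality_cycle(life_table: LifeTable, age: float, cycle_length_days: float) -> float:
    """Per-cycle death probability from the annual q of the attained age.

    Converts the annual probability to the cycle length assuming a constant
    hazard within the year: 1 - (1 - q)^(cycle_days / 365.25).  Ages outside
    the table clamp to its first/last row.
    """
    q = life_table.annual_q(age)
    return 1.0 - (1.0 - q) ** (cycle_length_days / DAYS_PER_YEAR)


def _per_cycle_probabilities(arm: str, config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (p_pfs_to_pd, p_pfs_to_death, p_pd_to_death) over all cycles."""
    n = config.n_cycles
    k = np.arange(n)
    p_prog = cycle_transition_probability(config.survival_params_cycle(arm, "pfs"), k)
    p_os = cycle_transition_probability(config.survival_params_cycle(arm, "os"), k)
    ages = config.start_age + k * config.cycle_years
    p_bg = np.array(
        [background_mortality_cycle(config.life_table, a, config.cycle_length_days) for a in ages]
    )
    return np.asarray(p_prog), p_bg, np.asarray(p_os)


def build_transition_matrix(
    cycle_index: int, arm: str, config: ScenarioConfig, current_age: float | None = None
) -> np.ndarray:
    """Row-stochastic 3x3 matrix for one cycle, states ordered (PFS, PD, death).

    If progression and background mortality together exceed one, the pair is
    rescaled proportionally so the PFS row stays a probability vector.
    """
    if cycle_index < 0:
        raise ConfigError("cycle_index must be >= 0")
    age = (
        config.start_age + cycle_index * config.cycle_years
        if current_age is None
        else current_age
    )
    p_prog = cycle_transition_probability(
        config.survival_params_cycle(arm, "pfs"), cycle_index
    )
    p_bg = background_mortality_cycle(config.life_table, age, config.cycle_length_days)
    p_os = cycle_transition_probability(config.survival_params_cycle(arm, "os"), cycle_index)
    exit_total = p_prog + p_bg
    if exit_total > 1.0:
        p_prog, p_bg = p_prog / exit_total, p_bg / exit_total
    m = np.array(
        [
            [1.0 - p_prog - p_bg, p_prog, p_bg],
            [0.0, 1.0 - p_os, p_os],
            [0.0, 0.0, 1.0],
        ]
    )
    if np.any(m < -1e-12):
        raise ConfigError("internal consistency: negative transition probability")
    return np.clip(m, 0.0, 1.0)


def run_cohort(arm: str, config: ScenarioConfig) -> CohortTrace:
    """Propagate the cohort from 100% PFS through every cycle of the horizon."""
    n = config.n_cycles
    p_prog, p_bg, p_os = _per_cycle_probabilities(arm, config)
    # proportional rescale where competing PFS exits overflow
    overflow = p_prog + p_bg
    scale = np.where(overflow > 1.0, 1.0 / np.maximum(overflow, 1e-300), 1.0)
    p_prog, p_bg = p_prog * scale, p_bg * scale

    occ = np.zeros((n + 1, 3))
    occ[0, 0] = 1.0
    for k in range(n):
        pfs, pd_, dead = occ[k]
        occ[k + 1, 0] = pfs * (1.0 - p_prog[k] - p_bg[k])
        occ[k + 1, 1] = pd_ * (1.0 - p_os[k]) + pfs * p_prog[k]
        occ[k + 1, 2] = dead + pd_ * p_os[k] + pfs * p_bg[k]
    times = np.arange(n + 1) * config.cycle_years
    return CohortTrace(occupancy=occ, times_years=times)


def half_cycle_corrected_occupancy(trace: CohortTrace) -> np.ndarray:
    """Trapezoidal occupancy: mean of consecutive boundary rows, one row per cycle."""
    if trace.occupancy.shape[0] < 2:
        raise InsufficientDataError("half-cycle correction needs a trace with >= 2 rows")
    return 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])


def discount_factor(cycle_index, config: ScenarioConfig):
    """(1 + r)^(-t) with t the cycle's start in years; accepts arrays."""
    k = np.asarray(cycle_index, dtype=float)
    out = (1.0 + config.discount_rate) ** (-k * config.cycle_years)
    return float(out) if np.ndim(cycle_index) == 0 else out


def accrue_outcomes(trace: CohortTrace, arm: str, config: ScenarioConfig) -> ArmOutcome:
    """Sum half-cycle-corrected, discounted costs, QALYs and life-years.

    Per cycle: cost = PFS·(drug + imaging) + PD·BSC; utility-weighted time =
    (PFS·u_pfs + PD·u_pd)·cycle_years.  The expected adverse-event management
    cost (incidence × unit cost, summed over events) is added once,
    undiscounted, at model entry.
    """
    hc = half_cycle_corrected_occupancy(trace)
    n = hc.shape[0]
    disc = discount_factor(np.arange(n), config)
    drug = config.drug_cost_per_cycle(arm)
    cost_per_cycle = hc[:, 0] * (drug + config.imaging_cost_per_cycle) + hc[:, 1] * config.bsc_cost_per_cycle
    qaly_per_cycle = (hc[:, 0] * config.utility_pfs + hc[:, 1] * config.utility_pd) * config.cycle_years
    ly_per_cycle = (hc[:, 0] + hc[:, 1]) * config.cycle_years
    ae = config.ae_expected_cost(arm)
    return ArmOutcome(
        arm=arm,
        cost=float(np.sum(disc * cost_per_cycle) + ae),
        qaly=float(np.sum(disc * qaly_per_cycle)),
        life_years=float(np.sum(disc * ly_per_cycle)),
        cost_undiscounted=float(np.sum(cost_per_cycle) + ae),
        qaly_undiscounted=float(np.sum(qaly_per_cycle)),
        life_years_undiscounted=float(np.sum(ly_per_cycle)),
    )


def run_arm(arm: str, config: ScenarioConfig) -> ArmOutcome:
    """Convenience: cohort propagation followed by accrual."""
    return accrue_outcomes(run_cohort(arm, config), arm, config)
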