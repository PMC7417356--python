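"""Incremental cost-effectiveness arithmetic and currency helpers."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError
from .markov import ArmOutcome

__all__ = [
    "DEFAULT_CNY_PER_USD",
    "ICERResult",
    "WTPDecision",
    "icer",
    "icer_from_deltas",
    "net_monetary_benefit",
    "wtp_decision",
    "convert_currency",
    "inflate_cost",
    "price_drop_percent",
    "budget_impact",
]

#: CNY per USD exchange rate used for cost conversion (February 2020).
DEFAULT_CNY_PER_USD = 6.9851


@dataclass(frozen=True)
class ICERResult:
    """Incremental cost, incremental effect and their ratio (or a dominance label).

    ``label`` is ``"ratio"`` in the ordinary trade-off quadrants,
    ``"dominant"`` when the intervention saves money and gains QALYs
    (ΔC < 0, ΔE > 0), ``"dominated"`` in the opposite case, and
    ``"undefined"`` when ΔE = 0 with ΔC ≠ 0 (icer reported as signed inf).
    """

    delta_cost: float
    delta_effect: float
    icer: float
    label: str
    intervention: str = "TXT"
    comparator: str = "TX"


@dataclass(frozen=True)
class WTPDecision:
    wtp: float
    cost_effective: bool
    nmb: float


def icer_from_deltas(
    delta_cost: float,
    delta_effect: float,
    intervention: str = "TXT",
    comparator: str = "TX",
) -> ICERResult:
    """Classify the incremental pair and compute ΔC/ΔE where it is meaningful."""
    if delta_effect > 0 and delta_cost < 0:
        label, ratio = "dominant", delta_cost / delta_effect
    elif delta_effect < 0 and delta_cost > 0:
        label, ratio = "dominated", delta_cost / delta_effect
    elif delta_effect == 0:
        if delta_cost == 0:
            label, ratio = "ratio", 0.0
        else:
            label, ratio = "undefined", math.copysign(math.inf, delta_cost)
    else:
        label, ratio = "ratio", delta_cost / delta_effect
    return ICERResult(
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=ratio,
        label=label,
        intervention=intervention,
        comparator=comparator,
    )


def icer(comparator: ArmOutcome, intervention: ArmOutcome) -> ICERResult:
    """ICER of the intervention arm against the comparator (discounted totals)."""
    return icer_from_deltas(
        delta_cost=intervention.cost - comparator.cost,
        delta_effect=intervention.qaly - comparator.qaly,
        intervention=intervention.arm,
        comparator=comparator.arm,
    )


def net_monetary_benefit(delta_cost: float, delta_effect: float, wtp: float) -> float:
    """NMB = WTP·ΔE − ΔC; positive iff cost-effective at that threshold."""
    if wtp < 0:
        raise InvalidParameterError(f"wtp must be >= 0, got {wtp}")
    return wtp * delta_effect - delta_cost


def wtp_decision(delta_cost: float, delta_effect: float, wtp: float) -> WTPDecision:
    nmb = net_monetary_benefit(delta_cost, delta_effect, wtp)
    return WTPDecision(wtp=wtp, cost_effective=nmb > 0, nmb=nmb)


def convert_currency(amount_cny: float, cny_per_usd: float = DEFAULT_CNY_PER_USD) -> float:
    """CNY -> USD at the configured exchange rate."""
    if amount_cny < 0:
        raise InvalidParameterError(f"amount must be >= 0, got {amount_cny}")
    if not cny_per_usd > 0:
        raise InvalidParameterError("exchange rate must be positive")
    return amount_cny / cny_per_usd


def inflate_cost(amount: float, cpi_from: float, cpi_to: float) -> float:
    """Re-express a historical cost at another price level: amount · cpi_to / cpi_from."""
    if not (cpi_from > 0 and cpi_to > 0):
        raise InvalidParameterError("CPI indices must be positive")
    return amount * cpi_to / cpi_from


def price_drop_percent(list_price: float, paid_price: float) -> float:
    """Percent reduction of the paid price relative to the list price.

    A paid price above list yields a negative drop; it is returned as-is so
    callers can flag it.
    """
    if not list_price > 0:
        raise InvalidParameterError(f"list_price must be positive, got {list_price}")
    return 100.0 * (1.0 - paid_price / list_price)


def budget_impact(
    delta_cost_per_patient: float,
    population: float,
    incidence_per_100k: float,
    her2_fraction: float,
) -> float:
    """Annual budget impact: population · incidence · eligible fraction · ΔC."""
    for name, v in (
        ("delta_cost_per_patient", delta_cost_per_patient),
        ("population", population),
        ("incidence_per_100k", incidence_per_100k),
        ("her2_fraction", her2_fraction),
    ):
        if v < 0:
            raise InvalidParameterError(f"{name} must be >= 0, got {v}")
    return population * (incidence_per_100k / 1e5) * her2_fraction * delta_cost_per_patient
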