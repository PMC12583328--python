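"""Cost-minimization scenarios: discounts on robotic equipment/consumables.

The robotic arm's ratio-adjusted per-procedure cost (see
:mod:`endocost.scale_model`) is affine in two negotiable levers: a discount
d_e on the equipment purchase price (applied before amortization) and a
discount d_c on the per-procedure consumables mean,

    cost(d_e, d_c) = theatre + consumables·(1 − d_c) + stay
                     + price·(1 − d_e) / total_capacity.

Theatre and stay costs are facility rates and are never discounted. The
scenario grid crosses scale models with discount levels and flags where the
robotic cost converges with (drops to or below) the laparoscopic reference;
the break-even consumables discount at a given d_e follows in closed form
from the affine structure. Extending the lifespan of limited-use robotic
instruments is an equivalent lever: raising the number of uses from u to u'
acts like a consumables discount of 1 − u/u' (see
:func:`extended_uses_discount`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .cost_core import ArmCostSummary, ConfigurationError, EquipmentSpec, InvalidInputError
from .scale_model import ratio_adjusted_cost

__all__ = [
    "DiscountScenario",
    "UNREACHABLE",
    "discounted_cost",
    "scenario_grid",
    "break_even_consumables_discount",
    "extended_uses_discount",
    "DEFAULT_EQUIPMENT_DISCOUNTS",
    "DEFAULT_CONSUMABLES_DISCOUNTS",
]

DEFAULT_EQUIPMENT_DISCOUNTS: tuple[float, ...] = (0.0, 0.10, 0.15, 0.20)
DEFAULT_CONSUMABLES_DISCOUNTS: tuple[float, ...] = (0.30, 0.35)

#: Sentinel returned when no consumables discount below 100% reaches break-even.
UNREACHABLE = math.inf


@dataclass(frozen=True)
class DiscountScenario:
    """Discount fractions applied to the robotic arm, each in [0, 1)."""

    equipment_discount: float = 0.0
    consumables_discount: float = 0.0

    def __post_init__(self) -> None:
        for name, d in (
            ("equipment_discount", self.equipment_discount),
            ("consumables_discount", self.consumables_discount),
        ):
            if not (0 <= d < 1):
                raise ConfigurationError(f"{name} must be in [0, 1), got {d}")


def discounted_cost(
    rbt: ArmCostSummary,
    spec: EquipmentSpec,
    total_capacity: int,
    scenario: DiscountScenario,
) -> float:
    """Robotic ratio-adjusted cost under an equipment/consumables discount.

    Identity at (0, 0): equals :func:`ratio_adjusted_cost`. Strictly
    decreasing and affine in each discount fraction.
    """
    base = ratio_adjusted_cost(rbt, spec, total_capacity)
    return (
        base
        - rbt.component_means["consumables"] * scenario.consumables_discount
        - (spec.purchase_price / total_capacity) * scenario.equipment_discount
    )


def scenario_grid(
    rbt: ArmCostSummary,
    lps_cost_by_model: Mapping[int, float],
    spec: EquipmentSpec,
    capacities_by_model: Mapping[int, int],
    equipment_discounts: Sequence[float] = DEFAULT_EQUIPMENT_DISCOUNTS,
    consumables_discounts: Sequence[float] = DEFAULT_CONSUMABLES_DISCOUNTS,
) -> pd.DataFrame:
    """Cross scale models with discount levels; flag convergence.

    One row per (model k, d_e, d_c): robotic discounted cost, the
    model-specific laparoscopic reference cost, their difference and a
    ``converged`` flag (robotic ≤ laparoscopic).
    """
    if not equipment_discounts or not consumables_discounts:
        raise InvalidInputError("discount grids must be non-empty")
    if set(lps_cost_by_model) != set(capacities_by_model):
        raise InvalidInputError("models in costs and capacities must match")
    rows = []
    for k in sorted(capacities_by_model):
        for d_e in equipment_discounts:
            for d_c in consumables_discounts:
                cost = discounted_cost(
                    rbt,
                    spec,
                    capacities_by_model[k],
                    DiscountScenario(d_e, d_c),
                )
                lps_cost = lps_cost_by_model[k]
                rows.append(
                    {
                        "procedures_per_session": k,
                        "equipment_discount": d_e,
                        "consumables_discount": d_c,
                        "rbt_cost": cost,
                        "lps_cost": lps_cost,
                        "difference": cost - lps_cost,
                        "converged": cost <= lps_cost,
                    }
                )
    return pd.DataFrame(rows)


def break_even_consumables_discount(
    rbt: ArmCostSummary,
    lps_cost: float,
    spec: EquipmentSpec,
    total_capacity: int,
    equipment_discount: float = 0.0,
) -> float:
    """Smallest consumables discount at which robotic cost ≤ ``lps_cost``.

    Closed form from the affine cost:
    d_c* = (cost(d_e, 0) − lps_cost) / consumables mean, clipped to [0, 1).
    Returns 0.0 if already converged and :data:`UNREACHABLE` (``inf``) if no
    discount below 100% suffices.
    """
    consumables_mean = rbt.component_means["consumables"]
    if consumables_mean <= 0:
        raise ConfigurationError(
            "break-even undefined: consumables mean must be > 0"
        )
    at_de = discounted_cost(
        rbt, spec, total_capacity, DiscountScenario(equipment_discount, 0.0)
    )
    d_c = (at_de - lps_cost) / consumables_mean
    if d_c <= 0:
        return 0.0
    if d_c >= 1:
        return UNREACHABLE
    return d_c


def extended_uses_discount(current_uses: int, extended_uses: int) -> float:
    """Consumables discount equivalent to extending instrument lifespan.

    A limited-use instrument costed at unit price / uses drops its per-use
    cost by 1 − current/extended when certified for more uses.
    """
    if current_uses < 1 or extended_uses < current_uses:
        raise ConfigurationError(
            "need 1 <= current_uses <= extended_uses, got "
            f"{current_uses}, {extended_uses}"
        )
    return 1.0 - current_uses / extended_uses
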