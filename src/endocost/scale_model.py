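"""Stay-ratio economy-of-scale model for theatre capacity and cost.

The throughput of a surgical programme whose ideal minimally-invasive stay is
one admission day is capped by the *stay ratio*: surgeries performed divided
by the total admission days those surgeries generated, i.e. 1 / (mean stay).
A ratio of 1 means every case left after one day; the closer to 0, the fewer
cases can be scheduled without pushing the average stay above one day.

Capacity over an amortization horizon is then

    annual = round(sessions_per_year × procedures_per_session × ratio)
    total  = annual × amortization_years

and the ratio-adjusted per-procedure cost replaces the fixed-horizon
equipment depreciation share by purchase_price / total_capacity, keeping the
arm's observed theatre, consumables and stay mean costs. Comparing arms at
k = 1, 2, 3 procedures per session gives the three scale models, each with
the robotic cost overrun (absolute and as a percent of the robotic cost) and
the extra procedures enabled by the robotic arm's shorter stays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .cost_core import (
    ArmCostSummary,
    ConfigurationError,
    EmptyInputError,
    EquipmentSpec,
    InvalidInputError,
    PatientRecord,
)

__all__ = [
    "StayRatio",
    "ScaleScenario",
    "ScaleResult",
    "UndefinedRatioError",
    "stay_ratio",
    "capacity",
    "ratio_adjusted_cost",
    "compare_models",
    "results_to_frame",
]

StayPolicy = Literal["observed", "fixed_one_day"]


class UndefinedRatioError(InvalidInputError):
    """Stay ratio undefined (zero total admission days)."""


@dataclass(frozen=True)
class StayRatio:
    """Surgeries per admission day, in (0, 1] for stays of at least one day.

    ``value`` is the ratio rounded to 2 decimals, the precision at which it
    enters capacity planning; ``raw`` keeps full precision. ``source``
    records whether the ratio was computed from records or supplied as a
    reported override (useful to reproduce a published analysis verbatim).
    """

    value: float
    source: Literal["computed_from_records", "reported_override"]
    raw: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.value <= 1):
            raise InvalidInputError(f"stay ratio must be in (0, 1], got {self.value}")
        if self.raw is None:
            object.__setattr__(self, "raw", self.value)


@dataclass(frozen=True)
class ScaleScenario:
    """A session plan: k procedures per session, S sessions/year, Y years."""

    procedures_per_session: int
    sessions_per_year: int = 300
    amortization_years: int = 10

    def __post_init__(self) -> None:
        if self.procedures_per_session < 1:
            raise ConfigurationError("procedures_per_session must be >= 1")
        if self.sessions_per_year < 1:
            raise ConfigurationError("sessions_per_year must be >= 1")
        if self.amortization_years < 1:
            raise ConfigurationError("amortization_years must be >= 1")


@dataclass(frozen=True)
class ScaleResult:
    """One scale model: capacities, ratio-adjusted costs and robotic overrun."""

    procedures_per_session: int
    lps_annual_capacity: int
    lps_total_capacity: int
    rbt_annual_capacity: int
    rbt_total_capacity: int
    lps_adjusted_cost: float
    rbt_adjusted_cost: float

    @property
    def overrun(self) -> float:
        """Robotic minus laparoscopic adjusted cost (€ per procedure)."""
        return self.rbt_adjusted_cost - self.lps_adjusted_cost

    @property
    def overrun_pct(self) -> float:
        """Overrun as a percentage of the *robotic* adjusted cost."""
        return 100.0 * self.overrun / self.rbt_adjusted_cost

    @property
    def capacity_increase_annual(self) -> int:
        return self.rbt_annual_capacity - self.lps_annual_capacity

    @property
    def capacity_increase_total(self) -> int:
        return self.rbt_total_capacity - self.lps_total_capacity


def stay_ratio(records: Sequence[PatientRecord]) -> StayRatio:
    """Stay ratio of a cohort: number of surgeries / total admission days.

    Equals 1 / (mean stay). Rounded to 2 decimals in ``value`` (full
    precision kept in ``raw``); invariant to record order.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("cannot compute a stay ratio from zero records")
    total_days = sum(r.stay_days for r in records)
    if total_days <= 0:
        raise UndefinedRatioError("total admission days is zero; ratio undefined")
    raw = len(records) / total_days
    return StayRatio(
        value=min(round(raw, 2), 1.0), source="computed_from_records", raw=raw
    )


def capacity(ratio: StayRatio, scenario: ScaleScenario) -> tuple[int, int]:
    """(annual, total) procedure capacity under a session plan.

    annual = round(S × k × ratio); total = annual × Y exactly.
    """
    annual = int(
        round(scenario.sessions_per_year * scenario.procedures_per_session * ratio.value)
    )
    return annual, annual * scenario.amortization_years


def ratio_adjusted_cost(
    summary: ArmCostSummary,
    spec: EquipmentSpec,
    total_capacity: int,
    stay_policy: StayPolicy = "observed",
    stay_rate: float | None = None,
) -> float:
    """Per-procedure cost with equipment amortized over ``total_capacity``.

    theatre mean + consumables mean + stay mean + price / total_capacity.

    The stay component defaults to the arm's *observed* mean stay cost; with
    ``stay_policy="fixed_one_day"`` it is one day at ``stay_rate`` instead
    (the idealised one-day admission). The theatre mean is held constant
    across session plans: stacking procedures in a session does not change
    the billed minutes of each.
    """
    if total_capacity < 1:
        raise ConfigurationError(f"total_capacity must be >= 1, got {total_capacity}")
    if stay_policy == "observed":
        stay_component = summary.component_means["stay"]
    elif stay_policy == "fixed_one_day":
        if stay_rate is None:
            raise ConfigurationError("fixed_one_day policy requires stay_rate")
        stay_component = stay_rate
    else:
        raise ConfigurationError(f"unknown stay_policy {stay_policy!r}")
    return (
        summary.component_means["theatre"]
        + summary.component_means["consumables"]
        + stay_component
        + spec.purchase_price / total_capacity
    )


def compare_models(
    lps: ArmCostSummary,
    rbt: ArmCostSummary,
    lps_spec: EquipmentSpec,
    rbt_spec: EquipmentSpec,
    lps_ratio: StayRatio,
    rbt_ratio: StayRatio,
    scenarios: Sequence[ScaleScenario] | None = None,
    stay_policy: StayPolicy = "observed",
    stay_rate: float | None = None,
) -> list[ScaleResult]:
    """Run the scale models (default k = 1, 2, 3) for both arms.

    Each result pairs arm capacities with ratio-adjusted costs and the
    robotic overrun. Overrun percent uses the robotic cost as denominator.
    """
    if lps.arm == rbt.arm:
        raise InvalidInputError("compare_models needs summaries from distinct arms")
    if lps.arm.value != "LPS" or rbt.arm.value != "RBT":
        raise InvalidInputError("pass the laparoscopic summary first, robotic second")
    if scenarios is None:
        scenarios = [ScaleScenario(procedures_per_session=k) for k in (1, 2, 3)]
    results = []
    for scenario in scenarios:
        lps_annual, lps_total = capacity(lps_ratio, scenario)
        rbt_annual, rbt_total = capacity(rbt_ratio, scenario)
        results.append(
            ScaleResult(
                procedures_per_session=scenario.procedures_per_session,
                lps_annual_capacity=lps_annual,
                lps_total_capacity=lps_total,
                rbt_annual_capacity=rbt_annual,
                rbt_total_capacity=rbt_total,
                lps_adjusted_cost=ratio_adjusted_cost(
                    lps, lps_spec, lps_total, stay_policy, stay_rate
                ),
                rbt_adjusted_cost=ratio_adjusted_cost(
                    rbt, rbt_spec, rbt_total, stay_policy, stay_rate
                ),
            )
        )
    return results


def results_to_frame(results: Sequence[ScaleResult]) -> pd.DataFrame:
    """Long-format table of scale-model results (one row per arm × model)."""
    rows = []
    for r in results:
        for arm, annual, total, cost in (
            ("LPS", r.lps_annual_capacity, r.lps_total_capacity, r.lps_adjusted_cost),
            ("RBT", r.rbt_annual_capacity, r.rbt_total_capacity, r.rbt_adjusted_cost),
        ):
            rows.append(
                {
                    "arm": arm,
                    "procedures_per_session": r.procedures_per_session,
                    "annual_capacity": annual,
                    "total_capacity": total,
                    "adjusted_cost": cost,
                    "overrun": r.overrun,
                    "overrun_pct": r.overrun_pct,
                    "capacity_increase_annual": r.capacity_increase_annual,
                    "capacity_increase_total": r.capacity_increase_total,
                }
            )
    return pd.DataFrame(rows)
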