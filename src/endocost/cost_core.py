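"""Per-procedure cost decomposition for minimally invasive surgery.

The costing convention: indirect costs are facility time billed at fixed
rates (operating theatre €/minute, hospital stay €/day); direct costs are
per-procedure consumables plus a straight-line equipment-depreciation share
(purchase price spread over a fixed number of procedures). The total cost of
one case is the exact sum of the four components. Arm-level summaries carry
per-component sample means and SDs plus each component's share of the mean
total, mirroring the way such cost tables are reported.

All currency values are kept at full floating precision internally; rounding
to whole euros happens only when a report is rendered (see
:func:`endocost.report.round_eur`). Costs are pre-tax euros with no inflation
adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Arm",
    "COMPONENTS",
    "CostRates",
    "EquipmentSpec",
    "PatientRecord",
    "ProcedureCost",
    "ArmCostSummary",
    "EndocostError",
    "InvalidRecordError",
    "InvalidInputError",
    "ConfigurationError",
    "EmptyInputError",
    "theatre_cost",
    "stay_cost",
    "equipment_share",
    "procedure_cost",
    "summarize_arm",
    "per_use_cost",
    "read_records",
    "write_records",
    "records_to_frame",
    "frame_to_records",
]


class EndocostError(ValueError):
    """Base class for domain errors raised by this package."""


class InvalidRecordError(EndocostError):
    """A patient record violates its invariants."""


class InvalidInputError(EndocostError):
    """An operation received structurally invalid input (e.g. mixed arms)."""


class ConfigurationError(EndocostError):
    """Economic parameters violate their invariants."""


class EmptyInputError(EndocostError):
    """An operation requiring at least one record received none."""


class Arm(str, Enum):
    """Surgical approach: laparoscopic (LPS) or robotic-assisted (RBT)."""

    LPS = "LPS"
    RBT = "RBT"


#: Cost components of one procedure, in reporting order.
COMPONENTS: tuple[str, ...] = ("theatre", "consumables", "equipment", "stay")

COMPLEXITY_GROUPS: tuple[str, ...] = ("A", "B", "C")


@dataclass(frozen=True)
class CostRates:
    """Facility billing rates.

    Parameters
    ----------
    theatre_rate
        Operating-theatre cost per minute of occupation (€/min), covering
        facility use, the fixed surgical/anaesthetic/nursing team and
        intra-operative medication.
    stay_rate
        Hospital-stay cost per admission day (€/day), covering room, meals
        and post-operative care.
    """

    theatre_rate: float
    stay_rate: float

    def __post_init__(self) -> None:
        if not (self.theatre_rate > 0 and self.stay_rate > 0):
            raise ConfigurationError(
                f"rates must be strictly positive, got theatre_rate="
                f"{self.theatre_rate}, stay_rate={self.stay_rate}"
            )


@dataclass(frozen=True)
class EquipmentSpec:
    """Inventoriable equipment amortized over a fixed number of procedures.

    ``purchase_price / depreciation_procedures`` is the per-procedure
    depreciation share. ``annual_maintenance`` is an optional additive annual
    cost (default 0; platform maintenance is usually bundled into direct
    costs without a separate figure).
    """

    label: str
    purchase_price: float
    depreciation_procedures: int
    annual_maintenance: float = 0.0

    def __post_init__(self) -> None:
        if not self.purchase_price > 0:
            raise ConfigurationError(
                f"purchase_price must be > 0, got {self.purchase_price}"
            )
        if self.depreciation_procedures < 1:
            raise ConfigurationError(
                "depreciation_procedures must be >= 1, got "
                f"{self.depreciation_procedures}"
            )
        if self.annual_maintenance < 0:
            raise ConfigurationError("annual_maintenance must be >= 0")


@dataclass(frozen=True)
class PatientRecord:
    """One surgical case.

    ``theatre_minutes`` is total theatre occupation including surgical-field
    preparation and docking (theatre cost is billed per minute of use).
    ``consumables_cost`` is already per-use prorated for limited-use
    instruments (see :func:`per_use_cost`). ``complexity_group`` encodes the
    procedure: A = hysterectomy + double adnexectomy, B = A + sentinel node
    biopsy, C = A or B + lymphadenectomy ± omentectomy.
    """

    arm: Arm
    theatre_minutes: float
    stay_days: int
    consumables_cost: float
    complexity_group: str = "B"
    age: float = math.nan
    bmi: float = math.nan
    complication_flag: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "arm", Arm(self.arm))
        if not self.theatre_minutes > 0:
            raise InvalidRecordError(
                f"theatre_minutes must be > 0, got {self.theatre_minutes}"
            )
        if self.stay_days < 0:
            raise InvalidRecordError(f"stay_days must be >= 0, got {self.stay_days}")
        if self.consumables_cost < 0:
            raise InvalidRecordError(
                f"consumables_cost must be >= 0, got {self.consumables_cost}"
            )
        if self.complexity_group not in COMPLEXITY_GROUPS:
            raise InvalidRecordError(
                f"complexity_group must be one of {COMPLEXITY_GROUPS}, "
                f"got {self.complexity_group!r}"
            )


@dataclass(frozen=True)
class ProcedureCost:
    """Cost decomposition of a single procedure (€)."""

    theatre_cost: float
    consumables_cost: float
    equipment_share: float
    stay_cost: float

    @property
    def total(self) -> float:
        return (
            self.theatre_cost
            + self.consumables_cost
            + self.equipment_share
            + self.stay_cost
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "theatre": self.theatre_cost,
            "consumables": self.consumables_cost,
            "equipment": self.equipment_share,
            "stay": self.stay_cost,
            "total": self.total,
        }


@dataclass(frozen=True)
class ArmCostSummary:
    """Per-arm cost summary: component means/SDs and cost shares.

    ``component_means`` / ``component_sds`` are keyed by :data:`COMPONENTS`.
    ``cost_shares`` are fractions of the mean total (summing to 1). SDs use
    the n−1 denominator; a single-record arm has SD 0.
    """

    arm: Arm
    n: int
    component_means: Mapping[str, float]
    component_sds: Mapping[str, float]
    total_mean: float
    total_sd: float
    cost_shares: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidInputError(f"n must be >= 1, got {self.n}")
        missing = set(COMPONENTS) - set(self.component_means)
        if missing:
            raise InvalidInputError(f"missing components: {sorted(missing)}")
        if any(sd < 0 for sd in self.component_sds.values()) or self.total_sd < 0:
            raise InvalidInputError("SDs must be non-negative")
        if not self.cost_shares:
            shares = {
                c: self.component_means[c] / self.total_mean for c in COMPONENTS
            }
            object.__setattr__(self, "cost_shares", shares)
        s = sum(self.cost_shares.values())
        if abs(s - 1.0) > 1e-9:
            raise InvalidInputError(f"cost_shares must sum to 1, got {s}")

    @classmethod
    def from_moments(
        cls,
        arm: Arm | str,
        n: int,
        *,
        theatre: tuple[float, float],
        consumables: tuple[float, float],
        equipment: tuple[float, float],
        stay: tuple[float, float],
        total_sd: float = 0.0,
    ) -> "ArmCostSummary":
        """Build a summary directly from reported (mean, SD) pairs.

        This is the entry point for *reproduction mode*, where published
        component means stand in for patient-level records. ``total_mean`` is
        always the exact sum of the component means (printed totals can
        differ by a euro or two from the sum of independently rounded
        component means; this class never forces a printed total).
        """
        means = dict(
            zip(COMPONENTS, (theatre[0], consumables[0], equipment[0], stay[0]))
        )
        sds = dict(zip(COMPONENTS, (theatre[1], consumables[1], equipment[1], stay[1])))
        return cls(
            arm=Arm(arm),
            n=n,
            component_means=means,
            component_sds=sds,
            total_mean=sum(means.values()),
            total_sd=total_sd,
        )


# ---------------------------------------------------------------------------
# Elementary cost operations
# ---------------------------------------------------------------------------


def theatre_cost(minutes: float, rates: CostRates) -> float:
    """Operating-theatre cost: occupation minutes × per-minute rate."""
    if not minutes > 0:
        raise InvalidRecordError(f"theatre minutes must be > 0, got {minutes}")
    return minutes * rates.theatre_rate


def stay_cost(days: float, rates: CostRates) -> float:
    """Hospital-stay cost: admission days × per-day rate."""
    if days < 0:
        raise InvalidRecordError(f"stay days must be >= 0, got {days}")
    return days * rates.stay_rate


def equipment_share(spec: EquipmentSpec) -> float:
    """Per-procedure straight-line depreciation share of an equipment item."""
    if spec.depreciation_procedures < 1:
        raise ConfigurationError("depreciation horizon must be >= 1 procedure")
    return spec.purchase_price / spec.depreciation_procedures


def per_use_cost(unit_price: float, uses: int) -> float:
    """Per-use cost of a limited-use instrument (unit price / number of uses).

    Ingest-time helper for building ``consumables_cost``: instruments with a
    pre-established number of uses (robotic instruments typically allow
    10–18) enter the per-procedure consumables cost at one use per surgery.
    """
    if unit_price < 0:
        raise ConfigurationError(f"unit_price must be >= 0, got {unit_price}")
    if uses < 1:
        raise ConfigurationError(f"uses must be >= 1, got {uses}")
    return unit_price / uses


def procedure_cost(
    record: PatientRecord, rates: CostRates, spec: EquipmentSpec
) -> ProcedureCost:
    """Full cost decomposition of one case; ``total`` is the exact sum."""
    return ProcedureCost(
        theatre_cost=theatre_cost(record.theatre_minutes, rates),
        consumables_cost=record.consumables_cost,
        equipment_share=equipment_share(spec),
        stay_cost=stay_cost(record.stay_days, rates),
    )


def summarize_arm(
    records: Sequence[PatientRecord], rates: CostRates, spec: EquipmentSpec
) -> ArmCostSummary:
    """Per-arm cost summary over patient-level records.

    All records must belong to a single arm. Component means and SDs use the
    sample (n−1) SD; the equipment component is constant across records, so
    its SD is exactly 0. Cost shares are component means divided by the mean
    total.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("cannot summarize an empty arm")
    arms = {r.arm for r in records}
    if len(arms) > 1:
        raise InvalidInputError(f"records mix arms: {sorted(a.value for a in arms)}")

    costs = [procedure_cost(r, rates, spec) for r in records]
    mat = np.array(
        [[c.theatre_cost, c.consumables_cost, c.equipment_share, c.stay_cost] for c in costs]
    )
    totals = mat.sum(axis=1)
    ddof = 1 if len(records) > 1 else 0
    means = dict(zip(COMPONENTS, mat.mean(axis=0)))
    sds = dict(zip(COMPONENTS, mat.std(axis=0, ddof=ddof)))
    return ArmCostSummary(
        arm=arms.pop(),
        n=len(records),
        component_means=means,
        component_sds=sds,
        total_mean=float(totals.mean()),
        total_sd=float(totals.std(ddof=ddof)),
    )


# ---------------------------------------------------------------------------
# Patient-record CSV interface
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "arm",
    "theatre_minutes",
    "stay_days",
    "consumables_cost",
    "complexity_group",
    "age",
    "bmi",
    "complication_flag",
]


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = [
        {
            "arm": r.arm.value,
            "theatre_minutes": r.theatre_minutes,
            "stay_days": r.stay_days,
            "consumables_cost": r.consumables_cost,
            "complexity_group": r.complexity_group,
            "age": r.age,
            "bmi": r.bmi,
            "complication_flag": r.complication_flag,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    missing = set(CSV_COLUMNS[:4]) - set(frame.columns)
    if missing:
        raise InvalidInputError(f"cohort table missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            PatientRecord(
                arm=Arm(str(row.arm)),
                theatre_minutes=float(row.theatre_minutes),
                stay_days=int(row.stay_days),
                consumables_cost=float(row.consumables_cost),
                complexity_group=str(getattr(row, "complexity_group", "B")),
                age=float(getattr(row, "age", math.nan)),
                bmi=float(getattr(row, "bmi", math.nan)),
                complication_flag=bool(getattr(row, "complication_flag", False)),
            )
        )
    return records


def read_records(path: str | Path) -> list[PatientRecord]:
    """Read a patient cohort from the standard CSV layout."""
    return frame_to_records(pd.read_csv(path))


def write_records(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write a patient cohort to the standard CSV layout (UTF-8, '.')."""
    records_to_frame(records).to_csv(path, index=False)
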