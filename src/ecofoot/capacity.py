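"""Supply-side accounting: land areas -> ecological carrying capacity and deficit.

Capacity (biocapacity) weights the region's actual land areas by both the
equivalence factor and the yield factor:

    EC = sum_j w_j * y_j * A_j        ec = EC / N

A fixed fraction of per-capita capacity (12% by default) is set aside as
biodiversity conservation land; the remainder is the *available* capacity.
The ecological deficit is demand minus available supply,

    ED = ef - (1 - b) * ec

positive when the population's footprint exceeds what the region supplies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

from .errors import DomainError, InvalidRecordError
from .landtypes import FactorTable, LandType


@dataclass(frozen=True)
class LandAreaRecord:
    """Physical area of one land type on the supply side, in hm²."""

    land_type: LandType
    area: float

    def validate(self) -> None:
        if self.area < 0:
            raise InvalidRecordError(
                f"area for {self.land_type.value} must be >= 0, got {self.area}"
            )


@dataclass
class CapacitySummary:
    """Supply-side result: capacities, the biodiversity deduction, deficit basis."""

    capacity_by_land_type: Dict[LandType, float]
    total_area: float
    ec_total: float
    ec_per_capita: float
    available_ec_per_capita: float
    biodiversity_fraction: float
    population: float


def land_capacity(record: LandAreaRecord, factors: FactorTable) -> float:
    """Capacity of one land type: area × equivalence factor × yield factor."""
    record.validate()
    return (
        record.area
        * factors.equivalence_for(record.land_type)
        * factors.yield_for(record.land_type)
    )


def total_capacity(
    records: Sequence[LandAreaRecord],
    factors: FactorTable,
    population: float,
) -> CapacitySummary:
    """Aggregate land capacities and apply the biodiversity deduction."""
    if not population > 0:
        raise DomainError(f"population must be > 0, got {population}")
    by_type: Dict[LandType, float] = {}
    total_area = 0.0
    for rec in records:
        cap = land_capacity(rec, factors)
        by_type[rec.land_type] = by_type.get(rec.land_type, 0.0) + cap
        total_area += rec.area
    ec_total = sum(by_type.values())
    ec_pc = ec_total / population
    available = (1.0 - factors.biodiversity_fraction) * ec_pc
    return CapacitySummary(
        capacity_by_land_type=by_type,
        total_area=total_area,
        ec_total=ec_total,
        ec_per_capita=ec_pc,
        available_ec_per_capita=available,
        biodiversity_fraction=factors.biodiversity_fraction,
        population=population,
    )


def ecological_balance(
    ef_per_capita: float, available_ec_per_capita: float
) -> float:
    """Ecological deficit (positive) or surplus (negative) per capita."""
    for name, v in (
        ("ef_per_capita", ef_per_capita),
        ("available_ec_per_capita", available_ec_per_capita),
    ):
        if not (v == v and abs(v) != float("inf")):
            raise DomainError(f"{name} must be finite, got {v}")
        if v < 0:
            raise DomainError(f"{name} must be >= 0, got {v}")
    return ef_per_capita - available_ec_per_capita
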