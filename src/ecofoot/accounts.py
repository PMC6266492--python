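"""Demand-side accounting: consumption records -> per-capita ecological footprint.

The demand side converts item-level biological production (tonnes) and energy
consumption (GJ) into biologically productive areas.  A biological item's
area is its total production divided by the item's global average yield; an
energy item's area is its consumption divided by the global average energy
footprint of the absorbing land (GJ per hectare of fossil-fuel land, or the
coal-equivalent footprint of built-up land for electricity and heat).

Per-capita areas are summed per land type, weighted by equivalence factors
and summed again to the ecological footprint per capita

    ef = sum_j w_j * A_j          EF = N * ef

where ``A_j`` is the per-capita area of land type ``j`` and ``N`` the resident
population.  Yield factors do not enter the demand side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from .errors import (
    ConfigurationError,
    DomainError,
    InvalidFactorError,
    InvalidRecordError,
)
from .landtypes import FactorTable, LandType

TONNES_TO_KG = 1000.0


@dataclass
class BioItemRecord:
    """One biological-resource item of a regional account.

    ``global_average_yield`` is in kg per hm²; production values are tonnes
    per city.  ``in_demand_aggregate`` marks whether the item enters the
    per-land-type aggregation (items can be accounted but excluded from the
    demand total, as published accounts occasionally do).
    """

    item_name: str
    land_type: LandType
    global_average_yield: float
    production_by_city: Mapping[str, float]
    in_demand_aggregate: bool = True

    def validate(self) -> None:
        if not self.global_average_yield > 0:
            raise InvalidFactorError(
                f"{self.item_name}: global average yield must be > 0, got "
                f"{self.global_average_yield}"
            )
        for city, v in self.production_by_city.items():
            if v < 0:
                raise InvalidRecordError(
                    f"{self.item_name}: negative production {v} for {city}"
                )


@dataclass
class EnergyItemRecord:
    """One energy item; consumption per city in GJ.

    Fuels consume fossil-energy land; secondary energy (electricity, heat)
    is attributed to built-up land.  ``convert_coefficient`` (GJ per tonne)
    is retained as metadata for accounts kept in physical tonnes; the city
    columns here are already GJ.
    """

    item_name: str
    land_type: LandType
    global_average_energy_footprint: float
    consumption_by_city: Mapping[str, float]
    convert_coefficient: Optional[float] = None

    def validate(self) -> None:
        if self.land_type not in (LandType.FOSSIL_ENERGY, LandType.BUILT_UP):
            raise InvalidRecordError(
                f"{self.item_name}: energy items consume fossil_energy or "
                f"built_up land, got {self.land_type.value}"
            )
        if not self.global_average_energy_footprint > 0:
            raise InvalidFactorError(
                f"{self.item_name}: global average energy footprint must be "
                f"> 0, got {self.global_average_energy_footprint}"
            )
        for city, v in self.consumption_by_city.items():
            if v < 0:
                raise InvalidRecordError(
                    f"{self.item_name}: negative consumption {v} for {city}"
                )


@dataclass
class RegionalAccount:
    """Item-level demand account of a multi-city region for one year.

    ``built_up_area_hm2`` optionally carries the physically built-up urban
    area, added to the built-up demand on top of the energy-derived area.
    """

    bio_items: List[BioItemRecord]
    energy_items: List[EnergyItemRecord]
    population: float
    year: int
    built_up_area_hm2: float = 0.0

    def validate(self) -> None:
        if not self.population > 0:
            raise DomainError(f"population must be > 0, got {self.population}")
        if self.built_up_area_hm2 < 0:
            raise InvalidRecordError("built-up area must be >= 0")
        for rec in self.bio_items:
            rec.validate()
        for rec in self.energy_items:
            rec.validate()


@dataclass
class FootprintSummary:
    """Demand-side result: per-capita areas and the aggregated footprint."""

    per_item_total_area: Dict[str, float]
    per_capita_area_by_land_type: Dict[LandType, float]
    equivalence_area_by_land_type: Dict[LandType, float]
    ef_per_capita: float
    ef_total: float
    population: float


def bio_item_footprint(record: BioItemRecord) -> float:
    """Total biologically productive area of one item, in hm².

    Production is summed over cities, converted tonnes -> kg, and divided by
    the item's global average yield (kg/hm²).
    """
    record.validate()
    total_kg = sum(record.production_by_city.values()) * TONNES_TO_KG
    return total_kg / record.global_average_yield


def energy_item_footprint(
    record: EnergyItemRecord, population: float
) -> Tuple[float, float]:
    """Per-capita consumption (GJ/person) and area (hm²/person) of one item."""
    if not population > 0:
        raise DomainError(f"population must be > 0, got {population}")
    record.validate()
    consumption_pc = sum(record.consumption_by_city.values()) / population
    area_pc = consumption_pc / record.global_average_energy_footprint
    return consumption_pc, area_pc


def energy_item_total_area(record: EnergyItemRecord) -> float:
    """Total absorbing-land area of one energy item, in hm²."""
    record.validate()
    return (
        sum(record.consumption_by_city.values())
        / record.global_average_energy_footprint
    )


def per_capita_area_by_land_type(
    account: RegionalAccount,
) -> Dict[LandType, float]:
    """Sum item areas per land type and divide by population.

    Every land type is present in the result (zero when the account has no
    item of that type).  Items flagged out of the demand aggregate are
    skipped here but still appear in per-item reconstructions.
    """
    account.validate()
    areas: Dict[LandType, float] = {lt: 0.0 for lt in LandType}
    for rec in account.bio_items:
        if not rec.in_demand_aggregate:
            continue
        areas[rec.land_type] += bio_item_footprint(rec) / account.population
    for rec in account.energy_items:
        _, area_pc = energy_item_footprint(rec, account.population)
        areas[rec.land_type] += area_pc
    areas[LandType.BUILT_UP] += account.built_up_area_hm2 / account.population
    return areas


def aggregate_footprint(
    areas: Mapping[LandType, float],
    factors: FactorTable,
    population: float,
    per_item_total_area: Optional[Dict[str, float]] = None,
) -> FootprintSummary:
    """Weight per-capita areas by equivalence factors and total them.

    ``ef_per_capita = sum_j w_j * A_j``; ``ef_total = N * ef_per_capita``.
    """
    if not population > 0:
        raise DomainError(f"population must be > 0, got {population}")
    equivalence_areas: Dict[LandType, float] = {}
    for lt, area in areas.items():
        if area < 0:
            raise InvalidRecordError(
                f"per-capita area for {lt.value} must be >= 0, got {area}"
            )
        equivalence_areas[lt] = area * factors.equivalence_for(lt)
    ef_pc = sum(equivalence_areas.values())
    return FootprintSummary(
        per_item_total_area=dict(per_item_total_area or {}),
        per_capita_area_by_land_type=dict(areas),
        equivalence_area_by_land_type=equivalence_areas,
        ef_per_capita=ef_pc,
        ef_total=population * ef_pc,
        population=population,
    )


def footprint_summary(
    account: RegionalAccount, factors: FactorTable
) -> FootprintSummary:
    """Full demand-side computation for one account."""
    per_item: Dict[str, float] = {}
    for rec in account.bio_items:
        per_item[rec.item_name] = bio_item_footprint(rec)
    for erec in account.energy_items:
        per_item[erec.item_name] = energy_item_total_area(erec)
    areas = per_capita_area_by_land_type(account)
    return aggregate_footprint(
        areas, factors, account.population, per_item_total_area=per_item
    )
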