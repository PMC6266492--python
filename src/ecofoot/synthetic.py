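"""Synthetic accounts and grey-consistent series, plus the packaged study data.

Two kinds of test-and-demo data live here:

* **Generators** produce multi-city account tables and annual series with the
  statistical structure the analysis assumes: series that satisfy the
  GM(1,1) discrete recursion exactly (so the fitter must recover the
  generating parameters to machine precision), optionally perturbed by
  multiplicative lognormal noise (lognormal keeps values positive, which
  the grey model requires); and item-level accounts whose aggregated
  per-capita footprint/capacity reproduce a prescribed trajectory.

* **Study fixtures** ship the published five-year account of an eight-city
  urban agglomeration in the lower-Yangtze region (2013–2017): item-level
  biological and energy accounts plus land areas for 2017, the published
  annual per-capita series for all five years, and the conversion-factor
  configuration.  The resident population and one item yield are
  calibrated from the published (total, per-capita) column pairs; see the
  fixture YAML for details.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .accounts import BioItemRecord, EnergyItemRecord, RegionalAccount
from .capacity import LandAreaRecord
from .errors import DomainError
from .gm11 import GreySeries
from .landtypes import FactorTable, LandType
from .pipeline import AnnualBalanceTable, YearInput, build_annual_table

# ---------------------------------------------------------------------------
# grey-consistent series generators


def generate_exact_gm_series(
    a: float,
    u: float,
    initial_value: float,
    n: int,
    start_year: int = 2013,
) -> GreySeries:
    """A series satisfying the GM(1,1) discrete recursion exactly.

    x⁽⁰⁾(k) = (u − a·x⁽¹⁾(k−1)) / (1 + a/2) for k ≥ 2, anchored at
    ``initial_value``; by construction the least-squares fit recovers
    (a, u) to machine precision.
    """
    if n < 4:
        raise DomainError(f"series length must be >= 4, got {n}")
    if not initial_value > 0:
        raise DomainError("initial value must be > 0")
    if abs(1.0 + a / 2.0) < 1e-12:
        raise DomainError(f"degenerate recursion for a = {a}")
    values = [float(initial_value)]
    cumulative = float(initial_value)
    for _ in range(1, n):
        x = (u - a * cumulative) / (1.0 + a / 2.0)
        if x <= 0:
            raise DomainError(
                f"parameters (a={a}, u={u}, x1={initial_value}) produce a "
                "nonpositive value; grey series must stay positive"
            )
        values.append(x)
        cumulative += x
    years = range(start_year, start_year + n)
    return GreySeries.from_arrays(years, values)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study generator.

    ``gm_params`` holds (a, u, initial_value) per generated series; the
    default pair of trajectories drifts like the per-capita demand/supply
    series of a mid-sized urban region (demand around 1.5 hm²/person
    shrinking a few percent a year, supply flat near 0.36 hm²/person).
    ``noise_cv`` is the coefficient of variation of multiplicative
    lognormal noise.  A seed is mandatory for any stochastic call.
    """

    n_cities: int = 8
    n_years: int = 5
    items_per_land_type: int = 2
    population: float = 4.3e7
    first_year: int = 2013
    gm_params: Mapping[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {
            "ef": (0.05, 1.9, 1.53),
            "ec": (0.02, 0.40, 0.35),
        }
    )
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 4:
            raise DomainError("n_years must be >= 4")
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be >= 0")
        if self.n_cities < 1:
            raise DomainError("n_cities must be >= 1")


def generate_noisy_series(
    spec: SyntheticSpec, which: str = "ef"
) -> GreySeries:
    """Exact grey series times multiplicative lognormal noise factors.

    The noise factors have mean 1 and coefficient of variation
    ``spec.noise_cv``; the output is a pure function of (spec, seed).
    """
    a, u, x1 = spec.gm_params[which]
    base = generate_exact_gm_series(
        a, u, x1, spec.n_years, start_year=spec.first_year
    )
    if spec.noise_cv == 0:
        return base
    rng = np.random.default_rng(spec.seed)
    sigma2 = np.log1p(spec.noise_cv**2)
    factors = rng.lognormal(
        mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=spec.n_years
    )
    values = np.asarray(base.values) * factors
    return GreySeries.from_arrays(base.labels, values)


# ---------------------------------------------------------------------------
# account-level generator

#: How the demand-side footprint is split across land types (sums to 1).
_DEMAND_SHARES: Dict[LandType, float] = {
    LandType.ARABLE: 0.22,
    LandType.PASTURE: 0.13,
    LandType.FOREST: 0.01,
    LandType.WATER: 0.51,
    LandType.FOSSIL_ENERGY: 0.10,
    LandType.BUILT_UP: 0.03,
}

#: Supply-side capacity shares (fossil-energy land supplies none).
_SUPPLY_SHARES: Dict[LandType, float] = {
    LandType.ARABLE: 0.56,
    LandType.PASTURE: 0.02,
    LandType.FOREST: 0.02,
    LandType.BUILT_UP: 0.38,
    LandType.WATER: 0.02,
}

_BIO_TYPES = (LandType.ARABLE, LandType.PASTURE, LandType.FOREST,
              LandType.WATER)
_ENERGY_TYPES = (LandType.FOSSIL_ENERGY, LandType.BUILT_UP)

_SYNTH_YIELD = 2000.0          # kg/hm², generic crop-scale yield
_SYNTH_ENERGY_FOOTPRINT = 70.0  # GJ/hm², generic fuel footprint


def generate_account_fixture(
    spec: SyntheticSpec,
    factors: Optional[FactorTable] = None,
) -> List[YearInput]:
    """Per-year accounts whose aggregation reproduces the target series.

    Demand: the target footprint is split across land types by fixed
    shares, each type's area across ``items_per_land_type`` items, and
    each item's production across cities by seeded Dirichlet proportions.
    Supply: land areas are solved from the target capacity and the
    equivalence/yield factors.  ``build_annual_table`` on the result
    returns the target ef/ec trajectories up to float rounding.
    """
    factors = factors or FactorTable()
    ef_series = generate_noisy_series(spec, "ef")
    ec_series = generate_noisy_series(spec, "ec")
    rng = np.random.default_rng(spec.seed + 1)
    cities = [f"city_{i+1}" for i in range(spec.n_cities)]
    inputs: List[YearInput] = []
    for year, ef_t, ec_t in zip(
        ef_series.labels, ef_series.values, ec_series.values
    ):
        bio_items: List[BioItemRecord] = []
        energy_items: List[EnergyItemRecord] = []
        for lt in _BIO_TYPES:
            w = factors.equivalence_for(lt)
            area_pc = ef_t * _DEMAND_SHARES[lt] / w
            for i in range(spec.items_per_land_type):
                item_area = area_pc / max(spec.items_per_land_type, 1)
                total_tonnes = (
                    item_area * spec.population * _SYNTH_YIELD / 1000.0
                )
                shares = rng.dirichlet(np.ones(spec.n_cities))
                bio_items.append(
                    BioItemRecord(
                        item_name=f"{lt.value}_item_{i+1}",
                        land_type=lt,
                        global_average_yield=_SYNTH_YIELD,
                        production_by_city=dict(
                            zip(cities, total_tonnes * shares)
                        ),
                    )
                )
        for lt in _ENERGY_TYPES:
            w = factors.equivalence_for(lt)
            area_pc = ef_t * _DEMAND_SHARES[lt] / w
            total_gj = area_pc * spec.population * _SYNTH_ENERGY_FOOTPRINT
            shares = rng.dirichlet(np.ones(spec.n_cities))
            energy_items.append(
                EnergyItemRecord(
                    item_name=f"{lt.value}_energy",
                    land_type=lt,
                    global_average_energy_footprint=_SYNTH_ENERGY_FOOTPRINT,
                    consumption_by_city=dict(zip(cities, total_gj * shares)),
                )
            )
        land_areas = []
        for lt, share in _SUPPLY_SHARES.items():
            wy = factors.equivalence_for(lt) * factors.yield_for(lt)
            if wy <= 0:
                raise DomainError(
                    f"cannot target capacity through {lt.value}: "
                    "equivalence x yield factor is zero"
                )
            land_areas.append(
                LandAreaRecord(
                    land_type=lt, area=ec_t * spec.population * share / wy
                )
            )
        land_areas.append(LandAreaRecord(LandType.FOSSIL_ENERGY, 0.0))
        account = RegionalAccount(
            bio_items=bio_items,
            energy_items=energy_items,
            population=spec.population,
            year=int(year),
        )
        inputs.append(YearInput(account=account, land_areas=land_areas))
    return inputs


# ---------------------------------------------------------------------------
# packaged study fixtures


def fixture_path(name: str) -> Path:
    """Absolute path of a packaged fixture file."""
    return Path(resources.files("ecofoot") / "fixtures" / name)


@dataclass
class StudyFixtures:
    """The packaged 2013–2017 study inputs."""

    factors: FactorTable
    account_2017: RegionalAccount
    land_areas_2017: List[LandAreaRecord]
    reference_table: AnnualBalanceTable
    population: float
    year: int
    first_year: int


def study_fixtures() -> StudyFixtures:
    """Load the packaged study inputs (factors, 2017 accounts, series)."""
    from .io import (
        read_annual_table,
        read_bio_account,
        read_energy_account,
        read_factors,
        read_land_areas,
    )

    meta = yaml.safe_load(fixture_path("study.yaml").read_text())
    population = float(meta["population"])
    year = int(meta["year"])
    account = RegionalAccount(
        bio_items=read_bio_account(fixture_path("bio_account_2017.csv")),
        energy_items=read_energy_account(
            fixture_path("energy_account_2017.csv")
        ),
        population=population,
        year=year,
    )
    return StudyFixtures(
        factors=read_factors(fixture_path("factors.yaml")),
        account_2017=account,
        land_areas_2017=read_land_areas(fixture_path("land_areas_2017.csv")),
        reference_table=read_annual_table(
            fixture_path("annual_reference_2013_2017.csv")
        ),
        population=population,
        year=year,
        first_year=int(meta["first_year"]),
    )


def study_annual_table(fixtures: Optional[StudyFixtures] = None) -> AnnualBalanceTable:
    """The study's five-year balance table, recomputed where possible.

    The 2017 row is computed from the item-level accounts; 2013–2016 carry
    the published raw per-capita ef/ec (no item-level data was published
    for those years), with the available-capacity and deficit columns
    recomputed from them.
    """
    fx = fixtures or study_fixtures()
    computed_2017 = build_annual_table(
        [YearInput(fx.account_2017, fx.land_areas_2017)], fx.factors
    )
    ref = fx.reference_table.data
    early = ref[ref["year"] < fx.year]
    early_table = AnnualBalanceTable.from_per_capita(
        list(zip(early["year"], early["ef_per_capita"],
                 early["ec_per_capita"])),
        biodiversity_fraction=fx.factors.biodiversity_fraction,
    )
    import pandas as pd

    return AnnualBalanceTable(
        pd.concat([early_table.data, computed_2017.data], ignore_index=True)
    )
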