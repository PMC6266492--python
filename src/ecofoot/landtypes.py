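"""Land-type taxonomy and conversion factors for ecological-footprint accounts.

Footprint accounting partitions consumption into six biologically productive
land types.  Two sets of dimensionless factors attach to them:

* the *equivalence factor* ``w_j`` converts one hectare of a land type into
  hectares of world-average productivity (demand and supply side);
* the *yield factor* ``y_j`` scales local area to world-average-yield area
  (supply side only — local land may be more or less productive than the
  world average for that type).

Fossil-energy land has a yield factor of 0 on the supply side: regions do not
actually set aside land to absorb CO2, so it contributes demand but no
capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import yaml

from .errors import ConfigurationError, InvalidFactorError


class LandType(str, Enum):
    """The six biologically productive land categories."""

    ARABLE = "arable"
    FOREST = "forest"
    PASTURE = "pasture"
    WATER = "water"
    FOSSIL_ENERGY = "fossil_energy"
    BUILT_UP = "built_up"

    @classmethod
    def parse(cls, name: str) -> "LandType":
        try:
            return cls(name)
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ConfigurationError(
                f"unknown land type {name!r}; expected one of: {valid}"
            ) from None


#: World-average-productivity weights per land type.
DEFAULT_EQUIVALENCE: Mapping[LandType, float] = {
    LandType.ARABLE: 2.51,
    LandType.FOREST: 1.26,
    LandType.PASTURE: 0.46,
    LandType.WATER: 0.37,
    LandType.FOSSIL_ENERGY: 1.26,
    LandType.BUILT_UP: 2.51,
}

#: Local-to-world yield ratios per land type (supply side).
DEFAULT_YIELD: Mapping[LandType, float] = {
    LandType.ARABLE: 1.66,
    LandType.PASTURE: 0.19,
    LandType.FOREST: 0.91,
    LandType.BUILT_UP: 1.66,
    LandType.WATER: 1.00,
    LandType.FOSSIL_ENERGY: 0.0,
}

#: Fraction of capacity reserved for biodiversity conservation.
DEFAULT_BIODIVERSITY_FRACTION = 0.12


@dataclass(frozen=True)
class FactorTable:
    """Equivalence factors, yield factors and the biodiversity deduction.

    Parameters
    ----------
    equivalence
        ``w_j`` per land type, dimensionless, >= 0.
    yield_factors
        ``y_j`` per land type, dimensionless, >= 0.
    biodiversity_fraction
        Fraction of per-capita capacity deducted for biodiversity
        conservation land, in [0, 1].  Default 0.12.
    """

    equivalence: Mapping[LandType, float] = field(
        default_factory=lambda: dict(DEFAULT_EQUIVALENCE)
    )
    yield_factors: Mapping[LandType, float] = field(
        default_factory=lambda: dict(DEFAULT_YIELD)
    )
    biodiversity_fraction: float = DEFAULT_BIODIVERSITY_FRACTION

    def __post_init__(self) -> None:
        for name, table in (("equivalence", self.equivalence),
                            ("yield", self.yield_factors)):
            for lt, v in table.items():
                if not isinstance(lt, LandType):
                    raise ConfigurationError(
                        f"{name} factor key {lt!r} is not a LandType"
                    )
                if not (v >= 0):
                    raise InvalidFactorError(
                        f"{name} factor for {lt.value} must be >= 0, got {v}"
                    )
        if not (0.0 <= self.biodiversity_fraction <= 1.0):
            raise ConfigurationError(
                "biodiversity_fraction must lie in [0, 1], got "
                f"{self.biodiversity_fraction}"
            )

    def equivalence_for(self, land_type: LandType) -> float:
        try:
            return self.equivalence[land_type]
        except KeyError:
            raise ConfigurationError(
                f"no equivalence factor configured for {land_type.value}"
            ) from None

    def yield_for(self, land_type: LandType) -> float:
        try:
            return self.yield_factors[land_type]
        except KeyError:
            raise ConfigurationError(
                f"no yield factor configured for {land_type.value}"
            ) from None

    @classmethod
    def from_dict(cls, data: Mapping) -> "FactorTable":
        """Build a table from a plain mapping (parsed YAML/JSON)."""
        try:
            eq = {LandType.parse(k): float(v)
                  for k, v in data["equivalence"].items()}
            yf = {LandType.parse(k): float(v)
                  for k, v in data["yield_factors"].items()}
        except KeyError as exc:
            raise ConfigurationError(
                f"factor config missing required section {exc.args[0]!r}"
            ) from None
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"malformed factor config: {exc}") from None
        frac = float(data.get("biodiversity_fraction",
                              DEFAULT_BIODIVERSITY_FRACTION))
        return cls(equivalence=eq, yield_factors=yf, biodiversity_fraction=frac)

    @classmethod
    def from_yaml(cls, path) -> "FactorTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"{path}: factor config is not a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "equivalence": {k.value: v for k, v in self.equivalence.items()},
            "yield_factors": {k.value: v for k, v in self.yield_factors.items()},
            "biodiversity_fraction": self.biodiversity_fraction,
        }
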