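"""Readers and writers for the account, area, series and report schemas.

All files are plain UTF-8 CSV (``.`` decimal, no thousands separators) or
YAML/JSON.  Readers validate strictly and raise :class:`SchemaError`
messages naming the offending file, row and column.  Writers are
deterministic: stable column order, no timestamps, per-capita quantities
rounded to 4 decimals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Union

import pandas as pd

from .accounts import BioItemRecord, EnergyItemRecord
from .capacity import LandAreaRecord
from .errors import SchemaError
from .gm11 import GreySeries
from .landtypes import FactorTable, LandType
from .pipeline import ANNUAL_COLUMNS, AnnualBalanceTable, ForecastReport

PathLike = Union[str, Path]

PER_CAPITA_DECIMALS = 4

_BIO_FIXED = ["item", "land_type", "global_avg_yield_kg_per_hm2"]
_BIO_OPTIONAL = ["in_demand_aggregate"]
_ENERGY_FIXED = [
    "item",
    "land_type",
    "global_avg_energy_footprint_GJ_per_hm2",
    "convert_coefficient_GJ_per_t",
]

_TRUTHY = {"true", "1", "yes"}
_FALSY = {"false", "0", "no"}


def _read_csv(path: PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _number(value: str, path, row_label: str, column: str) -> float:
    # no thousands separators in data files: a comma is a schema violation
    try:
        return float(value)
    except (ValueError, TypeError):
        raise SchemaError(
            f"{path}: row {row_label!r}, column {column!r}: "
            f"non-numeric value {value!r}"
        ) from None


def _land_type(value: str, path, row_label: str) -> LandType:
    try:
        return LandType(value)
    except ValueError:
        valid = ", ".join(m.value for m in LandType)
        raise SchemaError(
            f"{path}: row {row_label!r}, column 'land_type': unknown land "
            f"type {value!r} (expected one of: {valid})"
        ) from None


def _flag(value: str, path, row_label: str, column: str) -> bool:
    v = value.strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise SchemaError(
        f"{path}: row {row_label!r}, column {column!r}: expected a boolean, "
        f"got {value!r}"
    )


def read_bio_account(path: PathLike) -> List[BioItemRecord]:
    """Read a biological-resource account CSV (production in tonnes)."""
    df = _read_csv(path)
    _require_columns(df, _BIO_FIXED, path)
    has_flag = "in_demand_aggregate" in df.columns
    cities = [
        c for c in df.columns if c not in _BIO_FIXED + _BIO_OPTIONAL
    ]
    if not cities:
        raise SchemaError(f"{path}: no city columns found")
    records = []
    for _, row in df.iterrows():
        name = row["item"]
        rec = BioItemRecord(
            item_name=name,
            land_type=_land_type(row["land_type"], path, name),
            global_average_yield=_number(
                row["global_avg_yield_kg_per_hm2"], path, name,
                "global_avg_yield_kg_per_hm2",
            ),
            production_by_city={
                c: _number(row[c], path, name, c) for c in cities
            },
            in_demand_aggregate=(
                _flag(row["in_demand_aggregate"], path, name,
                      "in_demand_aggregate")
                if has_flag else True
            ),
        )
        rec.validate()
        records.append(rec)
    return records


def read_energy_account(path: PathLike) -> List[EnergyItemRecord]:
    """Read an energy account CSV (consumption already in GJ)."""
    df = _read_csv(path)
    _require_columns(df, _ENERGY_FIXED, path)
    cities = [c for c in df.columns if c not in _ENERGY_FIXED]
    if not cities:
        raise SchemaError(f"{path}: no city columns found")
    records = []
    for _, row in df.iterrows():
        name = row["item"]
        coeff_raw = row["convert_coefficient_GJ_per_t"].strip()
        rec = EnergyItemRecord(
            item_name=name,
            land_type=_land_type(row["land_type"], path, name),
            global_average_energy_footprint=_number(
                row["global_avg_energy_footprint_GJ_per_hm2"], path, name,
                "global_avg_energy_footprint_GJ_per_hm2",
            ),
            consumption_by_city={
                c: _number(row[c], path, name, c) for c in cities
            },
            convert_coefficient=(
                _number(coeff_raw, path, name, "convert_coefficient_GJ_per_t")
                if coeff_raw else None
            ),
        )
        rec.validate()
        records.append(rec)
    return records


def read_land_areas(path: PathLike) -> List[LandAreaRecord]:
    """Read a supply-side land-area CSV (`land_type,area_hm2`)."""
    df = _read_csv(path)
    _require_columns(df, ["land_type", "area_hm2"], path)
    records = []
    for idx, row in df.iterrows():
        rec = LandAreaRecord(
            land_type=_land_type(row["land_type"], path, str(idx)),
            area=_number(row["area_hm2"], path, row["land_type"], "area_hm2"),
        )
        rec.validate()
        records.append(rec)
    return records


def read_series(path: PathLike, value_column: str = "value") -> GreySeries:
    """Read an annual series CSV (`year,value`)."""
    df = _read_csv(path)
    _require_columns(df, ["year", value_column], path)
    if len(df) == 0:
        raise SchemaError(f"{path}: series file has no rows")
    years = [
        int(_number(y, path, y, "year")) for y in df["year"]
    ]
    values = [
        _number(v, path, str(y), value_column)
        for y, v in zip(years, df[value_column])
    ]
    return GreySeries.from_arrays(years, values)


def read_factors(path: PathLike) -> FactorTable:
    """Read a factor configuration from YAML (or JSON, a YAML subset)."""
    return FactorTable.from_yaml(path)


def read_annual_table(path: PathLike) -> AnnualBalanceTable:
    """Read a balance table CSV with the five standard columns."""
    df = _read_csv(path)
    _require_columns(df, ANNUAL_COLUMNS, path)
    out = pd.DataFrame(
        {
            "year": [int(_number(v, path, v, "year")) for v in df["year"]],
            **{
                c: [_number(v, path, str(y), c)
                    for y, v in zip(df["year"], df[c])]
                for c in ANNUAL_COLUMNS[1:]
            },
        }
    )
    return AnnualBalanceTable(out)


def _rounded_annual_frame(table: AnnualBalanceTable) -> pd.DataFrame:
    df = table.data.copy()
    for c in ANNUAL_COLUMNS[1:]:
        df[c] = df[c].round(PER_CAPITA_DECIMALS)
    return df


def write_annual_table(
    table: AnnualBalanceTable, path: PathLike, format: str = "csv"
) -> None:
    """Write a balance table as CSV or JSON, per-capita values at 4 decimals."""
    df = _rounded_annual_frame(table)
    if format == "csv":
        df.to_csv(path, index=False, float_format=f"%.{PER_CAPITA_DECIMALS}f")
    elif format == "json":
        payload = {"annual_balance": df.to_dict(orient="records")}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise SchemaError(f"unknown output format {format!r}")


def write_forecast_report(
    report: ForecastReport, path: PathLike, format: str = "csv"
) -> None:
    """Write a forecast report as CSV (forecast rows) or JSON (full models)."""
    if format == "csv":
        df = report.to_frame()
        for c in ("ef_forecast", "ec_forecast", "deficit_forecast"):
            df[c] = df[c].round(PER_CAPITA_DECIMALS)
        df.to_csv(path, index=False, float_format=f"%.{PER_CAPITA_DECIMALS}f")
    elif format == "json":
        Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    else:
        raise SchemaError(f"unknown output format {format!r}")


def write_gm11_fit(fit, path: PathLike) -> None:
    """Export a fitted grey model as JSON."""
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")
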