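"""Monetizing the trade-off: fish-catch value vs the replacement cost of
lost sponge filtration.

Catch value is ex-vessel (reported value, or landings × unit price),
brought to a common reference year by compound inflation.  The lost
filtration service is valued by replacement cost against a wastewater
treatment plant of substantially equivalent daily flow — by default the
Ashbridges Bay Treatment Plant (ABTP, Toronto): 818 ML day⁻¹ nominal
capacity, 598 ML day⁻¹ average daily flow, USD 182 M capital cost for its
UV disinfection facility plus USD 5.4 M operating cost over a three-year
horizon.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import pandas as pd
import yaml

from .datasets import INFLATION_RATE_TO_2018, REFERENCE_YEAR

__all__ = [
    "PlantSpec",
    "ABTP",
    "CatchValue",
    "ReplacementCost",
    "catch_value",
    "inflation_adjust",
    "adjust_catch_value",
    "replacement_cost",
    "compare_values",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantSpec:
    """A treatment plant standing in for the filtration service."""

    name: str = "Ashbridges Bay Treatment Plant"
    nominal_capacity_ml_day: float = 818.0  # ×10⁶ L day⁻¹
    average_daily_flow_ml_day: float = 598.0
    capital_cost_usd: float = 182e6
    operating_cost_horizon_usd: float = 5.4e6  # total over the 3-year horizon
    horizon_years: int = 3

    def __post_init__(self) -> None:
        if self.capital_cost_usd < 0 or self.operating_cost_horizon_usd < 0:
            raise ValueError("costs must be nonnegative")
        if self.average_daily_flow_ml_day > self.nominal_capacity_ml_day:
            raise ValueError("average daily flow cannot exceed nominal capacity")

    @property
    def cost_per_plant_usd(self) -> float:
        return self.capital_cost_usd + self.operating_cost_horizon_usd

    @classmethod
    def from_yaml(cls, path) -> "PlantSpec":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


#: Default plant: the published ABTP figures.
ABTP = PlantSpec()


@dataclass
class CatchValue:
    """Ex-vessel catch value by year, with rows that could not be priced."""

    per_year_usd: pd.Series
    excluded: pd.DataFrame

    @property
    def total_usd(self) -> float:
        return float(self.per_year_usd.sum())


def catch_value(catch_table: pd.DataFrame) -> CatchValue:
    """Sum ex-vessel value per year.

    Rows with a ``value_usd`` pass through; otherwise value = catch_t ×
    unit_price_usd_per_t.  Rows with neither are excluded and logged.
    """
    df = catch_table.copy()
    values = pd.Series(float("nan"), index=df.index)
    if "value_usd" in df:
        values = df["value_usd"].astype(float)
    if "unit_price_usd_per_t" in df:
        priced = df["catch_t"].astype(float) * df["unit_price_usd_per_t"].astype(float)
        values = values.fillna(priced)
    excluded = df[values.isna()]
    if len(excluded):
        logger.warning(
            "excluding %d catch rows with no value or unit price: %s",
            len(excluded), excluded["species"].tolist(),
        )
    kept = values.dropna()
    if kept.empty:
        return CatchValue(per_year_usd=pd.Series(dtype=float), excluded=excluded)
    per_year = kept.groupby(df.loc[kept.index, "year"]).sum().sort_index()
    return CatchValue(per_year_usd=per_year, excluded=excluded)


def inflation_adjust(value_usd: float, annual_rate: float, n_years: float) -> float:
    """Compound inflation: value × (1 + rate)^years."""
    if n_years < 0:
        raise ValueError("n_years must be nonnegative")
    if annual_rate < 0:
        raise ValueError("annual_rate must be nonnegative")
    return value_usd * (1.0 + annual_rate) ** n_years

def adjust_catch_value(
    catch: CatchValue,
    rates_by_year: dict[int, float] | None = None,
    reference_year: int = REFERENCE_YEAR,
) -> pd.DataFrame:
    """Nominal and inflation-adjusted value per year, plus a TOTAL row.

    ``rates_by_year`` maps each catch year to its average annual inflation
    rate over year→reference (defaults to the published 2010/2011/2012 →
    2018 rates).
    """
    if rates_by_year is None:
        rates_by_year = INFLATION_RATE_TO_2018
    rows = []
    for year, nominal in catch.per_year_usd.items():
        rate = rates_by_year[int(year)]
        adjusted = inflation_adjust(nominal, rate, reference_year - int(year))
        rows.append((int(year), nominal, rate, adjusted))
    df = pd.DataFrame(rows, columns=["year", "value_usd", "inflation_rate", "adjusted_usd"])
    total = pd.DataFrame(
        [["TOTAL", df["value_usd"].sum(), float("nan"), df["adjusted_usd"].sum()]],
        columns=df.columns,
    )
    return pd.concat([df, total], ignore_index=True)


@dataclass(frozen=True)
class ReplacementCost:
    """Replacement-cost valuation of a filtration loss."""

    loss_ml_day: float
    plant: PlantSpec
    equivalence_ratio: float  # loss / plant average daily flow
    n_plants: int
    cost_usd: float

    @property
    def cost_usd_millions(self) -> float:
        """Cost rounded to the nearest million USD, in millions."""
        return round(self.cost_usd / 1e6)


def replacement_cost(
    filtration_loss_ml_day: float,
    plant: PlantSpec = ABTP,
) -> ReplacementCost:
    """Cost of replacing the lost daily filtration with treatment plants.

    The equivalence ratio is loss / average daily flow.  A ratio in
    (0.5, 1.5] — "substantially equivalent" throughput — costs one plant:
    capital plus horizon operating cost.  Beyond that band the nearest
    integer number of plants is charged (at least one for any positive
    loss); zero loss costs nothing.
    """
    if filtration_loss_ml_day < 0:
        raise ValueError("filtration loss must be nonnegative")
    ratio = filtration_loss_ml_day / plant.average_daily_flow_ml_day
    if filtration_loss_ml_day == 0:
        n_plants = 0
    elif 0.5 < ratio <= 1.5:
        n_plants = 1
    else:
        n_plants = max(1, round(ratio))
    return ReplacementCost(
        loss_ml_day=filtration_loss_ml_day,
        plant=plant,
        equivalence_ratio=ratio,
        n_plants=n_plants,
        cost_usd=n_plants * plant.cost_per_plant_usd,
    )


def compare_values(catch_total_adjusted_usd: float, replacement_cost_usd: float) -> dict:
    """Catch value vs replacement cost, both ways round."""
    if catch_total_adjusted_usd <= 0 or replacement_cost_usd <= 0:
        raise ValueError("both values must be positive to compare")
    return {
        "catch_usd": catch_total_adjusted_usd,
        "replacement_usd": replacement_cost_usd,
        "catch_to_replacement": catch_total_adjusted_usd / replacement_cost_usd,
        "replacement_to_catch": replacement_cost_usd / catch_total_adjusted_usd,
    }
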