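"""Income over feed cost and structural herd indicators from accounting data.

IOFC is milk revenue minus total feed cost (concentrates, vitamins,
minerals, wet by-products, roughage), expressed per cow-year and per
100 kg of milk delivered.  Structural indicators: equity ratio, expansion
rate (annualized over the gap to the nearest earlier record year) and
herd intensity (kg milk per hectare).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "FEED_COMPONENTS",
    "EconomicIndicators",
    "compute_iofc",
    "compute_price_indicators",
    "compute_structural_indicators",
    "compute_indicator_table",
]

logger = logging.getLogger(__name__)

FEED_COMPONENTS = (
    "feed_concentrates",
    "feed_vitamins",
    "feed_minerals",
    "feed_wet_byproducts",
    "feed_roughage",
)


@dataclass(frozen=True)
class EconomicIndicators:
    herd_id: object
    year: int
    iofc_cow: float
    iofc_milk: float
    total_feed_cost: float
    herd_milk_price: float
    relative_milk_price: float
    equity_ratio: float
    expansion_rate: float  # NaN when no earlier year exists
    herd_intensity: float


def compute_iofc(
    milk_revenue: float,
    feed_components: Sequence[float],
    herd_size: float,
    milk_delivered: float,
) -> tuple[float, float, float]:
    """(IOFC per cow-year, IOFC per 100 kg delivered, total feed cost)."""
    if herd_size <= 0:
        raise DomainError("herd_size must be positive")
    if milk_delivered <= 0:
        raise DomainError("milk_delivered must be positive")
    total_feed = float(np.sum(feed_components))
    margin = milk_revenue - total_feed
    return margin / herd_size, 100.0 * margin / milk_delivered, total_feed


def compute_price_indicators(
    milk_revenue: float, milk_delivered: float, national_price: float
) -> tuple[float, float]:
    """(herd milk price in EUR/100 kg, difference to the national price)."""
    if milk_delivered <= 0:
        raise DomainError("milk_delivered must be positive")
    herd_price = 100.0 * milk_revenue / milk_delivered
    return herd_price, herd_price - national_price


def compute_structural_indicators(
    assets: float,
    liabilities: float,
    sizes_by_year: Mapping[int, float],
    year: int,
    milk_kg: float,
    hectares: float,
) -> tuple[float, float, float]:
    """(equity ratio, expansion rate per year, herd intensity kg/ha).

    Expansion uses the nearest available earlier year n:
    ``((size_m - size_n)/size_n)/(m - n)``; with no earlier year it is NaN
    (missing, not zero) and logged.
    """
    if assets <= 0:
        raise DomainError("assets must be positive")
    if hectares <= 0:
        raise DomainError("hectares must be positive")
    if year not in sizes_by_year:
        raise DomainError(f"reference year {year} absent from sizes_by_year")
    equity = (assets - liabilities) / assets

    earlier = [y for y in sizes_by_year if y < year]
    if earlier:
        n = max(earlier)
        size_n, size_m = sizes_by_year[n], sizes_by_year[year]
        expansion = ((size_m - size_n) / size_n) / (year - n)
    else:
        logger.info("no year before %s: expansion rate left missing", year)
        expansion = float("nan")
    return equity, expansion, milk_kg / hectares


def compute_indicator_table(
    accounting: pd.DataFrame, national_price: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized indicators per (herd, year) from the accounting table.

    ``accounting`` columns: herd_id, year, milk_revenue, the five
    ``FEED_COMPONENTS``, total_assets, total_liabilities, herd_size,
    hectares, milk_delivered.  ``national_price``: year, national_price
    (EUR/100 kg).
    """
    acc = accounting.merge(national_price, on="year", how="left", validate="m:1")
    if acc["national_price"].isna().any():
        missing = sorted(acc.loc[acc["national_price"].isna(), "year"].unique())
        raise DomainError(f"no national milk price for year(s) {missing}")

    total_feed = acc[list(FEED_COMPONENTS)].sum(axis=1)
    margin = acc["milk_revenue"] - total_feed
    out = pd.DataFrame(
        {
            "herd_id": acc["herd_id"],
            "year": acc["year"].astype(int),
            "iofc_cow": margin / acc["herd_size"],
            "iofc_milk": 100.0 * margin / acc["milk_delivered"],
            "total_feed_cost": total_feed,
            "herd_milk_price": 100.0 * acc["milk_revenue"] / acc["milk_delivered"],
            "equity_ratio": (acc["total_assets"] - acc["total_liabilities"])
            / acc["total_assets"],
            "herd_intensity": acc["milk_delivered"] / acc["hectares"],
        }
    )
    out["relative_milk_price"] = out["herd_milk_price"] - acc["national_price"]

    # expansion against the nearest earlier year of the same herd
    acc_sorted = acc.sort_values(["herd_id", "year"])
    prev_size = acc_sorted.groupby("herd_id")["herd_size"].shift(1)
    prev_year = acc_sorted.groupby("herd_id")["year"].shift(1)
    expansion = ((acc_sorted["herd_size"] - prev_size) / prev_size) / (
        acc_sorted["year"] - prev_year
    )
    out["expansion_rate"] = expansion.reindex(out.index)
    return out
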