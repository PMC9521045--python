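"""Merge the three herd-year sources and apply the exclusion cascade.

Order of edits: (1) herds without a run of consecutive record years,
(2) direct sellers and organic herds, (3) extremely small herds below a
herd-size percentile, (4) per-variable percentile outliers, (5) records
with missing values.  Every step writes its excluded/remaining counts to
an audit log whose arithmetic must reconcile.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import pandas as pd

from .errors import IntegrityError, InvalidConfigError

__all__ = ["FilterConfig", "EditAuditLog", "merge_sources", "apply_filters"]

logger = logging.getLogger(__name__)

DEFAULT_OUTLIER_VARIABLES = (
    "iofc_cow",
    "iofc_milk",
    "herd_intensity",
    "equity_ratio",
    "hm305",
    "relative_milk_price",
    "scc",
    "calving_interval",
    "persistency_primiparous",
    "persistency_multiparous",
    "age_days",
)

HLCC_WIDE_COLUMNS = tuple(
    f"{var}_{grp}"
    for var in ("magnitude", "time_to_peak", "persistency")
    for grp in ("primiparous", "multiparous")
)


@dataclass(frozen=True)
class FilterConfig:
    min_consecutive_years: int = 2
    exclude_direct_sellers: bool = True
    exclude_organic: bool = True
    small_herd_percentile: float = 0.01
    outlier_variables: tuple[str, ...] = DEFAULT_OUTLIER_VARIABLES
    outlier_lower: float = 0.005
    outlier_upper: float = 0.995
    #: recompute percentiles on the table entering each step (vs once upfront)
    sequential_percentiles: bool = True

    def __post_init__(self) -> None:
        for p in (self.small_herd_percentile, self.outlier_lower, self.outlier_upper):
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError("percentiles must lie in [0, 1]")
        if self.outlier_lower >= self.outlier_upper:
            raise InvalidConfigError("outlier_lower must be < outlier_upper")
        if self.min_consecutive_years < 1:
            raise InvalidConfigError("min_consecutive_years must be >= 1")


@dataclass
class EditAuditLog:
    """Ordered record of the cascade: step name, excluded, remaining."""

    input_records: int = 0
    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, excluded: int, remaining: int) -> None:
        if self.steps and remaining > self.steps[-1]["remaining"]:
            raise IntegrityError("remaining counts must be non-increasing")
        self.steps.append(
            {"step": name, "excluded": int(excluded), "remaining": int(remaining)}
        )
        logger.info("edit step %-24s excluded=%-6d remaining=%d", name, excluded, remaining)

    @property
    def final_remaining(self) -> int:
        return self.steps[-1]["remaining"] if self.steps else self.input_records

    def reconciles(self) -> bool:
        total_excluded = sum(s["excluded"] for s in self.steps)
        return self.final_remaining == self.input_records - total_excluded

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def merge_sources(
    economics: pd.DataFrame,
    hlcc_wide: pd.DataFrame,
    performance: pd.DataFrame,
) -> pd.DataFrame:
    """Inner-join the three sources on (herd_id, year).

    ``hlcc_wide`` must already carry one row per herd-year with the six
    parity-specific HLCC columns (see
    :func:`lactecon.hlcc_aggregation.pivot_hlcc_wide`).  Duplicate keys in
    any source raise :class:`~lactecon.errors.IntegrityError`.
    """
    for name, df in (
        ("economics", economics),
        ("hlcc", hlcc_wide),
        ("performance", performance),
    ):
        if df.duplicated(subset=["herd_id", "year"]).any():
            raise IntegrityError(f"duplicate (herd_id, year) keys in {name} table")
    merged = economics.merge(hlcc_wide, on=["herd_id", "year"], how="inner")
    merged = merged.merge(performance, on=["herd_id", "year"], how="inner")
    return merged.reset_index(drop=True)


def _consecutive_mask(table: pd.DataFrame, min_years: int) -> pd.Series:
    """True for records inside a run of >= min_years consecutive years."""
    keep = pd.Series(False, index=table.index)
    for _, grp in table.groupby("herd_id"):
        years = sorted(grp["year"].unique())
        run = [years[0]] if years else []
        runs = []
        for y in years[1:]:
            if y == run[-1] + 1:
                run.append(y)
            else:
                runs.append(run)
                run = [y]
        if run:
            runs.append(run)
        good_years = {y for r in runs if len(r) >= min_years for y in r}
        keep.loc[grp.index[grp["year"].isin(good_years)]] = True
    return keep


def apply_filters(
    merged: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, EditAuditLog]:
    """Run the exclusion cascade; returns (analysis table, audit log)."""
    config = config or FilterConfig()
    unknown = [v for v in config.outlier_variables if v not in merged.columns]
    if unknown:
        raise InvalidConfigError(f"unknown outlier variable(s): {unknown}")

    table = merged.copy()
    log = EditAuditLog(input_records=len(table))

    keep = _consecutive_mask(table, config.min_consecutive_years)
    n_before = len(table)
    table = table[keep]
    log.add("consecutive_years", n_before - len(table), len(table))

    drop = pd.Series(False, index=table.index)
    if config.exclude_direct_sellers and "direct_seller" in table.columns:
        drop |= table["direct_seller"].astype(bool)
    if config.exclude_organic and "organic" in table.columns:
        drop |= table["organic"].astype(bool)
    n_before = len(table)
    table = table[~drop]
    log.add("herd_type", n_before - len(table), len(table))

    if "herd_size" in table.columns and len(table):
        cutoff = table["herd_size"].quantile(config.small_herd_percentile)
        n_before = len(table)
        table = table[table["herd_size"] >= cutoff]
        log.add("small_herds", n_before - len(table), len(table))
    else:
        log.add("small_herds", 0, len(table))

    base = table if config.sequential_percentiles else merged
    outlier = pd.Series(False, index=table.index)
    for var in config.outlier_variables:
        lo = base[var].quantile(config.outlier_lower)
        hi = base[var].quantile(config.outlier_upper)
        outlier |= (table[var] < lo) | (table[var] > hi)
    n_before = len(table)
    table = table[~outlier]
    log.add("outliers", n_before - len(table), len(table))

    n_before = len(table)
    table = table.dropna()
    log.add("missing_values", n_before - len(table), len(table))

    assert log.reconciles(), "audit log arithmetic failed to reconcile"
    return table.reset_index(drop=True), log
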