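"""Calendar-year partitioning of lactations and weighted-median herd curves.

A lactation that spans a year boundary contributes to each year it touches,
weighted by its number of test-day records in that year relative to the
herd-year-parity total.  Herd lactation curve characteristics (HLCC) are
the weighted medians of magnitude, time to peak and persistency over the
complete lactations in a herd x calendar year x parity cell; the first and
last year of the input span are dropped because their lactations are only
partially observed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "weighted_median",
    "partition_lactation_weights",
    "aggregate_hlcc",
]

logger = logging.getLogger(__name__)

_LACT_KEYS = ["herd_id", "cow_id", "lactation_id"]


def weighted_median(values, weights) -> float:
    """Lower weighted median: smallest value with cumulative weight >= 1/2.

    Weights are normalized internally; no interpolation between values.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise DomainError("weighted_median of empty sequence")
    if v.shape != w.shape:
        raise DomainError("values and weights must have equal length")
    if np.any(w < 0):
        raise DomainError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise DomainError("weights sum to zero")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order]) / total
    idx = np.searchsorted(cum, 0.5, side="left")
    return float(v[order][min(idx, v.size - 1)])


def partition_lactation_weights(
    test_days: pd.DataFrame, fits: pd.DataFrame
) -> pd.DataFrame:
    """Per-lactation calendar-year weights from test-day counts.

    For each lactation in ``fits``, counts its test-day records per calendar
    year (year of the test date) and normalizes by the total record count of
    the herd x year x parity-group cell, so that weights in every cell sum
    to one.  A lactation with 5 records in one year out of a cell total of
    n records gets weight 5/n there.

    ``test_days`` needs ``herd_id``, ``cow_id``, ``lactation_id`` and
    ``test_date`` (datetime-like); parity groups come from ``fits``.
    Lactations present in ``fits`` but with no test days are excluded and
    logged.
    """
    fits_keyed = fits.set_index(_LACT_KEYS)
    if fits_keyed.index.has_duplicates:
        raise DomainError("duplicate lactation keys in fits table")

    td = test_days.merge(
        fits[_LACT_KEYS + ["parity_group"]], on=_LACT_KEYS, how="inner"
    )
    missing = len(fits) - td.groupby(_LACT_KEYS).ngroups
    if missing:
        logger.warning("%d lactation(s) in fits have no test-day records", missing)

    td = td.assign(year=pd.to_datetime(td["test_date"]).dt.year)
    counts = (
        td.groupby(_LACT_KEYS + ["parity_group", "year"], sort=True)
        .size()
        .rename("test_days_in_year")
        .reset_index()
    )
    totals = (
        counts.groupby(["herd_id", "year", "parity_group"])["test_days_in_year"]
        .transform("sum")
    )
    counts["weight"] = counts["test_days_in_year"] / totals
    return counts


def aggregate_hlcc(
    fits: pd.DataFrame,
    weights: pd.DataFrame,
    year_span: tuple[int, int],
) -> pd.DataFrame:
    """Weighted-median HLCC per herd x year x parity group.

    Only complete, converged lactations contribute; the weighted median is
    invariant to the implied renormalization.  Rows for the first and last
    year of ``year_span`` are dropped.  Cells left without any contributing
    lactation produce no output row (logged).
    """
    first, last = year_span
    usable = fits[fits["complete"] & fits["converged"]]
    dropped = len(fits) - len(usable)
    if dropped:
        logger.info("excluded %d incomplete/unconverged lactations", dropped)

    merged = weights.merge(
        usable[_LACT_KEYS + ["magnitude", "ramp", "persistency"]],
        on=_LACT_KEYS,
        how="inner",
    )
    merged = merged[(merged["year"] > first) & (merged["year"] < last)]

    rows = []
    for (herd, year, parity), cell in merged.groupby(
        ["herd_id", "year", "parity_group"], sort=True
    ):
        w = cell["weight"].to_numpy()
        rows.append(
            {
                "herd_id": herd,
                "year": int(year),
                "parity_group": parity,
                "magnitude": weighted_median(cell["magnitude"], w),
                "time_to_peak": weighted_median(cell["ramp"], w),
                "persistency": weighted_median(cell["persistency"], w),
                "n_lactations": int(cell["lactation_id"].nunique()),
            }
        )
    if not rows:
        logger.warning("no herd-year-parity cell had complete lactations")
        return pd.DataFrame(
            columns=[
                "herd_id", "year", "parity_group",
                "magnitude", "time_to_peak", "persistency", "n_lactations",
            ]
        )
    return pd.DataFrame(rows)


def pivot_hlcc_wide(hlcc: pd.DataFrame) -> pd.DataFrame:
    """Pivot parity groups to columns: ``magnitude_primiparous`` etc."""
    wide = hlcc.pivot_table(
        index=["herd_id", "year"],
        columns="parity_group",
        values=["magnitude", "time_to_peak", "persistency"],
        aggfunc="first",
    )
    wide.columns = [f"{var}_{grp}" for var, grp in wide.columns]
    return wide.reset_index()
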