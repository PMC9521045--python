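"""Synthetic herd population with known ground truth.

Generates the four input tables of the pipeline — cow test-day records,
herd-year accounting, herd-year performance and national milk prices —
from a single seed, with every latent quantity (curve parameters, herd
intercepts, economic coefficients) recorded so downstream stages can be
tested for parameter recovery without any external data.

The income over feed cost per cow is built as an exact linear model in
the standardized herd-year covariates plus a herd random intercept and a
residual; accounting feed costs are then back-solved so that
``revenue - feed = IOFC_cow * herd_size`` holds by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .hlcc_aggregation import partition_lactation_weights, aggregate_hlcc, pivot_hlcc_wide
from .lactation_model import milkbot_yield, milkbot_m305, LN2
from .mixed_models import standardize_continuous

__all__ = [
    "ParityCurveParams",
    "SyntheticConfig",
    "GroundTruth",
    "PopulationTables",
    "generate_population",
    "generate_straddle_fixture",
    "write_population",
]

CONTINUOUS_COVARIATES = (
    "magnitude_primiparous",
    "time_to_peak_primiparous",
    "persistency_primiparous",
    "magnitude_multiparous",
    "time_to_peak_multiparous",
    "persistency_multiparous",
    "hm305",
    "herd_size",
    "equity_ratio",
    "expansion_rate",
    "herd_intensity",
    "relative_milk_price",
    "scc",
    "calving_interval",
    "age_days",
)


@dataclass(frozen=True)
class ParityCurveParams:
    """Lognormal curve-parameter distribution for one parity group."""

    a_mean: float
    b_mean: float
    d_mean: float
    herd_cv: float = 0.06  # herd-level spread of the group median
    cow_cv: float = 0.08  # cow-level spread within herd

    def __post_init__(self) -> None:
        if min(self.a_mean, self.b_mean, self.d_mean) <= 0:
            raise InvalidConfigError("curve parameter means must be positive")
        if min(self.herd_cv, self.cow_cv) < 0:
            raise InvalidConfigError("dispersions must be nonnegative")


def _default_primiparous() -> ParityCurveParams:
    return ParityCurveParams(a_mean=35.0, b_mean=29.6, d_mean=LN2 / 358.0)


def _default_multiparous() -> ParityCurveParams:
    return ParityCurveParams(a_mean=48.0, b_mean=22.1, d_mean=LN2 / 240.0)


def _default_coefficients() -> dict[str, float]:
    # true effects in EUR per SD of each standardized covariate
    return {
        "magnitude_primiparous": 50.0,
        "persistency_primiparous": 15.0,
        "magnitude_multiparous": 150.0,
        "persistency_multiparous": 65.0,
        "hm305": 0.0,
        "herd_size": -15.0,
        "scc": -22.0,
        "herd_intensity": -15.0,
        "calving_interval": -20.0,
        "relative_milk_price": 145.0,
    }


def _default_categorical_effects() -> dict[str, dict[str, float]]:
    # additive EUR effects of non-reference categorical levels
    return {"soil_type": {"sand": 20.0}, "outsourced_rearing": {"yes": 15.0}}


@dataclass(frozen=True)
class SyntheticConfig:
    n_herds: int = 20
    years: tuple[int, int] = (2007, 2016)  # test-day record span, inclusive
    herd_size_mean: float = 30.0
    parity_mix: float = 0.35  # fraction primiparous
    test_interval_days: float = 35.0
    test_interval_jitter: float = 7.0
    milk_noise_sd: float = 0.5
    straddle_frac: float = 0.5
    primiparous: ParityCurveParams = field(default_factory=_default_primiparous)
    multiparous: ParityCurveParams = field(default_factory=_default_multiparous)
    coefficients: dict = field(default_factory=_default_coefficients)
    categorical_effects: dict = field(default_factory=_default_categorical_effects)
    base_iofc: float = 2300.0
    year_effect_per_price: float = 60.0  # EUR per EUR/100kg deviation of the national price
    herd_sd: float = 200.0
    residual_sd: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_herds <= 0:
            raise InvalidConfigError("n_herds must be positive")
        if self.herd_size_mean <= 0:
            raise InvalidConfigError("herd_size_mean must be positive")
        if not 0.0 <= self.parity_mix <= 1.0:
            raise InvalidConfigError("parity_mix must lie in [0, 1]")
        if not 0.0 <= self.straddle_frac <= 1.0:
            raise InvalidConfigError("straddle_frac must lie in [0, 1]")
        if self.milk_noise_sd < 0 or self.herd_sd < 0 or self.residual_sd < 0:
            raise InvalidConfigError("standard deviations must be nonnegative")
        if self.test_interval_days <= self.test_interval_jitter:
            raise InvalidConfigError("test interval must exceed its jitter")
        first, last = self.years
        if last - first + 1 < 4:
            raise InvalidConfigError(
                "years span must cover >= 4 calendar years so edge-year "
                "exclusion leaves >= 2 usable years"
            )

    @property
    def usable_years(self) -> tuple[int, ...]:
        return tuple(range(self.years[0] + 1, self.years[1]))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    seed: int
    coefficients: dict
    categorical_effects: dict
    base_iofc: float
    year_effects: dict
    herd_intercepts: dict
    residual_sd: float
    scaling_means: dict
    scaling_sds: dict
    lactation_params: pd.DataFrame
    true_hlcc: pd.DataFrame
    analysis_frame: pd.DataFrame

    def to_json(self) -> str:
        payload = asdict(self)
        for key in ("lactation_params", "true_hlcc", "analysis_frame"):
            payload[key] = getattr(self, key).to_dict(orient="list")
        return json.dumps(payload, default=str)


class PopulationTables(NamedTuple):
    test_days: pd.DataFrame
    accounting: pd.DataFrame
    performance: pd.DataFrame
    national_price: pd.DataFrame
    truth: GroundTruth


def _draw_lognormal(rng, mean: float, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean, dtype=float)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(math.log(mean) - 0.5 * sigma * sigma, sigma, size=size)


def _generate_lactations(config: SyntheticConfig, rng, herd_year: pd.DataFrame):
    """Lactation-level latent parameters, calving dates and test schedules."""
    n_lact_per = herd_year["herd_size"].to_numpy()
    lact_herd = np.repeat(herd_year["herd_id"].to_numpy(), n_lact_per)
    lact_year = np.repeat(herd_year["year"].to_numpy(), n_lact_per)
    mult_a = np.repeat(herd_year["mult_a"].to_numpy(), n_lact_per)
    mult_b = np.repeat(herd_year["mult_b"].to_numpy(), n_lact_per)
    mult_d = np.repeat(herd_year["mult_d"].to_numpy(), n_lact_per)
    n_lact = len(lact_herd)

    primi = rng.random(n_lact) < config.parity_mix
    pp, mp = config.primiparous, config.multiparous
    a = np.where(
        primi,
        _draw_lognormal(rng, pp.a_mean, pp.cow_cv, n_lact),
        _draw_lognormal(rng, mp.a_mean, mp.cow_cv, n_lact),
    ) * mult_a
    b = np.where(
        primi,
        _draw_lognormal(rng, pp.b_mean, pp.cow_cv, n_lact),
        _draw_lognormal(rng, mp.b_mean, mp.cow_cv, n_lact),
    ) * mult_b
    d = np.where(
        primi,
        _draw_lognormal(rng, pp.d_mean, pp.cow_cv, n_lact),
        _draw_lognormal(rng, mp.d_mean, mp.cow_cv, n_lact),
    ) * mult_d

    # test-day schedule: first weighing DIM 5-14, then jittered intervals
    straddler = rng.random(n_lact) < config.straddle_frac
    dryoff = rng.integers(280, 421, size=n_lact).astype(float)
    dryoff = np.where(straddler, dryoff, np.minimum(dryoff, 350.0))
    first_dim = rng.integers(5, 15, size=n_lact).astype(float)
    max_tests = int(np.ceil(420.0 / (config.test_interval_days - config.test_interval_jitter))) + 2
    intervals = config.test_interval_days + rng.uniform(
        -config.test_interval_jitter, config.test_interval_jitter, size=(n_lact, max_tests)
    )
    dims = first_dim[:, None] + np.concatenate(
        [np.zeros((n_lact, 1)), np.cumsum(intervals, axis=1)[:, :-1]], axis=1
    )
    dims = np.round(dims)
    valid = dims <= dryoff[:, None]
    last_test_dim = np.max(np.where(valid, dims, 0.0), axis=1)

    # place calving day-of-year so the schedule does (not) cross New Year
    hi_ns = np.maximum(364.0 - last_test_dim, 0.0)
    doy_non = np.floor(rng.uniform(0.0, hi_ns + 1.0)).astype(int)
    lo_s = np.minimum(365.0 - last_test_dim + 1.0, 364.0)
    lo_s = np.maximum(lo_s, 0.0)
    doy_str = np.floor(rng.uniform(lo_s, 365.0)).astype(int)
    doy = np.where(straddler, doy_str, doy_non)

    lact = pd.DataFrame(
        {
            "herd_id": lact_herd,
            "calving_year": lact_year,
            "parity": np.where(primi, 1, rng.integers(2, 6, size=n_lact)),
            "a": a,
            "b": b,
            "d": d,
            "doy": doy,
            "straddler": straddler,
        }
    )
    lact["lactation_id"] = [f"L{i:07d}" for i in range(n_lact)]
    lact["cow_id"] = [f"C{i:07d}" for i in range(n_lact)]
    lact["parity_group"] = np.where(primi, "primiparous", "multiparous")
    lact["m305"] = milkbot_m305(a, b, d)
    return lact, dims, valid


def _test_day_table(config: SyntheticConfig, rng, lact: pd.DataFrame, dims, valid):
    counts = valid.sum(axis=1)
    flat_dim = dims[valid]
    idx = np.repeat(np.arange(len(lact)), counts)
    a = lact["a"].to_numpy()[idx]
    b = lact["b"].to_numpy()[idx]
    d = lact["d"].to_numpy()[idx]
    milk = milkbot_yield(flat_dim, a, b, d)
    if config.milk_noise_sd > 0:
        milk = milk + rng.normal(0.0, config.milk_noise_sd, size=len(milk))
    milk = np.maximum(milk, 0.0)

    n_rows = len(flat_dim)
    calving = pd.to_datetime(
        pd.DataFrame(
            {
                "year": lact["calving_year"].to_numpy()[idx],
                "month": np.ones(n_rows, dtype=int),
                "day": np.ones(n_rows, dtype=int),
            }
        )
    ) + pd.to_timedelta(lact["doy"].to_numpy()[idx], unit="D")
    test_date = calving + pd.to_timedelta(flat_dim, unit="D")
    return pd.DataFrame(
        {
            "herd_id": lact["herd_id"].to_numpy()[idx],
            "cow_id": lact["cow_id"].to_numpy()[idx],
            "lactation_id": lact["lactation_id"].to_numpy()[idx],
            "parity": lact["parity"].to_numpy()[idx],
            "calving_date": calving.dt.date,
            "test_date": test_date.dt.date,
            "dim": flat_dim.astype(int),
            "milk_kg": milk,
        }
    )


def generate_population(config: SyntheticConfig) -> PopulationTables:
    """Generate all four tables and the matching :class:`GroundTruth`.

    Deterministic in ``config.rng_seed``: two calls with the same config
    produce byte-identical tables.
    """
    rng = np.random.default_rng(config.rng_seed)
    first, last = config.years
    usable = list(config.usable_years)

    herd_ids = np.array([f"H{i:04d}" for i in range(config.n_herds)])
    base_size = np.maximum(
        6, np.round(_draw_lognormal(rng, config.herd_size_mean, 0.30, config.n_herds))
    ).astype(int)
    hectares = base_size * _draw_lognormal(rng, 0.55, 0.20, config.n_herds)
    assets = base_size * _draw_lognormal(rng, 25_000.0, 0.25, config.n_herds)
    liability_frac = rng.beta(2.2, 2.0, size=config.n_herds)
    soil = np.where(rng.random(config.n_herds) < 0.40, "sand", "other")
    milking = np.where(rng.random(config.n_herds) < 0.25, "automatic", "conventional")
    successor = np.where(rng.random(config.n_herds) < 0.50, "yes", "no")
    outsourced = np.where(rng.random(config.n_herds) < 0.30, "yes", "no")
    direct_seller = rng.random(config.n_herds) < 0.03
    organic = rng.random(config.n_herds) < 0.03
    herd_intercept = rng.normal(0.0, config.herd_sd, size=config.n_herds)
    rel_price_base = rng.normal(2.5, 2.0, size=config.n_herds)
    scc_base = rng.normal(190.0, 40.0, size=config.n_herds)
    ci_base = rng.normal(414.0, 15.0, size=config.n_herds)

    # per-herd multiplicative shift of the curve-parameter medians: the
    # between-herd signal the economic model is driven by
    mult_a = _draw_lognormal(rng, 1.0, config.primiparous.herd_cv, config.n_herds)
    mult_b = _draw_lognormal(rng, 1.0, config.primiparous.herd_cv, config.n_herds)
    mult_d = _draw_lognormal(rng, 1.0, config.multiparous.herd_cv, config.n_herds)

    all_years = list(range(first, last + 1))
    growth = rng.normal(0.03, 0.05, size=(config.n_herds, len(all_years)))
    growth[:, 0] = 0.0
    size_matrix = np.maximum(
        6, np.round(base_size[:, None] * np.cumprod(1.0 + growth, axis=1))
    ).astype(int)

    herd_year = pd.DataFrame(
        {
            "herd_id": np.repeat(herd_ids, len(all_years)),
            "year": np.tile(all_years, config.n_herds),
            "herd_size": size_matrix.ravel(),
            "mult_a": np.repeat(mult_a, len(all_years)),
            "mult_b": np.repeat(mult_b, len(all_years)),
            "mult_d": np.repeat(mult_d, len(all_years)),
        }
    )

    lact, dims, valid = _generate_lactations(config, rng, herd_year)
    test_days = _test_day_table(config, rng, lact, dims, valid)

    # ground-truth HLCC from the true parameters via the same partitioning
    true_fits = pd.DataFrame(
        {
            "herd_id": lact["herd_id"],
            "cow_id": lact["cow_id"],
            "lactation_id": lact["lactation_id"],
            "parity_group": lact["parity_group"],
            "magnitude": lact["a"],
            "ramp": lact["b"],
            "persistency": LN2 / lact["d"],
            "complete": True,
            "converged": True,
        }
    )
    weights = partition_lactation_weights(test_days, true_fits)
    true_hlcc = pivot_hlcc_wide(aggregate_hlcc(true_fits, weights, (first, last)))

    # national milk price: noisy series with a forced dip in the second
    # usable year to exercise the year fixed effect
    price_years = pd.DataFrame({"year": all_years})
    price = 34.0 + rng.normal(0.0, 1.5, size=len(all_years))
    if len(usable) >= 2:
        dip_idx = all_years.index(usable[1])
        price[dip_idx] -= 7.0
    price_years["national_price"] = np.round(price, 2)

    # herd-year level milk delivered: proportional to summed test-day milk
    td_year = test_days.assign(year=pd.to_datetime(test_days["test_date"]).dt.year)
    milk_sums = (
        td_year.groupby(["herd_id", "year"])["milk_kg"].sum().rename("milk_sum")
    )
    hy = herd_year[herd_year["year"].isin(usable)].copy()
    hy = hy.merge(milk_sums, on=["herd_id", "year"], how="left")
    hy["milk_sum"] = hy["milk_sum"].fillna(0.0)
    hy["milk_delivered"] = hy["milk_sum"] * config.test_interval_days
    hy = hy.merge(price_years, on="year")

    herd_frame = pd.DataFrame(
        {
            "herd_id": herd_ids,
            "hectares": hectares,
            "total_assets": assets,
            "liability_frac": liability_frac,
            "soil_type": soil,
            "milking_system": milking,
            "successor": successor,
            "outsourced_rearing": outsourced,
            "direct_seller": direct_seller,
            "organic": organic,
            "herd_intercept": herd_intercept,
            "rel_price_base": rel_price_base,
            "scc_base": scc_base,
            "ci_base": ci_base,
        }
    )
    hy = hy.merge(herd_frame, on="herd_id")
    hy = hy.sort_values(["herd_id", "year"]).reset_index(drop=True)
    n_hy = len(hy)

    hy["relative_milk_price"] = hy["rel_price_base"] + rng.normal(0.0, 0.5, n_hy)
    hy["herd_milk_price"] = hy["national_price"] + hy["relative_milk_price"]
    hy["milk_revenue"] = hy["herd_milk_price"] / 100.0 * hy["milk_delivered"]
    hy["total_liabilities"] = hy["total_assets"] * hy["liability_frac"] * (
        1.0 + rng.normal(0.0, 0.03, n_hy)
    )
    hy["equity_ratio"] = (hy["total_assets"] - hy["total_liabilities"]) / hy["total_assets"]
    hy["herd_intensity"] = hy["milk_delivered"] / hy["hectares"]
    hy["scc"] = np.maximum(hy["scc_base"] + rng.normal(0.0, 25.0, n_hy), 40.0)
    hy["calving_interval"] = hy["ci_base"] + rng.normal(0.0, 8.0, n_hy)
    hy["age_days"] = rng.normal(1716.0, 120.0, n_hy)

    # expansion vs previous calendar year (always available inside the span)
    year_pos = {y: i for i, y in enumerate(all_years)}
    prev_sizes = np.array(
        [
            size_matrix[np.where(herd_ids == h)[0][0], year_pos[y] - 1]
            for h, y in zip(hy["herd_id"], hy["year"])
        ]
    )
    hy["expansion_rate"] = (hy["herd_size"] - prev_sizes) / prev_sizes

    # HM305: test-day-weighted mean of the true per-lactation 305-d yields
    counts = (
        td_year.groupby(["herd_id", "year", "lactation_id"]).size().rename("n_td").reset_index()
    )
    counts = counts.merge(lact[["lactation_id", "m305"]], on="lactation_id")
    counts["w_m305"] = counts["n_td"] * counts["m305"]
    hm = counts.groupby(["herd_id", "year"]).agg(
        w_sum=("w_m305", "sum"), n_sum=("n_td", "sum")
    )
    hm["hm305"] = hm["w_sum"] / hm["n_sum"]
    hy = hy.merge(hm[["hm305"]], on=["herd_id", "year"], how="left")

    hy = hy.merge(true_hlcc, on=["herd_id", "year"], how="left")
    hlcc_cols = [c for c in true_hlcc.columns if c not in ("herd_id", "year")]
    for c in hlcc_cols:  # rare empty parity cells: fill for generation only
        hy[c] = hy[c].fillna(hy[c].mean())

    # IOFC from the configured linear model in standardized covariates
    covariates = [c for c in CONTINUOUS_COVARIATES if c in hy.columns]
    std, scaling = standardize_continuous(hy[covariates + ["herd_id", "year"]], covariates)
    linear = np.full(n_hy, config.base_iofc)
    for name, coef in config.coefficients.items():
        if name not in std.columns:
            raise InvalidConfigError(f"unknown coefficient target {name!r}")
        linear = linear + coef * std[name].to_numpy()
    for var, levels in config.categorical_effects.items():
        for level, effect in levels.items():
            linear = linear + effect * (hy[var].to_numpy() == level)
    mean_price = float(np.mean(price_years.loc[price_years["year"].isin(usable), "national_price"]))
    year_effects = {
        int(y): config.year_effect_per_price
        * (float(price_years.loc[price_years["year"] == y, "national_price"].iloc[0]) - mean_price)
        for y in usable
    }
    linear = linear + np.array([year_effects[int(y)] for y in hy["year"]])
    linear = linear + hy["herd_intercept"].to_numpy()
    iofc_cow = linear + rng.normal(0.0, config.residual_sd, n_hy)
    hy["iofc_cow"] = iofc_cow
    hy["iofc_milk"] = 100.0 * iofc_cow * hy["herd_size"] / hy["milk_delivered"]

    # back-solve feed so revenue - feed = IOFC_cow * herd_size exactly
    feed_total = hy["milk_revenue"] - hy["iofc_cow"] * hy["herd_size"]
    base_fracs = np.array([0.55, 0.03, 0.04, 0.13, 0.25])
    jitter = rng.uniform(0.85, 1.15, size=(n_hy, 5)) * base_fracs
    fracs = jitter / jitter.sum(axis=1, keepdims=True)
    feed_cols = [
        "feed_concentrates",
        "feed_vitamins",
        "feed_minerals",
        "feed_wet_byproducts",
        "feed_roughage",
    ]
    for j, col in enumerate(feed_cols):
        hy[col] = feed_total * fracs[:, j]

    accounting = hy[
        [
            "herd_id",
            "year",
            "milk_revenue",
            *feed_cols,
            "total_assets",
            "total_liabilities",
            "herd_size",
            "hectares",
            "milk_delivered",
            "soil_type",
            "milking_system",
            "successor",
            "outsourced_rearing",
            "direct_seller",
            "organic",
        ]
    ].copy()
    performance = hy[["herd_id", "year", "hm305", "scc", "calving_interval", "age_days"]].copy()

    analysis_frame = hy[
        ["herd_id", "year", "iofc_cow", "iofc_milk", *covariates,
         "soil_type", "milking_system", "successor", "outsourced_rearing"]
    ].copy()

    truth = GroundTruth(
        seed=config.rng_seed,
        coefficients=dict(config.coefficients),
        categorical_effects={k: dict(v) for k, v in config.categorical_effects.items()},
        base_iofc=config.base_iofc,
        year_effects=year_effects,
        herd_intercepts=dict(zip(herd_ids, herd_intercept)),
        residual_sd=config.residual_sd,
        scaling_means=scaling.means,
        scaling_sds=scaling.sds,
        lactation_params=lact[
            ["herd_id", "cow_id", "lactation_id", "parity_group", "calving_year",
             "a", "b", "d", "m305", "straddler"]
        ].copy(),
        true_hlcc=true_hlcc,
        analysis_frame=analysis_frame,
    )
    return PopulationTables(test_days, accounting, performance, price_years, truth)


def generate_straddle_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hand-built herd with one lactation straddling a year boundary.

    The straddling lactation ``L000`` (primiparous, calving 2008-08-10)
    has exactly 5 test days in 2008 and 3 in 2009.  Filler primiparous
    lactations bring the herd totals to n = 100 primiparous test-day
    records in 2008 and m = 50 in 2009, so its weights are 5/100 and
    3/50.  Returns ``(test_days, fits)`` where the fits carry dummy
    curve values and are flagged complete.
    """
    rows = []

    def add_lactation(lact_id, calving, dims):
        calving_ts = pd.Timestamp(calving)
        for dim in dims:
            rows.append(
                {
                    "herd_id": "HF01",
                    "cow_id": f"cow_{lact_id}",
                    "lactation_id": lact_id,
                    "parity": 1,
                    "calving_date": calving_ts.date(),
                    "test_date": (calving_ts + pd.Timedelta(days=dim)).date(),
                    "dim": dim,
                    "milk_kg": 30.0,
                }
            )

    # 5 tests in 2008 (Aug 20 .. Dec 18), 3 in 2009 (Jan 17 .. Mar 18)
    add_lactation("L000", "2008-08-10", [10, 40, 70, 100, 130, 160, 190, 220])
    for i in range(19):  # 19 x 5 = 95 filler records inside 2008
        add_lactation(f"L1{i:02d}", "2008-02-01", [10, 40, 70, 100, 130])
    for i in range(9):  # 9 x 5 = 45 filler records inside 2009
        add_lactation(f"L2{i:02d}", "2009-02-01", [10, 40, 70, 100, 130])
    # two more 2009 records to reach m = 50: one filler with 2 early tests
    add_lactation("L290", "2009-03-01", [10, 40])

    test_days = pd.DataFrame(rows)
    lact_ids = test_days["lactation_id"].unique()
    fits = pd.DataFrame(
        {
            "herd_id": "HF01",
            "cow_id": [f"cow_{l}" for l in lact_ids],
            "lactation_id": lact_ids,
            "parity_group": "primiparous",
            "magnitude": 30.0,
            "ramp": 25.0,
            "persistency": 300.0,
            "complete": True,
            "converged": True,
        }
    )
    return test_days, fits


def write_population(tables: PopulationTables, outdir: str | Path) -> dict[str, Path]:
    """Write the four CSVs plus the ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("test_days", tables.test_days),
        ("accounting", tables.accounting),
        ("performance", tables.performance),
        ("national_price", tables.national_price),
    ):
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(tables.truth.to_json())
    paths["ground_truth"] = truth_path
    return paths
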