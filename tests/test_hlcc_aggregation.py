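import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lactecon.errors import DomainError
from lactecon.hlcc_aggregation import (
    aggregate_hlcc,
    partition_lactation_weights,
    pivot_hlcc_wide,
    weighted_median,
)
from lactecon.synthetic_data import generate_straddle_fixture


def wm_oracle(values, weights):
    """Exhaustive enumeration of the lower-weighted-median definition."""
    pairs = sorted(zip(values, weights), key=lambda p: p[0])
    total = sum(w for _, w in pairs)
    cum = 0.0
    for v, w in pairs:
        cum += w
        if cum / total >= 0.5:
            return v
    return pairs[-1][0]


class TestWeightedMedian:
    def test_singleton(self):
        assert weighted_median([34.8], [1.0]) == 34.8

    def test_three_values(self):
        # cumulative weights 0.2, 0.5, 1.0 -> first >= 0.5 is 35
        assert weighted_median([30, 35, 40], [0.2, 0.3, 0.5]) == 35

    def test_lower_median_convention(self):
        assert weighted_median([10, 20], [0.5, 0.5]) == 10

    def test_unnormalized_weights_equivalent(self):
        assert weighted_median([30, 35, 40], [2, 3, 5]) == 35

    def test_empty_and_zero_weight_errors(self):
        with pytest.raises(DomainError):
            weighted_median([], [])
        with pytest.raises(DomainError):
            weighted_median([1.0, 2.0], [0.0, 0.0])
        with pytest.raises(DomainError):
            weighted_median([1.0], [-1.0])

    @given(
        st.lists(
            st.tuples(st.floats(-100, 100), st.floats(0.01, 10)),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_enumeration_oracle(self, pairs):
        values = [v for v, _ in pairs]
        weights = [w for _, w in pairs]
        assert weighted_median(values, weights) == wm_oracle(values, weights)

    def test_permutation_invariance(self, rng):
        values = rng.normal(size=7)
        weights = rng.uniform(0.1, 1, size=7)
        ref = weighted_median(values, weights)
        for _ in range(10):
            perm = rng.permutation(7)
            assert weighted_median(values[perm], weights[perm]) == ref


class TestPartition:
    def test_straddle_fixture_weights(self):
        test_days, fits = generate_straddle_fixture()
        weights = partition_lactation_weights(test_days, fits)
        row08 = weights.query("lactation_id == 'L000' and year == 2008").iloc[0]
        row09 = weights.query("lactation_id == 'L000' and year == 2009").iloc[0]
        assert row08["test_days_in_year"] == 5
        assert row09["test_days_in_year"] == 3
        n = weights.query("year == 2008")["test_days_in_year"].sum()
        m = weights.query("year == 2009")["test_days_in_year"].sum()
        assert n == 100 and m == 50
        assert row08["weight"] == pytest.approx(5 / 100)
        assert row09["weight"] == pytest.approx(3 / 50)

    def test_lone_lactation_weight_one(self):
        test_days, fits = generate_straddle_fixture()
        solo_td = test_days[test_days["lactation_id"] == "L100"]
        solo_fit = fits[fits["lactation_id"] == "L100"]
        weights = partition_lactation_weights(solo_td, solo_fit)
        assert len(weights) == 1
        assert weights["weight"].iloc[0] == pytest.approx(1.0)

    def test_cell_weights_sum_to_one(self, small_population):
        _, pop = small_population
        from lactecon.lactation_model import LN2

        fits = pop.truth.lactation_params.rename(
            columns={"a": "magnitude", "b": "ramp"}
        ).assign(
            persistency=lambda df: LN2 / df["d"], complete=True, converged=True
        )
        weights = partition_lactation_weights(pop.test_days, fits)
        sums = weights.groupby(["herd_id", "year", "parity_group"])["weight"].sum()
        assert np.allclose(sums.to_numpy(), 1.0, atol=1e-12)


class TestAggregate:
    def test_constant_inputs_exact(self):
        test_days, fits = generate_straddle_fixture()
        weights = partition_lactation_weights(test_days, fits)
        hlcc = aggregate_hlcc(fits, weights, (2007, 2010))
        assert (hlcc["magnitude"] == 30.0).all()
        assert (hlcc["time_to_peak"] == 25.0).all()
        assert (hlcc["persistency"] == 300.0).all()

    def test_edge_years_dropped(self, small_population):
        config, pop = small_population
        from lactecon.lactation_model import LN2

        fits = pop.truth.lactation_params.rename(
            columns={"a": "magnitude", "b": "ramp"}
        ).assign(persistency=lambda df: LN2 / df["d"], complete=True, converged=True)
        weights = partition_lactation_weights(pop.test_days, fits)
        hlcc = aggregate_hlcc(fits, weights, config.years)
        first, last = config.years
        assert hlcc["year"].min() > first
        assert hlcc["year"].max() < last

    def test_paper_year_span_pattern(self):
        # a 2007-2016 span must emit only 2008-2015
        rows = []
        for year in range(2007, 2017):
            for k in range(4):
                lid = f"L{year}_{k}"
                for dim in (10, 40, 70, 100, 130, 160, 190, 220, 250):
                    date = pd.Timestamp(f"{year}-01-05") + pd.Timedelta(days=dim)
                    rows.append(
                        {
                            "herd_id": "H1",
                            "cow_id": lid,
                            "lactation_id": lid,
                            "parity": 1,
                            "test_date": date,
                            "dim": dim,
                            "milk_kg": 30.0,
                        }
                    )
        test_days = pd.DataFrame(rows)
        lids = test_days["lactation_id"].unique()
        fits = pd.DataFrame(
            {
                "herd_id": "H1",
                "cow_id": lids,
                "lactation_id": lids,
                "parity_group": "primiparous",
                "magnitude": 30.0,
                "ramp": 25.0,
                "persistency": 280.0,
                "complete": True,
                "converged": True,
            }
        )
        weights = partition_lactation_weights(test_days, fits)
        hlcc = aggregate_hlcc(fits, weights, (2007, 2016))
        assert sorted(hlcc["year"].unique()) == list(range(2008, 2016))

    def test_matches_weighted_median_oracle(self, small_population):
        config, pop = small_population
        from lactecon.lactation_model import LN2

        fits = pop.truth.lactation_params.rename(
            columns={"a": "magnitude", "b": "ramp"}
        ).assign(persistency=lambda df: LN2 / df["d"], complete=True, converged=True)
        weights = partition_lactation_weights(pop.test_days, fits)
        hlcc = aggregate_hlcc(fits, weights, config.years)
        merged = weights.merge(
            fits[["lactation_id", "magnitude"]], on="lactation_id"
        )
        for _, row in hlcc.sample(20, random_state=0).iterrows():
            cell = merged.query(
                "herd_id == @row.herd_id and year == @row.year "
                "and parity_group == @row.parity_group"
            )
            expected = wm_oracle(cell["magnitude"].tolist(), cell["weight"].tolist())
            assert row["magnitude"] == pytest.approx(expected, abs=1e-9)

    def test_monotone_shift(self):
        test_days, fits = generate_straddle_fixture()
        fits2 = fits.copy()
        rng = np.random.default_rng(3)
        fits["magnitude"] = 30.0 + rng.uniform(-3, 3, len(fits))
        fits2["magnitude"] = fits["magnitude"] + 1.0
        weights = partition_lactation_weights(test_days, fits)
        h1 = aggregate_hlcc(fits, weights, (2007, 2010))
        h2 = aggregate_hlcc(fits2, weights, (2007, 2010))
        assert np.allclose(h2["magnitude"], h1["magnitude"] + 1.0)

    def test_row_order_invariance(self):
        test_days, fits = generate_straddle_fixture()
        rng = np.random.default_rng(5)
        fits["magnitude"] = 30.0 + rng.uniform(-3, 3, len(fits))
        weights = partition_lactation_weights(test_days, fits)
        base = aggregate_hlcc(fits, weights, (2007, 2010))
        shuffled = aggregate_hlcc(
            fits.sample(frac=1, random_state=1),
            weights.sample(frac=1, random_state=2),
            (2007, 2010),
        )
        pd.testing.assert_frame_equal(
            base.reset_index(drop=True), shuffled.reset_index(drop=True)
        )

    def test_incomplete_excluded(self):
        test_days, fits = generate_straddle_fixture()
        fits.loc[fits["lactation_id"] != "L000", "magnitude"] = 50.0
        fits.loc[fits["lactation_id"] != "L000", "complete"] = False
        weights = partition_lactation_weights(test_days, fits)
        hlcc = aggregate_hlcc(fits, weights, (2007, 2010))
        # only the straddler remains; its constant value survives
        assert (hlcc["magnitude"] == 30.0).all()

    def test_pivot_wide_columns(self, small_population):
        _, pop = small_population
        wide = pop.truth.true_hlcc
        assert {"magnitude_primiparous", "persistency_multiparous"} <= set(wide.columns)
        assert not wide.duplicated(subset=["herd_id", "year"]).any()
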