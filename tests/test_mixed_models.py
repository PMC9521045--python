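import numpy as np
import pandas as pd
import pytest

from lactecon.errors import DegenerateDataError, DomainError, InvalidConfigError
from lactecon.mixed_models import (
    ModelSpec,
    back_transform,
    backward_select_aic,
    compute_vif,
    fit_lmm,
    r2_decomposition,
    standardize_continuous,
)


def _sim_lmm(rng, n_herds=50, per=5, beta=(0.0, 0.0), herd_sd=1.0, resid_sd=1.0,
             intercept=5.0):
    n = n_herds * per
    herd = np.repeat(np.arange(n_herds), per)
    year = np.tile(np.arange(2008, 2008 + per), n_herds)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    u = rng.normal(0, herd_sd, n_herds)[herd]
    y = intercept + beta[0] * x1 + beta[1] * x2 + u + rng.normal(0, resid_sd, n)
    return pd.DataFrame(dict(herd_id=herd, year=year, x1=x1, x2=x2, y=y))


class TestStandardize:
    def test_mean_zero_sd_one(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, scaling = standardize_continuous(df, ["x"])
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert scaling.means["x"] == 2.0

    def test_idempotent_on_standardized(self):
        df = pd.DataFrame({"x": [-1.0, 0.0, 1.0]})
        once, _ = standardize_continuous(df, ["x"])
        twice, _ = standardize_continuous(once, ["x"])
        assert np.allclose(once["x"], twice["x"], atol=1e-12)

    def test_round_trip(self, rng):
        df = pd.DataFrame({"x": rng.normal(10, 3, 50), "y": rng.normal(size=50)})
        std, scaling = standardize_continuous(df, ["x"])
        back = back_transform(std, scaling)
        assert np.allclose(back["x"], df["x"], atol=1e-10)
        assert np.allclose(back["y"], df["y"])

    def test_zero_sd_errors(self):
        df = pd.DataFrame({"x": [2.0, 2.0, 2.0]})
        with pytest.raises(DegenerateDataError):
            standardize_continuous(df, ["x"])


class TestVif:
    def test_orthogonal_columns(self):
        design = pd.DataFrame({"a": [1.0, 1.0, -1.0, -1.0], "b": [1.0, -1.0, 1.0, -1.0]})
        vifs = compute_vif(design)
        assert vifs["a"] == pytest.approx(1.0, abs=1e-12)
        assert vifs["b"] == pytest.approx(1.0, abs=1e-12)

    def test_correlation_09_closed_form(self, rng):
        # build two columns with sample correlation exactly 0.9
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std(ddof=1)
        e = rng.normal(size=200)
        beta, _, _, _ = np.linalg.lstsq(
            np.column_stack([np.ones(200), x]), e, rcond=None
        )
        e = e - beta[0] - beta[1] * x  # orthogonal residual
        e = e / e.std(ddof=1)
        ycol = 0.9 * x + np.sqrt(1 - 0.81) * e
        design = pd.DataFrame({"x": x, "y": ycol})
        assert np.corrcoef(x, ycol)[0, 1] == pytest.approx(0.9, abs=1e-12)
        vifs = compute_vif(design)
        assert vifs["x"] == pytest.approx(1 / (1 - 0.81), abs=1e-3)
        assert vifs["x"] == pytest.approx(5.263, abs=1e-3)

    def test_duplicate_column_infinite(self):
        design = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]})
        vifs = compute_vif(design)
        assert np.isinf(vifs["a"]) and np.isinf(vifs["b"])

    def test_single_column_rejected(self):
        with pytest.raises(DomainError):
            compute_vif(pd.DataFrame({"a": [1.0, 2.0]}))


class TestModelSpec:
    def test_outcome_not_predictor(self):
        with pytest.raises(InvalidConfigError):
            ModelSpec(outcome="y", continuous_terms=("y", "x"))

    def test_formula_contains_forced_year(self):
        spec = ModelSpec(outcome="y", continuous_terms=("x",))
        assert spec.formula().startswith("y ~ C(year)")

    def test_without_removes_term(self):
        spec = ModelSpec(outcome="y", continuous_terms=("x", "z"))
        assert spec.without("z").continuous_terms == ("x",)


class TestFitLmm:
    def test_single_group_rejected(self):
        df = _sim_lmm(np.random.default_rng(0))
        df["herd_id"] = 0
        with pytest.raises(DegenerateDataError):
            fit_lmm(ModelSpec(outcome="y", continuous_terms=("x1",)), df)

    def test_recovers_known_coefficients(self, rng):
        df = _sim_lmm(rng, n_herds=100, per=8, beta=(2.0, -1.0))
        fit = fit_lmm(ModelSpec(outcome="y", continuous_terms=("x1", "x2")), df)
        co = fit.coefficients.set_index("term")
        assert abs(co.loc["x1", "beta"] - 2.0) < 3 * co.loc["x1", "se"]
        assert abs(co.loc["x2", "beta"] + 1.0) < 3 * co.loc["x2", "se"]
        assert fit.herd_variance == pytest.approx(1.0, abs=0.5)
        assert fit.residual_variance == pytest.approx(1.0, abs=0.3)

    def test_type_one_calibration(self):
        # all true betas zero: estimates within 3 SE in >= 99% of replicates
        local = np.random.default_rng(31)
        spec = ModelSpec(outcome="y", continuous_terms=("x1", "x2"))
        good = 0
        reps = 200
        for _ in range(reps):
            df = _sim_lmm(local, n_herds=40, per=5)
            fit = fit_lmm(spec, df, reml=True)
            co = fit.coefficients.set_index("term")
            good += all(
                abs(co.loc[t, "beta"]) < 3 * co.loc[t, "se"] for t in ("x1", "x2")
            )
        assert good / reps >= 0.99

    def test_zero_herd_variance_boundary(self):
        local = np.random.default_rng(11)
        ratios = []
        spec = ModelSpec(outcome="y", continuous_terms=("x1",))
        for _ in range(9):
            df = _sim_lmm(local, n_herds=60, per=6, herd_sd=0.0)
            fit = fit_lmm(spec, df, reml=True)
            ratios.append(fit.herd_variance / fit.residual_variance)
        assert np.median(ratios) <= 0.05


class TestBackwardSelection:
    def test_all_predictive_keeps_full_model(self, rng):
        df = _sim_lmm(rng, n_herds=80, per=6, beta=(2.0, -2.0))
        spec = ModelSpec(outcome="y", continuous_terms=("x1", "x2"))
        fit, trace = backward_select_aic(spec, df)
        assert set(fit.spec.removable_terms) == {"x1", "x2"}
        assert trace[0]["action"] == "full_model"

    def test_forced_year_never_removed(self, rng):
        # year has no simulated effect but stays in the model
        df = _sim_lmm(rng, n_herds=60, per=5, beta=(1.0, 0.0))
        spec = ModelSpec(outcome="y", continuous_terms=("x1", "x2"))
        fit, _ = backward_select_aic(spec, df)
        assert "C(year)" in fit.spec.formula()

    def test_aic_never_worse_than_full(self, rng):
        df = _sim_lmm(rng, n_herds=60, per=5, beta=(1.0, 0.0))
        spec = ModelSpec(outcome="y", continuous_terms=("x1", "x2"))
        full = fit_lmm(spec, df, reml=False)
        fit, _ = backward_select_aic(spec, df)
        refit_ml = fit_lmm(fit.spec, df, reml=False)
        assert refit_ml.aic <= full.aic + 1e-9

    def test_noise_term_removal_rate(self):
        # AIC drops a pure-noise term iff its LR improvement < 2, i.e. with
        # asymptotic probability P(chi2_1 < 2) ~= 0.843
        from scipy.stats import chi2

        expected = chi2.cdf(2.0, df=1)
        local = np.random.default_rng(17)
        spec = ModelSpec(outcome="y", continuous_terms=("x1", "z"))
        removed = 0
        reps = 50
        for _ in range(reps):
            n_h, per = 200, 10
            herd = np.repeat(np.arange(n_h), per)
            year = np.tile(np.arange(2008, 2010), n_h * per // 2)
            x1 = local.normal(size=n_h * per)
            z = local.normal(size=n_h * per)
            y = 1 + 0.3 * x1 + local.normal(0, 1, n_h)[herd] + local.normal(size=n_h * per)
            df = pd.DataFrame(dict(herd_id=herd, year=year, x1=x1, z=z, y=y))
            fit, _ = backward_select_aic(spec, df)
            removed += "z" not in fit.spec.removable_terms
        # within ~3 binomial SDs of the chi-square prediction
        sd = np.sqrt(expected * (1 - expected) / reps)
        assert abs(removed / reps - expected) < 3.5 * sd


class TestR2:
    def test_marginal_le_conditional(self, rng):
        df = _sim_lmm(rng, n_herds=60, per=5, beta=(1.5, 0.0))
        spec = ModelSpec(outcome="y", continuous_terms=("x1", "x2"))
        fit = fit_lmm(spec, df)
        r2 = r2_decomposition(fit, spec, df)
        assert 0.0 <= r2.marginal <= r2.conditional <= 1.0

    def test_intercept_only_zero_marginal(self, rng):
        df = _sim_lmm(rng, n_herds=40, per=4)
        df["year"] = 2008  # degenerate year -> intercept-only fixed part
        spec = ModelSpec(
            outcome="y", continuous_terms=(), forced_terms=(), forced_categorical=()
        )
        fit = fit_lmm(spec, df)
        r2 = r2_decomposition(fit, spec, df)
        assert r2.marginal == pytest.approx(0.0, abs=1e-10)

    def test_scale_invariance(self, rng):
        df = _sim_lmm(rng, n_herds=60, per=5, beta=(1.5, -0.5))
        spec = ModelSpec(outcome="y", continuous_terms=("x1", "x2"))
        fit = fit_lmm(spec, df)
        r2 = r2_decomposition(fit, spec, df)
        std, _ = standardize_continuous(df, ["x1", "x2"])
        fit_std = fit_lmm(spec, std)
        r2_std = r2_decomposition(fit_std, spec, std)
        assert r2.marginal == pytest.approx(r2_std.marginal, abs=1e-4)
        assert r2.conditional == pytest.approx(r2_std.conditional, abs=1e-4)

    def test_null_term_part_r2_small(self, rng):
        df = _sim_lmm(rng, n_herds=500, per=10, beta=(np.sqrt(2.0), 0.0))
        spec = ModelSpec(outcome="y", continuous_terms=("x1", "x2"))
        fit = fit_lmm(spec, df)
        r2 = r2_decomposition(fit, spec, df)
        assert r2.part["x2"] <= 0.01
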