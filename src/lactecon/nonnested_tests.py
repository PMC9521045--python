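"""Cox and J tests for comparing two non-nested regressions.

Direction "A-B" tests the null that model B's regressors cannot improve
model A.  The Cox statistic follows the Pesaran formulation on
least-squares refits of both fixed-effect sets; the J test augments model
A with model B's fitted values, either in plain OLS or inside the mixed
model.  Rejecting both directions means each model adds information over
the other ("no difference"); rejecting only one direction declares the
other model better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DegenerateDataError, DomainError
from .mixed_models import LmmFit, ModelSpec, fit_lmm

__all__ = [
    "NonNestedResult",
    "Verdict",
    "j_test",
    "cox_test",
    "interpret_comparison",
    "compare_models",
]


class Verdict:
    A_BETTER = "A better"
    B_BETTER = "B better"
    NO_DIFFERENCE = "no difference"
    NEITHER = "neither informative"


@dataclass(frozen=True)
class NonNestedResult:
    outcome: str
    direction: str  # "A-B": can B's regressors improve model A?
    test: str  # "cox" | "j"
    estimate: float
    se: float
    statistic: float
    p_value: float


def _ols_design(spec: ModelSpec, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(design matrix with intercept, response) for a fixed-effects refit."""
    import statsmodels.formula.api as smf

    model = smf.ols(spec.formula(), data=table)
    return np.asarray(model.exog), np.asarray(model.endog)


def _check_not_degenerate(X_a: np.ndarray, extra: np.ndarray) -> None:
    """Raise if ``extra`` lies in the column space of ``X_a``."""
    beta, _, _, _ = np.linalg.lstsq(X_a, extra, rcond=None)
    resid = extra - X_a @ beta
    centered = extra - extra.mean()
    scale = float(centered @ centered)
    if scale == 0 or float(resid @ resid) / scale < 1e-12:
        raise DegenerateDataError(
            "augmentation column is collinear with the null model's design"
        )


def j_test(
    spec_a: ModelSpec,
    spec_b: ModelSpec,
    table: pd.DataFrame,
    mode: str = "ols",
) -> NonNestedResult:
    """One J-test direction: does model B's content improve model A?

    ``mode='ols'`` refits both fixed-effect sets by least squares and
    augments A's regression with B's fitted values; ``mode='lmm'`` keeps
    the herd random intercept and augments inside the mixed model.
    """
    if spec_a.outcome != spec_b.outcome:
        raise DomainError("both models must share the outcome")
    if mode == "ols":
        X_a, y = _ols_design(spec_a, table)
        X_b, _ = _ols_design(spec_b, table)
        beta_b, _, _, _ = np.linalg.lstsq(X_b, y, rcond=None)
        fitted_b = X_b @ beta_b
        _check_not_degenerate(X_a, fitted_b)
        X_aug = np.column_stack([X_a, fitted_b])
        beta, _, _, _ = np.linalg.lstsq(X_aug, y, rcond=None)
        resid = y - X_aug @ beta
        n, k = X_aug.shape
        sigma2 = float(resid @ resid) / (n - k)
        cov = sigma2 * np.linalg.inv(X_aug.T @ X_aug)
        est = float(beta[-1])
        se = float(np.sqrt(cov[-1, -1]))
    elif mode == "lmm":
        fit_b = fit_lmm(spec_b, table, reml=False)
        fitted_b = fit_b.fixed_predictions
        X_a, _ = _ols_design(spec_a, table)
        _check_not_degenerate(X_a, fitted_b)
        fit_aug = fit_lmm(
            spec_a, table, reml=False, extra_columns={"_rival_fitted": fitted_b}
        )
        row = fit_aug.coefficients.set_index("term").loc["_rival_fitted"]
        est, se = float(row["beta"]), float(row["se"])
    else:
        raise DomainError(f"unknown J-test mode {mode!r}")

    stat = est / se
    p = 2.0 * norm.sf(abs(stat))
    return NonNestedResult(
        outcome=spec_a.outcome,
        direction="A-B",
        test="j",
        estimate=est,
        se=se,
        statistic=float(stat),
        p_value=float(p),
    )


def cox_test(
    spec_a: ModelSpec, spec_b: ModelSpec, table: pd.DataFrame
) -> NonNestedResult:
    """One Cox-test direction (Pesaran form) on least-squares refits.

    With sigma2_a = RSS_a/n, sigma2_b = RSS_b/n and M_b the residual-maker
    of B's design: sigma2_ba = sigma2_a + ||M_b f_a||²/n where f_a is A's
    fitted vector; the estimate is (n/2)·ln(sigma2_b/sigma2_ba) with
    variance sigma2_a · (f_a' M_b M_a M_b f_a) / sigma2_ba².
    """
    if spec_a.outcome != spec_b.outcome:
        raise DomainError("both models must share the outcome")
    X_a, y = _ols_design(spec_a, table)
    X_b, _ = _ols_design(spec_b, table)
    n = len(y)

    beta_a, _, _, _ = np.linalg.lstsq(X_a, y, rcond=None)
    beta_b, _, _, _ = np.linalg.lstsq(X_b, y, rcond=None)
    f_a = X_a @ beta_a
    f_b = X_b @ beta_b
    _check_not_degenerate(X_b, f_a)
    sigma2_a = float((y - f_a) @ (y - f_a)) / n
    sigma2_b = float((y - f_b) @ (y - f_b)) / n

    # w = M_b f_a ; q = M_a w
    gamma, _, _, _ = np.linalg.lstsq(X_b, f_a, rcond=None)
    w = f_a - X_b @ gamma
    delta, _, _, _ = np.linalg.lstsq(X_a, w, rcond=None)
    q = w - X_a @ delta

    sigma2_ba = sigma2_a + float(w @ w) / n
    estimate = (n / 2.0) * np.log(sigma2_b / sigma2_ba)
    variance = sigma2_a * float(w @ q) / sigma2_ba**2
    se = float(np.sqrt(variance))
    stat = estimate / se
    p = 2.0 * norm.sf(abs(stat))
    return NonNestedResult(
        outcome=spec_a.outcome,
        direction="A-B",
        test="cox",
        estimate=float(estimate),
        se=se,
        statistic=float(stat),
        p_value=float(p),
    )


def interpret_comparison(
    p_ab: float, p_ba: float, alpha: float = 0.05,
    label_a: str = "A", label_b: str = "B",
) -> str:
    """Combine the two directional p-values into a verdict.

    ``p_ab`` tests whether B's regressors improve model A; ``p_ba`` the
    reverse.  Both rejected: each model adds information — no difference.
    Only one rejected: the model whose content improved the other wins.
    Neither rejected: neither test is informative.
    """
    for p in (p_ab, p_ba):
        if not 0.0 <= p <= 1.0:
            raise DomainError("p-values must lie in [0, 1]")
    reject_ab = p_ab < alpha  # B improves A
    reject_ba = p_ba < alpha  # A improves B
    if reject_ab and reject_ba:
        return Verdict.NO_DIFFERENCE
    if reject_ab:
        return f"{label_b} is better than {label_a}" if label_b != "B" else Verdict.B_BETTER
    if reject_ba:
        return f"{label_a} is better than {label_b}" if label_a != "A" else Verdict.A_BETTER
    return Verdict.NEITHER


def compare_models(
    spec_a: ModelSpec,
    spec_b: ModelSpec,
    table: pd.DataFrame,
    alpha: float = 0.05,
    label_a: str = "A",
    label_b: str = "B",
    j_mode: str = "lmm",
) -> pd.DataFrame:
    """Both tests in both directions plus verdicts; one tidy table.

    Output columns: test, outcome, direction, estimate, se, statistic,
    p_value, interpretation.
    """
    rows = []
    for test_name in ("cox", "j"):
        if test_name == "cox":
            res_ab = cox_test(spec_a, spec_b, table)
            res_ba = cox_test(spec_b, spec_a, table)
        else:
            res_ab = j_test(spec_a, spec_b, table, mode=j_mode)
            res_ba = j_test(spec_b, spec_a, table, mode=j_mode)
        verdict = interpret_comparison(
            res_ab.p_value, res_ba.p_value, alpha, label_a=label_a, label_b=label_b
        )
        for res, direction in ((res_ab, f"{label_a}-{label_b}"), (res_ba, f"{label_b}-{label_a}")):
            rows.append(
                {
                    "test": test_name,
                    "outcome": res.outcome,
                    "direction": direction,
                    "estimate": res.estimate,
                    "se": res.se,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "interpretation": verdict,
                }
            )
    return pd.DataFrame(rows)
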