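"""Random-intercept linear mixed models with the study protocol.

Protocol: standardize continuous predictors, screen collinearity with
variance inflation factors, force the calendar-year fixed effect, add a
herd random intercept, select fixed effects backwards on ML AIC, report
the final model under REML, and decompose explained variance into
marginal, conditional and per-term (part) R².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import DegenerateDataError, DomainError, InvalidConfigError

__all__ = [
    "ModelSpec",
    "LmmFit",
    "R2Decomposition",
    "ScalingRecord",
    "standardize_continuous",
    "back_transform",
    "compute_vif",
    "fit_lmm",
    "backward_select_aic",
    "r2_decomposition",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Declares one mixed model: outcome, candidate terms, forced terms.

    ``categorical_terms`` are wrapped in ``C(...)`` when building the
    formula; ``forced_terms`` (the year by default) are never removable by
    selection.  Exactly one random-intercept grouping factor is supported.
    """

    outcome: str
    continuous_terms: tuple[str, ...] = ()
    categorical_terms: tuple[str, ...] = ()
    forced_terms: tuple[str, ...] = ("year",)
    forced_categorical: tuple[str, ...] = ("year",)
    group: str = "herd_id"

    def __post_init__(self) -> None:
        terms = set(self.continuous_terms) | set(self.categorical_terms) | set(
            self.forced_terms
        )
        if self.outcome in terms:
            raise InvalidConfigError("outcome cannot appear among predictors")

    @property
    def removable_terms(self) -> tuple[str, ...]:
        return tuple(
            t
            for t in self.continuous_terms + self.categorical_terms
            if t not in self.forced_terms
        )

    def formula(self, drop: tuple[str, ...] = ()) -> str:
        parts = []
        for t in self.forced_terms:
            parts.append(f"C({t})" if t in self.forced_categorical else t)
        for t in self.continuous_terms:
            if t not in self.forced_terms and t not in drop:
                parts.append(t)
        for t in self.categorical_terms:
            if t not in self.forced_terms and t not in drop:
                parts.append(f"C({t})")
        rhs = " + ".join(parts) if parts else "1"
        return f"{self.outcome} ~ {rhs}"

    def without(self, term: str) -> "ModelSpec":
        return replace(
            self,
            continuous_terms=tuple(t for t in self.continuous_terms if t != term),
            categorical_terms=tuple(t for t in self.categorical_terms if t != term),
        )


@dataclass(frozen=True)
class ScalingRecord:
    means: dict
    sds: dict


@dataclass
class LmmFit:
    """Wrapped MixedLM result with the pieces the pipeline reports."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # term, beta, se, p_value
    herd_variance: float
    residual_variance: float
    llf: float
    aic: float
    fixed_predictions: np.ndarray
    converged: bool
    reml: bool
    n_obs: int
    result: object = field(repr=False, default=None)


@dataclass(frozen=True)
class R2Decomposition:
    marginal: float
    conditional: float
    part: dict


def standardize_continuous(
    table: pd.DataFrame, variables: list[str]
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Replace each listed column with (x - mean)/SD; keep the scaling."""
    out = table.copy()
    means, sds = {}, {}
    for v in variables:
        x = out[v].astype(float)
        sd = float(x.std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateDataError(f"column {v!r} has zero/undefined SD")
        means[v], sds[v] = float(x.mean()), sd
        out[v] = (x - means[v]) / sd
    return out, ScalingRecord(means=means, sds=sds)


def back_transform(table: pd.DataFrame, scaling: ScalingRecord) -> pd.DataFrame:
    out = table.copy()
    for v, mu in scaling.means.items():
        out[v] = out[v] * scaling.sds[v] + mu
    return out


def compute_vif(design: pd.DataFrame) -> dict[str, float]:
    """VIF_j = 1/(1 - R²_j) from regressing column j on the others.

    Exact collinearity is reported as ``inf`` rather than raised.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise DomainError("need at least two columns for VIF")
    X = design.to_numpy(dtype=float)
    vifs = {}
    for j, name in enumerate(cols):
        y = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = np.sum((y - y.mean()) ** 2)
        if tss == 0:
            vifs[name] = float("inf")
            continue
        r2 = 1.0 - resid @ resid / tss
        vifs[name] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return vifs


def _extract_fit(spec: ModelSpec, result, reml: bool, n_obs: int) -> LmmFit:
    fe = result.fe_params
    se = result.bse_fe
    # Wald z p-values on fixed effects
    pvals = 2.0 * norm.sf(np.abs(fe.values / se.values))
    coef = pd.DataFrame(
        {"term": fe.index, "beta": fe.values, "se": se.values, "p_value": pvals}
    )
    herd_var = float(result.cov_re.iloc[0, 0])
    resid_var = float(result.scale)
    k = len(fe) + 2  # fixed effects + herd variance + residual variance
    aic = 2.0 * k - 2.0 * float(result.llf)
    fixed_pred = np.asarray(result.model.exog @ fe.values)
    return LmmFit(
        spec=spec,
        coefficients=coef,
        herd_variance=herd_var,
        residual_variance=resid_var,
        llf=float(result.llf),
        aic=aic,
        fixed_predictions=fixed_pred,
        converged=bool(getattr(result, "converged", True)),
        reml=reml,
        n_obs=n_obs,
    )


def fit_lmm(
    spec: ModelSpec,
    table: pd.DataFrame,
    reml: bool = True,
    extra_columns: dict[str, np.ndarray] | None = None,
) -> LmmFit:
    """Fit the random-intercept model declared by ``spec``.

    ML (``reml=False``) is used inside AIC selection; REML for the final
    reported fit.  ``extra_columns`` lets callers augment the fixed part
    (used by the non-nested J test in mixed-model mode).
    """
    data = table
    formula = spec.formula()
    if extra_columns:
        data = table.copy()
        for name, values in extra_columns.items():
            data[name] = values
        formula = formula + " + " + " + ".join(extra_columns)
    if data[spec.group].nunique() < 2:
        raise DegenerateDataError("random intercept needs >= 2 groups")

    model = smf.mixedlm(formula, data, groups=data[spec.group])
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            result = model.fit(reml=reml)
        except (ConvergenceWarning, np.linalg.LinAlgError):
            warnings.simplefilter("ignore", ConvergenceWarning)
            try:
                result = model.fit(reml=reml, method="powell")
            except np.linalg.LinAlgError:
                result = model.fit(reml=reml, method="nm", maxiter=2000)
            converged = False
    fit = _extract_fit(spec, result, reml=reml, n_obs=len(data))
    fit.converged = fit.converged and converged
    if not fit.converged:
        logger.warning("mixed model did not fully converge: %s", formula)
    return fit


def backward_select_aic(
    spec: ModelSpec, table: pd.DataFrame
) -> tuple[LmmFit, list[dict]]:
    """Backward elimination on ML AIC; forced terms are never dropped.

    At each step the removable term whose removal lowers AIC the most is
    dropped (ties broken by the larger Wald p-value); stops when no
    removal lowers AIC.  Returns the final model refit under REML and the
    selection trace.
    """
    current = spec
    current_fit = fit_lmm(current, table, reml=False)
    trace = [{"action": "full_model", "term": None, "aic": current_fit.aic}]
    while current.removable_terms:
        candidates = []
        for term in current.removable_terms:
            cand_spec = current.without(term)
            cand_fit = fit_lmm(cand_spec, table, reml=False)
            candidates.append((term, cand_spec, cand_fit))
        best_aic = min(f.aic for _, _, f in candidates)
        if best_aic >= current_fit.aic:
            break
        tied = [c for c in candidates if c[2].aic <= best_aic + 1e-9]
        if len(tied) > 1:
            # remove the least significant of the tied terms
            def term_p(item):
                term = item[0]
                rows = current_fit.coefficients["term"].str.contains(
                    term, regex=False
                )
                p = current_fit.coefficients.loc[rows, "p_value"]
                return p.max() if len(p) else 0.0

            tied.sort(key=term_p, reverse=True)
        term, current, current_fit = tied[0]
        trace.append({"action": "removed", "term": term, "aic": current_fit.aic})
    final = fit_lmm(current, table, reml=True)
    trace.append({"action": "final_reml", "term": None, "aic": final.aic})
    return final, trace


def _marginal_r2(fit: LmmFit) -> float:
    var_fixed = float(np.var(fit.fixed_predictions))
    denom = var_fixed + fit.herd_variance + fit.residual_variance
    if denom <= 0:
        raise DomainError("zero total variance")
    return var_fixed / denom


def r2_decomposition(
    fit: LmmFit, spec: ModelSpec, table: pd.DataFrame
) -> R2Decomposition:
    """Marginal, conditional and part R² of a fitted model.

    Part R² of a term group is the drop in marginal R² when the group is
    removed and the model refit (floored at zero); the forced year factor
    is treated as a single group.
    """
    var_fixed = float(np.var(fit.fixed_predictions))
    denom = var_fixed + fit.herd_variance + fit.residual_variance
    if denom <= 0:
        raise DomainError("zero total variance")
    marginal = var_fixed / denom
    conditional = (var_fixed + fit.herd_variance) / denom

    part: dict[str, float] = {}
    groups = list(spec.removable_terms) + list(spec.forced_terms)
    for term in dict.fromkeys(groups):
        if term in spec.forced_terms:
            reduced = replace(
                spec,
                forced_terms=tuple(t for t in spec.forced_terms if t != term),
            )
        else:
            reduced = spec.without(term)
        red_fit = fit_lmm(reduced, table, reml=fit.reml)
        part[term] = max(0.0, marginal - _marginal_r2(red_fit))
    return R2Decomposition(marginal=marginal, conditional=conditional, part=part)
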