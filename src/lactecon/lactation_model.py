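"""Simplified three-parameter lactation curve: evaluation, fitting, persistency.

The curve is ``Y(t) = a * (1 - exp(-t/b)/2) * exp(-d*t)`` with the offset of
the four-parameter form fixed at zero.  ``a`` is the magnitude (kg/day),
``b`` the ramp reported as time to peak yield (days), and ``d`` the late
lactation decay rate (1/day).  Persistency is the post-peak half-life
``ln 2 / d`` in days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DegenerateDataError, DomainError, InsufficientDataError

__all__ = [
    "LN2",
    "LactationFit",
    "milkbot_yield",
    "milkbot_m305",
    "persistency_from_decay",
    "fit_lactation",
    "fit_lactation_table",
    "MIN_WEIGHINGS",
    "PARAM_BOUNDS",
]

LN2 = math.log(2.0)

#: minimum weighings to fit three parameters with one residual df
MIN_WEIGHINGS = 4

#: (lower, upper) box for (a, b, d); brackets the biological range
PARAM_BOUNDS = ((1e-6, 1e-6, 0.0), (150.0, 100.0, 0.05))


@dataclass(frozen=True)
class LactationFit:
    """Fitted curve parameters and diagnostics for one lactation.

    ``persistency`` is ``inf`` when the decay estimate hits the zero bound.
    """

    magnitude: float
    ramp: float
    decay: float
    persistency: float
    n_points: int
    rss: float
    converged: bool
    parity_group: str = "multiparous"

    def predict(self, t):
        return milkbot_yield(t, self.magnitude, self.ramp, self.decay)

    def to_dict(self) -> dict:
        return asdict(self)


def milkbot_yield(t, a: float, b: float, d: float):
    """Evaluate the curve at days-in-milk ``t`` (scalar or array).

    ``Y(0) = a/2`` by construction and ``Y(t) -> a*exp(-d*t)`` once the
    ramp term has saturated.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if np.any(a_arr <= 0) or np.any(b_arr <= 0):
        raise DomainError("magnitude a and ramp b must be positive")
    if np.any(np.asarray(d, dtype=float) < 0):
        raise DomainError("decay d must be nonnegative")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("days in milk t must be nonnegative")
    out = a_arr * (1.0 - 0.5 * np.exp(-t_arr / b_arr)) * np.exp(-np.asarray(d, float) * t_arr)
    if np.isscalar(t) and np.isscalar(a):
        return float(out)
    return out


def milkbot_m305(a, b, d, horizon: float = 305.0):
    """Cumulative yield over ``[0, horizon]`` days, in kg (closed form).

    Integrates ``a(1 - e^{-t/b}/2)e^{-dt}``; used to derive a 305-d milk
    production from curve parameters.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    T = horizon
    with np.errstate(divide="ignore", invalid="ignore"):
        first = np.where(d > 0, -np.expm1(-d * T) / np.where(d > 0, d, 1.0), T)
    k = d + 1.0 / b
    second = 0.5 * (-np.expm1(-k * T)) / k
    out = a * (first - second)
    return float(out) if out.ndim == 0 else out


def persistency_from_decay(d: float) -> float:
    """Half-life of the post-peak decline: ``ln 2 / d`` days."""
    if d <= 0:
        raise DomainError("persistency is undefined for decay d <= 0")
    return LN2 / d


def _residuals(params, t, y):
    a, b, d = params
    return a * (1.0 - 0.5 * np.exp(-t / b)) * np.exp(-d * t) - y


def _jacobian(params, t, y):
    a, b, d = params
    ramp = 1.0 - 0.5 * np.exp(-t / b)
    decay = np.exp(-d * t)
    da = ramp * decay
    db = a * decay * (-0.5 * np.exp(-t / b) * t / b**2)
    dd = -t * a * ramp * decay
    return np.column_stack([da, db, dd])


def fit_lactation(
    weighings: Sequence[tuple[float, float]],
    parity_group: str = "multiparous",
) -> LactationFit:
    """Least-squares fit of (a, b, d) to ``(DIM, milk kg)`` pairs.

    Parameters are bounded to ``PARAM_BOUNDS``; the starting point uses
    ``Y(0) = a/2`` for the magnitude.  Raises
    :class:`~lactecon.errors.InsufficientDataError` below
    :data:`MIN_WEIGHINGS` points and
    :class:`~lactecon.errors.DegenerateDataError` for all-zero milk.
    """
    arr = np.asarray(weighings, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("weighings must be a sequence of (DIM, milk) pairs")
    if arr.shape[0] < MIN_WEIGHINGS:
        raise InsufficientDataError(
            f"need >= {MIN_WEIGHINGS} weighings, got {arr.shape[0]}"
        )
    t, y = arr[:, 0], arr[:, 1]
    if np.any(t <= 0):
        raise DomainError("DIM must be strictly positive")
    if np.any(np.diff(t) <= 0):
        raise DomainError("DIM must be strictly increasing")
    if np.all(y == 0):
        raise DegenerateDataError("all milk weights are zero")

    lo, hi = PARAM_BOUNDS
    x0 = np.array([min(2.0 * y.max(), hi[0] * 0.99), 21.0, 0.003])
    res = least_squares(
        _residuals,
        x0,
        jac=_jacobian,
        bounds=(lo, hi),
        args=(t, y),
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
    )
    a, b, d = res.x
    persistency = LN2 / d if d > 0 else math.inf
    return LactationFit(
        magnitude=float(a),
        ramp=float(b),
        decay=float(d),
        persistency=float(persistency),
        n_points=int(arr.shape[0]),
        rss=float(2.0 * res.cost),
        converged=bool(res.status > 0),
        parity_group=parity_group,
    )


def fit_lactation_table(
    test_days: pd.DataFrame,
    complete_min_dim: float = 240.0,
    dim_col: str = "dim",
    milk_col: str = "milk_kg",
) -> pd.DataFrame:
    """Fit every lactation of a test-day table; one row per lactation.

    The table must carry ``herd_id``, ``cow_id``, ``lactation_id``,
    ``parity`` (1 = primiparous), ``dim`` and ``milk_kg``.  A lactation is
    flagged complete when its last weighing is at or past
    ``complete_min_dim`` DIM.  Lactations with too few points or failed
    fits are emitted with ``converged=False`` and NaN parameters.
    """
    rows = []
    keys = ["herd_id", "cow_id", "lactation_id"]
    for (herd, cow, lact), grp in test_days.groupby(keys, sort=True):
        grp = grp.sort_values(dim_col)
        parity = int(grp["parity"].iloc[0])
        group = "primiparous" if parity == 1 else "multiparous"
        complete = bool(grp[dim_col].iloc[-1] >= complete_min_dim)
        base = {
            "herd_id": herd,
            "cow_id": cow,
            "lactation_id": lact,
            "parity_group": group,
            "complete": complete,
        }
        try:
            fit = fit_lactation(
                np.column_stack([grp[dim_col], grp[milk_col]]), parity_group=group
            )
        except (InsufficientDataError, DegenerateDataError):
            base.update(
                magnitude=np.nan, ramp=np.nan, decay=np.nan, persistency=np.nan,
                n_points=len(grp), rss=np.nan, converged=False,
            )
            rows.append(base)
            continue
        base.update(
            magnitude=fit.magnitude, ramp=fit.ramp, decay=fit.decay,
            persistency=fit.persistency, n_points=fit.n_points, rss=fit.rss,
            converged=fit.converged,
        )
        rows.append(base)
    return pd.DataFrame(rows)
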