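"""BrdU incorporation fits and subtype doubling-time comparison.

In a continuous-labelling experiment, the fraction of label-positive cells
saturates as the population turns over.  We fit

    F(t) = plateau * (1 - 2**(-t / Td))

so that the half-time of the fitted curve equals the population doubling
time Td literally.  The LT/ST doubling-time ratio quantifies how much less
frequently LT-HSCs divide; its significance comes from an
extra-sum-of-squares F test against a shared-Td null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinetics import FitError, InsufficientDataError

__all__ = ["BrdUFit", "fit_brdu", "doubling_time_ratio"]


@dataclass(frozen=True)
class BrdUFit:
    doubling_time: float  # hours (half-time of fit)
    plateau: float
    r_squared: float
    residual_ss: float
    n_points: int
    subtype: str = ""


def _saturation(t_hours, doubling_time, plateau):
    return plateau * (1.0 - np.power(2.0, -np.asarray(t_hours, float) / doubling_time))


def fit_brdu(series: pd.DataFrame, subtype: str = "") -> BrdUFit:
    """Least-squares saturating fit of a (day, fraction_labelled) table.

    Days are converted to hours internally; the reported doubling time is in
    hours.  Requires >= 4 time points spanning at least one half-time (a
    point above half the maximum fraction).
    """
    day = series["day"].to_numpy(dtype=float)
    frac = series["fraction_labelled"].to_numpy(dtype=float)
    if len(np.unique(day)) < 4:
        raise InsufficientDataError("need at least 4 distinct time points")
    if np.all(frac <= 0.0):
        raise InsufficientDataError("all labelled fractions are zero")
    t = day * 24.0
    fmax = float(frac.max())
    # crude half-time initialisation: first time the mean fraction crosses fmax/2
    means = pd.DataFrame({"t": t, "f": frac}).groupby("t")["f"].mean()
    above = means[means >= fmax / 2.0]
    if above.empty:
        raise InsufficientDataError("series does not span one half-time")
    t_half0 = max(float(above.index[0]), 1.0)
    p0 = (t_half0, min(fmax, 1.0))
    try:
        popt, _ = optimize.curve_fit(
            _saturation,
            t,
            frac,
            p0=p0,
            bounds=([1e-3, 1e-6], [1e6, 1.0]),
            maxfev=10000,
            xtol=1e-13,
            ftol=1e-13,
            gtol=1e-13,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"BrdU fit did not converge: {exc}", best=p0) from exc
    td, plateau = (float(v) for v in popt)
    resid = _saturation(t, td, plateau) - frac
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((frac - frac.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return BrdUFit(
        doubling_time=td,
        plateau=plateau,
        r_squared=max(0.0, min(1.0, r2)),
        residual_ss=ss_res,
        n_points=len(t),
        subtype=subtype,
    )


def _shared_td_ss(series_lt: pd.DataFrame, series_st: pd.DataFrame) -> tuple[float, int]:
    """Residual SS of the null model: one shared Td, per-group plateaus."""
    t_lt = series_lt["day"].to_numpy(float) * 24.0
    y_lt = series_lt["fraction_labelled"].to_numpy(float)
    t_st = series_st["day"].to_numpy(float) * 24.0
    y_st = series_st["fraction_labelled"].to_numpy(float)

    def resid(params):
        td, p_lt, p_st = params
        return np.concatenate(
            [_saturation(t_lt, td, p_lt) - y_lt, _saturation(t_st, td, p_st) - y_st]
        )

    fit0 = fit_brdu(pd.concat([series_lt, series_st], ignore_index=True))
    res = optimize.least_squares(
        resid,
        x0=[fit0.doubling_time, fit0.plateau, fit0.plateau],
        bounds=([1e-3, 1e-6, 1e-6], [1e6, 1.0, 1.0]),
    )
    return float(np.sum(res.fun**2)), len(t_lt) + len(t_st)


def doubling_time_ratio(
    fit_lt: BrdUFit,
    fit_st: BrdUFit,
    series_lt: pd.DataFrame | None = None,
    series_st: pd.DataFrame | None = None,
) -> dict:
    """LT/ST doubling-time ratio, optionally with an extra-SS p value.

    When the underlying series are supplied, the full model (separate Td and
    plateau per group, 4 parameters) is compared against a shared-Td null
    (3 parameters) with an F test.
    """
    ratio = fit_lt.doubling_time / fit_st.doubling_time
    out = {"ratio": float(ratio)}
    if series_lt is not None and series_st is not None:
        ss_null, n_total = _shared_td_ss(series_lt, series_st)
        ss_full = fit_lt.residual_ss + fit_st.residual_ss
        df_full = n_total - 4
        df_null = n_total - 3
        if df_full <= 0:
            raise ValueError("not enough points for the per-group model")
        f_stat = (max(ss_null - ss_full, 0.0) / (df_null - df_full)) / (ss_full / df_full)
        out["f_statistic"] = float(f_stat)
        out["p_value"] = float(stats.f.sf(f_stat, df_null - df_full, df_full))
    return out
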