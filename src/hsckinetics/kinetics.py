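"""Cumulative division curves, sigmoid fits and the kinetic triplet.

The characteristic time of a division wave is read off a least-squares
log-logistic (sigmoid) fit to the cumulative fraction of divided wells:

    F(t) = plateau / (1 + 10**(slope * (log_ec50 - log10(t))))

The EC50 (time at half-plateau) of the first-division curve is t_FirstDiv.
The second-division curve is built on the interval between first and second
division of each well, so its EC50 estimates the cell-cycle transit time
t_SecondDiv (= t_G1-S-G2-M).  The quiescence-exit duration is then

    t_G0exit = t_FirstDiv - t_SecondDiv,

the latency specific to cells that must leave G0 before cycling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .synthetic import SingleCellTrack

__all__ = [
    "InsufficientDataError",
    "FitError",
    "CumulativeCurve",
    "SigmoidFitResult",
    "SubsetKinetics",
    "cumulative_division_curve",
    "sigmoid",
    "fit_sigmoid",
    "derive_kinetics",
    "paired_compare",
    "compare_fits_extra_ss",
    "fit_pooled_sigmoid",
]


class InsufficientDataError(ValueError):
    """Too few usable wells / time points to proceed."""


class FitError(RuntimeError):
    """The least-squares fit did not converge; carries the best iterate."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


MIN_WELLS = 5


@dataclass(frozen=True)
class CumulativeCurve:
    """Cumulative fraction of divided wells over time (dead wells excluded)."""

    times: np.ndarray
    fraction_divided: np.ndarray
    n_alive: int

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self, "fraction_divided", np.asarray(self.fraction_divided, dtype=float)
        )


@dataclass(frozen=True)
class SigmoidFitResult:
    log_ec50: float
    ec50_hours: float
    slope: float
    plateau: float
    r_squared: float
    residual_ss: float
    n_points: int


@dataclass(frozen=True)
class SubsetKinetics:
    """Fitted kinetic triplet for one subtype in one sample.

    ``t_g0_exit`` is exactly ``t_first_div - t_second_div``; a negative
    value is kept (the estimator is unbiased) but flagged.
    """

    subtype: str
    sample_id: str
    t_first_div: float
    t_second_div: float
    t_g0_exit: float
    negative_g0_flag: bool


def _event_times(track: SingleCellTrack, division_index: int) -> float | None:
    if division_index == 1:
        return track.first_division_time
    if division_index == 2:
        # time since first division: the cell-cycle transit interval
        if track.first_division_time is None or track.second_division_time is None:
            return None
        return track.second_division_time - track.first_division_time
    raise ValueError("division_index must be 1 or 2")


def cumulative_division_curve(
    tracks: list[SingleCellTrack], division_index: int = 1
) -> CumulativeCurve:
    """Fraction of (non-dead) wells divided by each observation time.

    ``division_index=1`` uses the time of the first division;
    ``division_index=2`` uses the interval between first and second division,
    so that the curve's half-time estimates the cell-cycle transit time.
    Wells with the first division observed but the second censored count in
    the denominator of both curves.
    """
    alive = [t for t in tracks if not t.died]
    if len(alive) < MIN_WELLS:
        raise InsufficientDataError(
            f"need at least {MIN_WELLS} non-dead wells, got {len(alive)}"
        )
    interval = alive[0].observation_interval
    horizon = alive[0].horizon
    grid = interval * np.arange(0, int(np.floor(horizon / interval)) + 1)
    events = np.array(
        [e for t in alive if (e := _event_times(t, division_index)) is not None]
    )
    frac = np.array([(events <= g + 1e-9).sum() / len(alive) for g in grid])
    return CumulativeCurve(times=grid, fraction_divided=frac, n_alive=len(alive))


def sigmoid(t, plateau, log_ec50, slope):
    """Log-logistic curve; 0 at t=0 by construction."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = plateau / (1.0 + 10.0 ** (slope * (log_ec50 - np.log10(t[pos]))))
    return out


def _sigmoid_ss(params, t, y) -> float:
    return float(np.sum((sigmoid(t, *params) - y) ** 2))


def fit_sigmoid(curve: CumulativeCurve) -> SigmoidFitResult:
    """Least-squares log-logistic fit of a cumulative division curve.

    Initialisation: plateau = max observed fraction, log_ec50 = log10 of the
    first time at half-max, slope = 2.  Fails explicitly on flat/all-zero
    curves or non-convergence.
    """
    t = curve.times
    y = curve.fraction_divided
    mask = t > 0
    t, y = t[mask], y[mask]
    ymax = float(y.max(initial=0.0))
    if ymax <= 0.0:
        raise InsufficientDataError("all-zero curve: no divisions observed")
    if len(t) < 4:
        raise InsufficientDataError("need at least 4 positive-time points")
    if not ((y < 0.4 * ymax).any() and (y > 0.6 * ymax).any()):
        raise InsufficientDataError(
            "curve must bracket its half-maximum (one point below 0.4*max "
            "and one above 0.6*max)"
        )
    half_idx = int(np.argmax(y >= ymax / 2.0))
    p0 = (min(ymax, 1.0), float(np.log10(t[half_idx])), 2.0)
    bounds = ([1e-6, np.log10(t[0]) - 2.0, 0.05], [1.0, np.log10(t[-1]) + 2.0, 50.0])
    try:
        popt, _ = optimize.curve_fit(
            sigmoid, t, y, p0=p0, bounds=bounds, maxfev=10000, xtol=1e-12, ftol=1e-12
        )
    except RuntimeError as exc:  # pragma: no cover - curve_fit rarely fails here
        raise FitError(f"sigmoid fit did not converge: {exc}", best=p0) from exc
    plateau, log_ec50, slope = (float(v) for v in popt)
    ss_res = _sigmoid_ss(popt, t, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return SigmoidFitResult(
        log_ec50=log_ec50,
        ec50_hours=10.0 ** log_ec50,
        slope=slope,
        plateau=plateau,
        r_squared=max(0.0, min(1.0, r2)),
        residual_ss=ss_res,
        n_points=len(t),
    )


def derive_kinetics(
    first_fit: SigmoidFitResult,
    second_fit: SigmoidFitResult,
    subtype: str,
    sample_id: str = "",
) -> SubsetKinetics:
    """Combine first- and second-division fits into the kinetic triplet."""
    t_first = first_fit.ec50_hours
    t_second = second_fit.ec50_hours
    g0 = t_first - t_second
    return SubsetKinetics(
        subtype=subtype,
        sample_id=sample_id,
        t_first_div=t_first,
        t_second_div=t_second,
        t_g0_exit=g0,
        negative_g0_flag=g0 < 0,
    )


def paired_compare(values_a, values_b) -> dict:
    """Two-sided paired t test; also reports the mean difference."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if np.allclose(diff, 0.0):
        return {"statistic": 0.0, "p_value": 1.0, "mean_difference": 0.0, "n": len(a)}
    res = stats.ttest_rel(a, b)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_difference": float(diff.mean()),
        "n": len(a),
    }


def compare_fits_extra_ss(
    fit_joint: SigmoidFitResult,
    fit_a: SigmoidFitResult,
    fit_b: SigmoidFitResult,
    n_params: int = 3,
) -> dict:
    """Extra-sum-of-squares F test of one shared curve vs per-group curves.

    The joint fit pools both groups with shared parameters; the separate
    fits spend ``n_params`` each.  F = ((SS_j - SS_s)/(df_j - df_s)) /
    (SS_s/df_s), with p from the F distribution.
    """
    ss_sep = fit_a.residual_ss + fit_b.residual_ss
    ss_joint = fit_joint.residual_ss
    n_total = fit_a.n_points + fit_b.n_points
    df_joint = n_total - n_params
    df_sep = n_total - 2 * n_params
    if df_sep <= 0:
        raise ValueError("not enough points for the separate-fits model")
    num = max(ss_joint - ss_sep, 0.0) / (df_joint - df_sep)
    den = ss_sep / df_sep
    if ss_joint <= 1e-12 and ss_sep <= 1e-12:
        f_stat = 0.0  # both models fit essentially perfectly: no evidence
    elif den == 0.0:
        f_stat = 0.0 if num == 0.0 else np.inf
    else:
        f_stat = num / den
    p = float(stats.f.sf(f_stat, df_joint - df_sep, df_sep))
    return {"f_statistic": float(f_stat), "p_value": p, "df_num": df_joint - df_sep, "df_den": df_sep}


def fit_pooled_sigmoid(curves: list[CumulativeCurve]) -> SigmoidFitResult:
    """One shared-parameter sigmoid over the pooled points of several curves.

    This is the null model of :func:`compare_fits_extra_ss`.
    """
    t = np.concatenate([c.times for c in curves])
    y = np.concatenate([c.fraction_divided for c in curves])
    order = np.argsort(t)
    pooled = CumulativeCurve(times=t[order], fraction_divided=y[order], n_alive=sum(c.n_alive for c in curves))
    return fit_sigmoid(pooled)
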