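"""Weibull survival models fitted to digitized Kaplan-Meier curves.

The parametrisation used throughout is

    S(t) = exp(-lambda * t**gamma)

with a rate-like scale ``lambda`` (units: time**-gamma) and a dimensionless
shape ``gamma``.  ``gamma > 1`` means an increasing hazard (wear-out),
``gamma = 1`` reduces to the exponential distribution and ``gamma < 1`` to a
decreasing hazard.

Fitting follows the pseudo-individual-patient-data recipe used for published
Kaplan-Meier figures: read (time, survival) points off the curve, reconstruct
per-interval event and censoring counts with the help of the numbers-at-risk
table, and regress the complementary log-log transform

    ln(-ln S(t)) = ln(lambda) + gamma * ln(t)

by (weighted) least squares.  The transform is linear in ``ln t``, so in the
noiseless case the generating parameters are recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import isotonic_regression

from .errors import InsufficientDataError, InvalidParameterError, MalformedCurveError

__all__ = [
    "WeibullParams",
    "WeibullFit",
    "survival_at",
    "median_survival",
    "calibrate_scale_to_median",
    "rescale_time",
    "cycle_transition_probability",
    "clean_curve",
    "reconstruct_interval_counts",
    "fit_weibull",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class WeibullParams:
    """Scale/shape pair of a Weibull survival function S(t) = exp(-λ t^γ)."""

    scale_lambda: float
    shape_gamma: float

    def __post_init__(self) -> None:
        if not (self.scale_lambda > 0.0 and np.isfinite(self.scale_lambda)):
            raise InvalidParameterError(
                f"scale_lambda must be positive and finite, got {self.scale_lambda}"
            )
        if not (self.shape_gamma > 0.0 and np.isfinite(self.shape_gamma)):
            raise InvalidParameterError(
                f"shape_gamma must be positive and finite, got {self.shape_gamma}"
            )


@dataclass(frozen=True)
class WeibullFit:
    """Result of a least-squares Weibull fit to a digitized curve.

    Standard errors are reported on the log scale (ln λ, ln γ) because both
    parameters are positive and the regression estimates ln λ directly.
    """

    params: WeibullParams
    se_log_lambda: float
    se_log_gamma: float
    rss: float
    n_points: int


def survival_at(params: WeibullParams, t):
    """Survivor function S(t) = exp(-λ t^γ); accepts scalars or arrays, t >= 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidParameterError("survival_at requires t >= 0")
    out = np.exp(-params.scale_lambda * t_arr**params.shape_gamma)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def median_survival(params: WeibullParams) -> float:
    """Median of the Weibull law: (ln 2 / λ)^(1/γ)."""
    return float((LN2 / params.scale_lambda) ** (1.0 / params.shape_gamma))


def calibrate_scale_to_median(median: float, shape_gamma: float) -> WeibullParams:
    """Solve λ from a target median for a fixed shape: λ = ln 2 / median^γ.

    This is how fixture scenarios pin the survival inputs to published median
    PFS/OS values when the fitted parameters themselves were never reported.
    """
    if not median > 0:
        raise InvalidParameterError(f"median must be positive, got {median}")
    lam = LN2 / median**shape_gamma
    return WeibullParams(scale_lambda=lam, shape_gamma=shape_gamma)


def rescale_time(params: WeibullParams, unit_factor: float) -> WeibullParams:
    """Re-express the scale on a new time unit.

    If ``params`` is per-month and one new unit equals ``unit_factor`` months
    (e.g. 21/30.4375 for a 3-week cycle), the returned parameters satisfy
    S_new(k) = S_old(k * unit_factor): λ' = λ * unit_factor^γ, γ unchanged.
    """
    if not unit_factor > 0:
        raise InvalidParameterError(f"unit_factor must be positive, got {unit_factor}")
    return WeibullParams(
        scale_lambda=params.scale_lambda * unit_factor**params.shape_gamma,
        shape_gamma=params.shape_gamma,
    )


def cycle_transition_probability(
    params: WeibullParams, cycle_index, cycle_length: float = 1.0
):
    """Per-cycle transition probability 1 - exp(λ t^γ - λ (t+1)^γ).

    ``t`` is the cycle index (time measured in cycles).  ``cycle_length``
    converts parameters expressed on another time unit: it is the length of
    one cycle in the unit of ``params`` (leave at 1.0 when the parameters are
    already on the cycle timescale).  The value equals the conditional exit
    probability 1 - S(t+1)/S(t) and always lies in [0, 1].
    """
    k = np.asarray(cycle_index, dtype=float)
    if np.any(k < 0):
        raise InvalidParameterError("cycle_index must be >= 0")
    if not cycle_length > 0:
        raise InvalidParameterError("cycle_length must be positive")
    p = rescale_time(params, cycle_length) if cycle_length != 1.0 else params
    lam, g = p.scale_lambda, p.shape_gamma
    out = 1.0 - np.exp(lam * k**g - lam * (k + 1.0) ** g)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(cycle_index) or k.ndim == 0 else out


def clean_curve(
    times, survival, *, max_adjust: float = 0.10, tol: float = 1e-9
) -> np.ndarray:
    """Repair a digitized curve into a valid (non-increasing) survival function.

    Pool-adjacent-violators isotonic regression enforces monotonicity; values
    are clipped to [0, 1].  If any point has to move by more than
    ``max_adjust`` the curve is considered malformed rather than merely noisy.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(survival, dtype=float)
    if t.shape != s.shape or t.ndim != 1:
        raise MalformedCurveError("times and survival must be 1-D and equally long")
    if np.any(np.diff(t) <= 0):
        raise MalformedCurveError("times must be strictly increasing")
    s_clipped = np.clip(s, 0.0, 1.0)
    res = isotonic_regression(s_clipped, increasing=False)
    fixed = np.asarray(res.x, dtype=float)
    if np.max(np.abs(fixed - s_clipped)) > max_adjust + tol:
        raise MalformedCurveError(
            "survival increases beyond repairable tolerance "
            f"(max adjustment {np.max(np.abs(fixed - s_clipped)):.4f} > {max_adjust})"
        )
    return np.clip(fixed, 0.0, 1.0)


def reconstruct_interval_counts(curve, risk) -> pd.DataFrame:
    """Reconstruct per-interval event and censoring counts from a digitized
    curve plus a numbers-at-risk table.

    For each interval between consecutive digitized points the expected number
    of events is ``n_at_risk * (S_start - S_end) / S_start`` (the conditional
    probability of an event times the current risk set), rounded to a
    non-negative integer.  Whenever an anchor time from the risk table is
    passed, censorings are allocated so the running risk-set size matches the
    published number at risk.

    Parameters
    ----------
    curve : object with ``times`` and ``survival`` arrays (a DigitizedCurve).
    risk : object with ``times`` and ``n_at_risk`` arrays (a RiskTable).

    Returns
    -------
    DataFrame with columns ``t_start, t_end, n_at_risk, events, censored``.
    """
    t = np.asarray(curve.times, dtype=float)
    s = clean_curve(curve.times, curve.survival)
    rt = np.asarray(risk.times, dtype=float)
    rn = np.asarray(risk.n_at_risk, dtype=float)
    if len(rt) == 0:
        raise InvalidParameterError("risk table is empty")

    n_cur = float(rn[0])
    rows = []
    anchor = 1  # index of next risk-table anchor to reconcile
    for i in range(len(t) - 1):
        t0, t1 = t[i], t[i + 1]
        s0, s1 = s[i], s[i + 1]
        # reconcile any anchors falling inside (t0, t1]
        while anchor < len(rt) and rt[anchor] <= t0:
            censored_here = max(n_cur - rn[anchor], 0.0)
            if rows:
                rows[-1]["censored"] += round(censored_here)
            n_cur = min(n_cur, float(rn[anchor]))
            anchor += 1
        if s0 <= 0:
            events = 0.0
        else:
            events = n_cur * (s0 - s1) / s0
        events = max(round(events), 0)
        events = min(events, int(n_cur))
        rows.append(
            dict(t_start=t0, t_end=t1, n_at_risk=int(round(n_cur)), events=int(events), censored=0)
        )
        n_cur -= events
    return pd.DataFrame(rows, columns=["t_start", "t_end", "n_at_risk", "events", "censored"])


def fit_weibull(curve, weights=None) -> WeibullFit:
    """Fit S(t) = exp(-λ t^γ) to digitized points by cloglog regression.

    Points with S in {0, 1} or t = 0 are excluded (the transform is undefined
    there).  ``weights`` are optional per-point least-squares weights, e.g.
    reconstructed event counts per interval; they must align with the curve's
    points before exclusion.
    """
    t = np.asarray(curve.times, dtype=float)
    s = clean_curve(curve.times, curve.survival)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != t.shape:
        raise InvalidParameterError("weights must align with curve points")
    usable = (t > 0) & (s > 0.0) & (s < 1.0) & (w > 0)
    if int(usable.sum()) < 4:
        raise InsufficientDataError(
            f"need >= 4 usable points with 0 < S < 1 and t > 0, got {int(usable.sum())}"
        )
    x = np.log(t[usable])
    y = np.log(-np.log(s[usable]))
    if np.ptp(x) < 1e-12 or np.ptp(y) < 1e-15:
        raise InsufficientDataError("degenerate design: no variation in usable points")
    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=w[usable]).fit()
    intercept, slope = res.params
    if slope <= 0:
        raise InsufficientDataError(
            f"fitted shape is non-positive ({slope:.4g}); curve is not Weibull-like"
        )
    params = WeibullParams(scale_lambda=float(np.exp(intercept)), shape_gamma=float(slope))
    se_log_lambda = float(res.bse[0])
    se_log_gamma = float(res.bse[1] / slope)  # delta method for ln gamma
    rss = float(np.sum(w[usable] * res.resid**2))
    return WeibullFit(
        params=params,
        se_log_lambda=se_log_lambda,
        se_log_gamma=se_log_gamma,
        rss=rss,
        n_points=int(usable.sum()),
    )
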