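"""Synthetic survival data with known ground truth.

Trial Kaplan-Meier figures cannot be redistributed, so every stage of the
pipeline is exercised on data generated here instead: individual patient
records drawn from a known Weibull law, their Kaplan-Meier estimate, a
point-sampled "digitized" version of that curve emulating what a plot
digitizer would read off a published figure, the accompanying numbers-at-risk
table, and a Gompertz-like life-table fixture standing in for national life
tables.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import InsufficientDataError, InvalidParameterError
from .weibull import WeibullParams

__all__ = [
    "StepCurve",
    "DigitizedCurve",
    "RiskTable",
    "LifeTable",
    "simulate_survival_times",
    "kaplan_meier",
    "emulate_digitization",
    "numbers_at_risk",
    "make_life_table_fixture",
    "read_ipd",
    "write_ipd",
    "read_curve",
    "write_curve",
    "read_risk_table",
    "write_risk_table",
    "read_life_table",
    "write_life_table",
]


@dataclass(frozen=True)
class StepCurve:
    """Right-continuous step survival function with steps at event times."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise InvalidParameterError("times and survival must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("step times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12) or (len(s) and s[0] > 1.0 + 1e-12):
            raise InvalidParameterError("survival must be non-increasing and <= 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)

    def evaluate(self, t):
        """Step-function value: survival after the last step time <= t (1.0 before the first)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t_arr, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


@dataclass(frozen=True)
class DigitizedCurve:
    """(time, survival) pairs as read off a published figure."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise InvalidParameterError("times and survival must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("digitized times must be strictly increasing")
        if np.any(s < 0) or np.any(s > 1):
            raise InvalidParameterError("digitized survival must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)


@dataclass(frozen=True)
class RiskTable:
    """Numbers at risk at chosen timepoints, as printed under a KM figure."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_at_risk, dtype=int)
        if t.shape != n.shape or t.ndim != 1:
            raise InvalidParameterError("times and n_at_risk must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("risk-table times must be strictly increasing")
        if np.any(n < 0) or np.any(np.diff(n) > 0):
            raise InvalidParameterError("n_at_risk must be non-negative and non-increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_at_risk", n)


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities by integer age; last row is an absorbing plateau."""

    age: np.ndarray
    q_annual: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.age, dtype=int)
        q = np.asarray(self.q_annual, dtype=float)
        if a.shape != q.shape or a.ndim != 1 or len(a) == 0:
            raise InvalidParameterError("age and q_annual must be equal-length non-empty 1-D")
        if np.any(np.diff(a) != 1):
            raise InvalidParameterError("ages must be contiguous integers")
        if np.any(q < 0) or np.any(q >= 1):
            raise InvalidParameterError("q_annual must lie in [0, 1)")
        object.__setattr__(self, "age", a)
        object.__setattr__(self, "q_annual", q)

    def annual_q(self, age: float) -> float:
        """q for the integer age containing ``age``, clamped to the table range."""
        idx = int(np.clip(np.floor(age) - self.age[0], 0, len(self.age) - 1))
        return float(self.q_annual[idx])


def simulate_survival_times(
    params: WeibullParams,
    n: int,
    max_follow_up: float | None = None,
    censor_rate: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw right-censored Weibull event times as a `time,event` frame.

    Event times use inverse-CDF sampling of S(t) = exp(-λ t^γ); censoring is
    an independent exponential clock with per-unit-time hazard ``censor_rate``
    plus administrative censoring at ``max_follow_up``.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if censor_rate < 0:
        raise InvalidParameterError("censor_rate must be >= 0")
    if max_follow_up is not None and max_follow_up < 0:
        raise InvalidParameterError("max_follow_up must be >= 0")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    event_t = (-np.log(u) / params.scale_lambda) ** (1.0 / params.shape_gamma)
    censor_t = np.full(n, np.inf)
    if censor_rate > 0:
        censor_t = rng.exponential(scale=1.0 / censor_rate, size=n)
    if max_follow_up is not None:
        censor_t = np.minimum(censor_t, max_follow_up)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return pd.DataFrame({"time": time, "event": event})


def kaplan_meier(ipd: pd.DataFrame) -> StepCurve:
    """Product-limit survival estimate with steps only at event times."""
    if len(ipd) == 0:
        raise InsufficientDataError("no records supplied")
    if int(ipd["event"].sum()) == 0:
        raise InsufficientDataError("Kaplan-Meier estimate requires at least one event")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd["time"], event_observed=ipd["event"])
    event_times = np.unique(ipd.loc[ipd["event"] == 1, "time"].to_numpy(dtype=float))
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    return StepCurve(times=event_times, survival=surv)


def emulate_digitization(
    curve: StepCurve,
    n_points: int = 50,
    noise_sd: float = 0.005,
    seed: int | None = None,
    t_max: float | None = None,
) -> DigitizedCurve:
    """Sample a step curve on an even time grid the way a plot digitizer would.

    The grid spans [0, t_max] (default: the last step time).  Times are read
    exactly; survival picks up optional additive Gaussian noise on the
    vertical axis, is clipped to [0, 1] and made non-increasing by a running
    minimum — a digitizer operator never lets the traced curve rise.
    """
    if n_points < 4:
        raise InvalidParameterError(f"n_points must be >= 4, got {n_points}")
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    end = float(curve.times[-1]) if t_max is None else float(t_max)
    grid = np.linspace(0.0, end, n_points)
    surv = np.atleast_1d(curve.evaluate(grid)).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        surv = surv + rng.normal(scale=noise_sd, size=n_points)
    surv = np.minimum.accumulate(np.clip(surv, 0.0, 1.0))
    return DigitizedCurve(times=grid, survival=surv)


def numbers_at_risk(ipd: pd.DataFrame, times) -> RiskTable:
    """Count records still under observation (time >= t) at each requested time."""
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InvalidParameterError("requested times must be sorted strictly ascending")
    obs = np.sort(ipd["time"].to_numpy(dtype=float))
    n = len(obs) - np.searchsorted(obs, t, side="left")
    return RiskTable(times=t, n_at_risk=n.astype(int))


def make_life_table_fixture(
    age_start: int, age_end: int, q0: float, doubling_years: float
) -> LifeTable:
    """Gompertz-like fixture: q doubles every ``doubling_years``, capped at 0.999.

    Stands in for a national life table; real tables load through
    :func:`read_life_table` with the same interface.
    """
    if age_end < age_start:
        raise InvalidParameterError(f"age_end {age_end} < age_start {age_start}")
    if not (0 < q0 < 1):
        raise InvalidParameterError(f"q0 must be in (0, 1), got {q0}")
    if not doubling_years > 0:
        raise InvalidParameterError("doubling_years must be positive")
    ages = np.arange(age_start, age_end + 1)
    q = np.minimum(q0 * 2.0 ** ((ages - age_start) / doubling_years), 0.999)
    return LifeTable(age=ages, q_annual=q)


# -- plain-text round trips -------------------------------------------------

def write_ipd(ipd: pd.DataFrame, path) -> None:
    ipd[["time", "event"]].to_csv(path, index=False)


def read_ipd(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != ["time", "event"]:
        raise InvalidParameterError(f"expected header time,event in {path}")
    return df


def write_curve(curve, path) -> None:
    pd.DataFrame({"time": curve.times, "survival": curve.survival}).to_csv(path, index=False)


def read_curve(path) -> DigitizedCurve:
    df = pd.read_csv(path)
    if list(df.columns) != ["time", "survival"]:
        raise InvalidParameterError(f"expected header time,survival in {path}")
    return DigitizedCurve(times=df["time"].to_numpy(), survival=df["survival"].to_numpy())


def write_risk_table(risk: RiskTable, path) -> None:
    pd.DataFrame({"time": risk.times, "n_at_risk": risk.n_at_risk}).to_csv(path, index=False)


def read_risk_table(path) -> RiskTable:
    df = pd.read_csv(path)
    if list(df.columns) != ["time", "n_at_risk"]:
        raise InvalidParameterError(f"expected header time,n_at_risk in {path}")
    return RiskTable(times=df["time"].to_numpy(), n_at_risk=df["n_at_risk"].to_numpy())


def write_life_table(table: LifeTable, path) -> None:
    pd.DataFrame({"age": table.age, "q_annual": table.q_annual}).to_csv(path, index=False)


def read_life_table(path) -> LifeTable:
    df = pd.read_csv(path)
    if list(df.columns) != ["age", "q_annual"]:
        raise InvalidParameterError(f"expected header age,q_annual in {path}")
    return LifeTable(age=df["age"].to_numpy(), q_annual=df["q_annual"].to_numpy())
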