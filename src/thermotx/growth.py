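"""Growth-rate estimation and cardinal-temperature modelling.

Two jobs live here:

1. Extract the exponential-phase specific growth rate (h^-1) from an OD600
   time series, as the slope of ln OD versus time over the steepest
   contiguous window — the classic "easy linear" estimator.
2. Fit the four-parameter square-root (Ratkowsky) model

       sqrt(r) = b * (T - Tmin) * (1 - exp(c * (T - Tmax)))

   to a set of (temperature, rate) pairs, which yields the cardinal
   temperatures Tmin and Tmax bounding the growth-permissive range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigError, DataError, NumericalError


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series for one culture.

    ``times`` (hours) must be strictly increasing, ``od600`` strictly
    positive; at least 4 points are required for rate fitting.
    """

    temperature: float
    replicate: str
    times: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od600", od)
        if t.ndim != 1 or od.shape != t.shape:
            raise DataError("times and od600 must be 1-D arrays of equal length")
        if len(t) < 4:
            raise DataError("a growth curve needs at least 4 points")
        if not np.all(np.diff(t) > 0):
            raise DataError("times must be strictly increasing")
        if not np.all(od > 0):
            raise DataError("od600 values must be strictly positive")


@dataclass(frozen=True)
class GrowthRateFit:
    """Result of the log-phase slope fit."""

    rate: float                 # h^-1, slope of ln OD vs t over the window
    window: tuple[int, int]     # index span [start, stop) of the window used
    r_squared: float

    @property
    def window_length(self) -> int:
        return self.window[1] - self.window[0]


@dataclass(frozen=True)
class RatkowskyParams:
    """Parameters of the extended square-root growth model."""

    b: float
    c: float
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_max):
            raise ConfigError("t_min must be below t_max")
        if self.b <= 0 or self.c <= 0:
            raise ConfigError("b and c must be positive")

    def sqrt_rate(self, temperature) -> np.ndarray:
        """Model value of sqrt(rate); may be negative outside (t_min, t_max)."""
        t = np.asarray(temperature, dtype=float)
        return self.b * (t - self.t_min) * (1.0 - np.exp(self.c * (t - self.t_max)))

    def rate(self, temperature) -> np.ndarray:
        """Predicted growth rate, clipped to 0 outside (t_min, t_max)."""
        t = np.asarray(temperature, dtype=float)
        s = self.sqrt_rate(t)
        r = np.where((t > self.t_min) & (t < self.t_max), s * s, 0.0)
        return r if r.ndim else float(r)


def _ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and R^2 of the OLS line y ~ t.

    A window whose residuals vanish (including a perfectly constant one)
    gets R^2 = 1 so that flat curves report rate 0 cleanly.
    """
    tc = t - t.mean()
    yc = y - y.mean()
    stt = float(tc @ tc)
    sty = float(tc @ yc)
    syy = float(yc @ yc)
    slope = sty / stt
    rss = syy - sty * sty / stt
    if syy <= 0 or rss <= 1e-15 * max(syy, 1.0):
        return slope, 1.0
    return slope, 1.0 - rss / syy


def fit_log_phase_rate(curve: GrowthCurve, min_window: int = 5) -> GrowthRateFit:
    """Exponential growth rate as the steepest ln-OD window slope.

    All contiguous windows of at least ``min_window`` points are scanned;
    the window with the largest OLS slope of ln OD vs time wins.  Ties go
    to the longer window, then to the earlier start, which makes the
    estimate deterministic and — on a noiseless exponential segment —
    returns the full segment and the exact rate.
    """
    if min_window < 3:
        raise ConfigError("min_window must be at least 3")
    n = len(curve.times)
    if n < min_window:
        raise DataError(
            f"curve has {n} points; at least min_window={min_window} required"
        )
    logod = np.log(curve.od600)
    best = None  # (slope, length, -start, r2, window)
    for length in range(min_window, n + 1):
        for start in range(0, n - length + 1):
            stop = start + length
            slope, r2 = _ols_slope(curve.times[start:stop], logod[start:stop])
            key = (round(slope, 12), length, -start)
            if best is None or key > best[0]:
                best = (key, slope, r2, (start, stop))
    _, slope, r2, window = best
    return GrowthRateFit(rate=slope, window=window, r_squared=r2)


def fit_ratkowsky(
    rates: dict[float, float],
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[RatkowskyParams, dict]:
    """Least-squares fit of the square-root model to (temperature, rate) pairs.

    Parameters
    ----------
    rates
        Mapping temperature (C) -> growth rate (h^-1), rates >= 0; at least
        4 distinct temperatures.
    n_starts
        Number of jittered initialisations (multi-start guards against the
        local minima of the exponential shoulder).
    seed
        Seed for the initialisation jitter only.

    Returns
    -------
    (params, diagnostics)
        ``diagnostics`` holds ``rss``, ``converged`` and the residuals.
        Non-convergence is flagged, never silent.
    """
    temps = np.array(sorted(rates), dtype=float)
    if len(temps) < 4:
        raise DataError("fit_ratkowsky needs at least 4 distinct temperatures")
    r = np.array([rates[t] for t in temps], dtype=float)
    if (r < 0).any():
        raise DataError("growth rates must be non-negative")
    sq = np.sqrt(r)

    def resid(p):
        b, c, tmin, tmax = p
        return b * (temps - tmin) * (1.0 - np.exp(c * (temps - tmax))) - sq

    # init: tmin below the coldest, tmax above the warmest observation;
    # b from the low-temperature slope of sqrt(r) vs T; c small.
    lo2 = temps[:2]
    b0 = max((sq[1] - sq[0]) / (lo2[1] - lo2[0]), 1e-4)
    base = np.array([b0, 0.1, temps[0] - 5.0, temps[-1] + 2.0])
    rng = np.random.default_rng(seed)
    lower = np.array([1e-8, 1e-8, temps[0] - 60.0, temps[-1] + 1e-6])
    upper = np.array([10.0, 10.0, temps[0] - 1e-6, temps[-1] + 60.0])

    best = None
    for i in range(n_starts):
        p0 = base.copy()
        if i > 0:
            p0 = p0 * rng.uniform(0.7, 1.3, size=4)
            p0[2] = base[2] - rng.uniform(0.0, 10.0)
            p0[3] = base[3] + rng.uniform(0.0, 10.0)
        p0 = np.clip(p0, lower + 1e-9, upper - 1e-9)
        try:
            sol = least_squares(
                resid, p0, bounds=(lower, upper),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000,
            )
        except Exception:  # numerical failure of one start is not fatal
            continue
        rss = float(sol.cost * 2)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise NumericalError("Ratkowsky fit failed from every start")
    rss, sol = best
    b, c, tmin, tmax = sol.x
    params = RatkowskyParams(b=float(b), c=float(c), t_min=float(tmin), t_max=float(tmax))
    diagnostics = {
        "rss": rss,
        "converged": bool(sol.success),
        "residuals": resid(sol.x).tolist(),
        "n_temperatures": int(len(temps)),
    }
    return params, diagnostics


def rates_from_curves(
    curves, min_window: int = 5
) -> dict[float, float]:
    """Mean log-phase rate per temperature across replicate curves."""
    per_temp: dict[float, list[float]] = {}
    for c in curves:
        fit = fit_log_phase_rate(c, min_window=min_window)
        per_temp.setdefault(float(c.temperature), []).append(fit.rate)
    return {t: float(np.mean(v)) for t, v in sorted(per_temp.items())}
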