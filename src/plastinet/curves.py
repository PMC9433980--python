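"""Parametric and nonparametric curve representations.

Two families are used throughout the pipeline:

* logistic growth curves ``a / (1 + b e^{-r t})`` for mean trajectories of
  genotype groups, and
* Legendre orthogonal polynomial expansions for smoothing arbitrary
  time-varying curves (genetic effect curves, ODE component functions),
  with analytic derivatives.

The Legendre basis is evaluated on the affine image of the time window
onto [-1, 1], the polynomials' natural domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.optimize import least_squares

__all__ = [
    "LogisticParams",
    "LegendreCurve",
    "logistic_eval",
    "fit_logistic",
    "fit_legendre",
    "legendre_derivative",
]


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of a logistic growth curve a / (1 + b exp(-r t)).

    a is the asymptote in trait units, b a dimensionless shape parameter
    (value at t=0 is a/(1+b)), r the relative growth rate per day.
    ``flagged`` marks degenerate fits (no growth information in the data).
    """

    a: float
    b: float
    r: float
    flagged: bool = False

    def __call__(self, t):
        return logistic_eval(self, t)


def logistic_eval(p: LogisticParams, t):
    """Evaluate the logistic curve a/(1 + b e^{-r t}) at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    return p.a / (1.0 + p.b * np.exp(-p.r * t))


def _logistic_residuals(theta, t, y):
    a, b, r = theta
    return a / (1.0 + b * np.exp(-r * t)) - y


def fit_logistic(y, times, *, max_starts: int = 12) -> LogisticParams:
    """Fit a logistic growth curve by multi-start nonlinear least squares.

    Starting points are a deterministic coarse grid over (b, r) seeded from
    the data (a0 = 1.05 * max(y)); the start reaching the lowest SSE wins.
    Constant or non-informative data yield a flagged fit.

    Parameters
    ----------
    y : array of length T, trait values (positive for growth traits).
    times : array of length T, strictly increasing measurement times.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or y.shape != t.shape:
        raise ValueError("y and times must be 1-D arrays of equal length")
    if y.size < 4:
        raise ValueError("need at least 4 time points to fit a logistic curve")

    span = y.max() - y.min()
    if span <= 1e-12 * max(1.0, abs(y).max()):
        # flat data: no growth information
        return LogisticParams(a=float(y.mean()), b=1e-6, r=1e-6, flagged=True)

    a0 = 1.05 * y.max()
    tspan = t.max() - t.min()
    # coarse deterministic grid: r spanning slow to fast growth over the
    # window, b placing the inflection at several positions inside it
    r_grid = np.array([0.5, 1.0, 2.0, 4.0, 8.0]) / tspan
    frac = np.array([0.25, 0.5, 0.75])  # inflection position within window
    starts = []
    for r0 in r_grid:
        for f in frac:
            t_inf = t.min() + f * tspan
            b0 = np.exp(r0 * t_inf)
            starts.append((a0, b0, r0))
    starts = starts[:max_starts] if max_starts else starts

    best = None
    best_sse = np.inf
    for theta0 in starts:
        try:
            res = least_squares(
                _logistic_residuals,
                theta0,
                args=(t, y),
                bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=400,
            )
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if sse < best_sse:
            best_sse = sse
            best = res.x
    if best is None:  # pragma: no cover - all starts failed
        return LogisticParams(a=a0, b=1.0, r=1.0 / tspan, flagged=True)
    a, b, r = (float(v) for v in best)
    return LogisticParams(a=a, b=b, r=r)


@dataclass(frozen=True)
class LegendreCurve:
    """Legendre polynomial expansion of a curve over a time window.

    ``coefficients[k]`` multiplies the degree-k Legendre polynomial P_k(u)
    with u the affine image of t from [t_min, t_max] onto [-1, 1].
    """

    coefficients: np.ndarray
    t_min: float
    t_max: float

    def __post_init__(self):
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )
        if self.t_max <= self.t_min:
            raise ValueError("time window must have positive length")

    @property
    def order(self) -> int:
        return len(self.coefficients) - 1

    def map_time(self, t):
        """Affine map of real time onto the Legendre domain [-1, 1]."""
        t = np.asarray(t, dtype=float)
        return 2.0 * (t - self.t_min) / (self.t_max - self.t_min) - 1.0

    def __call__(self, t):
        return npleg.legval(self.map_time(t), self.coefficients)

    def derivative(self, t):
        return legendre_derivative(self, t)

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "t_min": self.t_min,
            "t_max": self.t_max,
            "coefficients": [float(c) for c in self.coefficients],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LegendreCurve":
        return cls(
            coefficients=np.array(d["coefficients"], dtype=float),
            t_min=float(d["t_min"]),
            t_max=float(d["t_max"]),
        )


def legendre_design(times, order: int, t_min: float, t_max: float) -> np.ndarray:
    """Design matrix of Legendre polynomials P_0..P_order at mapped times."""
    u = 2.0 * (np.asarray(times, dtype=float) - t_min) / (t_max - t_min) - 1.0
    return npleg.legvander(u, order)


def fit_legendre(y, times, order: int, *, weights=None) -> LegendreCurve:
    """Least-squares projection of sampled values onto the Legendre basis.

    Exact (zero residual) when ``y`` is a polynomial of degree <= order in
    mapped time; interpolating when order = T - 1.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if order < 0:
        raise ValueError("order must be >= 0")
    if order + 1 > t.size:
        raise ValueError(f"order+1 = {order + 1} exceeds number of points {t.size}")
    t_min, t_max = float(t.min()), float(t.max())
    X = legendre_design(t, order, t_min, t_max)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        X = X * w[:, None]
        y = y * w
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return LegendreCurve(coefficients=coef, t_min=t_min, t_max=t_max)


def legendre_derivative(c: LegendreCurve, t):
    """Analytic time derivative of a Legendre curve.

    Includes the chain-rule factor 2/(t_max - t_min) from the affine map.
    """
    dcoef = npleg.legder(c.coefficients)
    u = c.map_time(t)
    return npleg.legval(u, dcoef) * (2.0 / (c.t_max - c.t_min))
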