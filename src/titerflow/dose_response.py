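"""Fractional-polynomial logistic dose-response model.

The model is

    f(x) = c + (d - c) / (1 + exp(b * ln(x+1)^p1 + e * ln(x+1)^p2))

with four free parameters (b, c, d, e) and two fixed positive powers
(p1, p2). Because the covariate is ln(x+1), a dose of exactly 0 is
representable and f(0) = (c + d)/2 for every parameterization.

Beyond evaluation and least-squares fitting, this module extracts the
analytic slope, the input dynamic range (the contiguous log-dose span where
the log-dose slope is at least ``epsilon_frac`` of its maximum), and the
induction threshold (lowest dose whose median exceeds the upper bootstrap
confidence bound of the zero-dose median).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import InsufficientDataError, ParameterError

__all__ = [
    "FpLogisticModel",
    "DoseResponseFit",
    "DynamicRange",
    "fplogistic_eval",
    "fit_fplogistic",
    "curve_slope",
    "input_dynamic_range",
    "induction_threshold",
]


@dataclass(frozen=True)
class FpLogisticModel:
    """Dose-response curve parameters: shape (b, e), asymptotes (c, d),
    fixed powers (p1, p2)."""

    b: float
    c: float
    d: float
    e: float
    p1: float = 1.0
    p2: float = 2.0

    def __post_init__(self):
        if not (self.p1 > 0 and self.p2 > 0):
            raise ParameterError(
                f"powers p1, p2 must be > 0, got p1={self.p1}, p2={self.p2}"
            )

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in ("b", "c", "d", "e", "p1", "p2")}


def _check_dose(x):
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ParameterError("dose must be >= 0")
    return x


def fplogistic_eval(m: FpLogisticModel, x):
    """Evaluate f(x); numerically stable (saturates to c or d, no overflow)."""
    x = _check_dose(x)
    L = np.log1p(x)
    g = m.b * L**m.p1 + m.e * L**m.p2
    # 1/(1+exp(g)) == expit(-g), stable for any |g|
    out = m.c + (m.d - m.c) * expit(-g)
    if out.ndim == 0:
        return float(out)
    return out


def curve_slope(m: FpLogisticModel, x):
    """Analytic df/dx. At x=0 with p1 or p2 < 1 the one-sided limit is
    returned (possibly +/- infinity)."""
    x = _check_dose(x)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    L = np.log1p(x)
    g = m.b * L**m.p1 + m.e * L**m.p2
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        gprime = (m.b * m.p1 * L ** (m.p1 - 1.0)
                  + m.e * m.p2 * L ** (m.p2 - 1.0)) / (x + 1.0)
        # s(1-s) for s = 1/(1+exp(g)), in sech form to defer underflow
        sig_deriv = (0.5 / np.cosh(0.5 * g)) ** 2
    amp = (m.d - m.c) * sig_deriv
    with np.errstate(invalid="ignore"):
        slope = -amp * gprime
    # 0 * inf at x=0 when the curve is flat there: the limit is 0
    slope = np.where(np.isnan(slope) & (amp == 0), 0.0, slope)
    return float(slope[0]) if scalar else slope


@dataclass
class DoseResponseFit:
    """Result of fitting the model to per-dose medians."""

    model: FpLogisticModel
    doses: np.ndarray
    medians: np.ndarray
    residuals: np.ndarray
    rmse: float
    converged: bool
    flat: bool = False
    sse: float = field(init=False)

    def __post_init__(self):
        self.sse = float(np.sum(self.residuals**2))


# multi-start grid for (b0, e0); the objective is multimodal
_B0_GRID = (-2.0, -0.5, 0.5, 2.0)
_E0_GRID = (-0.1, 0.0, 0.1)


def fit_fplogistic(doses, medians, p1: float = 1.0, p2: float = 2.0) -> DoseResponseFit:
    """Least-squares fit of (b, c, d, e) with p1, p2 held fixed.

    Uses multi-start Levenberg-Marquardt from a grid of shape initializations
    with c0 = min(medians), d0 = max(medians); the start with the lowest SSE
    wins, ties broken by smallest |b| + |e|.
    """
    doses = _check_dose(doses)
    medians = np.asarray(medians, dtype=np.float64)
    if doses.shape != medians.shape:
        raise ParameterError("doses and medians must have equal length")
    if len(doses) < 5:
        raise InsufficientDataError(
            f"need >= 5 (dose, median) pairs, got {len(doses)}"
        )
    if len(np.unique(doses)) < 3:
        raise InsufficientDataError("need >= 3 distinct doses")
    if not np.all(np.isfinite(medians)):
        raise ParameterError("medians must be finite")

    if np.ptp(medians) == 0:
        warnings.warn("all medians equal: returning flat fit", stacklevel=2)
        model = FpLogisticModel(0.0, medians[0], medians[0], 0.0, p1, p2)
        resid = np.zeros_like(medians)
        return DoseResponseFit(model, doses, medians, resid, 0.0, True, flat=True)

    L = np.log1p(doses)
    Lp1, Lp2 = L**p1, L**p2

    def residual(theta):
        b, c, d, e = theta
        return c + (d - c) * expit(-(b * Lp1 + e * Lp2)) - medians

    c0, d0 = float(medians.min()), float(medians.max())
    best = None
    for b0 in _B0_GRID:
        for e0 in _E0_GRID:
            try:
                res = least_squares(
                    residual, x0=[b0, c0, d0, e0], method="lm", max_nfev=5000
                )
            except Exception:
                continue
            sse = float(np.sum(res.fun**2))
            simplicity = abs(res.x[0]) + abs(res.x[3])
            key = (sse, simplicity)
            if best is None or _better(key, best[0]):
                best = (key, res)
    if best is None:
        raise InsufficientDataError("fit failed from every start")
    res = best[1]
    b, c, d, e = (float(v) for v in res.x)
    model = FpLogisticModel(b, c, d, e, p1, p2)
    resid = medians - fplogistic_eval(model, doses)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return DoseResponseFit(model, doses, medians, resid, rmse, res.status > 0)


def _better(key, ref, rtol=1e-9):
    sse, simp = key
    sse0, simp0 = ref
    if sse < sse0 * (1 - rtol):
        return True
    if sse <= sse0 * (1 + rtol):
        return simp < simp0
    return False


@dataclass(frozen=True)
class DynamicRange:
    """Contiguous dose span where the log-dose slope is non-negligible."""

    lower: float | None
    upper: float | None
    ratio: float | None
    epsilon_frac: float

    @property
    def empty(self) -> bool:
        return self.lower is None

    def to_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "ratio": self.ratio,
            "epsilon_frac": self.epsilon_frac,
        }


def input_dynamic_range(
    m: FpLogisticModel,
    epsilon_frac: float = 0.01,
    x_min: float = 0.01,
    x_max: float = 10_000.0,
    n_grid: int = 1000,
) -> DynamicRange:
    """Span of doses with "non-zero" slope on a log-dose axis.

    Evaluates |df/d(ln x)| = |x * df/dx| on ``n_grid`` log-spaced points and
    returns the contiguous run, containing the maximum, where the slope is at
    least ``epsilon_frac`` times its maximum. Flat curves give an empty range.
    """
    if not 0 < epsilon_frac < 1:
        raise ParameterError(f"epsilon_frac must be in (0, 1), got {epsilon_frac}")
    if not (0 < x_min < x_max):
        raise ParameterError("require 0 < x_min < x_max")
    xs = np.logspace(np.log10(x_min), np.log10(x_max), n_grid)
    log_slope = np.abs(xs * curve_slope(m, xs))
    peak = np.nanmax(log_slope)
    if not np.isfinite(peak) or peak == 0:
        return DynamicRange(None, None, None, epsilon_frac)
    mask = log_slope >= epsilon_frac * peak
    i = int(np.nanargmax(log_slope))
    lo = i
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = i
    while hi < n_grid - 1 and mask[hi + 1]:
        hi += 1
    lower, upper = float(xs[lo]), float(xs[hi])
    return DynamicRange(lower, upper, upper / lower, epsilon_frac)


def induction_threshold(doses, medians, zero_dose_ci) -> float | None:
    """Lowest tested dose whose median exceeds the upper bound of the
    zero-dose median's bootstrap CI; None if no dose qualifies."""
    doses = np.asarray(doses, dtype=np.float64)
    medians = np.asarray(medians, dtype=np.float64)
    if doses.shape != medians.shape:
        raise ParameterError("doses and medians must have equal length")
    if not np.any(doses == 0):
        raise ParameterError("a zero-dose sample is required")
    upper = float(zero_dose_ci.upper)
    order = np.argsort(doses)
    for i in order:
        if doses[i] > 0 and medians[i] > upper:
            return float(doses[i])
    return None
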