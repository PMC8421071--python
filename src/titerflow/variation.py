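"""Volume proxy, the VIV statistic, percentile bootstrap, and rank-matching
volume calibration.

VIV (volume-independent variation) is the residual standard deviation of a
robust (Huber M-estimator) linear model relating reporter fluorescence to a
per-event cell-volume proxy, computed by default on natural-log scales of
both variables so that expression-proportional-to-volume power laws become
linear and the statistic is invariant to positive rescaling of the reporter.

The volume proxy is the Euclidean magnitude of the (FSC-W, SSC-H) scatter
vector. The robust scale estimate is 1.4826 * median(|residuals|), the MAD
scaled for consistency with the Gaussian standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
)
from .flow_events import ChannelMap, EventTable

__all__ = [
    "RobustFit",
    "VIVResult",
    "BootstrapCI",
    "VolumeCalibration",
    "volume_proxy",
    "robust_linear_fit",
    "viv",
    "bootstrap_ci",
    "calibrate_volume",
]

HUBER_K = 1.345        # 95% Gaussian efficiency
MAD_TO_SD = 1.4826     # consistency factor for Gaussian data
_TOL = 1e-8
_MAX_ITER = 50


def volume_proxy(t: EventTable, cmap: ChannelMap) -> np.ndarray:
    """Per-event magnitude of the (FSC-W, SSC-H) scatter vector."""
    return np.hypot(t.channel(cmap.volume_x), t.channel(cmap.volume_y))


@dataclass(frozen=True)
class RobustFit:
    """Huber IRLS regression result. Iterable as (slope, intercept, scale)."""

    slope: float
    intercept: float
    scale: float          # 1.4826 * MAD of final residuals
    residual_sd: float    # plain SD of final residuals (n-2 dof)
    n_iter: int
    converged: bool

    def __iter__(self):
        return iter((self.slope, self.intercept, self.scale))


def robust_linear_fit(x, y, k: float = HUBER_K,
                      tol: float = _TOL, max_iter: int = _MAX_ITER) -> RobustFit:
    """Huber M-estimator line fit via iteratively reweighted least squares.

    The scale is re-estimated every iteration as ``1.4826 * median(|resid|)``;
    iteration stops when the largest coefficient change is below ``tol`` or
    after ``max_iter`` iterations.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D with equal length")
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("x is constant: slope is unidentifiable")

    # OLS start
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    converged = False
    n_iter = 0
    scale = 0.0
    for n_iter in range(1, max_iter + 1):
        resid = y - X @ coef
        scale = MAD_TO_SD * float(np.median(np.abs(resid)))
        if scale == 0.0:
            converged = True
            break
        cut = k * scale
        absr = np.abs(resid)
        w = np.where(absr <= cut, 1.0, cut / np.where(absr > 0, absr, 1.0))
        sw = np.sqrt(w)
        new_coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        delta = float(np.max(np.abs(new_coef - coef)))
        coef = new_coef
        if delta < tol:
            converged = True
            break
    resid = y - X @ coef
    scale = MAD_TO_SD * float(np.median(np.abs(resid)))
    dof = max(len(x) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return RobustFit(
        slope=float(coef[1]), intercept=float(coef[0]), scale=scale,
        residual_sd=residual_sd, n_iter=n_iter, converged=converged,
    )


@dataclass(frozen=True)
class VIVResult:
    """Robust-fit coefficients and residual standard deviation (the VIV value)."""

    slope: float
    intercept: float
    rsd: float            # robust scale at convergence: the VIV statistic
    residual_sd: float    # plain residual SD, reported alongside
    n_used: int
    n_dropped: int
    transform: str

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept, "rsd": self.rsd,
            "residual_sd": self.residual_sd, "n_used": self.n_used,
            "n_dropped": self.n_dropped, "transform": self.transform,
        }


def _transform_pairs(proxy: np.ndarray, reporter: np.ndarray, transform: str):
    if transform == "loglog":
        keep = (proxy > 0) & (reporter > 0)
        return np.log(proxy[keep]), np.log(reporter[keep]), keep
    if transform == "semilog":
        keep = reporter > 0
        return proxy[keep], np.log(reporter[keep]), keep
    if transform == "raw":
        keep = np.ones(len(proxy), dtype=bool)
        return proxy, reporter, keep
    raise ParameterError(f"transform must be loglog/semilog/raw, got {transform!r}")


def viv(t: EventTable, cmap: ChannelMap, transform: str = "loglog",
        min_events: int = 100) -> VIVResult:
    """Volume-independent variation of the reporter channel.

    Computes the volume proxy, transforms both variables (default: natural
    log of each, dropping nonpositive values), robust-fits reporter on proxy
    and returns the robust residual scale as the VIV statistic.
    """
    proxy = volume_proxy(t, cmap)
    reporter = t.channel(cmap.reporter)
    tx, ty, keep = _transform_pairs(proxy, reporter, transform)
    n_used = int(keep.sum())
    n_dropped = t.n_events - n_used
    if n_used < 3:
        raise InsufficientDataError(
            f"only {n_used} usable events after dropping nonpositive values"
        )
    if n_used < min_events:
        warnings.warn(
            f"viv computed on only {n_used} events (< {min_events})",
            stacklevel=2,
        )
    fit = robust_linear_fit(tx, ty)
    return VIVResult(
        slope=fit.slope, intercept=fit.intercept, rsd=fit.scale,
        residual_sd=fit.residual_sd, n_used=n_used, n_dropped=n_dropped,
        transform=transform,
    )


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap confidence interval."""

    point: float
    lower: float
    upper: float
    level: float = 0.95
    n_boot: int = 1000
    seed: int | None = None

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def to_dict(self) -> dict:
        return {
            "point": self.point, "lower": self.lower, "upper": self.upper,
            "level": self.level, "n_boot": self.n_boot, "seed": self.seed,
        }


def _viv_rsd_from_pairs(pairs: np.ndarray, transform: str = "loglog") -> float:
    tx, ty, _ = _transform_pairs(pairs[:, 0], pairs[:, 1], transform)
    if len(tx) < 3:
        raise InsufficientDataError("too few usable events for viv_rsd")
    return robust_linear_fit(tx, ty).scale


def bootstrap_ci(values, statistic="median", n_boot: int = 1000,
                 level: float = 0.95, seed: int | None = None,
                 transform: str = "loglog") -> BootstrapCI:
    """Percentile bootstrap CI of a statistic.

    ``statistic`` is ``"median"`` (values: 1-D vector), ``"viv_rsd"``
    (values: (n, 2) array of paired proxy/reporter intensities), or any
    callable mapping a resampled array to a float. Resamples are the same
    size as the input, drawn with replacement; bounds are the empirical
    (1-level)/2 and 1-(1-level)/2 quantiles of the resampled statistics.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ParameterError("values must be nonempty")
    if n_boot < 2:
        raise ParameterError(f"n_boot must be >= 2, got {n_boot}")
    if not 0 < level < 1:
        raise ParameterError(f"level must be in (0, 1), got {level}")
    rng = np.random.default_rng(seed)
    n = values.shape[0]

    if statistic == "median":
        if values.ndim != 1:
            raise ParameterError("median statistic expects a 1-D vector")
        point = float(np.median(values))
        idx = rng.integers(0, n, size=(n_boot, n))
        stats = np.median(values[idx], axis=1)
    else:
        if statistic == "viv_rsd":
            if values.ndim != 2 or values.shape[1] != 2:
                raise ParameterError(
                    "viv_rsd statistic expects an (n, 2) proxy/reporter array"
                )
            func = lambda v: _viv_rsd_from_pairs(v, transform)  # noqa: E731
        elif callable(statistic):
            func = statistic
        else:
            raise ParameterError(f"unknown statistic {statistic!r}")
        point = float(func(values))
        stats = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            stats[i] = func(values[idx])

    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(stats, [alpha, 1.0 - alpha])
    return BootstrapCI(point=point, lower=float(lower), upper=float(upper),
                       level=level, n_boot=n_boot, seed=seed)


@dataclass(frozen=True)
class VolumeCalibration:
    """Linear map from Coulter volume (fL) to the cytometric volume proxy."""

    slope: float
    intercept: float
    n_draws: int = 5000
    excluded_groups: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept,
            "n_draws": self.n_draws,
            "excluded_groups": list(self.excluded_groups),
        }


def calibrate_volume(proxy_values, coulter_volumes, n_draws: int = 5000,
                     seed: int | None = None,
                     excluded_groups=()) -> VolumeCalibration:
    """Rank-matching calibration of the volume proxy against Coulter volumes.

    Draws ``n_draws`` values with replacement from each dataset
    independently, sorts each drawn sample ascending, pairs them by rank and
    fits proxy (response) on volume (predictor) by ordinary least squares.
    Subpopulations deemed unrepresentative should be filtered out by the
    caller before the call; their labels can be recorded via
    ``excluded_groups``.
    """
    proxy = np.asarray(proxy_values, dtype=np.float64)
    vol = np.asarray(coulter_volumes, dtype=np.float64)
    if proxy.size == 0 or vol.size == 0:
        raise ParameterError("both input vectors must be nonempty")
    if n_draws < 2:
        raise DegenerateDataError(f"n_draws must be >= 2, got {n_draws}")
    if np.ptp(proxy) == 0 or np.ptp(vol) == 0:
        raise DegenerateDataError("constant input vector: fit is degenerate")
    rng = np.random.default_rng(seed)
    ps = np.sort(rng.choice(proxy, size=n_draws, replace=True))
    vs = np.sort(rng.choice(vol, size=n_draws, replace=True))
    if np.ptp(vs) == 0:
        raise DegenerateDataError("drawn volume sample is constant")
    slope, intercept = np.polyfit(vs, ps, 1)
    return VolumeCalibration(
        slope=float(slope), intercept=float(intercept), n_draws=n_draws,
        excluded_groups=tuple(excluded_groups),
    )
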