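"""Population summary metrics: medians, fold metrics, CoV, 0-100 scaling.

All metrics operate on the whole (ungated) population by default. Fold
metrics are ratios of sample medians; CoV uses the n-1 sample standard
deviation divided by the sample mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, InsufficientDataError, UndefinedRatioError
from .flow_events import EventTable

__all__ = [
    "MetricReport",
    "median_fluorescence",
    "fold_difference",
    "fold_over_autofluorescence",
    "percent_of_reference",
    "coefficient_of_variation",
    "normalize_0_100",
]


@dataclass(frozen=True)
class MetricReport:
    median_reporter: float
    cov: float
    fold_difference: float | None = None
    fold_over_autofluorescence: float | None = None
    percent_of_reference: float | None = None


def median_fluorescence(t: EventTable, channel: str) -> float:
    """Sample median of one channel (even n: mean of the two central order
    statistics)."""
    return float(np.median(t.channel(channel)))


def _ratio(num: float, den: float, what: str) -> float:
    if den <= 0:
        raise UndefinedRatioError(
            f"{what} undefined: denominator median is {den} (must be > 0)"
        )
    return num / den


def fold_difference(max_t: EventTable, repressed_t: EventTable, channel: str) -> float:
    """Median of the maximum-activity population over the repressed one."""
    return _ratio(
        median_fluorescence(max_t, channel),
        median_fluorescence(repressed_t, channel),
        "fold difference",
    )


def fold_over_autofluorescence(t: EventTable, auto_t: EventTable, channel: str) -> float:
    """Median signal over the median autofluorescent background."""
    return _ratio(
        median_fluorescence(t, channel),
        median_fluorescence(auto_t, channel),
        "fold over autofluorescence",
    )


def percent_of_reference(t: EventTable, ref_t: EventTable, channel: str) -> float:
    """Median signal as a percentage of a reference population's median."""
    return 100.0 * _ratio(
        median_fluorescence(t, channel),
        median_fluorescence(ref_t, channel),
        "percent of reference",
    )


def coefficient_of_variation(t: EventTable, channel: str) -> float:
    """Sample SD (n-1 denominator) divided by sample mean."""
    x = t.channel(channel)
    if len(x) < 2:
        raise InsufficientDataError("CoV requires at least 2 events")
    mean = float(np.mean(x))
    if mean <= 0:
        raise UndefinedRatioError(f"CoV undefined: mean is {mean} (must be > 0)")
    return float(np.std(x, ddof=1)) / mean


def normalize_0_100(series) -> np.ndarray:
    """Affine map of an ordered curve so min -> 0 and max -> 100."""
    y = np.asarray(series, dtype=np.float64)
    if y.ndim != 1 or len(y) < 2:
        raise DegenerateDataError("series must be 1-D with >= 2 points")
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi <= lo:
        raise DegenerateDataError("constant series cannot be scaled to 0-100")
    return 100.0 * (y - lo) / (hi - lo)
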