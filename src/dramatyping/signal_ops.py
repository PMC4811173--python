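"""Numeric primitives composed by the classification cascade.

The lab-value curve is treated as a discrete-time biosignal on a daily grid.
Because the standard signal-processing routines expect contiguous samples,
days without an observation are temporarily filled with zeros carrying a very
low weight (default 1e-6), so weighted fits and means effectively ignore them
while convolution-type operations can run on a regular grid.

Primitives provided here:

* reference-interval normalization of absolute lab values,
* gap filling to a contiguous weighted series,
* 1-D Gaussian low-pass filtering (σ = 1.5 by default),
* outlier removal (the two most extremely deviating values → median),
* weighted constant/linear least-squares fits with a tolerance test,
* the predicates used by the cascade: phase-mean difference, edge
  detection, zig-zag detection, deviation from the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import LabValueEpisode

__all__ = [
    "InvalidReferenceIntervalError",
    "NotEnoughDataError",
    "WeightedSeries",
    "FitResult",
    "normalize_lab_value",
    "fill_gaps",
    "gaussian_lowpass",
    "remove_outliers",
    "fit_and_test",
    "phase_means_differ",
    "detect_edge",
    "is_zigzag",
    "deviates_from_mean",
]

RISING = "rising"
FALLING = "falling"
FLAT = "flat"


class InvalidReferenceIntervalError(ValueError):
    """Upper reference bound does not exceed the lower bound."""


class NotEnoughDataError(ValueError):
    """Too few observed values for the requested operation."""


@dataclass(frozen=True)
class WeightedSeries:
    """A contiguous daily series with per-sample weights in ``(0, 1]``.

    Observed samples carry weight 1; artificial gap fillers carry the tiny
    gap weight.  ``days`` are strictly increasing integers.
    """

    days: np.ndarray
    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        days = np.asarray(self.days, dtype=int)
        values = np.asarray(self.values, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if not (len(days) == len(values) == len(weights)):
            raise ValueError("days, values and weights must have equal length")
        if len(days) and np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(weights <= 0):
            raise ValueError("weights must be positive")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "weights", weights)

    def __len__(self) -> int:
        return len(self.days)

    @property
    def observed_mask(self) -> np.ndarray:
        """True where the sample is a real observation (weight 1)."""
        return self.weights >= 0.5

    def subset(self, mask: np.ndarray) -> "WeightedSeries":
        return WeightedSeries(self.days[mask], self.values[mask], self.weights[mask])

    def with_values(self, values: np.ndarray) -> "WeightedSeries":
        return WeightedSeries(self.days, np.asarray(values, dtype=float), self.weights)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a tolerance-tested weighted least-squares fit.

    ``residual`` is the weighted RMS deviation
    ``sqrt(Σ wᵢ (yᵢ − ŷᵢ)² / Σ wᵢ)`` of the data from the fitted curve;
    ``within_tolerance`` is ``residual <= tol`` for the tolerance supplied
    to :func:`fit_and_test`.
    """

    kind: str  # "constant" | "linear"
    coefficients: Tuple[float, ...]  # (level,) or (slope, intercept)
    residual: float
    within_tolerance: bool

    @property
    def level(self) -> float:
        if self.kind != "constant":
            raise AttributeError("level is defined for constant fits only")
        return self.coefficients[0]

    @property
    def slope(self) -> float:
        if self.kind != "linear":
            raise AttributeError("slope is defined for linear fits only")
        return self.coefficients[0]

    @property
    def intercept(self) -> float:
        if self.kind != "linear":
            raise AttributeError("intercept is defined for linear fits only")
        return self.coefficients[1]


def normalize_lab_value(lv_a: float, bv_l: float, bv_u: float) -> float:
    """Map an absolute lab value onto the reference-interval scale.

    ``(lv_a − bv_l) / (bv_u − bv_l)``: the patient-specific reference
    interval ``[bv_l, bv_u]`` maps to ``[0, 1]``.  Values outside the
    interval map outside ``[0, 1]`` and stay meaningful.
    """
    if not bv_u > bv_l:
        raise InvalidReferenceIntervalError(
            f"upper bound {bv_u!r} must exceed lower bound {bv_l!r}"
        )
    return (lv_a - bv_l) / (bv_u - bv_l)


def fill_gaps(episode: LabValueEpisode, gap_weight: float = 1e-6) -> WeightedSeries:
    """Expand an episode to a contiguous daily series.

    Every integer day from the first to the last observation is present;
    observed days keep their value at weight 1, missing days get value 0 at
    ``gap_weight``.  The tiny weight makes the artificial zeros negligible in
    every weighted computation downstream.
    """
    first, last = episode.first_day, episode.last_day
    days = np.arange(first, last + 1)
    values = np.zeros(len(days))
    weights = np.full(len(days), gap_weight)
    observed = {d: v for d, v in episode.observations}
    for i, d in enumerate(days):
        if int(d) in observed:
            values[i] = observed[int(d)]
            weights[i] = 1.0
    return WeightedSeries(days, values, weights)


def gaussian_lowpass(series: WeightedSeries, sigma: float) -> WeightedSeries:
    """Apply a 1-D Gaussian low-pass filter to the series values.

    Truncated discrete kernel (4σ radius), reflective boundary handling.
    Days and weights are unchanged; the low-weight gap fillers are smoothed
    along with the observations (the error this introduces is negligible at
    the default gap weight).
    """
    if len(series) == 0:
        raise NotEnoughDataError("cannot filter an empty series")
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    smoothed = gaussian_filter1d(series.values, sigma=sigma, mode="reflect")
    return series.with_values(smoothed)


def remove_outliers(series: WeightedSeries) -> WeightedSeries:
    """Replace the two most extremely deviating observed values by the median.

    Deviation is measured from the median of the observed (weight-1) values;
    gap fillers are never touched and never counted.  Exactly two values are
    replaced, even when the second deviates little; ties are broken in favor
    of the earliest day.
    """
    observed_idx = np.flatnonzero(series.observed_mask)
    if len(observed_idx) < 3:
        raise NotEnoughDataError(
            f"outlier removal needs >= 3 observed values, got {len(observed_idx)}"
        )
    observed_values = series.values[observed_idx]
    median = float(np.median(observed_values))
    deviations = np.abs(observed_values - median)
    # stable sort: equal deviations keep day order, so argsort of -dev with
    # kind="stable" picks the earliest day among ties
    order = np.argsort(-deviations, kind="stable")
    replace = observed_idx[order[:2]]
    new_values = series.values.copy()
    new_values[replace] = median
    return series.with_values(new_values)


def _weighted_rms(values: np.ndarray, fitted: np.ndarray, weights: np.ndarray) -> float:
    return float(np.sqrt(np.sum(weights * (values - fitted) ** 2) / np.sum(weights)))


def fit_and_test(series: WeightedSeries, kind: str, tol: float) -> FitResult:
    """Weighted least-squares constant or linear fit with a tolerance test.

    The constant/linear least-squares problem has a closed-form solution
    which coincides with the Levenberg–Marquardt optimum, so the closed form
    is used.  Gap weights suppress the artificial zeros.
    """
    if kind not in ("constant", "linear"):
        raise ValueError(f"unknown fit kind {kind!r}")
    n_observed = int(np.count_nonzero(series.observed_mask))
    if kind == "constant" and n_observed < 1:
        raise NotEnoughDataError("constant fit needs >= 1 observed value")
    if kind == "linear" and n_observed < 2:
        raise NotEnoughDataError("linear fit needs >= 2 observed values")
    w = series.weights
    y = series.values
    if kind == "constant":
        level = float(np.sum(w * y) / np.sum(w))
        fitted = np.full_like(y, level)
        coeffs: Tuple[float, ...] = (level,)
    else:
        x = series.days.astype(float)
        slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
        fitted = slope * x + intercept
        coeffs = (float(slope), float(intercept))
    residual = _weighted_rms(y, fitted, w)
    return FitResult(kind, coeffs, residual, residual <= tol)


def constant_residual_about(series: WeightedSeries, level: float) -> float:
    """Weighted RMS deviation of the series from a fixed constant level.

    Used by the cascade to ask whether values that were constant in one phase
    are still on the same level in another.
    """
    if len(series) == 0:
        raise NotEnoughDataError("empty series")
    fitted = np.full_like(series.values, float(level))
    return _weighted_rms(series.values, fitted, series.weights)


def _weighted_mean(values, weights=None) -> float:
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise NotEnoughDataError("cannot take the mean of an empty value list")
    if weights is None:
        return float(values.mean())
    weights = np.asarray(weights, dtype=float)
    return float(np.sum(weights * values) / np.sum(weights))


def phase_means_differ(
    pre_values: Sequence[float],
    later_values: Sequence[float],
    tol: float,
    pre_weights: Optional[Sequence[float]] = None,
    later_weights: Optional[Sequence[float]] = None,
) -> bool:
    """True iff the pre-phase mean and the mid/post mean differ by more than ``tol``.

    Optional weights let the caller suppress artificial gap fillers.
    """
    if len(pre_values) == 0:
        raise NotEnoughDataError("empty pre-phase")
    if len(later_values) == 0:
        raise NotEnoughDataError("empty mid/post phase")
    diff = abs(_weighted_mean(pre_values, pre_weights) - _weighted_mean(later_values, later_weights))
    return diff > tol


def detect_edge(
    phase_values: Sequence[float],
    slope_threshold: float,
    weights: Optional[Sequence[float]] = None,
) -> str:
    """Classify a (low-pass filtered) phase as rising, falling or flat.

    Fits a line over the sample index (the series is on a contiguous daily
    grid, so index spacing equals day spacing) and thresholds its slope.
    Fewer than 2 values count as flat so the cascade degrades gracefully on
    empty phases.
    """
    y = np.asarray(phase_values, dtype=float)
    if len(y) < 2:
        return FLAT
    x = np.arange(len(y), dtype=float)
    w = None if weights is None else np.sqrt(np.asarray(weights, dtype=float))
    slope = np.polyfit(x, y, 1, w=w)[0]
    if slope > slope_threshold:
        return RISING
    if slope < -slope_threshold:
        return FALLING
    return FLAT


def is_zigzag(values: Sequence[float], zigzag_amp: float, zigzag_frac: float) -> bool:
    """Detect strong alternation ("zig-zag") in a value sequence.

    Consecutive differences with magnitude above ``zigzag_amp`` are kept; the
    sequence zig-zags iff there are at least 3 such differences and the
    fraction of sign alternations between successive kept differences is at
    least ``zigzag_frac``.
    """
    y = np.asarray(values, dtype=float)
    if len(y) < 4:
        return False
    diffs = np.diff(y)
    strong = diffs[np.abs(diffs) > zigzag_amp]
    if len(strong) < 3:
        return False
    signs = np.sign(strong)
    alternations = np.count_nonzero(signs[1:] != signs[:-1])
    return bool(alternations / (len(strong) - 1) >= zigzag_frac)


def deviates_from_mean(values: Sequence[float], mean_dev_tol: float) -> bool:
    """True iff any value deviates from the mean by more than ``mean_dev_tol``."""
    y = np.asarray(values, dtype=float)
    if len(y) == 0:
        raise NotEnoughDataError("empty value list")
    return bool(np.max(np.abs(y - y.mean())) > mean_dev_tol)
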