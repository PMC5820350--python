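"""Growth-rate estimation from microplate OD time series.

Local growth rates are the slopes of ordinary least-squares regressions of
ln(OD) on time in rolling 5-point windows (10-min sampling).  The reported
population rate is the mean of local rates where the background-subtracted
OD sits inside the open exponential-phase band (0.04, 0.4).  The production
load of a producer relative to a non-producer population is the relative
growth-rate difference 1 - r_producer / r_nonproducer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ODSeries",
    "GrowthEstimate",
    "background_subtract",
    "local_growth_rates",
    "mean_band_rate",
    "estimate_growth",
    "production_load",
]

#: OD floor applied after blank subtraction, for log-transform safety.
EPSILON_OD = 1e-4


@dataclass(frozen=True)
class ODSeries:
    """One well's OD630 trace plus un-inoculated blank wells.

    ``times_min`` must be strictly increasing (nominally uniform 10-min
    spacing); ``blanks`` has one row per blank well, same length as
    ``times_min``.
    """

    times_min: np.ndarray
    od_raw: np.ndarray
    blanks: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        od = np.asarray(self.od_raw, dtype=float)
        blanks = np.atleast_2d(np.asarray(self.blanks, dtype=float))
        if t.shape != od.shape:
            raise ValueError("times and OD must have equal length")
        if blanks.size and blanks.shape[1] != t.size:
            raise ValueError("blank traces must match the time grid")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "od_raw", od)
        object.__setattr__(self, "blanks", blanks)


@dataclass(frozen=True)
class GrowthEstimate:
    local_rates: np.ndarray  # per hour, NaN outside window coverage
    mean_rate: float  # per hour, mean over in-band points
    band: tuple[float, float]
    n_points_used: int


def background_subtract(series: ODSeries) -> np.ndarray:
    """Subtract the per-time mean of blank wells; floor at a small epsilon."""
    if series.blanks.size == 0:
        raise ValueError("at least one un-inoculated blank well is required")
    corrected = series.od_raw - series.blanks.mean(axis=0)
    return np.maximum(corrected, EPSILON_OD)


def local_growth_rates(
    corrected: np.ndarray, times_min: np.ndarray, window: int = 5, log_od: bool = True
) -> np.ndarray:
    """Per-point local growth rates (1/h) from rolling OLS regressions.

    The rate at a centre point is the slope of ln(OD) (or raw OD with
    ``log_od=False``) on time in hours over the surrounding ``window``
    points.  Edge points without a full window, and windows containing
    floored (non-positive before flooring) OD values, are NaN.
    """
    corrected = np.asarray(corrected, dtype=float)
    t_h = np.asarray(times_min, dtype=float) / 60.0
    n = corrected.size
    if n < window:
        raise ValueError(f"series length {n} is shorter than the window ({window})")
    y = np.log(corrected) if log_od else corrected
    half = window // 2
    rates = np.full(n, np.nan)
    for i in range(half, n - (window - 1 - half)):
        sl = slice(i - half, i - half + window)
        if log_od and np.any(corrected[sl] <= EPSILON_OD):
            continue  # floored value inside the window: skip
        tw, yw = t_h[sl], y[sl]
        tc = tw - tw.mean()
        rates[i] = float(np.dot(tc, yw - yw.mean()) / np.dot(tc, tc))
    return rates


def mean_band_rate(
    local_rates: np.ndarray,
    corrected: np.ndarray,
    band: tuple[float, float] = (0.04, 0.4),
) -> float:
    """Arithmetic mean of local rates where corrected OD lies strictly
    inside the band."""
    local_rates = np.asarray(local_rates, dtype=float)
    corrected = np.asarray(corrected, dtype=float)
    mask = (corrected > band[0]) & (corrected < band[1]) & np.isfinite(local_rates)
    if not mask.any():
        raise ValueError(
            f"no usable points inside OD band {band}: series spans "
            f"[{corrected.min():.3g}, {corrected.max():.3g}]"
        )
    return float(local_rates[mask].mean())


def estimate_growth(
    series: ODSeries, window: int = 5, band: tuple[float, float] = (0.04, 0.4), log_od: bool = True
) -> GrowthEstimate:
    """Full pipeline: blank subtraction, rolling regression, band mean."""
    corrected = background_subtract(series)
    rates = local_growth_rates(corrected, series.times_min, window=window, log_od=log_od)
    mask = (corrected > band[0]) & (corrected < band[1]) & np.isfinite(rates)
    return GrowthEstimate(
        local_rates=rates,
        mean_rate=mean_band_rate(rates, corrected, band),
        band=band,
        n_points_used=int(mask.sum()),
    )


def production_load(rate_producer: float, rate_nonproducer: float) -> float:
    """Production load as relative growth-rate difference:
    1 - r_producer / r_nonproducer."""
    if rate_producer < 0 or rate_nonproducer <= 0:
        raise ValueError("growth rates must be non-negative (non-producer strictly positive)")
    return 1.0 - rate_producer / rate_nonproducer
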