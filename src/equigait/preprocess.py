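"""Likelihood filtering and trimmed excursion statistics.

Pose-estimation trackers occasionally misplace a landmark; the analysis
therefore (a) discards frames whose detection confidence falls below a
threshold (default 0.60) and (b) summarises a coordinate series not by its
raw extrema but by *percentile bands*: the top and bottom 5% of measured
values are discarded as potential tracking errors, the mean of the 90-95th
percentile band (Max̄) stands in for the maximum, the mean of the 5-10th
percentile band (Min̄) for the minimum, and their absolute difference is the
excursion span of the landmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .io_trajectories import KeypointSeries

#: Detection-confidence cutoff below which a frame is treated as missing.
LIKELIHOOD_THRESHOLD = 0.60

#: Percentile bands (lo, hi) whose means stand in for the series extrema.
MAXIMA_BAND = (90.0, 95.0)
MINIMA_BAND = (5.0, 10.0)

#: Minimum usable frames for band statistics (each 5% band non-empty).
MIN_USABLE_FRAMES = 20


@dataclass(frozen=True)
class ExcursionStats:
    """Trimmed band means and their span for one coordinate series."""

    max_mean: float
    min_mean: float
    span: float
    n_used: int


def filter_by_likelihood(
    series: KeypointSeries, threshold: float = LIKELIHOOD_THRESHOLD
) -> KeypointSeries:
    """Mark frames with likelihood strictly below ``threshold`` as missing.

    Frame count and alignment are preserved: rejected frames keep their
    slot with NaN coordinates.  ``threshold=0`` is the identity.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    drop = series.likelihood < threshold
    x = series.x.copy()
    y = series.y.copy()
    x[drop] = np.nan
    y[drop] = np.nan
    return KeypointSeries(x, y, series.likelihood.copy())


def percentile_band_mean(values: np.ndarray, lo: float, hi: float) -> float:
    """Mean of the values whose rank-percentile falls in ``[lo, hi)``.

    Non-missing values are sorted ascending; the value at 0-based sorted
    index ``i`` of ``n`` has rank-percentile ``100 * (i + 0.5) / n`` and
    belongs to the band iff ``lo <= p < hi``.
    """
    if not 0 <= lo < hi <= 100:
        raise ValueError(f"need 0 <= lo < hi <= 100, got ({lo}, {hi})")
    values = np.asarray(values, dtype=float)
    clean = np.sort(values[np.isfinite(values)])
    n = clean.size
    if n == 0:
        raise InsufficientDataError("no usable values for band statistics")
    p = 100.0 * (np.arange(n) + 0.5) / n
    band = clean[(p >= lo) & (p < hi)]
    if band.size == 0:
        raise InsufficientDataError(
            f"percentile band ({lo}, {hi}) is empty for n={n} values"
        )
    return float(band.mean())


def excursion_stats(
    series: KeypointSeries,
    axis: str,
    detrend_window: Optional[int] = None,
    label: str = "",
) -> ExcursionStats:
    """Trimmed excursion statistics of one coordinate of a filtered series.

    ``max_mean`` is the mean of the 90-95th percentile band, ``min_mean``
    the mean of the 5-10th band, ``span`` their absolute difference.  The
    optional moving-median detrend (window in frames) is intended for
    panning-camera footage and is off by default.
    """
    coord = series.coord(axis).astype(float)
    if detrend_window:
        trend = (
            pd.Series(coord)
            .rolling(detrend_window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        coord = coord - trend
    n_used = int(np.isfinite(coord).sum())
    if n_used < MIN_USABLE_FRAMES:
        where = f" for {label}" if label else ""
        raise InsufficientDataError(
            f"only {n_used} usable frames{where}; need >= {MIN_USABLE_FRAMES}"
        )
    max_mean = percentile_band_mean(coord, *MAXIMA_BAND)
    min_mean = percentile_band_mean(coord, *MINIMA_BAND)
    return ExcursionStats(
        max_mean=max_mean,
        min_mean=min_mean,
        span=abs(max_mean - min_mean),
        n_used=n_used,
    )
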