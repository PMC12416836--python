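"""Division and death event detection on single-cell trajectories.

Divisions are read from the cycle-marker trace as local maxima passing
prominence, separation and height filters (prominence is relative to the
trace's own maximum, so detection is invariant to marker rescaling).  Death
is the first time the cleaved death-marker fraction exceeds a threshold,
linearly interpolated between grid points so the detected time does not snap
to the output grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigurationError, InputError
from .model import ModelSpecs, Trajectory

__all__ = [
    "PeakParams",
    "detect_division_events",
    "first_division",
    "detect_death",
]


@dataclass(frozen=True)
class PeakParams:
    """Peak filters: prominence as a fraction of the trace max, separation in
    hours, and an absolute marker floor."""

    min_prominence: float = 0.2
    min_separation: float = 6.0
    min_height: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.min_prominence <= 1:
            raise ConfigurationError("min_prominence must lie in [0, 1]")
        if self.min_separation < 0 or self.min_height < 0:
            raise ConfigurationError("min_separation and min_height must be >= 0")


def detect_division_events(
    marker: np.ndarray,
    times: np.ndarray,
    params: PeakParams | None = None,
) -> np.ndarray:
    """Times of marker peaks passing all filters, in increasing order.

    Endpoints are never peaks.  Peaks closer than ``min_separation`` keep the
    higher one (ties resolve to the earlier).
    """
    params = params if params is not None else PeakParams()
    marker = np.asarray(marker, float)
    times = np.asarray(times, float)
    if marker.shape != times.shape or marker.size < 3:
        raise InputError("marker and times must be equal-length series of >= 3 points")
    if not (np.all(np.isfinite(marker)) and np.all(np.isfinite(times))):
        raise InputError("marker/time series contain non-finite values")
    top = float(marker.max())
    if top <= 0:
        return np.empty(0)
    dt = float(np.median(np.diff(times)))
    distance = max(1, int(round(params.min_separation / dt)))
    idx, _ = find_peaks(
        marker,
        prominence=params.min_prominence * top,
        distance=distance,
        height=params.min_height,
    )
    return times[idx]


def first_division(
    trajectory: Trajectory,
    specs: ModelSpecs | None = None,
    params: PeakParams | None = None,
) -> float | None:
    """Time of the earliest detected division peak, or None."""
    specs = specs if specs is not None else trajectory.specs
    peaks = detect_division_events(
        trajectory.states[:, specs.index(specs.cc_marker)], trajectory.times, params
    )
    return float(peaks[0]) if peaks.size else None


def detect_death(
    trajectory: Trajectory,
    specs: ModelSpecs | None = None,
    threshold: float = 0.5,
) -> float | None:
    """First time the cleaved fraction strictly exceeds ``threshold``.

    Returns None when the model has no death marker or the threshold is never
    crossed.  The crossing is linearly interpolated between grid points; a
    trace already above threshold at birth returns the first time point.
    """
    if not 0 < threshold < 1:
        raise ConfigurationError("death threshold must lie in (0, 1)")
    specs = specs if specs is not None else trajectory.specs
    if specs.death_marker is None:
        return None
    series = trajectory.states[:, specs.index(specs.death_marker)]
    if not np.all(np.isfinite(series)):
        raise InputError("death-marker series contains non-finite values")
    above = series > threshold
    if not np.any(above):
        return None
    j = int(np.argmax(above))
    if j == 0:
        return float(trajectory.times[0])
    t0, t1 = trajectory.times[j - 1], trajectory.times[j]
    v0, v1 = series[j - 1], series[j]
    return float(t0 + (threshold - v0) / (v1 - v0) * (t1 - t0))
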