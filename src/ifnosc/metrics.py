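"""Quantitative features of simulated time courses.

The damped-oscillation phenotype is summarized by a handful of scalar
features: the times and amplitudes of local maxima ("first peak", "second
peak"), the time at which a series decays to half its maximum, and the
total time a series spends above a fraction of its maximum (the "high
plateau" of the SOCS1-knockout response).

Peak definition.  A grid point is a peak when it is strictly greater than
both neighbours; a maximal flat run bounded by strictly smaller values
counts once, at its leftmost point.  Endpoints are never peaks.  Peaks
whose topographic prominence is below ``min_prominence_fraction`` of the
series' global maximum are discarded, so solver ripple never creates
spurious "second peaks" (the default 2% is far below the amplitude of any
genuine secondary peak of this model, and far above integration noise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.signal import peak_prominences

from .errors import UsageError

__all__ = [
    "Peak",
    "PeakMetrics",
    "find_local_maxima",
    "half_max_decay_time",
    "high_plateau_duration",
    "peak_metrics",
]

DEFAULT_PROMINENCE_FRACTION = 0.02


class Peak(NamedTuple):
    time: float
    value: float


@dataclass(frozen=True)
class PeakMetrics:
    """Peak summary of one series over one simulation window."""

    peaks: tuple                      # ordered Peak list (retained only)
    global_max: Peak
    half_max_decay_time: Optional[float]  # minutes, or None if never reached
    plateau_duration_at_fraction: float   # minutes at the fraction used
    plateau_fraction: float


def _candidate_peak_indices(values: np.ndarray):
    """Strict local maxima; flat tops contribute their leftmost index."""
    idx = []
    i = 1
    n = len(values)
    while i < n - 1:
        if values[i] > values[i - 1]:
            j = i
            while j + 1 < n and values[j + 1] == values[i]:
                j += 1
            if j < n - 1 and values[j + 1] < values[i]:
                idx.append(i)
            i = j + 1
        else:
            i += 1
    return idx


def find_local_maxima(times, values,
                      min_prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION):
    """Ordered list of retained peaks of a uniformly sampled series."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise UsageError("empty series")
    if values.size < 3:
        raise UsageError("peak detection needs at least 3 grid points")
    cand = _candidate_peak_indices(values)
    if not cand:
        return []
    gmax = float(values.max())
    prom = peak_prominences(values, cand)[0]
    return [Peak(float(times[i]), float(values[i]))
            for i, pr in zip(cand, prom) if pr >= min_prominence_fraction * gmax]


def half_max_decay_time(times, values) -> Optional[float]:
    """First time after the global maximum at which the series has fallen
    to half that maximum, linearly interpolated between grid points.

    Returns None when the series never reaches half-max inside the window
    (e.g. a constant series), which is an absent value, not an error.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise UsageError("empty series")
    imax = int(np.argmax(values))
    vmax = values[imax]
    if vmax <= 0:
        return None
    half = 0.5 * vmax
    below = np.flatnonzero(values[imax:] <= half)
    if below.size == 0:
        return None
    k = imax + below[0]
    if k == imax:
        return float(times[k])
    t0, t1 = times[k - 1], times[k]
    v0, v1 = values[k - 1], values[k]
    if v0 == v1:
        return float(times[k])
    return float(t0 + (v0 - half) / (v0 - v1) * (t1 - t0))


def high_plateau_duration(times, values, fraction: float) -> float:
    """Total time (minutes) the series spends at or above
    ``fraction * max``, with linear interpolation at threshold crossings."""
    if not 0 < fraction < 1:
        raise UsageError("fraction must be in (0, 1)")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise UsageError("empty series")
    vmax = float(values.max())
    if vmax <= 0:
        return 0.0
    thr = fraction * vmax
    above = values >= thr
    total = 0.0
    for k in range(len(values) - 1):
        dt = times[k + 1] - times[k]
        v0, v1 = values[k], values[k + 1]
        if above[k] and above[k + 1]:
            total += dt
        elif above[k] != above[k + 1] and v0 != v1:
            frac_inside = abs((v0 if above[k] else v1) - thr) / abs(v1 - v0)
            total += dt * frac_inside
    return float(total)


def peak_metrics(times, values,
                 min_prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
                 plateau_fraction: float = 0.5) -> PeakMetrics:
    """Bundle the standard features of one series."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    peaks = tuple(find_local_maxima(times, values, min_prominence_fraction))
    imax = int(np.argmax(values))
    return PeakMetrics(
        peaks=peaks,
        global_max=Peak(float(times[imax]), float(values[imax])),
        half_max_decay_time=half_max_decay_time(times, values),
        plateau_duration_at_fraction=high_plateau_duration(times, values, plateau_fraction),
        plateau_fraction=plateau_fraction,
    )
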