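"""Population doubling time from daily viability-assay reads.

During exponential growth, log2(background-corrected signal) is linear in
time with slope 1/Td doublings per hour, so an ordinary least-squares fit of
log2(signal) on time gives Td = 1/slope directly (regressing on log2 rather
than ln keeps the slope unit-transparent). Because cultures eventually leave
the exponential phase, the fit is restricted to a data-driven exponential
window: the plateau end of the series is trimmed until the window is
log-linear (r^2 >= 0.98) and its final increment still carries at least half
the window's average slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DomainError, InsufficientDataError, NoGrowthError

R2_MIN = 0.98
PLATEAU_SLOPE_FRACTION = 0.5


@dataclass
class GrowthFit:
    td_h: float
    window: tuple[float, float]
    r_squared: float
    slope: float  # log2 doublings per hour
    n_reads: int


def _ols_log2(times: np.ndarray, signals: np.ndarray):
    res = sps.linregress(times, np.log2(signals))
    return res.slope, res.intercept, res.rvalue ** 2


def exponential_window(times, signals) -> tuple[float, float]:
    """Select the exponential-phase time window.

    Starting from the full range, the last read is dropped while the final
    increment's slope falls below half the current window slope (plateau) or
    the window's log-linear r^2 is below 0.98, keeping at least 3 reads. If
    no qualifying window exists the full range is used with a warning.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(signals, dtype=float)
    if len(t) < 4:
        warnings.warn("fewer than 4 reads; using the full time range")
        return float(t.min()), float(t.max())
    if np.any(s <= 0):
        raise DomainError("signals must be positive after background correction")

    order = np.argsort(t)
    t, s = t[order], s[order]
    ut = np.unique(t)
    hi = len(ut)
    while hi >= 3:
        mask = t <= ut[hi - 1]
        slope, _, r2 = _ols_log2(t[mask], s[mask])
        # slope of the final inter-read increment (on per-time means)
        m_last = t == ut[hi - 1]
        m_prev = t == ut[hi - 2]
        inc = (np.log2(s[m_last].mean()) - np.log2(s[m_prev].mean())) / (
            ut[hi - 1] - ut[hi - 2])
        if r2 >= R2_MIN and (slope <= 0 or inc >= PLATEAU_SLOPE_FRACTION * slope):
            return float(ut[0]), float(ut[hi - 1])
        hi -= 1
    warnings.warn("no exponential window met the criteria; using the full range")
    return float(ut[0]), float(ut[-1])


def fit_doubling_time(times, signals, window: tuple[float, float] | None = None) -> GrowthFit:
    """OLS of log2(signal) on time within the exponential window; Td = 1/slope.

    ``signals`` must be background-corrected and positive. Raises
    :class:`NoGrowthError` when the fitted slope is not positive.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(signals, dtype=float)
    if len(t) != len(s):
        raise DomainError("times and signals must have equal length")
    if len(t) < 3:
        raise InsufficientDataError("doubling-time fit needs >= 3 reads")
    if np.any(s <= 0):
        raise DomainError("signals must be positive after background correction")
    if window is None:
        window = exponential_window(t, s)
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3:
        raise InsufficientDataError("fewer than 3 reads inside the window")
    slope, _, r2 = _ols_log2(t[mask], s[mask])
    if slope <= 0:
        raise NoGrowthError("no positive growth detected (slope <= 0)")
    return GrowthFit(td_h=1.0 / slope, window=(float(lo), float(hi)),
                     r_squared=float(r2), slope=float(slope),
                     n_reads=int(mask.sum()))
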