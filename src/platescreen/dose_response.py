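"""Conventional dose-response metrics: 4PL fit, absolute IC50, Emax, AUC.

The viability curve is a four-parameter log-logistic

    V(c) = bottom + (top - bottom) / (1 + (c / ec50)^hill)

fitted by trust-region least squares on log10 concentration with multi-start
initialization. ``top`` is free but bounded in [50, 150] because suboptimal
controls produce curves starting above 100% viability, which a fixed-top
model would hide.

IC50 is *absolute*: the smallest concentration where the fitted curve crosses
50% of matched control, inverted in closed form. When the curve never reaches
50% inside the tested range, the result is the typed sentinel
:data:`NOT_REACHED` — never an arbitrary large number — matching the
reporting convention of screens whose least-sensitive lines simply do not
reach half-maximal inhibition.

AUC is the trapezoidal integral of mean viability/100 over log10(c),
normalized by the tested log-range, so a flat 100% series scores exactly 1
and values are comparable across drugs with different grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError
from .normalize import ViabilitySeries


class _NotReached:
    """Sentinel: the defining threshold is never crossed in the tested range."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NOT_REACHED"

    def __str__(self) -> str:
        return "NR"


NOT_REACHED = _NotReached()


@dataclass
class DoseResponseFit:
    top: float
    bottom: float
    ec50: float     # relative EC50 (curve inflection)
    hill: float
    rss: float
    converged: bool
    n_points: int

    def predict(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(c > 0, (c / self.ec50) ** self.hill, 0.0)
        return self.bottom + (self.top - self.bottom) / (1.0 + ratio)


@dataclass
class PotencyResult:
    ic50: float | _NotReached
    emax: float
    auc: float


_BOUNDS_LO = np.array([50.0, -10.0, -np.inf, 0.1])   # top, bottom, log10 ec50, hill
_BOUNDS_HI = np.array([150.0, 100.0, np.inf, 10.0])


def fit_viability_curve(series: ViabilitySeries) -> DoseResponseFit:
    """Least-squares 4PL fit on replicate-level points.

    Requires >= 4 distinct concentrations. An all-identical series returns a
    flat fit (top = bottom = mean) with ``converged`` true; IC50 downstream
    is then NOT_REACHED.
    """
    concs = series.concentrations
    if len(concs) < 4:
        raise InsufficientDataError(
            f"4PL fit needs >= 4 distinct concentrations, got {len(concs)}"
        )
    c_all, v_all = [], []
    for p in series.points:
        c_all.extend([p.concentration] * p.n)
        v_all.extend(p.values)
    c_all = np.asarray(c_all, dtype=float)
    v_all = np.asarray(v_all, dtype=float)
    logc = np.log10(c_all)

    if np.ptp(v_all) < 1e-12:
        m = float(v_all.mean())
        return DoseResponseFit(m, m, float(np.sqrt(concs[0] * concs[-1])), 1.0,
                               0.0, True, len(concs))

    def resid(theta):
        top, bottom, logec50, hill = theta
        pred = bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - logec50)))
        return pred - v_all

    top0 = float(np.clip(series.means.max(), 50.0, 150.0))
    bottom0 = float(np.clip(series.means.min(), -10.0, 100.0))
    lo, hi = _BOUNDS_LO.copy(), _BOUNDS_HI.copy()
    lo[2], hi[2] = np.log10(concs[0]) - 2.0, np.log10(concs[-1]) + 2.0

    best = None
    for logec0 in np.linspace(np.log10(concs[0]), np.log10(concs[-1]), 5):
        for hill0 in (0.5, 1.0, 2.0):
            x0 = np.clip(np.array([top0, bottom0, logec0, hill0]), lo, hi)
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            if best is None or res.cost < best.cost - 1e-12:
                best = res
    top, bottom, logec50, hill = best.x
    if bottom > top:  # orientation guard; the 4PL with hill > 0 is decreasing
        top, bottom = bottom, top
    return DoseResponseFit(float(top), float(bottom), float(10.0 ** logec50),
                           float(hill), float(2.0 * best.cost),
                           bool(best.success), len(concs))


def ic50(fit: DoseResponseFit, c_range: tuple[float, float]) -> float | _NotReached:
    """Absolute IC50: smallest c in ``c_range`` with V(c) = 50, in closed form.

    NOT_REACHED when 50% lies outside the (bottom, top) span or the crossing
    falls outside the tested range.
    """
    c_min, c_max = c_range
    if not (fit.bottom < 50.0 < fit.top):
        return NOT_REACHED
    c = fit.ec50 * ((fit.top - 50.0) / (50.0 - fit.bottom)) ** (1.0 / fit.hill)
    if not (c_min <= c <= c_max):
        return NOT_REACHED
    return float(c)


def emax(series: ViabilitySeries) -> float:
    """Mean viability at the highest tested concentration (%)."""
    if not series.points:
        raise InsufficientDataError("emax needs a nonempty series")
    return series.points[-1].mean


def auc(series: ViabilitySeries) -> float:
    """Normalized trapezoidal area under viability/100 over log10(c)."""
    concs = series.concentrations
    if len(concs) < 2:
        raise InsufficientDataError("auc needs >= 2 distinct concentrations")
    logc = np.log10(concs)
    area = np.trapezoid(series.means / 100.0, logc)
    return float(area / (logc[-1] - logc[0]))


def potency(series: ViabilitySeries, fit: DoseResponseFit | None = None) -> PotencyResult:
    """IC50/Emax/AUC bundle for one condition."""
    if fit is None:
        fit = fit_viability_curve(series)
    concs = series.concentrations
    return PotencyResult(
        ic50=ic50(fit, (float(concs[0]), float(concs[-1]))),
        emax=emax(series),
        auc=auc(series),
    )
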