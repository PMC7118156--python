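"""Growth-rate-inhibition dose-response metrics: GR curve fit, GR50, GRmax,
GR_AOC.

The GR curve is the sigmoid

    GR(c) = gr_inf + (1 - gr_inf) / (1 + (c / gec50)^h_gr)

with GR(0) = 1 and asymptote gr_inf in [-1, 1]; -1 is the physical
complete-kill limit. A sigmoid is accepted over a constant fit only when an
F-test for its two extra parameters is significant at alpha = 0.05; otherwise
the fit is flagged flat and GR50 is NOT_REACHED.

GRmax here is the GR value at the maximal tested concentration (typically
negative for cytotoxic drugs) — screens report it as the efficacy analogue of
Emax even though the GR value at top dose is the *minimal* GR measured. A
``variant`` switch averages the top two concentrations instead. GR_AOC is the
normalized trapezoidal area over the curve, 1 - GR, integrated on log10(c):
0 for no effect everywhere, approaching 2 for complete kill everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .errors import InsufficientDataError
from .dose_response import NOT_REACHED, _NotReached
from .normalize import GRSeries


@dataclass
class GRFit:
    gr_inf: float | None
    gec50: float | None
    h_gr: float | None
    flat: bool
    rss: float
    gr_mean: float  # constant-model level; the curve itself when flat
    n_points: int

    def predict(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        if self.flat:
            return np.full_like(c, self.gr_mean, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(c > 0, (c / self.gec50) ** self.h_gr, 0.0)
        return self.gr_inf + (1.0 - self.gr_inf) / (1.0 + ratio)


@dataclass
class GRResult:
    gr50: float | _NotReached
    gr_max: float
    gr_aoc: float


def fit_gr_curve(series: GRSeries, alpha: float = 0.05) -> GRFit:
    """Least-squares GR sigmoid fit with flat-fit fallback.

    GR replicate values below -1 (possible when noise drives a fully killed
    well below background) are kept for fitting, but the fitted asymptote is
    bounded at -1.
    """
    concs = series.concentrations
    if len(concs) < 4:
        raise InsufficientDataError(
            f"GR fit needs >= 4 distinct concentrations, got {len(concs)}"
        )
    c_all, g_all = [], []
    for p in series.points:
        c_all.extend([p.concentration] * p.n)
        g_all.extend(p.values)
    c_all = np.asarray(c_all, dtype=float)
    g_all = np.asarray(g_all, dtype=float)
    if not np.all(np.isfinite(g_all)):
        raise InsufficientDataError("GR values must be finite")
    logc = np.log10(c_all)
    n = len(g_all)

    g_mean = float(g_all.mean())
    rss0 = float(np.sum((g_all - g_mean) ** 2))

    lo = np.array([-1.0, np.log10(concs[0]) - 2.0, 0.1])
    hi = np.array([1.0, np.log10(concs[-1]) + 2.0, 10.0])

    def resid(theta):
        gr_inf, logec50, h = theta
        pred = gr_inf + (1.0 - gr_inf) / (1.0 + 10.0 ** (h * (logc - logec50)))
        return pred - g_all

    best = None
    for logec0 in np.linspace(np.log10(concs[0]), np.log10(concs[-1]), 5):
        for h0 in (0.5, 1.0, 2.0):
            x0 = np.clip(np.array([max(-1.0, min(1.0, g_all.min())), logec0, h0]),
                         lo, hi)
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            if best is None or res.cost < best.cost - 1e-12:
                best = res
    rss1 = float(2.0 * best.cost)

    # F-test: does the 2-extra-parameter sigmoid beat the constant?
    flat = True
    if rss0 <= 1e-18:
        flat = True  # data are constant; the sigmoid adds nothing
    elif n > 3:
        if rss1 <= 1e-300:
            flat = False
        else:
            f = ((rss0 - rss1) / 2.0) / (rss1 / (n - 3))
            p = float(stats.f.sf(f, 2, n - 3)) if f > 0 else 1.0
            flat = p >= alpha
    if flat:
        return GRFit(None, None, None, True, rss0, g_mean, len(concs))
    gr_inf, logec50, h = best.x
    return GRFit(float(gr_inf), float(10.0 ** logec50), float(h), False,
                 rss1, g_mean, len(concs))


def gr50(fit: GRFit, c_range: tuple[float, float] | None = None) -> float | _NotReached:
    """Concentration where the fitted curve crosses GR = 0.5, in closed form:
    gec50 * (0.5 / (0.5 - gr_inf))^(1/h_gr); NOT_REACHED when the asymptote
    stays at or above 0.5, the fit is flat, or the crossing lies outside the
    tested range."""
    if fit.flat or fit.gr_inf >= 0.5:
        return NOT_REACHED
    c = fit.gec50 * (0.5 / (0.5 - fit.gr_inf)) ** (1.0 / fit.h_gr)
    if c_range is not None and not (c_range[0] <= c <= c_range[1]):
        return NOT_REACHED
    return float(c)


def gr_max(series: GRSeries, variant: str = "single_top") -> float:
    """GR at maximal tested concentration ("single_top", default) or the mean
    over the top two concentrations ("top_two")."""
    if not series.points:
        raise InsufficientDataError("gr_max needs a nonempty series")
    if variant == "top_two" and len(series.points) >= 2:
        return float(np.mean([series.points[-1].mean, series.points[-2].mean]))
    return series.points[-1].mean


def gr_aoc(series: GRSeries) -> float:
    """Normalized trapezoidal area over the measured mean GR curve."""
    concs = series.concentrations
    if len(concs) < 2:
        raise InsufficientDataError("gr_aoc needs >= 2 distinct concentrations")
    logc = np.log10(concs)
    area = np.trapezoid(1.0 - series.means, logc)
    return float(area / (logc[-1] - logc[0]))


def gr_result(series: GRSeries, fit: GRFit | None = None,
              grmax_variant: str = "single_top") -> GRResult:
    if fit is None:
        fit = fit_gr_curve(series)
    concs = series.concentrations
    return GRResult(
        gr50=gr50(fit, (float(concs[0]), float(concs[-1]))),
        gr_max=gr_max(series, grmax_variant),
        gr_aoc=gr_aoc(series),
    )
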