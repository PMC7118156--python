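"""Raw absorbance -> percent viability and growth-rate-inhibition (GR) values.

Percent viability is computed exactly as

    100% x (treated - background) / (matched DMSO control - background)

with background and matched-control means pooled per plate: matched controls
are plate-local by design (evaporation makes controls on other plates
incomparable). Values are deliberately not clipped to [0, 100] — starts above
100% are a diagnostic the QC layer must be able to see.

The GR transform corrects for differing division rates using the untreated
cell number at treatment time (t=0):

    GR = 2^( log2(x/x0) / log2(x_ctrl/x0) ) - 1

where x, x0 and x_ctrl are background-corrected signals used as cell-count
proxies. GR = 1 means unimpeded growth, 0 cytostasis, negative values net
cell loss, and -1 complete kill.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateControlError, NoGrowthError, DomainError
from .io import Screen, matched_control_mean
from .wells import WellRole


def percent_viability(treated: float, matched_control: float, background: float) -> float:
    """100% x (treated - background) / (matched control - background)."""
    if matched_control <= background:
        raise DegenerateControlError(
            f"matched control ({matched_control}) does not exceed background "
            f"({background}); viability undefined"
        )
    return 100.0 * (treated - background) / (matched_control - background)


def gr_value(x: float, x0: float, x_ctrl: float) -> float:
    """Growth-rate inhibition from background-corrected count proxies."""
    if x_ctrl <= x0:
        raise NoGrowthError(
            f"control ({x_ctrl}) did not outgrow the t=0 reference ({x0}); "
            "GR metrics are undefined for this screen"
        )
    if x <= 0 or x0 <= 0:
        raise DomainError("gr_value requires positive count proxies")
    return float(2.0 ** (np.log2(x / x0) / np.log2(x_ctrl / x0)) - 1.0)


@dataclass
class ViabilityPoint:
    """Replicate viability (or GR) values at one concentration."""

    concentration: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sem(self) -> float:
        """Standard error of the mean: sample SD / sqrt(n)."""
        if self.n < 2:
            return float("nan")
        return float(self.values.std(ddof=1) / np.sqrt(self.n))


@dataclass
class ViabilitySeries:
    """Per-condition dose series of replicate viability values (%)."""

    cell_line: str
    drug: str
    treat_time_h: float
    conc_unit: str
    points: list[ViabilityPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p.concentration)
        concs = self.concentrations
        if np.any(np.diff(concs) <= 0):
            raise DomainError("concentrations must be strictly increasing")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p.concentration for p in self.points])

    @property
    def means(self) -> np.ndarray:
        return np.array([p.mean for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_line": self.cell_line, "drug": self.drug,
            "treat_time_h": self.treat_time_h,
            "conc": self.concentrations, "conc_unit": self.conc_unit,
            "mean": self.means,
            "sem": [p.sem for p in self.points],
            "n": [p.n for p in self.points],
        })


class GRSeries(ViabilitySeries):
    """Same container, but values are GR values rather than % viability."""


def _plate_background(plate) -> float:
    return plate.background_mean()


def build_series(
    screen: Screen,
    cell_line: str,
    drug: str,
    treat_time_h: float | None = None,
    decimal_places: int = 4,
) -> ViabilitySeries:
    """Assemble the per-concentration viability series for one condition.

    Each treated replicate is normalized against the mean of its own plate's
    matched DMSO controls and the mean of its own plate's background wells,
    then replicates are pooled across plates and experiments.
    """
    per_conc: dict[float, list[float]] = {}
    unit = None
    tt = None
    for plate in screen.plates():
        df = plate.wells
        sel = (df["role"] == WellRole.TREATED.value) & \
              (df["cell_line"] == cell_line) & (df["drug"] == drug)
        if treat_time_h is not None:
            sel &= df["treat_time_h"].astype(float) == float(treat_time_h)
        treated = df[sel]
        if treated.empty:
            continue
        bg = _plate_background(plate)
        for _, row in treated.iterrows():
            ctrl = matched_control_mean(float(row["dmso_pct"]), plate,
                                        decimal_places=decimal_places)
            v = percent_viability(float(row["signal"]), ctrl, bg)
            per_conc.setdefault(float(row["conc"]), []).append(v)
            unit = row["conc_unit"]
            tt = float(row["treat_time_h"])
    if not per_conc:
        raise KeyError(f"no treated wells for ({cell_line!r}, {drug!r})")
    points = [ViabilityPoint(c, np.array(v)) for c, v in sorted(per_conc.items())]
    return ViabilitySeries(cell_line, drug, tt, unit, points)


def _x0_reference(screen: Screen, cell_line: str, experiment: str | None) -> float:
    """Background-corrected mean of the untreated t=0 reference wells.

    Pooled per experiment when an ``experiment`` column is present (the
    default), otherwise across the whole screen.
    """
    vals = []
    for plate in screen.plates():
        df = plate.wells
        sel = (df["role"] == WellRole.UNTREATED_REFERENCE.value) & \
              (df["cell_line"] == cell_line)
        if experiment is not None and "experiment" in df.columns:
            sel &= df["experiment"] == experiment
        ref = df[sel]
        if ref.empty:
            continue
        bg = _plate_background(plate)
        vals.extend(ref["signal"].astype(float) - bg)
    if not vals:
        raise NoGrowthError(
            f"no untreated_reference wells found for cell line {cell_line!r}"
        )
    return float(np.mean(vals))


def build_gr_series(
    screen: Screen,
    cell_line: str,
    drug: str,
    treat_time_h: float | None = None,
    x0_scope: str = "experiment",
    decimal_places: int = 4,
) -> GRSeries:
    """Assemble the per-concentration GR series for one condition.

    ``x0_scope`` controls where the t=0 reference comes from: "experiment"
    (default; reference wells of the same experiment, typically on a sister
    plate) or "screen" (pooled over all reference wells for the cell line).
    """
    per_conc: dict[float, list[float]] = {}
    unit = None
    tt = None
    x0_cache: dict[str | None, float] = {}
    for plate in screen.plates():
        df = plate.wells
        sel = (df["role"] == WellRole.TREATED.value) & \
              (df["cell_line"] == cell_line) & (df["drug"] == drug)
        if treat_time_h is not None:
            sel &= df["treat_time_h"].astype(float) == float(treat_time_h)
        treated = df[sel]
        if treated.empty:
            continue
        bg = _plate_background(plate)
        if x0_scope == "experiment" and "experiment" in df.columns:
            exp = str(df["experiment"].iloc[0])
        else:
            exp = None
        if exp not in x0_cache:
            x0_cache[exp] = _x0_reference(screen, cell_line, exp)
        x0 = x0_cache[exp]
        for _, row in treated.iterrows():
            ctrl = matched_control_mean(float(row["dmso_pct"]), plate,
                                        decimal_places=decimal_places)
            x = float(row["signal"]) - bg
            # noise can push a fully-killed well below background; floor the
            # proxy so the GR value stays finite (far below -1, kept for fits)
            x = max(x, 1e-6 * (ctrl - bg))
            g = gr_value(x, x0, ctrl - bg)
            per_conc.setdefault(float(row["conc"]), []).append(g)
            unit = row["conc_unit"]
            tt = float(row["treat_time_h"])
    if not per_conc:
        raise KeyError(f"no treated wells for ({cell_line!r}, {drug!r})")
    points = [ViabilityPoint(c, np.array(v)) for c, v in sorted(per_conc.items())]
    return GRSeries(cell_line, drug, tt, unit, points)


def series_table(series_list: list[ViabilitySeries]) -> pd.DataFrame:
    """Tidy CSV-ready table of one or more dose series."""
    frames = [s.to_frame() for s in series_list]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
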