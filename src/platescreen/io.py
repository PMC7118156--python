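"""Long-format plate-table I/O and the Screen/PlateRead data model.

The interchange format is a UTF-8 CSV with a header row and one record per
(plate_id, well, read_time_h). Required columns::

    plate_id, well, row, col, role, cell_line, drug, conc, conc_unit,
    dmso_pct, treat_time_h, read_time_h, signal

Optional screen-level metadata columns (seeding_density, medium, fbs_pct,
resazurin_pct, resazurin_incubation_h, storage_condition, experiment) and any
unknown columns are preserved. Signals are raw plate-reader absorbance in
arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRecordError,
    MissingMatchedControlError,
    ParseError,
    SchemaError,
    ValidationError,
)
from .wells import WellAddress, WellRole

REQUIRED_COLUMNS = [
    "plate_id", "well", "row", "col", "role", "cell_line", "drug",
    "conc", "conc_unit", "dmso_pct", "treat_time_h", "read_time_h", "signal",
]

METADATA_COLUMNS = [
    "seeding_density", "medium", "fbs_pct", "resazurin_pct",
    "resazurin_incubation_h", "storage_condition",
]

_NUMERIC_COLUMNS = ["conc", "dmso_pct", "treat_time_h", "read_time_h", "signal"]

#: Decimal places used when matching treated-well DMSO % to vehicle controls.
DMSO_DECIMALS = 4


@dataclass
class PlateRead:
    """All wells of one plate at one read time."""

    plate_id: str
    read_time_h: float
    wells: pd.DataFrame  # one row per well, REQUIRED_COLUMNS subset

    def signals(self, role: WellRole | str | None = None) -> np.ndarray:
        df = self.wells
        if role is not None:
            df = df[df["role"] == str(getattr(role, "value", role))]
        return df["signal"].to_numpy(dtype=float)

    def background_mean(self) -> float:
        bg = self.signals(WellRole.BACKGROUND)
        if bg.size == 0:
            raise ValidationError(f"plate {self.plate_id!r} has no background wells")
        return float(bg.mean())


@dataclass
class Screen:
    """An ordered collection of plate reads plus screen-level metadata."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    def plates(self) -> Iterator[PlateRead]:
        for (pid, rt), df in self.data.groupby(["plate_id", "read_time_h"], sort=True):
            yield PlateRead(str(pid), float(rt), df)

    def plate(self, plate_id: str, read_time_h: float | None = None) -> PlateRead:
        df = self.data[self.data["plate_id"] == plate_id]
        if read_time_h is not None:
            df = df[df["read_time_h"] == read_time_h]
        if df.empty:
            raise KeyError(f"no records for plate {plate_id!r}")
        times = df["read_time_h"].unique()
        if len(times) > 1:
            raise KeyError(
                f"plate {plate_id!r} has reads at {sorted(times)}; pass read_time_h"
            )
        return PlateRead(plate_id, float(times[0]), df)

    def conditions(self) -> pd.DataFrame:
        """Distinct (cell_line, drug, treat_time_h) among treated wells."""
        t = self.data[self.data["role"] == WellRole.TREATED.value]
        return (
            t[["cell_line", "drug", "treat_time_h"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )


def _parse_numeric(df: pd.DataFrame, col: str) -> pd.Series:
    # float() is correctly rounded, so written signals round-trip bit-exactly
    # (pandas' fast strtod can be off by one ulp)
    raw = df[col]
    out = np.empty(len(raw), dtype=float)
    for i, v in enumerate(raw):
        s = str(v).strip()
        if s == "":
            out[i] = 0.0
            continue
        try:
            out[i] = float(s)
        except ValueError:
            raise ParseError(
                f"non-numeric value {v!r} in column {col!r} at data row {i + 1}"
            ) from None
    return pd.Series(out, index=raw.index)


def read_screen(path, decimal_places: int = DMSO_DECIMALS, validate: bool = True) -> Screen:
    """Read and validate a long-format plate table.

    Raises :class:`SchemaError` for missing columns, :class:`ParseError`
    (citing the 1-based data row) for unparseable numbers,
    :class:`DuplicateRecordError` for repeated (plate_id, well, read_time_h)
    keys, and :class:`MissingMatchedControlError` when a treated well lacks a
    vehicle control at its DMSO concentration.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in _NUMERIC_COLUMNS:
        df[col] = _parse_numeric(df, col)
    df["col"] = _parse_numeric(df, "col").astype(int)

    dup = df.duplicated(subset=["plate_id", "well", "read_time_h"], keep=False)
    if dup.any():
        key = df.loc[dup, ["plate_id", "well", "read_time_h"]].iloc[0].tolist()
        raise DuplicateRecordError(
            f"duplicate record for plate={key[0]!r} well={key[1]!r} read_time={key[2]}"
        )

    valid_roles = {r.value for r in WellRole}
    bad_roles = set(df["role"]) - valid_roles
    if bad_roles:
        raise SchemaError(f"unknown role value(s): {sorted(bad_roles)}")

    # normalise well strings and cross-check against row/col
    for i, (well, row, col) in enumerate(zip(df["well"], df["row"], df["col"])):
        addr = WellAddress.from_string(well)
        if addr.row != row.upper() or addr.col != int(col):
            raise SchemaError(
                f"well {well!r} disagrees with row/col ({row!r}, {col}) at data row {i + 1}"
            )
    df["well"] = [str(WellAddress.from_string(w)) for w in df["well"]]
    df["row"] = df["row"].str.upper()

    metadata = {}
    for col in METADATA_COLUMNS:
        if col in df.columns:
            vals = df[col].unique()
            if len(vals) == 1:
                metadata[col] = vals[0]

    screen = Screen(df, metadata)
    if validate:
        validate_screen(screen, decimal_places=decimal_places)
    return screen


def write_screen(screen: Screen, path) -> None:
    """Write a screen back to CSV; numeric columns round-trip bit-identically."""
    cols = REQUIRED_COLUMNS + [c for c in screen.data.columns if c not in REQUIRED_COLUMNS]
    screen.data.to_csv(path, index=False, columns=cols)


def validate_screen(screen: Screen, decimal_places: int = DMSO_DECIMALS) -> None:
    """Check structural invariants: finite nonnegative signals, background
    wells on every plate, and a matched vehicle control for every treated
    DMSO concentration on the same plate."""
    df = screen.data
    sig = df["signal"].to_numpy(dtype=float)
    if not np.all(np.isfinite(sig)) or np.any(sig < 0):
        raise ValidationError("signals must be finite and >= 0")
    for plate in screen.plates():
        roles = set(plate.wells["role"])
        if WellRole.TREATED.value in roles:
            if WellRole.BACKGROUND.value not in roles:
                raise ValidationError(
                    f"plate {plate.plate_id!r} has treated wells but no background wells"
                )
            treated = plate.wells[plate.wells["role"] == WellRole.TREATED.value]
            for dmso in np.unique(np.round(treated["dmso_pct"].astype(float), decimal_places)):
                if match_control(float(dmso), plate, decimal_places=decimal_places).empty:
                    raise MissingMatchedControlError(
                        f"plate {plate.plate_id!r}: no vehicle control at "
                        f"{dmso}% DMSO for treated wells at that concentration"
                    )


def match_control(
    dmso_pct: float, plate: PlateRead, decimal_places: int = DMSO_DECIMALS
) -> pd.DataFrame:
    """Vehicle-control wells on ``plate`` whose DMSO % matches ``dmso_pct``.

    Both sides are rounded to ``decimal_places`` before comparison, which
    absorbs the floating-point arithmetic of a dilution series.
    """
    ctrl = plate.wells[plate.wells["role"] == WellRole.VEHICLE_CONTROL.value]
    want = round(float(dmso_pct), decimal_places)
    got = np.round(ctrl["dmso_pct"].astype(float), decimal_places)
    return ctrl[got == want]


def matched_control_mean(
    dmso_pct: float, plate: PlateRead, decimal_places: int = DMSO_DECIMALS
) -> float:
    ctrl = match_control(dmso_pct, plate, decimal_places=decimal_places)
    if ctrl.empty:
        raise MissingMatchedControlError(
            f"plate {plate.plate_id!r}: no vehicle control at {dmso_pct}% DMSO"
        )
    return float(ctrl["signal"].astype(float).mean())
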