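"""96-well plate geometry: well addresses, roles, and the perimeter set.

The layout convention is the industry standard for 96-well microplates:
letter rows A-H (top to bottom) and 1-based columns 1-12. The canonical
string form zero-pads the column ("A01"). Perimeter wells (rows A and H,
columns 1 and 12) are prone to evaporation-driven signal inflation (the
"edge effect") and are treated specially throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .errors import ValidationError

ROWS = "ABCDEFGH"
N_COLS = 12

_WELL_RE = re.compile(r"^([A-Ha-h])\s*0*([1-9]|1[0-2])$")


@dataclass(frozen=True, order=True)
class WellAddress:
    """A single well on a 96-well plate, e.g. ``WellAddress("B", 7)``."""

    row: str
    col: int

    def __post_init__(self) -> None:
        row = self.row.upper()
        if row not in ROWS:
            raise ValidationError(f"well row must be one of A-H, got {self.row!r}")
        if not (1 <= int(self.col) <= N_COLS):
            raise ValidationError(f"well column must be 1-12, got {self.col!r}")
        object.__setattr__(self, "row", row)
        object.__setattr__(self, "col", int(self.col))

    @classmethod
    def from_string(cls, s: str) -> "WellAddress":
        m = _WELL_RE.match(s.strip())
        if m is None:
            raise ValidationError(f"not a valid 96-well address: {s!r}")
        return cls(m.group(1), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.col:02d}"

    @property
    def index(self) -> int:
        """Row-major 0-based index on the 8x12 grid (A01 -> 0, H12 -> 95)."""
        return ROWS.index(self.row) * N_COLS + (self.col - 1)

    @property
    def is_perimeter(self) -> bool:
        return self.row in ("A", "H") or self.col in (1, N_COLS)


class WellRole(str, Enum):
    """What a well contains and how the analysis treats it.

    * ``treated`` - cells plus drug at a nonzero concentration.
    * ``vehicle_control`` - cells plus solvent (DMSO) only, matched to a dose.
    * ``background`` - medium/resazurin without cells; defines the signal floor.
    * ``untreated_reference`` - untreated cells read at treatment time t=0,
      used as the x0 reference for growth-rate-corrected (GR) metrics.
    * ``excluded`` - wells deliberately taken out of the assay (e.g. PBS-filled
      perimeter wells); retained in files for auditability, never analysed.
    """

    TREATED = "treated"
    VEHICLE_CONTROL = "vehicle_control"
    BACKGROUND = "background"
    UNTREATED_REFERENCE = "untreated_reference"
    EXCLUDED = "excluded"


def all_wells() -> list[WellAddress]:
    """All 96 wells in row-major order (A01 ... H12)."""
    return [WellAddress(r, c) for r in ROWS for c in range(1, N_COLS + 1)]


def perimeter_wells() -> frozenset[WellAddress]:
    """The 36 wells in rows A and H plus columns 1 and 12."""
    return frozenset(w for w in all_wells() if w.is_perimeter)


def interior_wells() -> list[WellAddress]:
    """The 60 non-perimeter wells (rows B-G, columns 2-11), row-major."""
    return [w for w in all_wells() if not w.is_perimeter]
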