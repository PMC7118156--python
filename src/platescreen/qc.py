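"""Assay quality-control metrics: Z-factor, signal window (SW), CV.

All three are computed from raw absorbance of treated cells (positive group)
versus background controls (negative group), with pass cutoffs Z > 0.4,
SW > 2 and CV < 20% (strict inequalities exactly as printed on screening QC
dashboards). A well-optimized resazurin assay typically sits far inside
these bounds (Z > 0.75, SW > 10, CV < 5%).

Two signal-window conventions circulate in HTS validation guidelines; the
default is the replicate-corrected form

    SW = ( |mu_max - mu_min| - 3(sd_max/sqrt(n_max) + sd_min/sqrt(n_min)) )
         / (sd_max/sqrt(n_max))

with the uncorrected variant (raw SDs in place of SEMs) behind a switch,
because the choice changes pass/fail near the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError
from .io import Screen
from .wells import WellRole

Z_CUTOFF = 0.4
SW_CUTOFF = 2.0
CV_CUTOFF = 20.0


@dataclass
class GroupStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DomainError("sd must be >= 0")

    @classmethod
    def from_values(cls, values) -> "GroupStats":
        v = np.asarray(values, dtype=float)
        if v.size < 1:
            raise InsufficientDataError("empty group")
        sd = float(v.std(ddof=1)) if v.size >= 2 else 0.0
        return cls(float(v.mean()), sd, int(v.size))


def z_factor(positive: GroupStats, negative: GroupStats) -> float:
    """Z = 1 - 3(sd_p + sd_n)/|mu_p - mu_n|; at most 1, and exactly 1 only
    when both groups are noiseless."""
    if positive.mean == negative.mean:
        raise DomainError("Z-factor undefined: group means are equal")
    return 1.0 - 3.0 * (positive.sd + negative.sd) / abs(positive.mean - negative.mean)


def cv(group: GroupStats) -> float:
    """Coefficient of variation, 100 * sd / mean (%)."""
    if group.mean <= 0:
        raise DomainError("CV undefined for non-positive mean")
    return 100.0 * group.sd / group.mean


def signal_window(max_g: GroupStats, min_g: GroupStats,
                  replicate_corrected: bool = True) -> float:
    """Signal window between the high- and low-signal groups.

    Returns +inf (degenerate, flagged by callers) when the high-signal group
    has zero spread.
    """
    if replicate_corrected:
        se_max = max_g.sd / math.sqrt(max_g.n)
        se_min = min_g.sd / math.sqrt(min_g.n)
    else:
        se_max, se_min = max_g.sd, min_g.sd
    if se_max == 0:
        return math.inf
    return (abs(max_g.mean - min_g.mean) - 3.0 * (se_max + se_min)) / se_max


@dataclass
class QCReport:
    """Per-plate / per-condition QC table with pass flags and any warnings."""

    table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def all_pass(self) -> bool:
        if self.table.empty:
            return False
        return bool(self.table[["pass_z", "pass_sw", "pass_cv"]].all().all())


def _qc_row(plate_id, condition, pos: GroupStats, neg: GroupStats,
            replicate_corrected: bool) -> dict:
    z = z_factor(pos, neg)
    sw = signal_window(pos, neg, replicate_corrected)
    c = cv(pos)
    return {
        "plate_id": plate_id, "condition": condition,
        "z": z, "sw": sw, "cv": c,
        "pass_z": z > Z_CUTOFF, "pass_sw": sw > SW_CUTOFF, "pass_cv": c < CV_CUTOFF,
        "n_pos": pos.n, "n_neg": neg.n,
    }


def _top_signal_group(treated: pd.DataFrame) -> np.ndarray:
    """Replicate signals at the concentration with the highest mean signal —
    the group that defines the assay's dynamic range against background.
    Pooling across doses would fold the dose-response itself into sd_p."""
    means = treated.groupby("conc")["signal"].mean()
    best = means.idxmax()
    return treated.loc[treated["conc"] == best, "signal"].to_numpy(dtype=float)


def qc_report(screen: Screen, replicate_corrected: bool = True,
              per_concentration: bool = True) -> QCReport:
    """QC metrics per plate (dynamic-range treated group vs background) and,
    optionally, per tested concentration, plus a screen-pooled row.

    Groups with fewer than 2 replicates are skipped with a warning recorded
    in the report.
    """
    rows: list[dict] = []
    warnings: list[str] = []
    all_pos: list[float] = []
    all_neg: list[float] = []
    for plate in screen.plates():
        treated_df = plate.wells[plate.wells["role"] == WellRole.TREATED.value]
        neg_v = plate.signals(WellRole.BACKGROUND)
        if treated_df.empty:
            continue
        pos_v = _top_signal_group(treated_df)
        if pos_v.size < 2 or neg_v.size < 2:
            warnings.append(
                f"plate {plate.plate_id!r}: group too small for QC "
                f"(n_pos={pos_v.size}, n_neg={neg_v.size}); skipped"
            )
            continue
        all_pos.extend(pos_v)
        all_neg.extend(neg_v)
        pos = GroupStats.from_values(pos_v)
        neg = GroupStats.from_values(neg_v)
        rows.append(_qc_row(plate.plate_id, "plate", pos, neg, replicate_corrected))
        if per_concentration:
            treated = plate.wells[plate.wells["role"] == WellRole.TREATED.value]
            for conc, grp in treated.groupby("conc"):
                v = grp["signal"].to_numpy(dtype=float)
                if v.size < 2:
                    warnings.append(
                        f"plate {plate.plate_id!r} conc {conc}: n < 2; skipped"
                    )
                    continue
                rows.append(_qc_row(plate.plate_id, f"conc={conc:g}",
                                    GroupStats.from_values(v), neg,
                                    replicate_corrected))
    if len(all_pos) >= 2 and len(all_neg) >= 2:
        rows.append(_qc_row("__screen__", "pooled",
                            GroupStats.from_values(all_pos),
                            GroupStats.from_values(all_neg),
                            replicate_corrected))
    cols = ["plate_id", "condition", "z", "sw", "cv",
            "pass_z", "pass_sw", "pass_cv", "n_pos", "n_neg"]
    return QCReport(pd.DataFrame(rows, columns=cols), warnings)
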